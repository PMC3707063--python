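"""Differential comparison and hybrid mode-of-action classification.

Pairwise differential testing between libraries uses Fisher's exact test on
pooled counts against library sizes; the hybrid mode of gene action is
classified against the mid-parent value (MPV = mean of the two parental
rates), with reciprocal-hybrid consistency required, following the
statsmodels Model/Results idiom: ``HybridModeModel(...).fit()`` returns a
``HybridModeResults`` with per-gene calls, mode tallies, a BH false-discovery
rate for the mode tests, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree

from .config import AnalysisConfig
from .quantify import LibraryCounts

MODES = ("additive", "up", "down", "conserved", "discordant")


def diff_test(count_a: int, libsize_a: int, count_b: int, libsize_b: int):
    """Two-sided Fisher's exact test between two library-normalized counts.

    The 2x2 table is [[a, A - a], [b, B - b]] for counts a, b and library
    sizes A, B. Returns (p-value, fold change a-rate / b-rate); when either
    count is zero both counts get +0.5 continuity so the fold change stays
    finite.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if libsize_a <= 0 or libsize_b <= 0:
        raise ValueError("library sizes must be positive")
    p = stats.fisher_exact(
        [[count_a, libsize_a - count_a], [count_b, libsize_b - count_b]]
    ).pvalue
    a, b = (count_a, count_b)
    if count_a == 0 or count_b == 0:
        a, b = count_a + 0.5, count_b + 0.5
    fc = (a / libsize_a) / (b / libsize_b)
    return float(p), float(fc)


def replicate_filter(
    rep_counts: pd.DataFrame,
    libsizes: pd.Series,
    p_replicate: float = 0.05,
) -> set[str]:
    """Drop genes with a significant discrepancy between any replicate pair.

    ``rep_counts`` is genes x replicate libraries; a gene is retained iff no
    replicate pair differs at p < ``p_replicate`` under :func:`diff_test`.
    With a single replicate everything passes, with a warning.
    """
    reps = list(rep_counts.columns)
    if len(reps) < 2:
        warnings.warn("single replicate: replicate filter is a pass-through",
                      stacklevel=2)
        return set(rep_counts.index)
    retained = set()
    for gene, row in rep_counts.iterrows():
        ok = True
        for r1, r2 in combinations(reps, 2):
            p, _ = diff_test(int(row[r1]), int(libsizes[r1]),
                             int(row[r2]), int(libsizes[r2]))
            if p < p_replicate:
                ok = False
                break
        if ok:
            retained.add(gene)
    return retained


def detected_in_both_filter(calls_a: set, calls_b: set) -> set:
    """Genes detected in both compared samples (the comparable set)."""
    return set(calls_a) & set(calls_b)


# ------------------------------------------------------------- mode model


@dataclass
class HybridModeResults:
    """Per-gene mode-of-action calls and mode tallies.

    ``calls`` columns: mode, plus per-hybrid rate, MPV rate, p-values for
    the hybrid-vs-MPV and parent-vs-parent tests. The per-hybrid labels are
    merged: reciprocal hybrids disagreeing -> "discordant" (excluded from
    the mode lists).
    """

    calls: pd.DataFrame
    config: AnalysisConfig
    metadata: dict = field(default_factory=dict)

    @property
    def mode_counts(self) -> pd.Series:
        return self.calls["mode"].value_counts().reindex(MODES, fill_value=0)

    def genes(self, mode: str) -> list[str]:
        return list(self.calls.index[self.calls["mode"] == mode])

    def fdr(self, mode: str) -> float | None:
        """Benjamini-Hochberg FDR of the listed mode's hybrid-vs-MPV calls."""
        pv = self.calls["p_h12"].to_numpy(float)
        q = stats.false_discovery_control(pv, method="bh")
        sel = (self.calls["mode"] == mode).to_numpy()
        return float(q[sel].max()) if sel.any() else None

    def summary(self) -> str:
        lines = [
            "Hybrid mode-of-action classification (vs mid-parent value)",
            f"  genes tested:        {len(self.calls)}",
            f"  mode test cutoff:    P < {self.config.p_mode}",
        ]
        for m in MODES:
            lines.append(f"  {m:<12} {self.mode_counts[m]:>8}")
        for m in ("up", "down", "additive"):
            f = self.fdr(m)
            if f is not None:
                lines.append(f"  FDR({m}) = {f:.4g}")
        return "\n".join(lines)


class HybridModeModel:
    """Classify hybrid gene action as additive / up / down vs the MPV.

    Built from pooled per-genotype counts (genes x {P1, P2, H12, H21}) and
    per-genotype pooled library sizes. Each hybrid is tested against its
    expected MPV count (mean parental rate x hybrid library size) with
    Fisher's exact test at ``config.p_mode``: significantly above -> up,
    below -> down; non-significant with parents significantly different ->
    additive; otherwise conserved. Reciprocal hybrids must agree, else the
    gene is discordant.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        libsizes: pd.Series,
        config: AnalysisConfig | None = None,
        parent_cols: tuple[str, str] = ("P1", "P2"),
        hybrid_cols: tuple[str, str] = ("H12", "H21"),
    ):
        self.config = config or AnalysisConfig()
        need = set(parent_cols) | set(hybrid_cols)
        missing = need - set(counts.columns)
        if missing:
            raise ValueError(f"missing genotype columns: {sorted(missing)}")
        if missing := need - set(libsizes.index):
            raise ValueError(f"missing library sizes: {sorted(missing)}")
        self.counts = counts
        self.libsizes = libsizes
        self.parent_cols = parent_cols
        self.hybrid_cols = hybrid_cols

    @classmethod
    def from_libraries(
        cls,
        libs: dict[str, LibraryCounts],
        organ: str,
        config: AnalysisConfig | None = None,
        genes=None,
    ) -> "HybridModeModel":
        """Pool replicates per genotype for one organ and build the model."""
        by_geno: dict[str, list[LibraryCounts]] = {}
        for lc in libs.values():
            if lc.organ == organ:
                by_geno.setdefault(lc.genotype, []).append(lc)
        counts = pd.DataFrame(
            {g: sum(lc.counts for lc in v) for g, v in by_geno.items()}
        )
        libsizes = pd.Series(
            {g: sum(lc.total_mapped for lc in v) for g, v in by_geno.items()}
        )
        if genes is not None:
            counts = counts.loc[sorted(genes)]
        return cls(counts, libsizes, config=config)

    def fit(self) -> HybridModeResults:
        cfg = self.config
        p1c, p2c = self.parent_cols
        h1c, h2c = self.hybrid_cols
        l1, l2 = int(self.libsizes[p1c]), int(self.libsizes[p2c])
        lh = {h: int(self.libsizes[h]) for h in (h1c, h2c)}
        rows = []
        for gene, row in self.counts.iterrows():
            c1, c2 = int(row[p1c]), int(row[p2c])
            p_par, _ = diff_test(c1, l1, c2, l2)
            mpv_rate = 0.5 * (c1 / l1 + c2 / l2)
            rec = {"p_parents": p_par, "mpv_rate": mpv_rate}
            labels = []
            for h in (h1c, h2c):
                ch = int(row[h])
                mpv_count = int(round(mpv_rate * lh[h]))
                p_h, _ = diff_test(ch, lh[h], mpv_count, lh[h])
                rate_h = ch / lh[h]
                if p_h < cfg.p_mode:
                    lab = "up" if rate_h > mpv_rate else "down"
                elif p_par < cfg.p_mode:
                    lab = "additive"
                else:
                    lab = "conserved"
                labels.append(lab)
                rec[f"rate_{h.lower()}"] = rate_h
                rec[f"p_{h.lower()}"] = p_h
                rec[f"label_{h.lower()}"] = lab
            rec["mode"] = labels[0] if labels[0] == labels[1] else "discordant"
            rows.append(pd.Series(rec, name=gene))
        calls = pd.DataFrame(rows)
        return HybridModeResults(
            calls=calls, config=cfg,
            metadata={"additive_requires_parent_difference": True,
                      "parents": self.parent_cols, "hybrids": self.hybrid_cols},
        )


# --------------------------------------------------- concurrence & correlation


@dataclass
class ConcurrenceResult:
    n_marked: int
    n_same_direction: int

    @property
    def defined(self) -> bool:
        return self.n_marked > 0

    @property
    def percent(self) -> float | None:
        if not self.defined:
            return None
        return 100.0 * self.n_same_direction / self.n_marked


def concurrence_frequency(
    mark_direction: pd.Series, expr_direction: pd.Series
) -> ConcurrenceResult:
    """Share of differentially-marked genes also differentially expressed
    in the same direction. Directions are arbitrary but shared labels
    (e.g. "A-higher"/"B-higher"). Denominator: all diff-marked genes."""
    n_marked = len(mark_direction)
    common = mark_direction.index.intersection(expr_direction.index)
    same = int((mark_direction.loc[common] == expr_direction.loc[common]).sum())
    return ConcurrenceResult(n_marked=n_marked, n_same_direction=same)


@dataclass
class CorrelationResult:
    r: float | None
    pvalue: float | None
    n: int

    @property
    def defined(self) -> bool:
        return self.r is not None


def mark_expression_correlation(
    mark_l2fc: pd.Series, expr_l2fc: pd.Series
) -> CorrelationResult:
    """Pearson correlation of paired log2 fold changes (mark vs expression)."""
    common = mark_l2fc.index.intersection(expr_l2fc.index)
    x = mark_l2fc.loc[common].to_numpy(float)
    y = expr_l2fc.loc[common].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired fold changes")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(None, None, len(x))
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


# --------------------------------------------------------------- clustering


@dataclass
class SampleClustering:
    linkage: np.ndarray
    samples: list[str]

    def top_split(self) -> tuple[set[str], set[str]]:
        """The two sample groups separated by the root of the dendrogram."""
        tree = to_tree(self.linkage)
        left = {self.samples[i] for i in tree.left.pre_order()}
        right = {self.samples[i] for i in tree.right.pre_order()}
        return left, right

    def newick(self) -> str:
        def walk(node):
            if node.is_leaf():
                return self.samples[node.id]
            return (f"({walk(node.left)},{walk(node.right)})"
                    f":{node.dist:.6g}")
        return walk(to_tree(self.linkage)) + ";"


def hierarchical_cluster(matrix: pd.DataFrame) -> SampleClustering:
    """Ward-linkage / Euclidean-distance clustering of the sample columns.

    The input is genes x samples, restricted by the caller to genes
    significant in at least one pairwise comparison. Columns are sorted by
    sample id first so ties break deterministically.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    samples = sorted(matrix.columns)
    X = matrix[samples].to_numpy(float).T  # samples x genes
    Z = linkage(X, method="ward", metric="euclidean")
    return SampleClustering(linkage=Z, samples=list(samples))
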