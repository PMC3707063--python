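"""Allele-specific expression in hybrids.

Parental SNPs are discriminated from parental pileups; allele-specific read
counts at those SNPs are tested for bias with an exact two-sided binomial
test (null: the two parental alleles contribute equally); gene-level calls
sum the allele counts over a gene's SNPs. Concordance of bias direction is
compared between reciprocal hybrids and between organs.

``AllelicBiasModel(table).fit()`` returns an ``AllelicBiasResults`` with
SNP- and gene-level calls and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig


def call_parental_snps(
    pileup1: pd.DataFrame,
    pileup2: pd.DataFrame,
    min_depth: int = 10,
    max_minor: float = 0.1,
) -> pd.DataFrame:
    """Discriminating SNPs between two effectively homozygous parents.

    Pileups are frames indexed by (chrom, pos) with columns A, C, G, T of
    per-base read counts, aligned on shared coordinates. A position is a SNP
    when both parents reach ``min_depth``, each parent's minor-allele
    fraction is <= ``max_minor``, and the two major alleles differ.
    Positions failing any rule are skipped; the result carries counts of
    skipped positions in ``.attrs['n_skipped']``.
    """
    bases = ["A", "C", "G", "T"]
    common = pileup1.index.intersection(pileup2.index)
    p1 = pileup1.loc[common, bases].to_numpy(float)
    p2 = pileup2.loc[common, bases].to_numpy(float)
    d1, d2 = p1.sum(axis=1), p2.sum(axis=1)
    maj1, maj2 = p1.argmax(axis=1), p2.argmax(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor1 = 1 - p1.max(axis=1) / np.where(d1 > 0, d1, 1)
        minor2 = 1 - p2.max(axis=1) / np.where(d2 > 0, d2, 1)
    ok = (
        (d1 >= min_depth) & (d2 >= min_depth)
        & (minor1 <= max_minor) & (minor2 <= max_minor)
        & (maj1 != maj2)
    )
    out = pd.DataFrame(
        {
            "p1_allele": np.array(bases)[maj1[ok]],
            "p2_allele": np.array(bases)[maj2[ok]],
        },
        index=common[ok],
    )
    out.attrs["n_skipped"] = int((~ok).sum())
    return out


@dataclass
class BiasTestResult:
    pvalue: float | None

    @property
    def defined(self) -> bool:
        return self.pvalue is not None


def binomial_bias_test(count1: int, count2: int) -> BiasTestResult:
    """Exact two-sided binomial p-value under equal allelic contribution.

    The two-sided mass sums every outcome whose probability under
    Binomial(n, 0.5) does not exceed that of the observed outcome (the
    minimum-likelihood rule — exact, symmetric, never above 1). Both counts
    zero is undefined.
    """
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be non-negative")
    n = count1 + count2
    if n == 0:
        return BiasTestResult(None)
    # scipy's two-sided binomtest implements exactly the minimum-likelihood rule
    return BiasTestResult(float(stats.binomtest(count1, n, 0.5).pvalue))


@dataclass
class BiasCall:
    unit: str           # snp or gene id
    pvalue: float | None
    count1: int
    count2: int
    biased: bool
    direction: str | None  # "parent1" / "parent2" when biased, else None


def gene_bias_call(snp_counts: pd.DataFrame, alpha: float = 0.05) -> BiasCall:
    """Gene-level bias call from its SNPs' allele counts (columns count1, count2).

    Allele counts are summed over SNPs — the sufficient statistic under a
    shared per-gene bias — then tested as one binomial.
    """
    genes = snp_counts["gene_id"].unique() if "gene_id" in snp_counts else [None]
    if len(genes) > 1:
        raise ValueError(f"SNPs map to multiple genes: {sorted(genes)}")
    c1 = int(snp_counts["count1"].sum())
    c2 = int(snp_counts["count2"].sum())
    res = binomial_bias_test(c1, c2)
    biased = res.defined and res.pvalue < alpha
    direction = None
    if biased:
        direction = "parent1" if c1 > c2 else "parent2"
    return BiasCall(unit=str(genes[0]), pvalue=res.pvalue, count1=c1, count2=c2,
                    biased=biased, direction=direction)


@dataclass
class AllelicBiasResults:
    """SNP- and gene-level allelic-bias calls for one or more libraries."""

    snp_calls: pd.DataFrame   # per snp x library: counts, pvalue, biased, direction
    gene_calls: pd.DataFrame  # per gene x library: summed counts, pvalue, biased, direction
    alpha: float

    def biased_genes(self, library: str) -> pd.DataFrame:
        gc = self.gene_calls
        return gc[(gc["library"] == library) & gc["biased"]]

    def summary(self) -> str:
        lines = [f"Allelic-bias calls (binomial test, P < {self.alpha})"]
        for lib, sub in self.gene_calls.groupby("library"):
            ns = self.snp_calls[(self.snp_calls["library"] == lib)
                                & self.snp_calls["biased"]]
            lines.append(
                f"  {lib}: {len(ns)} biased SNPs, "
                f"{int(sub['biased'].sum())} biased genes of {len(sub)}"
            )
            d = sub.loc[sub["biased"], "direction"].value_counts()
            lines.append(
                f"    direction: parent1={int(d.get('parent1', 0))} "
                f"parent2={int(d.get('parent2', 0))}"
            )
        return "\n".join(lines)


class AllelicBiasModel:
    """Binomial allelic-bias testing over an allelic count table.

    The table has one row per SNP with columns snp_id, gene_id and, per
    hybrid library L, ``{L}_p1`` / ``{L}_p2`` allele read counts (the layout
    the simulator writes). ``fit()`` tests every SNP and every gene (allele
    counts summed over its SNPs) in every library.
    """

    def __init__(self, table: pd.DataFrame, config: AnalysisConfig | None = None):
        self.table = table
        self.config = config or AnalysisConfig()
        self.libraries = sorted(
            {c[:-3] for c in table.columns if c.endswith("_p1")}
        )
        if not self.libraries:
            raise ValueError("no *_p1/*_p2 count columns found")

    def fit(self) -> AllelicBiasResults:
        alpha = self.config.p_ase
        snp_rows, gene_rows = [], []
        for lib in self.libraries:
            c1 = self.table[f"{lib}_p1"].to_numpy(int)
            c2 = self.table[f"{lib}_p2"].to_numpy(int)
            pv = _binom_pvalues(c1, c2)
            biased = (pv < alpha) & ~np.isnan(pv)
            direction = np.where(biased, np.where(c1 > c2, "parent1", "parent2"), None)
            snp_rows.append(pd.DataFrame({
                "snp_id": self.table["snp_id"], "gene_id": self.table["gene_id"],
                "library": lib, "count1": c1, "count2": c2,
                "pvalue": pv, "biased": biased, "direction": direction,
            }))
            agg = (
                pd.DataFrame({"gene_id": self.table["gene_id"], "c1": c1, "c2": c2})
                .groupby("gene_id", sort=True).sum()
            )
            gpv = _binom_pvalues(agg["c1"].to_numpy(), agg["c2"].to_numpy())
            gbiased = (gpv < alpha) & ~np.isnan(gpv)
            gdir = np.where(gbiased, np.where(agg["c1"] > agg["c2"],
                                              "parent1", "parent2"), None)
            gene_rows.append(pd.DataFrame({
                "gene_id": agg.index, "library": lib,
                "count1": agg["c1"].to_numpy(int), "count2": agg["c2"].to_numpy(int),
                "pvalue": gpv, "biased": gbiased, "direction": gdir,
            }))
        return AllelicBiasResults(
            snp_calls=pd.concat(snp_rows, ignore_index=True),
            gene_calls=pd.concat(gene_rows, ignore_index=True),
            alpha=alpha,
        )


def _binom_pvalues(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided binomial p-values (minimum-likelihood rule)."""
    c1 = np.asarray(c1, dtype=int)
    c2 = np.asarray(c2, dtype=int)
    n = c1 + c2
    out = np.full(len(c1), np.nan)
    # group by n: one pmf table per total serves all SNPs with that depth
    for total in np.unique(n):
        if total == 0:
            continue
        idx = np.where(n == total)[0]
        k = np.arange(total + 1)
        pmf = stats.binom.pmf(k, total, 0.5)
        # two-sided mass: sum of outcomes no more likely than the observed
        obs = pmf[c1[idx]]
        out[idx] = np.array(
            [pmf[pmf <= o * (1 + 1e-10)].sum() for o in obs]
        )
    return np.minimum(out, 1.0)


# ------------------------------------------------------------- concordance


@dataclass
class ConcordanceStats:
    n_common: int
    n_same_direction: int
    percent: float | None          # rounded to one decimal
    pearson_r: float | None
    defined: bool = field(init=False)

    def __post_init__(self) -> None:
        self.defined = self.n_common > 0


def direction_percent(n_same: int, n_common: int) -> float:
    """Share of common biased genes agreeing in direction, one-decimal percent."""
    if n_common <= 0:
        raise ValueError("n_common must be positive")
    return round(100.0 * n_same / n_common, 1)


def concordance_stats(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> ConcordanceStats:
    """Direction-of-bias agreement between two gene-level call sets.

    Both frames are gene-level calls (one library each) as produced by
    ``AllelicBiasModel.fit()``; only genes biased in BOTH sets enter the
    comparison. The correlation is Pearson's r on the paired allelic
    log2(count1/count2) ratios of those genes (+0.5 continuity).
    """
    a = calls_a.loc[calls_a["biased"].astype(bool)].set_index("gene_id")
    b = calls_b.loc[calls_b["biased"].astype(bool)].set_index("gene_id")
    common = a.index.intersection(b.index)
    n_common = len(common)
    if n_common == 0:
        return ConcordanceStats(0, 0, None, None)
    same = int((a.loc[common, "direction"] == b.loc[common, "direction"]).sum())
    la = np.log2((a.loc[common, "count1"] + 0.5) / (a.loc[common, "count2"] + 0.5))
    lb = np.log2((b.loc[common, "count1"] + 0.5) / (b.loc[common, "count2"] + 0.5))
    r = None
    if n_common >= 3 and la.std() > 0 and lb.std() > 0:
        r = float(stats.pearsonr(la, lb)[0])
    return ConcordanceStats(n_common, same, direction_percent(same, n_common), r)
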