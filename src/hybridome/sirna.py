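"""siRNA clusters and transposable-element enrichment.

An siRNA cluster is a region containing at least ``min_reads`` (default 6)
small-RNA reads of one size class, each separated from its nearest neighbor
by at most ``max_gap`` (default 200 nt). Clusters and methylated regions are
assigned to the TE class covering at least half the region's length, and
per-class chi-square tests compare the assigned proportions against each
class's share of genomic TE bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TE_CLASSES, interval_overlap, merge_intervals


@dataclass
class SirnaCluster:
    chrom: str
    start: int
    end: int
    size_class: int
    n_reads: int


def call_sirna_clusters(
    reads: pd.DataFrame,
    size_class: int,
    min_reads: int = 6,
    max_gap: int = 200,
    gap_mode: str = "start",
) -> list[SirnaCluster]:
    """Single-linkage chaining of same-size reads into clusters.

    Reads (chrom, start, end, length, copies) are filtered to ``size_class``,
    expanded by ``copies``, and sorted; consecutive reads join one chain iff
    their gap is <= ``max_gap``. The gap is measured start-to-start
    (``gap_mode="start"``) or from the upstream read's end to the downstream
    start (``"end"``). Chains with >= ``min_reads`` reads become clusters
    spanning min start to max end; duplicate-position reads each count.
    """
    if gap_mode not in ("start", "end"):
        raise ValueError("gap_mode must be 'start' or 'end'")
    sel = reads[reads["length"] == size_class]
    if len(sel) == 0:
        return []
    copies = sel["copies"].to_numpy(int) if "copies" in sel else np.ones(len(sel), int)
    rep = sel.loc[sel.index.repeat(copies)]
    clusters: list[SirnaCluster] = []
    for chrom, sub in rep.groupby("chrom", sort=True):
        starts = np.sort(sub["start"].to_numpy(int))
        ends = np.sort(sub["end"].to_numpy(int))
        if gap_mode == "start":
            gaps = np.diff(starts)
        else:
            gaps = starts[1:] - ends[:-1]
        breaks = np.where(gaps > max_gap)[0] + 1
        for chunk_s, chunk_e in zip(
            np.split(starts, breaks), np.split(ends, breaks)
        ):
            if len(chunk_s) >= min_reads:
                clusters.append(
                    SirnaCluster(chrom=str(chrom), start=int(chunk_s[0]),
                                 end=int(chunk_e.max()), size_class=size_class,
                                 n_reads=len(chunk_s))
                )
    return clusters


def clusters_to_frame(clusters: list[SirnaCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.chrom, c.start, c.end, c.size_class, c.n_reads) for c in clusters],
        columns=["chrom", "start", "end", "size_class", "n_reads"],
    )


def write_clusters_bed(clusters: list[SirnaCluster], path) -> None:
    df = clusters_to_frame(clusters)
    df["name"] = [f"siRNA{c.size_class}nt_{i}" for i, c in enumerate(clusters)]
    df[["chrom", "start", "end", "name", "n_reads"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def chromosomal_density(
    regions: pd.DataFrame, chrom_lengths: dict[str, int], bin_size: int
) -> dict[str, np.ndarray]:
    """Per-bin fraction of bp covered by the (possibly overlapping) regions."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    out = {}
    for chrom, clen in chrom_lengths.items():
        n_bins = int(np.ceil(clen / bin_size))
        edges_s = np.arange(n_bins) * bin_size
        edges_e = np.minimum(edges_s + bin_size, clen)
        sub = regions[regions["chrom"] == chrom]
        ms, me = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        cov = interval_overlap(edges_s, edges_e, ms, me)
        out[chrom] = cov / (edges_e - edges_s)
    return out


def write_bedgraph(track: dict[str, np.ndarray], bin_size: int, path) -> None:
    with open(path, "w") as fh:
        for chrom, vals in track.items():
            for i, v in enumerate(vals):
                fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


def assign_te_overlap(
    regions: pd.DataFrame,
    tes: pd.DataFrame,
    min_frac: float = 0.5,
) -> pd.Series:
    """Assign each region the TE class covering >= ``min_frac`` of its length.

    Same-class TE annotations are merged before measuring overlap. If
    several classes clear the fraction, the largest overlap wins; exact
    ties break by alphabetical class code (deterministic). Regions with no
    qualifying class get the label "unassigned".
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0,1]")
    flat = regions.reset_index(drop=True)
    lengths = (flat["end"] - flat["start"]).to_numpy(float)
    overlaps = np.zeros((len(flat), len(TE_CLASSES)))
    for j, cls in enumerate(TE_CLASSES):
        csub = tes[tes["class_code"] == cls]
        for chrom, rsub in flat.groupby("chrom"):
            tsub = csub[csub["chrom"] == chrom]
            ms, me = merge_intervals(tsub["start"].to_numpy(), tsub["end"].to_numpy())
            overlaps[rsub.index.to_numpy(), j] = interval_overlap(
                rsub["start"].to_numpy(), rsub["end"].to_numpy(), ms, me
            )
    qualifies = overlaps >= min_frac * lengths[:, None]
    masked = np.where(qualifies, overlaps, -1.0)
    # argmax takes the first (alphabetically smallest) class on exact ties
    best = masked.argmax(axis=1)
    labels = np.where(qualifies.any(axis=1),
                      np.array(TE_CLASSES)[best], "unassigned")
    return pd.Series(labels, index=regions.index, name="class_code")


def te_background_fractions(tes: pd.DataFrame) -> pd.Series:
    """Each class's share of genomic TE bp (merged within class)."""
    bp = {}
    for cls in TE_CLASSES:
        sub = tes[tes["class_code"] == cls]
        total = 0
        for _, csub in sub.groupby("chrom"):
            ms, me = merge_intervals(csub["start"].to_numpy(), csub["end"].to_numpy())
            total += int((me - ms).sum())
        bp[cls] = total
    s = pd.Series(bp, dtype=float)
    return s / s.sum()


@dataclass
class TeEnrichmentResult:
    table: pd.DataFrame  # per class: observed, obs_fraction, bg_fraction, chi2, pvalue, direction, low_count

    def enriched(self, alpha: float = 0.001) -> list[str]:
        t = self.table
        return list(t.index[(t.direction == "over") & (t.pvalue < alpha)])

    def depleted(self, alpha: float = 0.001) -> list[str]:
        t = self.table
        return list(t.index[(t.direction == "under") & (t.pvalue < alpha)])


def te_enrichment_test(
    assigned: pd.Series, background: pd.Series
) -> TeEnrichmentResult:
    """Per-class 1-df chi-square of assigned counts vs the genomic background.

    ``assigned`` holds per-region class labels ("unassigned" rows are
    dropped); ``background`` the per-class genomic fractions (summing to 1).
    Each class is tested class-vs-rest: chi2 = sum (O - E)^2 / E over the
    two cells. Classes whose expected count is below 5 are flagged.
    """
    counts = assigned[assigned != "unassigned"].value_counts()
    total = int(counts.sum())
    if total < 1:
        raise ValueError("no regions assigned to any TE class")
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background fractions must sum to 1")
    rows = {}
    for cls in background.index:
        obs = int(counts.get(cls, 0))
        exp = total * float(background[cls])
        if exp in (0.0, float(total)):
            chi2, p = 0.0, 1.0
        else:
            chi2 = (obs - exp) ** 2 / exp + ((total - obs) - (total - exp)) ** 2 / (total - exp)
            p = float(stats.chi2.sf(chi2, df=1))
        rows[cls] = {
            "observed": obs,
            "obs_fraction": obs / total,
            "bg_fraction": float(background[cls]),
            "chi2": float(chi2),
            "pvalue": p,
            "direction": "over" if obs >= exp else "under",
            "low_count": exp < 5,
        }
    return TeEnrichmentResult(table=pd.DataFrame(rows).T.infer_objects())


@dataclass
class WindowCorrelation:
    r: float | None
    pvalue: float | None
    n_windows: int

    @property
    def defined(self) -> bool:
        return self.r is not None


def sirna_methylation_correlation(
    sirna: pd.DataFrame,
    methylation: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
) -> WindowCorrelation:
    """Pearson correlation of log siRNA vs methylation abundance per window.

    Abundance is the weight-summed bp coverage of each feature set in shared
    genomic windows; windows where both are zero are dropped, and the
    correlation runs on log1p-scaled values.
    """
    x = _window_weights(sirna, chrom_lengths, window)
    y = _window_weights(methylation, chrom_lengths, window)
    keep = (x > 0) | (y > 0)
    x, y = np.log1p(x[keep]), np.log1p(y[keep])
    if keep.sum() < 3:
        raise ValueError("need at least 3 shared windows with signal")
    if np.std(x) == 0 or np.std(y) == 0:
        return WindowCorrelation(None, None, int(keep.sum()))
    r, p = stats.pearsonr(x, y)
    return WindowCorrelation(float(r), float(p), int(keep.sum()))


def _window_weights(regions: pd.DataFrame, chrom_lengths, window) -> np.ndarray:
    vals = []
    w = regions["weight"] if "weight" in regions else (
        regions["n_reads"] if "n_reads" in regions else pd.Series(1, index=regions.index)
    )
    for chrom, clen in chrom_lengths.items():
        n_bins = int(np.ceil(clen / window))
        acc = np.zeros(n_bins)
        sub = regions[regions["chrom"] == chrom]
        for start, end, wt in zip(sub["start"], sub["end"], w.loc[sub.index]):
            mid = (start + end) // 2
            acc[min(int(mid // window), n_bins - 1)] += wt * (end - start)
        vals.append(acc)
    return np.concatenate(vals)
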