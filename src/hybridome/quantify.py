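"""Per-library quantification.

RPKM normalization (reads per kilobase of exon model — or genic/genomic
region — per million mapped reads), exon-vs-intron active-gene calling,
randomization-threshold calling of modification-positive genes, metagene
coverage profiles anchored at TSS/TTS, and genic/intergenic assignment of
modified regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, interval_overlap, merge_intervals


@dataclass
class LibraryCounts:
    """Read counts for one sequencing library (genotype x organ x assay x rep)."""

    library_id: str
    genotype: str
    organ: str
    assay: str
    replicate: int
    counts: pd.Series  # feature -> non-negative integer count
    total_mapped: int

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.total_mapped < int(self.counts.sum()):
            raise ValueError("total_mapped smaller than the sum of feature counts")


def compute_rpkm(counts: LibraryCounts, exon_lengths: pd.Series) -> pd.Series:
    """RPKM = count * 1e9 / (feature length in bp * total mapped reads)."""
    missing = counts.counts.index.difference(exon_lengths.index)
    if len(missing):
        raise ValueError(f"missing exon lengths for genes: {sorted(missing)[:10]}")
    if (exon_lengths.loc[counts.counts.index] <= 0).any():
        raise ValueError("exon lengths must be positive")
    if counts.total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    L = exon_lengths.loc[counts.counts.index].astype(float)
    return counts.counts * 1e9 / (L * counts.total_mapped)


def rpkm_matrix(libs: dict[str, LibraryCounts], exon_lengths: pd.Series) -> pd.DataFrame:
    return pd.DataFrame({k: compute_rpkm(v, exon_lengths) for k, v in libs.items()})


@dataclass
class ActiveGeneCalls:
    active: set[str]
    cutoff: float
    method: str  # "intron-quantile" or "rpkm-fallback"


def call_active_genes(
    exon_cov: pd.Series,
    intron_cov: pd.Series,
    quantile: float = 0.95,
    fallback_cutoff: float = 1.0,
) -> ActiveGeneCalls:
    """Call a gene transcribed when its exon coverage clears the intron background.

    The empirical cutoff is the ``quantile``-th percentile of the pooled
    intron-coverage distribution (introns measure background read-through);
    a gene is active iff its mean exon coverage exceeds that cutoff. With no
    intron data at all, falls back to a fixed coverage cutoff with a warning.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0,1)")
    intron_cov = intron_cov.dropna()
    if len(intron_cov) == 0:
        warnings.warn(
            "no genes with introns: falling back to fixed coverage cutoff",
            stacklevel=2,
        )
        cutoff, method = float(fallback_cutoff), "rpkm-fallback"
    else:
        cutoff = float(np.quantile(intron_cov.to_numpy(float), quantile))
        method = "intron-quantile"
    active = set(exon_cov.index[exon_cov > cutoff])
    return ActiveGeneCalls(active=active, cutoff=cutoff, method=method)


@dataclass
class ModificationCallSet:
    """Per-gene modification calls against a randomization-derived threshold."""

    calls: pd.DataFrame  # columns: count, threshold, called

    @property
    def called(self) -> set[str]:
        return set(self.calls.index[self.calls["called"]])


def call_modified_genes(
    genic_counts: pd.Series,
    gene_lengths: pd.Series,
    genome_length: int,
    total_reads: int,
    n_randomizations: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    n_length_bins: int = 10,
) -> ModificationCallSet:
    """Call modification-positive genes by a randomization threshold.

    The null places ``total_reads`` uniformly at random on the genome
    ``n_randomizations`` times and records the count landing in each gene.
    Genes are stratified into ``n_length_bins`` length deciles; within each
    bin the threshold is the (1 - alpha) quantile of the pooled null counts,
    and a gene is called iff its observed count exceeds its bin's threshold.
    Stratification keeps long genes from inheriting short-gene thresholds.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if n_randomizations < 100:
        raise ValueError("n_randomizations must be >= 100")
    genes = genic_counts.index
    L = gene_lengths.loc[genes].to_numpy(float)
    if L.sum() > genome_length:
        raise ValueError("gene lengths exceed genome length")
    rng = np.random.default_rng(seed)
    # uniform placement: per-randomization genic counts are multinomial over
    # (gene_1 ... gene_n, intergenic remainder)
    p = np.concatenate([L / genome_length, [1 - L.sum() / genome_length]])
    null = rng.multinomial(total_reads, p, size=n_randomizations)[:, :-1]

    n_bins = min(n_length_bins, max(1, len(genes)))
    bins = np.asarray(
        pd.qcut(L, q=n_bins, labels=False, duplicates="drop"), dtype=float
    )
    bins[np.isnan(bins)] = 0  # constant gene lengths collapse to one stratum
    thresholds = np.empty(len(genes))
    for b in np.unique(bins):
        mask = bins == b
        thresholds[mask] = np.quantile(null[:, mask].ravel(), 1 - alpha)
    obs = genic_counts.to_numpy(float)
    calls = pd.DataFrame(
        {"count": genic_counts.astype(int),
         "threshold": thresholds,
         "called": obs > thresholds},
        index=genes,
    )
    return ModificationCallSet(calls=calls)


def metagene_profile(
    coverage: dict[str, np.ndarray],
    ann: GenomeAnnotation,
    groups: dict[str, str] | pd.Series | None = None,
    flank: int = 1000,
    n_body_bins: int = 40,
    flank_bin: int = 50,
) -> tuple[pd.DataFrame, int]:
    """Mean coverage profiles over [TSS - flank, TTS + flank], length-normalized.

    Gene bodies are rescaled into ``n_body_bins`` bins; flanks use fixed
    ``flank_bin``-bp bins. Minus-strand genes are reversed so bin 0 is
    always the 5' end. ``groups`` maps gene -> group label (e.g. expression
    tertile); ungrouped genes form one group. Returns (group x bin matrix,
    number of genes skipped for being shorter than two body bins).
    """
    n_flank_bins = flank // flank_bin
    total_bins = n_body_bins + 2 * n_flank_bins
    if groups is None:
        groups = {g.gene_id: "all" for g in ann.genes}
    groups = dict(pd.Series(groups))
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    skipped = 0
    for g in ann.genes:
        if g.gene_id not in groups:
            continue
        cov = coverage[g.chrom]
        if g.length < 2 * n_body_bins:
            skipped += 1
            continue
        up = _binned(cov, g.start - flank, g.start, n_flank_bins)
        body = _binned(cov, g.start, g.end, n_body_bins)
        down = _binned(cov, g.end, g.end + flank, n_flank_bins)
        prof = np.concatenate([up, body, down])
        if g.strand == "-":
            prof = prof[::-1]
        lab = groups[g.gene_id]
        if lab not in sums:
            sums[lab] = np.zeros(total_bins)
            counts[lab] = 0
        sums[lab] += prof
        counts[lab] += 1
    mat = pd.DataFrame(
        {lab: sums[lab] / counts[lab] for lab in sums}
    ).T
    mat.columns = range(total_bins)
    return mat, skipped


def _binned(cov: np.ndarray, start: int, end: int, n_bins: int) -> np.ndarray:
    """Mean coverage in n_bins equal slices of [start, end), zero-padded off-chromosome."""
    edges = np.linspace(start, end, n_bins + 1)
    out = np.empty(n_bins)
    for i in range(n_bins):
        a, b = int(np.floor(edges[i])), int(np.ceil(edges[i + 1]))
        a2, b2 = max(a, 0), min(b, len(cov))
        out[i] = cov[a2:b2].mean() if b2 > a2 else 0.0
    return out


def expression_tertiles(expr: pd.Series) -> pd.Series:
    """Split genes with detected transcripts into equal-size low/mid/high groups."""
    detected = expr[expr > 0].rank(method="first")
    tert = pd.qcut(detected, q=3, labels=["low", "mid", "high"])
    return tert.astype(str)


@dataclass
class RegionClassification:
    labels: pd.Series  # per-region "genic" / "intergenic"
    genic_fraction: float | None
    intergenic_fraction: float | None

    @property
    def empty(self) -> bool:
        return len(self.labels) == 0


def classify_regions(regions: pd.DataFrame, ann: GenomeAnnotation) -> RegionClassification:
    """Label each region genic iff it overlaps any gene span by >= 1 bp."""
    if len(regions) == 0:
        return RegionClassification(pd.Series(dtype=object), None, None)
    gt = ann.gene_table()
    flat = regions.reset_index(drop=True)
    labels = np.full(len(flat), "intergenic", dtype=object)
    for chrom, sub in flat.groupby("chrom"):
        gsub = gt[gt.chrom == chrom]
        ms, me = merge_intervals(gsub.start.to_numpy(), gsub.end.to_numpy())
        ov = interval_overlap(sub.start.to_numpy(), sub.end.to_numpy(), ms, me)
        labels[sub.index.to_numpy()] = np.where(ov >= 1, "genic", "intergenic")
    labels = pd.Series(labels, index=regions.index)
    genic = float((labels == "genic").mean())
    return RegionClassification(labels, genic, 1.0 - genic)
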