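"""Synthetic data with planted ground truth.

Generates everything the analysis consumes — a genome annotation, read-count
tables for a 4-genotype x 2-organ x 3-replicate design, per-SNP parental
allele counts in hybrids, small-RNA reads emitted from designated TE classes,
and methylated regions — together with a truth record for every planted
effect, so downstream calls can be scored against what was simulated.

Counts are negative-binomial around genotype-specific means
(``var = m + dispersion * m**2``); hybrids inherit the mid-parent rate for
additive genes and deviate by a stated fold for planted up/down genes, with
both reciprocal hybrids sharing the planted mode. Replicates within a
genotype share one mean. Coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import TE_CLASSES, Gene, GenomeAnnotation
from .quantify import LibraryCounts

PARENT1 = "P1"
PARENT2 = "P2"
HYBRID12 = "H12"  # P1 x P2
HYBRID21 = "H21"  # P2 x P1 (reciprocal)
GENOTYPES = (PARENT1, PARENT2, HYBRID12, HYBRID21)
ORGANS = ("shoot", "root")

# Relative genome-wide abundance of each TE class, loosely mirroring a
# retrotransposon-dominated cereal genome (Gypsy > Copia >> DNA transposons).
TE_CLASS_MIX = {
    "RLG": 0.35, "RLC": 0.25, "RLX": 0.10, "RIL": 0.03, "RIX": 0.02,
    "DTA": 0.06, "DTC": 0.07, "DTH": 0.05, "DTM": 0.05, "DTT": 0.02,
}


@dataclass
class Design:
    """The crossing design: two parents, two reciprocal hybrids, two organs."""

    genotypes: tuple[str, ...] = GENOTYPES
    organs: tuple[str, ...] = ORGANS
    n_replicates: int = 3
    assay: str = "mRNA"

    def libraries(self):
        for g in self.genotypes:
            for o in self.organs:
                for r in range(1, self.n_replicates + 1):
                    yield g, o, r, f"{g}_{o}_{self.assay}_rep{r}"


@dataclass
class SimulationTruth:
    """Ground truth for every planted effect in one simulation."""

    modes: dict[str, str] = field(default_factory=dict)        # gene -> mode label
    parent_fold: dict[str, float] = field(default_factory=dict)  # P1/P2 rate ratio
    snp_bias: dict[str, float] = field(default_factory=dict)   # gene -> bias fraction
    emission: dict[str, float] = field(default_factory=dict)   # "CLASS:SIZE" -> rate
    methylation: dict[str, float] = field(default_factory=dict)

    def validate(self, gene_ids=None) -> None:
        ok = {"additive", "up", "down", "conserved"}
        bad = {m for m in self.modes.values() if m not in ok}
        if bad:
            raise ValueError(f"unknown mode labels: {bad}")
        if gene_ids is not None and set(self.modes) != set(gene_ids):
            raise ValueError("mode labels must cover every simulated gene exactly once")
        for g, b in self.snp_bias.items():
            if not 0 < b < 1:
                raise ValueError(f"bias fraction for {g} outside (0,1): {b}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"modes": self.modes, "parent_fold": self.parent_fold,
                 "snp_bias": self.snp_bias, "emission": self.emission,
                 "methylation": self.methylation},
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ------------------------------------------------------------------ genome


def make_genome(
    n_chrom: int,
    chrom_len: int,
    n_genes: int,
    te_density: float,
    seed: int,
    min_gene_len: int = 1000,
    max_gene_len: int = 6000,
) -> GenomeAnnotation:
    """Generate a genome annotation with non-overlapping genes and biased TEs.

    Genes get 1-10 exons each. TE classes are placed with class-specific
    spatial bias: Gypsy (RLG) concentrated in the middle ("pericentromeric")
    third of each chromosome, hAT/PIF-Harbinger (DTA/DTH) near genes, the
    rest uniform. ``te_density`` is the target fraction of genome covered
    by TE annotations (overlaps allowed, as in real repeat annotation).
    """
    if not 0 <= te_density <= 0.95:
        raise ValueError("te_density must lie in [0, 0.95]")
    chrom_len = int(chrom_len)
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}

    per_chrom = np.full(n_chrom, n_genes // n_chrom)
    per_chrom[: n_genes % n_chrom] += 1
    if n_genes and max_gene_len * per_chrom.max() > 0.7 * chrom_len:
        raise ValueError(
            f"cannot pack {per_chrom.max()} genes of up to {max_gene_len} bp "
            f"into a {chrom_len} bp chromosome (capacity limit: 70% of length)"
        )

    genes: list[Gene] = []
    gid = 0
    for ci, (cname, clen) in enumerate(chroms.items()):
        k = per_chrom[ci]
        if k == 0:
            continue
        # genes are depleted in the pericentromeric (middle) third, as in
        # a heterochromatin-rich cereal genome: 85% land in the outer thirds
        third = clen // 3
        regions = [(0, third), (third, 2 * third), (2 * third, clen)]
        shares = np.array([0.425, 0.15, 0.425])
        alloc = rng.multinomial(k, shares)
        for (r_lo, r_hi), k_r in zip(regions, alloc):
            if k_r == 0:
                continue
            lengths = rng.integers(min_gene_len, max_gene_len + 1, size=k_r)
            spare = (r_hi - r_lo) - int(lengths.sum())
            if spare < k_r + 1:
                raise ValueError(
                    f"cannot pack {k_r} genes ({int(lengths.sum())} bp) into a "
                    f"{r_hi - r_lo} bp chromosome segment"
                )
            gaps = rng.multinomial(spare, np.ones(k_r + 1) / (k_r + 1))
            starts = r_lo + np.cumsum(gaps[:-1]) + np.concatenate(
                [[0], np.cumsum(lengths[:-1])]
            )
            for j in range(k_r):
                gid += 1
                s, L = int(starts[j]), int(lengths[j])
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    Gene(f"gene{gid:05d}", cname, s, s + L, strand,
                         exons=_make_exons(rng, s, s + L))
                )

    tes = _make_tes(rng, chroms, genes, te_density)
    ann = GenomeAnnotation(chromosomes=chroms, genes=genes, tes=tes)
    ann.validate()
    return ann


def _make_exons(rng, start: int, end: int) -> list[tuple[int, int]]:
    """Partition [start, end) into 1-10 exons separated by introns >= 50 bp."""
    L = end - start
    max_exons = min(10, max(1, L // 200))
    k = int(rng.integers(1, max_exons + 1))
    if k == 1:
        return [(start, end)]
    # 2k-1 alternating segments (exon, intron, ..., exon), each >= 50 bp
    n_seg = 2 * k - 1
    w = rng.dirichlet(np.ones(n_seg))
    seg = 50 + np.floor(w * (L - 50 * n_seg)).astype(int)
    seg[-1] += L - seg.sum()
    bounds = start + np.concatenate([[0], np.cumsum(seg)])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)]


def _make_tes(rng, chroms, genes, te_density) -> pd.DataFrame:
    genome_len = sum(chroms.values())
    target_bp = te_density * genome_len
    if target_bp <= 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "class_code"])
    classes = list(TE_CLASS_MIX)
    probs = np.array([TE_CLASS_MIX[c] for c in classes])
    gene_pos = pd.DataFrame(
        {"chrom": [g.chrom for g in genes],
         "start": [g.start for g in genes],
         "end": [g.end for g in genes]}
    )
    cnames = list(chroms)
    rows = []
    placed = 0.0
    while placed < target_bp:
        cls = classes[rng.choice(len(classes), p=probs)]
        if cls.startswith("R"):  # retrotransposons: long
            L = int(rng.integers(3000, 12000))
        else:  # DNA transposons: short
            L = int(rng.integers(500, 3000))
        cname = cnames[rng.integers(len(cnames))]
        clen = chroms[cname]
        if cls == "RLG":
            # pericentromeric third
            lo, hi = clen // 3, 2 * clen // 3
            start = int(rng.integers(lo, max(lo + 1, hi - L)))
        elif cls in ("DTA", "DTH") and len(gene_pos):
            near = gene_pos[gene_pos.chrom == cname]
            if len(near):
                g = near.iloc[rng.integers(len(near))]
                anchor = g.start if rng.random() < 0.5 else g.end
                start = int(anchor + rng.integers(-20000, 20000))
                start = int(np.clip(start, 0, clen - L))
            else:
                start = int(rng.integers(0, clen - L))
        else:
            start = int(rng.integers(0, clen - L))
        rows.append((cname, start, start + L, cls))
        placed += L
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class_code"])


# ------------------------------------------------------------------ counts


def plant_modes(
    gene_ids,
    seed: int,
    frac_additive: float = 0.10,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    parent_fold: float = 4.0,
) -> SimulationTruth:
    """Assign a mode label to every gene and a parental fold where needed.

    Additive genes get parents ``parent_fold`` apart (additivity is only
    observable when the parents differ); up/down genes deviate from the MPV;
    the remainder are conserved (parents equal, hybrid at parental level).
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    labels = np.array(["conserved"] * n, dtype=object)
    idx = rng.permutation(n)
    n_add = int(round(frac_additive * n))
    n_up = int(round(frac_up * n))
    n_down = int(round(frac_down * n))
    labels[idx[:n_add]] = "additive"
    labels[idx[n_add:n_add + n_up]] = "up"
    labels[idx[n_add + n_up:n_add + n_up + n_down]] = "down"
    truth = SimulationTruth()
    for g, lab in zip(gene_ids, labels):
        truth.modes[g] = str(lab)
        if lab == "additive":
            f = parent_fold if rng.random() < 0.5 else 1.0 / parent_fold
            truth.parent_fold[g] = f
        else:
            truth.parent_fold[g] = 1.0
    return truth


def simulate_counts(
    ann: GenomeAnnotation,
    design: Design,
    effects: SimulationTruth,
    dispersion: float,
    seed: int,
    depth: int = 1_000_000,
    mode_fold: float = 4.0,
    genic_fraction: float = 0.7,
    poisson: bool = False,
    base_expression: np.ndarray | None = None,
) -> dict[str, LibraryCounts]:
    """Draw per-library gene counts for the full crossing design.

    Per-gene rates are lognormal across genes and normalized per parent;
    the hybrid rate is the mid-parent rate, multiplied (divided) by
    ``mode_fold`` for planted up (down) genes. Expected genic counts sum to
    ``genic_fraction * depth`` so ``total_mapped = depth`` stays an upper
    bound on the genic total. With ``poisson=True`` counts are Poisson
    (the dispersion -> 0 limit); otherwise negative-binomial with
    ``var = m + dispersion * m**2``.
    """
    if not poisson and dispersion <= 0:
        raise ValueError("dispersion must be positive (or set poisson=True)")
    if {PARENT1, PARENT2, HYBRID12, HYBRID21} - set(design.genotypes):
        raise ValueError("design must include two parents and both reciprocal hybrids")
    if design.n_replicates < 2:
        raise ValueError("design must include at least 2 replicates")
    effects.validate(gene_ids=ann.gene_ids)

    rng = np.random.default_rng(seed)
    gene_ids = ann.gene_ids
    n = len(gene_ids)
    if base_expression is not None:
        base = np.asarray(base_expression, dtype=float)
        if len(base) != n or (base <= 0).any():
            raise ValueError("base_expression must be positive, one value per gene")
    else:
        base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    pf = np.array([effects.parent_fold[g] for g in gene_ids])
    modes = np.array([effects.modes[g] for g in gene_ids])

    lam1 = base * np.sqrt(pf)
    lam2 = base / np.sqrt(pf)
    r1 = lam1 / lam1.sum()
    r2 = lam2 / lam2.sum()
    mpv = 0.5 * (r1 + r2)
    rh = mpv.copy()
    rh[modes == "up"] *= mode_fold
    rh[modes == "down"] /= mode_fold
    rates = {PARENT1: r1, PARENT2: r2, HYBRID12: rh, HYBRID21: rh}

    out: dict[str, LibraryCounts] = {}
    for geno, organ, rep, lib_id in design.libraries():
        mean = depth * genic_fraction * rates[geno]
        if poisson:
            counts = rng.poisson(mean)
        else:
            size = 1.0 / dispersion
            p = size / (size + mean)
            counts = rng.negative_binomial(size, p)
        out[lib_id] = LibraryCounts(
            library_id=lib_id, genotype=geno, organ=organ,
            assay=design.assay, replicate=rep,
            counts=pd.Series(counts, index=gene_ids, dtype=int),
            total_mapped=int(depth),
        )
    return out


def counts_to_frame(libs: dict[str, LibraryCounts]) -> pd.DataFrame:
    """Feature x library count table with a ``total_mapped`` footer row."""
    df = pd.DataFrame({k: v.counts for k, v in libs.items()})
    df.loc["__total_mapped__"] = {k: v.total_mapped for k, v in libs.items()}
    return df


# ------------------------------------------------------------------ allelic


def simulate_allelic(
    genes,
    n_snps: int,
    bias,
    depth: int,
    seed: int,
    libraries=("H12_shoot",),
    snp_genes=None,
) -> pd.DataFrame:
    """Per-SNP parental-allele read counts in hybrid libraries.

    ``bias`` is the probability a hybrid read at any SNP of a gene carries
    the parent-1 allele: a scalar, or a mapping gene -> fraction. Counts are
    binomial(depth, bias) per SNP per library. ``snp_genes`` optionally
    fixes the SNP-to-gene assignment; every entry must name a known gene.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    gene_ids = list(genes.gene_ids) if isinstance(genes, GenomeAnnotation) else list(genes)
    rng = np.random.default_rng(seed)
    if snp_genes is not None:
        unknown = set(snp_genes) - set(gene_ids)
        if unknown:
            raise ValueError(f"SNPs assigned to unknown genes: {sorted(unknown)[:5]}")
        assign = list(snp_genes)
        if len(assign) != n_snps:
            raise ValueError("snp_genes length must equal n_snps")
    else:
        assign = [gene_ids[i] for i in rng.integers(len(gene_ids), size=n_snps)]

    def bias_of(g):
        b = bias[g] if not np.isscalar(bias) else bias
        if not 0 < b <= 1:
            raise ValueError(f"bias for {g} outside (0,1]: {b}")
        return b

    bases = np.array(list("ACGT"))
    rows = []
    for i, g in enumerate(assign):
        a1, a2 = bases[rng.choice(4, size=2, replace=False)]
        rows.append({"snp_id": f"snp{i + 1:06d}", "gene_id": g,
                     "chrom": "chr1", "pos": int(rng.integers(0, 10**6)),
                     "p1_allele": a1, "p2_allele": a2})
    df = pd.DataFrame(rows)
    for lib in libraries:
        b = np.array([bias_of(g) for g in assign])
        c1 = rng.binomial(depth, b)
        df[f"{lib}_p1"] = c1
        df[f"{lib}_p2"] = depth - c1
    return df


# ------------------------------------------------------------------ sRNA


def simulate_srna_reads(
    ann: GenomeAnnotation,
    emission: dict[tuple[str, int], float],
    n_reads: int,
    seed: int,
    cluster_frac: float = 0.8,
    burst_range: tuple[int, int] = (6, 25),
    max_spacing: int = 150,
) -> pd.DataFrame:
    """Emit small-RNA reads from TEs of designated classes and size classes.

    ``emission`` maps (TE class code, read length in nt) to a relative rate;
    size classes are restricted to 21/22/24 nt. A ``cluster_frac`` share of
    reads is emitted in bursts of ``burst_range`` reads spaced <= ``max_spacing``
    nt apart (downstream-callable clusters); the rest are scattered
    singletons. Returns a BED-like frame (chrom, start, end, length, copies).
    """
    for (cls, size) in emission:
        if cls not in TE_CLASSES:
            raise ValueError(f"unknown TE class {cls}")
        if size not in (21, 22, 24):
            raise ValueError(f"size class must be 21, 22 or 24 nt, got {size}")
    total_rate = sum(emission.values())
    if n_reads > 0 and total_rate <= 0:
        raise ValueError("all emission rates are zero but n_reads > 0")
    rng = np.random.default_rng(seed)
    keys = list(emission)
    probs = np.array([emission[k] for k in keys]) / total_rate
    alloc = rng.multinomial(n_reads, probs)

    tes = ann.tes
    rows: list[tuple[str, int, int, int]] = []
    for (cls, size), n_k in zip(keys, alloc):
        pool = tes[tes.class_code == cls].reset_index(drop=True)
        if len(pool) == 0 and n_k > 0:
            raise ValueError(f"no TEs of class {cls} in the annotation")
        remaining = int(n_k)
        while remaining > 0:
            te = pool.iloc[int(rng.integers(len(pool)))]
            te_len = te.end - te.start
            if rng.random() < cluster_frac and remaining >= burst_range[0]:
                spacing = int(rng.integers(20, max_spacing + 1))
                cap = max(burst_range[0], (te_len - size) // spacing + 1)
                hi = min(burst_range[1], cap, remaining)
                k = int(rng.integers(burst_range[0], hi + 1)) if hi > burst_range[0] else burst_range[0]
                spacing = min(spacing, max(1, (te_len - size) // max(1, k - 1)))
                span = spacing * (k - 1) + size
                off = int(rng.integers(te.start, max(te.start + 1, te.end - span)))
                for j in range(k):
                    s = off + j * spacing
                    rows.append((te.chrom, s, s + size, size))
                remaining -= k
            else:
                s = int(rng.integers(te.start, max(te.start + 1, te.end - size)))
                rows.append((te.chrom, s, s + size, size))
                remaining -= 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])
    df["copies"] = 1
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def simulate_methylation(
    ann: GenomeAnnotation,
    gypsy_weight: float,
    n_regions: int,
    seed: int,
    median_len: int = 500,
    sigma: float = 0.5,
) -> pd.DataFrame:
    """Methylated regions placed with stated odds of falling in Gypsy TEs.

    With ``gypsy_weight`` w and RLG genomic fraction f, each region lands
    inside an RLG element with probability w*f / (w*f + 1 - f) (w = 1 gives
    the genomic fraction, i.e. no preference). Region lengths are log-normal
    with the given median; ``weight`` is a per-region read abundance.
    """
    if gypsy_weight < 1:
        raise ValueError("gypsy_weight must be >= 1")
    rng = np.random.default_rng(seed)
    if n_regions == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "weight"])
    from .annotation import merge_intervals

    rlg = ann.tes[ann.tes.class_code == "RLG"]
    merged = []  # (chrom, start, end) over merged RLG intervals
    for chrom, sub in rlg.groupby("chrom"):
        ms, me = merge_intervals(sub.start.to_numpy(), sub.end.to_numpy())
        merged.extend((chrom, int(s), int(e)) for s, e in zip(ms, me))
    rlg_bp = sum(e - s for _, s, e in merged)
    f = rlg_bp / ann.genome_length
    p_rlg = gypsy_weight * f / (gypsy_weight * f + (1 - f)) if rlg_bp else 0.0
    lens = np.array([e - s for _, s, e in merged], dtype=float)
    cnames = list(ann.chromosomes)
    by_chrom = {c: [(s, e) for cc, s, e in merged if cc == c] for c in cnames}
    rows = []
    for _ in range(n_regions):
        L = max(50, int(rng.lognormal(np.log(median_len), sigma)))
        if rng.random() < p_rlg:
            # inside a merged RLG interval, chosen with probability ~ length
            i = rng.choice(len(merged), p=lens / lens.sum())
            chrom, ts, te = merged[i]
            L = min(L, te - ts)
            s = int(rng.integers(ts, max(ts + 1, te - L)))
            rows.append((chrom, s, s + L))
        else:
            # uniform on the non-RLG complement (rejection sampling on midpoint)
            while True:
                c = cnames[int(rng.integers(len(cnames)))]
                s = int(rng.integers(0, ann.chromosomes[c] - L))
                mid = s + L // 2
                if not any(ts <= mid < te for ts, te in by_chrom[c]):
                    break
            rows.append((c, s, s + L))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["weight"] = np.maximum(1, rng.poisson(10, size=n_regions))
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ------------------------------------------------------------------ writers


def write_counts_tsv(libs: dict[str, LibraryCounts], path) -> None:
    counts_to_frame(libs).to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path) -> dict[str, LibraryCounts]:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    totals = df.loc["__total_mapped__"]
    df = df.drop(index="__total_mapped__")
    out = {}
    for lib_id in df.columns:
        parts = lib_id.split("_")
        geno, organ, assay, rep = parts[0], parts[1], parts[2], int(parts[3][3:])
        out[lib_id] = LibraryCounts(
            library_id=lib_id, genotype=geno, organ=organ, assay=assay,
            replicate=rep, counts=df[lib_id].astype(int),
            total_mapped=int(totals[lib_id]),
        )
    return out


def write_srna_bed(reads: pd.DataFrame, path) -> None:
    """BED with the read length in the score column."""
    out = reads[["chrom", "start", "end"]].copy()
    out["name"] = [f"read{i}" for i in range(len(reads))]
    out["score"] = reads["length"].values
    out["strand"] = "+"
    out.to_csv(path, sep="\t", header=False, index=False)


def read_srna_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    out = df[["chrom", "start", "end"]].copy()
    out["length"] = df["score"].astype(int)
    out["copies"] = 1
    return out
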