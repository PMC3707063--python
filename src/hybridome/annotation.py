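"""Genome annotation containers and flat-file I/O.

Coordinates are 0-based half-open throughout the package (BED convention);
GFF3 output converts to 1-based closed at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The ten transposable-element class codes used in maize annotation:
#: class II DNA transposons (DTA hAT, DTC CACTA, DTH PIF/Harbinger,
#: DTM Mutator, DTT Tc1/Mariner) and class I retrotransposons
#: (RIL LINE, RIX unknown LINE, RLC Copia, RLG Gypsy, RLX unknown LTR).
TE_CLASSES = ("DTA", "DTC", "DTH", "DTM", "DTT", "RIL", "RIX", "RLC", "RLG", "RLX")


@dataclass
class Gene:
    """A gene model: span on a chromosome plus non-overlapping exon intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_length(self) -> int:
        """Total exon-model length in bp (the RPKM denominator)."""
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons, in genomic order."""
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)
                if ex[i + 1][0] > ex[i][1]]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, gene models and TE features for one genome build."""

    chromosomes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    tes: pd.DataFrame | None = None  # columns: chrom, start, end, class_code

    def __post_init__(self) -> None:
        if self.tes is None:
            self.tes = pd.DataFrame(columns=["chrom", "start", "end", "class_code"])

    @property
    def genome_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def exon_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.exon_length for g in self.genes}, dtype=int)

    def gene_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self.genes}, dtype=int)

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )

    def validate(self) -> None:
        """Raise ``ValueError`` on any structural invariant violation."""
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.gene_id}: span outside chromosome")
            ex = sorted(g.exons)
            for s, e in ex:
                if s < g.start or e > g.end:
                    raise ValueError(f"gene {g.gene_id}: exon outside gene span")
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                if s2 < e1:
                    raise ValueError(f"gene {g.gene_id}: overlapping exons")
        if len(self.tes):
            bad = ~self.tes["class_code"].isin(TE_CLASSES)
            if bad.any():
                raise ValueError(
                    f"unknown TE class codes: {sorted(self.tes.loc[bad, 'class_code'].unique())}"
                )
            for _, t in self.tes.iterrows():
                if t.chrom not in self.chromosomes:
                    raise ValueError(f"TE on unknown chromosome {t.chrom}")
                if not (0 <= t.start < t.end <= self.chromosomes[t.chrom]):
                    raise ValueError("TE outside chromosome bounds")

    # ---------------------------------------------------------------- I/O

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, length in self.chromosomes.items():
                fh.write(f"##sequence-region {name} 1 {length}\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\thybridome\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(sorted(g.exons), 1):
                    fh.write(
                        f"{g.chrom}\thybridome\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )

    def write_te_bed(self, path) -> None:
        """BED6 with the TE class code in the name field."""
        df = self.tes
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df["class_code"],
                "score": 0,
                "strand": "+",
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path) -> GenomeAnnotation:
    """Read a GFF3 gene annotation written by :meth:`GenomeAnnotation.write_gff3`.

    Only ``gene`` and ``exon`` records are used; sequence-region pragmas
    supply chromosome lengths (falling back to max feature end).
    """
    chroms: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, name, _start, end = line.split()
                chroms[name] = int(end)
                continue
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                continue
            rows.append(parts)
    genes: dict[str, Gene] = {}
    for chrom, _src, ftype, start, end, _score, strand, _phase, attrs in rows:
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attr["ID"]
            genes[gid] = Gene(gid, chrom, int(start) - 1, int(end), strand)
        elif ftype == "exon":
            parent = attr["Parent"]
            genes[parent].exons.append((int(start) - 1, int(end)))
    for g in genes.values():
        g.exons.sort()
        if chroms.get(g.chrom, 0) < g.end:
            chroms[g.chrom] = g.end
    return GenomeAnnotation(chromosomes=chroms, genes=list(genes.values()))


def read_te_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "class_code"],
        dtype={"chrom": str, "start": int, "end": int, "class_code": str},
    )
    return df


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping half-open intervals into a disjoint sorted set."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    ms, me = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= me[-1]:
            me[-1] = max(me[-1], e[i])
        else:
            ms.append(s[i])
            me.append(e[i])
    return np.array(ms), np.array(me)


def interval_overlap(
    q_start: np.ndarray, q_end: np.ndarray, t_start: np.ndarray, t_end: np.ndarray
) -> np.ndarray:
    """Total bp overlap of each query interval with a merged, sorted target set.

    Targets must be disjoint and sorted (see :func:`merge_intervals`).
    Vectorized over queries via a prefix-sum of target coverage.
    """
    q_start = np.asarray(q_start)
    q_end = np.asarray(q_end)
    if len(t_start) == 0 or len(q_start) == 0:
        return np.zeros(len(q_start), dtype=int)
    lengths = np.concatenate([[0], np.cumsum(t_end - t_start)])

    def covered_before(pos: np.ndarray) -> np.ndarray:
        # total target bp strictly left of pos
        idx = np.searchsorted(t_start, pos, side="right")
        base = lengths[idx]
        # subtract the part of the containing interval right of pos
        prev = idx - 1
        inside = (prev >= 0) & (pos < t_end[np.clip(prev, 0, None)])
        adj = np.where(inside, t_end[np.clip(prev, 0, None)] - pos, 0)
        return base - adj

    return (covered_before(q_end) - covered_before(q_start)).astype(int)
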