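"""End-to-end orchestration on declared inputs, with a run manifest.

``make_demo`` writes a complete synthetic input set (annotation, counts,
SNP table, sRNA reads, methylated regions, truth record); ``run_pipeline``
executes quantify -> diffcompare -> allelic_bias -> sirna_te on those files
and records per-stage outputs, timings and warnings in a manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allelic, annotation, diffcompare, quantify, simulate, sirna
from .config import AnalysisConfig


@dataclass
class StageRecord:
    name: str
    outputs: list[str] = field(default_factory=list)
    seconds: float = 0.0
    warnings: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    failed: bool = False
    error: str | None = None


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "seed": self.seed,
                 "input_digests": self.input_digests,
                 "stages": [asdict(s) for s in self.stages]},
                fh, indent=1,
            )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def make_demo(
    outdir,
    seed: int = 42,
    n_genes: int = 400,
    n_chrom: int = 2,
    chrom_len: int = 2_000_000,
    depth: int = 60_000,
    n_snps: int = 400,
    n_srna_reads: int = 8000,
    n_meth_regions: int = 400,
) -> Path:
    """Write a small synthetic input set sized for a fast end-to-end run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seeds = [seed + i for i in range(6)]
    ann = simulate.make_genome(n_chrom, chrom_len, n_genes, 0.4, rng_seeds[0])
    truth = simulate.plant_modes(ann.gene_ids, rng_seeds[1])
    design = simulate.Design()
    libs = simulate.simulate_counts(ann, design, truth, dispersion=0.01,
                                    seed=rng_seeds[2], depth=depth)
    # allelic bias: a subset of genes gets a planted bias of 0.7
    rng = pd.Series(ann.gene_ids).sample(frac=0.2, random_state=rng_seeds[3])
    for g in ann.gene_ids:
        truth.snp_bias[g] = 0.7 if g in set(rng) else 0.5
    snps = simulate.simulate_allelic(
        ann.gene_ids, n_snps, truth.snp_bias, depth=30, seed=rng_seeds[3],
        libraries=("H12_shoot", "H21_shoot", "H12_root", "H21_root"),
    )
    emission = {("RLC", 22): 0.25, ("RLG", 22): 0.25,
                ("DTA", 24): 0.2, ("DTC", 24): 0.15, ("DTH", 24): 0.15}
    truth.emission = {f"{c}:{s}": r for (c, s), r in emission.items()}
    reads = simulate.simulate_srna_reads(ann, emission, n_srna_reads, rng_seeds[4])
    meth = simulate.simulate_methylation(ann, gypsy_weight=10.0,
                                         n_regions=n_meth_regions, seed=rng_seeds[5])
    truth.methylation = {"gypsy_weight": 10.0}

    ann.write_gff3(outdir / "genes.gff3")
    ann.write_te_bed(outdir / "tes.bed")
    simulate.write_counts_tsv(libs, outdir / "counts.tsv")
    snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    simulate.write_srna_bed(reads, outdir / "srna_reads.bed")
    meth.to_csv(outdir / "methylation.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    AnalysisConfig().to_yaml(outdir / "config.yaml")
    return outdir


def run_pipeline(indir, outdir, config: AnalysisConfig | None = None,
                 seed: int = 0) -> RunManifest:
    """Run every analysis stage on the files in ``indir``; write to ``outdir``."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or (
        AnalysisConfig.from_yaml(indir / "config.yaml")
        if (indir / "config.yaml").exists() else AnalysisConfig()
    )
    manifest = RunManifest(config=cfg.asdict(), seed=seed)
    inputs = {
        "genes": indir / "genes.gff3", "tes": indir / "tes.bed",
        "counts": indir / "counts.tsv", "snps": indir / "snps.tsv",
        "srna": indir / "srna_reads.bed", "methylation": indir / "methylation.tsv",
    }
    for name, path in inputs.items():
        if not path.exists():
            raise FileNotFoundError(f"stage inputs: missing {name} file {path}")
        manifest.input_digests[name] = _digest(path)

    ann = annotation.read_gff3(inputs["genes"])
    ann.tes = annotation.read_te_bed(inputs["tes"])
    libs = simulate.read_counts_tsv(inputs["counts"])

    def stage(name, fn):
        rec = StageRecord(name=name)
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                fn(rec)
            rec.warnings = [str(w.message) for w in wlist]
        except Exception as exc:  # partial manifest with failure record
            rec.failed = True
            rec.error = f"{type(exc).__name__}: {exc}"
        rec.seconds = round(time.perf_counter() - t0, 3)
        manifest.stages.append(rec)
        if rec.failed:
            manifest.to_json(outdir / "manifest.json")
            raise RuntimeError(f"stage {name} failed: {rec.error}")

    detected: dict[str, set] = {}

    def _quantify(rec):
        exon_len = ann.exon_lengths()
        mat = quantify.rpkm_matrix(libs, exon_len)
        path = outdir / "rpkm.tsv"
        mat.round(4).to_csv(path, sep="\t", index_label="gene_id")
        rec.outputs.append(str(path))
        for lib_id, lc in libs.items():
            cov = lc.counts * 1.0  # gene-level detection proxy: nonzero RPKM
            detected[lib_id] = set(cov.index[cov > 0])
        rec.counts["genes"] = len(mat)
        rec.counts["libraries"] = len(libs)

    def _diff(rec):
        results = {}
        for organ in ("shoot", "root"):
            organ_libs = {k: v for k, v in libs.items() if v.organ == organ}
            if not organ_libs:
                continue
            # replicate concordance per genotype, then pool
            retained = set(ann.gene_ids)
            for geno in simulate.GENOTYPES:
                gl = {k: v for k, v in organ_libs.items() if v.genotype == geno}
                rc = pd.DataFrame({k: v.counts for k, v in gl.items()})
                ls = pd.Series({k: v.total_mapped for k, v in gl.items()})
                retained &= diffcompare.replicate_filter(rc, ls, cfg.p_replicate)
            det = set.intersection(*(detected[k] for k in organ_libs))
            usable = sorted(retained & det)
            model = diffcompare.HybridModeModel.from_libraries(
                libs, organ, config=cfg, genes=usable
            )
            res = model.fit()
            path = outdir / f"modes_{organ}.tsv"
            res.calls.to_csv(path, sep="\t", index_label="gene_id")
            rec.outputs.append(str(path))
            rec.counts[f"{organ}_retained"] = len(usable)
            rec.counts[f"{organ}_modes"] = {
                k: int(v) for k, v in res.mode_counts.items()
            }
            results[organ] = res
        with open(outdir / "mode_summary.json", "w") as fh:
            json.dump(rec.counts, fh, indent=1)
        rec.outputs.append(str(outdir / "mode_summary.json"))
        # sample dendrogram over genes differential in >= 1 comparison
        sig = set()
        for res in results.values():
            sig |= set(res.calls.index[res.calls["mode"] != "conserved"])
        if len(sig) >= 2:
            pooled = {}
            for lc in libs.values():
                key = f"{lc.genotype}_{lc.organ}"
                pooled[key] = pooled.get(key, 0) + lc.counts * 1e6 / lc.total_mapped
            mat = pd.DataFrame(pooled).loc[sorted(sig)]
            tree = diffcompare.hierarchical_cluster(np.log2(mat + 1))
            (outdir / "sample_dendrogram.nwk").write_text(tree.newick() + "\n")
            rec.outputs.append(str(outdir / "sample_dendrogram.nwk"))

    def _ase(rec):
        table = pd.read_csv(inputs["snps"], sep="\t")
        res = allelic.AllelicBiasModel(table, config=cfg).fit()
        path = outdir / "allelic_bias.tsv"
        res.gene_calls.to_csv(path, sep="\t", index=False)
        rec.outputs.append(str(path))
        libs_ase = sorted(res.gene_calls["library"].unique())
        report = {}
        for la, lb in [(a, b) for a in libs_ase for b in libs_ase if a < b]:
            st = allelic.concordance_stats(
                res.gene_calls[res.gene_calls.library == la],
                res.gene_calls[res.gene_calls.library == lb],
            )
            report[f"{la}|{lb}"] = {
                "n_common": st.n_common, "n_same_direction": st.n_same_direction,
                "percent": st.percent, "pearson_r": st.pearson_r,
            }
        with open(outdir / "ase_concordance.json", "w") as fh:
            json.dump(report, fh, indent=1)
        rec.outputs.append(str(outdir / "ase_concordance.json"))
        rec.counts["biased_genes"] = int(res.gene_calls["biased"].sum())

    def _sirna(rec):
        reads = simulate.read_srna_bed(inputs["srna"])
        meth = pd.read_csv(inputs["methylation"], sep="\t")
        bg = sirna.te_background_fractions(ann.tes)
        all_rows = []
        for size in (21, 22, 24):
            clusters = sirna.call_sirna_clusters(
                reads, size, cfg.min_reads, cfg.max_gap, cfg.gap_mode
            )
            rec.counts[f"clusters_{size}nt"] = len(clusters)
            if not clusters:
                continue
            cdf = sirna.clusters_to_frame(clusters)
            sirna.write_clusters_bed(clusters, outdir / f"clusters_{size}nt.bed")
            rec.outputs.append(str(outdir / f"clusters_{size}nt.bed"))
            assigned = sirna.assign_te_overlap(cdf, ann.tes, cfg.min_overlap_frac)
            if (assigned != "unassigned").sum() >= 1:
                enr = sirna.te_enrichment_test(assigned, bg)
                t = enr.table.copy()
                t["size_class"] = size
                all_rows.append(t)
        if all_rows:
            pd.concat(all_rows).to_csv(outdir / "te_enrichment.tsv", sep="\t",
                                       index_label="class_code")
            rec.outputs.append(str(outdir / "te_enrichment.tsv"))
        track = sirna.chromosomal_density(
            meth, ann.chromosomes, bin_size=100_000
        )
        sirna.write_bedgraph(track, 100_000, outdir / "methylation_density.bedgraph")
        rec.outputs.append(str(outdir / "methylation_density.bedgraph"))

    stage("quantify", _quantify)
    stage("diffcompare", _diff)
    stage("allelic_bias", _ase)
    stage("sirna_te", _sirna)
    manifest.to_json(outdir / "manifest.json")
    return manifest
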