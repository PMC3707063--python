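"""siRNA cluster calling, TE assignment, enrichment, spatial correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from hybridome import simulate, sirna


def _reads(starts, length=24, chrom="chr1"):
    starts = np.asarray(starts)
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + length, "length": length, "copies": 1})


def cluster_oracle(starts, min_reads=6, max_gap=200):
    """Independent single-linkage oracle: connected components of the graph
    joining any two reads whose start positions lie within max_gap."""
    s = np.asarray(starts)
    n = len(s)
    adj = np.abs(s[:, None] - s[None, :]) <= max_gap
    _, lab = connected_components(csr_matrix(adj), directed=False)
    out = []
    for c in np.unique(lab):
        members = s[lab == c]
        if len(members) >= min_reads:
            out.append((int(members.min()), int(members.max()), len(members)))
    return sorted(out)


# ----------------------------------------------------------------- calling


def test_five_stacked_reads_no_cluster():
    clusters = sirna.call_sirna_clusters(_reads([100] * 5), 24)
    assert clusters == []


def test_six_reads_spaced_150_one_cluster():
    clusters = sirna.call_sirna_clusters(_reads([0, 150, 300, 450, 600, 750]), 24)
    assert len(clusters) == 1
    c = clusters[0]
    assert (c.start, c.end, c.n_reads) == (0, 774, 6)


def test_gap_above_threshold_splits():
    starts = [0, 150, 300, 450, 600, 750, 1200, 1350, 1500, 1650, 1800, 1950]
    clusters = sirna.call_sirna_clusters(_reads(starts), 24)
    assert len(clusters) == 2
    assert [c.n_reads for c in clusters] == [6, 6]


def test_duplicate_positions_count_via_copies():
    df = _reads([0, 150, 300])
    df.loc[0, "copies"] = 4  # 4 + 1 + 1 = 6 reads
    clusters = sirna.call_sirna_clusters(df, 24)
    assert len(clusters) == 1 and clusters[0].n_reads == 6


def test_size_classes_are_independent():
    df = pd.concat([_reads([0, 100, 200], 24), _reads([50, 150, 250], 22)],
                   ignore_index=True)
    assert sirna.call_sirna_clusters(df, 24) == []
    assert sirna.call_sirna_clusters(df, 22) == []


def test_input_order_invariance(rng):
    starts = rng.integers(0, 100_000, 500)
    df = _reads(starts)
    shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
    a = sirna.clusters_to_frame(sirna.call_sirna_clusters(df, 24))
    b = sirna.clusters_to_frame(sirna.call_sirna_clusters(shuffled, 24))
    pd.testing.assert_frame_equal(a, b)


def test_clusters_match_graph_oracle_and_are_maximal(rng):
    starts = np.sort(rng.integers(0, 300_000, 2000))
    clusters = sirna.call_sirna_clusters(_reads(starts), 24)
    got = sorted((c.start, c.end - 24, c.n_reads) for c in clusters)
    assert got == cluster_oracle(starts)
    # disjoint and maximal: nearest outside read violates max_gap
    spans = sorted((c.start, c.end) for c in clusters)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 > e1
    for c in clusters:
        outside = starts[(starts < c.start) | (starts > c.end - 24)]
        if len(outside):
            nearest = np.abs(outside - np.array([c.start, c.end - 24])[:, None]).min()
            assert nearest > 200


def test_end_to_start_gap_mode():
    # gaps of 210 between starts, 186 end-to-start: joined only in "end" mode
    starts = np.arange(6) * 210
    assert sirna.call_sirna_clusters(_reads(starts), 24, gap_mode="start") == []
    assert len(sirna.call_sirna_clusters(_reads(starts), 24, gap_mode="end")) == 1


def test_burst_simulation_yields_exactly_one_cluster(small_genome):
    reads = simulate.simulate_srna_reads(
        small_genome, {("RLG", 24): 1.0}, 6, seed=2, cluster_frac=1.0,
        burst_range=(6, 6),
    )
    clusters = sirna.call_sirna_clusters(reads, 24)
    assert len(clusters) == 1 and clusters[0].n_reads == 6


# ----------------------------------------------------------------- density


def test_density_uniform_near_flat(rng):
    starts = rng.integers(0, 999_000, 5000)
    regions = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500})
    track = sirna.chromosomal_density(regions, {"chr1": 1_000_000}, 100_000)["chr1"]
    assert track.std() / track.mean() < 0.2


def test_density_half_empty():
    starts = np.arange(0, 400_000, 1000)
    regions = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 200})
    track = sirna.chromosomal_density(regions, {"chr1": 1_000_000}, 100_000)["chr1"]
    assert (track[5:] == 0).all()
    assert (track[:4] > 0).all()


def test_pericentromeric_contrast_methylation_vs_24nt():
    """Gypsy-weighted methylation tracks Gypsy density; 24 nt siRNAs from
    gene-proximal DNA TEs anticorrelate with it along the chromosome."""
    ann = simulate.make_genome(1, 2_000_000, 150, 0.5, seed=13)
    meth = simulate.simulate_methylation(ann, gypsy_weight=10.0,
                                         n_regions=2000, seed=14)
    reads = simulate.simulate_srna_reads(
        ann, {("DTA", 24): 0.5, ("DTH", 24): 0.5}, 20_000, seed=15
    )
    rlg = ann.tes[ann.tes.class_code == "RLG"]
    binsz = 100_000
    t_rlg = sirna.chromosomal_density(rlg, ann.chromosomes, binsz)["chr1"]
    t_meth = sirna.chromosomal_density(meth, ann.chromosomes, binsz)["chr1"]
    t_24 = sirna.chromosomal_density(reads, ann.chromosomes, binsz)["chr1"]
    assert stats.pearsonr(t_rlg, t_meth)[0] > 0.5
    assert stats.pearsonr(t_rlg, t_24)[0] < 0.0


# -------------------------------------------------------------- assignment


def _te(chrom, start, end, cls):
    return {"chrom": chrom, "start": start, "end": end, "class_code": cls}


def test_region_inside_te_assigned():
    tes = pd.DataFrame([_te("chr1", 1000, 9000, "RLC")])
    regions = pd.DataFrame([{"chrom": "chr1", "start": 2000, "end": 2100}])
    assert list(sirna.assign_te_overlap(regions, tes)) == ["RLC"]


def test_region_below_half_overlap_unassigned():
    tes = pd.DataFrame([_te("chr1", 0, 1049, "DTA")])
    regions = pd.DataFrame([{"chrom": "chr1", "start": 1000, "end": 1100}])
    assert list(sirna.assign_te_overlap(regions, tes)) == ["unassigned"]


def test_largest_overlap_wins_and_tie_breaks_alphabetical():
    tes = pd.DataFrame([
        _te("chr1", 0, 1060, "RLG"),    # 60 bp overlap
        _te("chr1", 1020, 2000, "RLC"),  # 80 bp overlap
    ])
    regions = pd.DataFrame([{"chrom": "chr1", "start": 1000, "end": 1100}])
    assert list(sirna.assign_te_overlap(regions, tes)) == ["RLC"]
    # exact tie: both cover 60/100
    tes2 = pd.DataFrame([
        _te("chr1", 0, 1060, "RLG"), _te("chr1", 1040, 2000, "RLC"),
    ])
    assert list(sirna.assign_te_overlap(regions, tes2)) == ["RLC"]


def test_same_class_tes_merged_before_overlap():
    # two overlapping DTA fragments jointly cover 60% of the region
    tes = pd.DataFrame([
        _te("chr1", 1000, 1040, "DTA"), _te("chr1", 1020, 1060, "DTA"),
    ])
    regions = pd.DataFrame([{"chrom": "chr1", "start": 1000, "end": 1100}])
    assert list(sirna.assign_te_overlap(regions, tes)) == ["DTA"]


def test_assignment_matches_brute_force_oracle(small_genome, rng):
    n = 1000
    chroms = list(small_genome.chromosomes)
    regions = pd.DataFrame({
        "chrom": [chroms[i] for i in rng.integers(len(chroms), size=n)],
        "start": rng.integers(0, 495_000, n),
    })
    regions["end"] = regions["start"] + rng.integers(50, 3000, n)
    got = sirna.assign_te_overlap(regions, small_genome.tes, 0.5)
    tes = small_genome.tes
    for i in range(n):
        r = regions.iloc[i]
        best, best_ov = "unassigned", -1
        for cls in sorted(tes.class_code.unique()):
            sub = tes[(tes.class_code == cls) & (tes.chrom == r.chrom)]
            mask = np.zeros(r.end - r.start, dtype=bool)
            for _, t in sub.iterrows():
                lo, hi = max(t.start, r.start), min(t.end, r.end)
                if hi > lo:
                    mask[lo - r.start:hi - r.start] = True
            ov = int(mask.sum())
            if ov >= 0.5 * (r.end - r.start) and ov > best_ov:
                best, best_ov = cls, ov
        assert got.iloc[i] == best, i


def test_assigned_plus_unassigned_total(small_genome, rng):
    n = 300
    regions = pd.DataFrame({
        "chrom": "chr1",
        "start": rng.integers(0, 490_000, n),
    })
    regions["end"] = regions["start"] + 200
    got = sirna.assign_te_overlap(regions, small_genome.tes)
    assert got.isin(list(sirna.TE_CLASSES) + ["unassigned"]).all()
    assert len(got) == n


# -------------------------------------------------------------- enrichment


def test_enrichment_null_is_flat():
    assigned = pd.Series(["RLC"] * 50 + ["RLG"] * 50)
    bg = pd.Series({"RLC": 0.5, "RLG": 0.5})
    res = sirna.te_enrichment_test(assigned, bg)
    assert np.allclose(res.table["chi2"].astype(float), 0.0)
    assert np.allclose(res.table["pvalue"].astype(float), 1.0)


def test_enrichment_hand_computed_chi2():
    """900/100 observed vs 50/50 background: chi2 = 640 for each class."""
    assigned = pd.Series(["RLC"] * 900 + ["DTA"] * 100)
    bg = pd.Series({"RLC": 0.5, "DTA": 0.5})
    res = sirna.te_enrichment_test(assigned, bg)
    assert res.table.loc["RLC", "chi2"] == pytest.approx(640.0)
    assert res.table.loc["DTA", "chi2"] == pytest.approx(640.0)
    assert res.table.loc["RLC", "direction"] == "over"
    assert res.table.loc["DTA", "direction"] == "under"


def test_enrichment_low_count_flagged():
    assigned = pd.Series(["RLC"] * 10)
    bg = pd.Series({"RLC": 0.9, "DTA": 0.1})
    res = sirna.te_enrichment_test(assigned, bg)
    assert bool(res.table.loc["DTA", "low_count"])


def test_planted_emission_recovers_class_split():
    """22 nt from Copia/Gypsy and 24 nt from hAT/CACTA/Harbinger: each size
    class is enriched for its source classes and depleted for the others."""
    ann = simulate.make_genome(2, 2_000_000, 100, 0.6, seed=19)
    emission = {("RLC", 22): 0.25, ("RLG", 22): 0.25,
                ("DTA", 24): 0.2, ("DTC", 24): 0.15, ("DTH", 24): 0.15}
    reads = simulate.simulate_srna_reads(ann, emission, 30_000, seed=23)
    bg = sirna.te_background_fractions(ann.tes)
    for size, sources in ((22, {"RLC", "RLG"}), (24, {"DTA", "DTC", "DTH"})):
        clusters = sirna.call_sirna_clusters(reads, size)
        assigned = sirna.assign_te_overlap(
            sirna.clusters_to_frame(clusters), ann.tes
        )
        res = sirna.te_enrichment_test(assigned, bg)
        assert sources <= set(res.enriched(0.001)), size
        assert not sources & set(res.depleted(0.001)), size


def test_enrichment_direction_stable_under_subsampling(small_genome, rng):
    emission = {("RLC", 22): 0.5, ("RLG", 22): 0.5}
    reads = simulate.simulate_srna_reads(small_genome, emission, 20_000, seed=29)
    clusters = sirna.clusters_to_frame(sirna.call_sirna_clusters(reads, 22))
    bg = sirna.te_background_fractions(small_genome.tes)
    full = sirna.te_enrichment_test(
        sirna.assign_te_overlap(clusters, small_genome.tes), bg
    ).table["direction"]
    sub = clusters.sample(frac=0.5, random_state=5)
    half = sirna.te_enrichment_test(
        sirna.assign_te_overlap(sub, small_genome.tes), bg
    ).table["direction"]
    strong = ["RLC", "RLG"]
    assert (full.loc[strong] == half.loc[strong]).all()


# -------------------------------------------------------------- correlation


def test_sirna_methylation_proportional_r_near_one(rng):
    starts = rng.integers(0, 990_000, 300)
    sir = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 1000,
                        "n_reads": rng.integers(5, 100, 300)})
    meth = sir.rename(columns={"n_reads": "weight"}).copy()
    meth["weight"] = sir["n_reads"] * 3  # proportional by construction
    res = sirna.sirna_methylation_correlation(sir, meth, {"chr1": 1_000_000})
    assert res.r == pytest.approx(1.0, abs=1e-6)


def test_sirna_methylation_independent_near_zero(rng):
    s1 = rng.integers(0, 990_000, 2000)
    s2 = rng.integers(0, 990_000, 2000)
    sir = pd.DataFrame({"chrom": "chr1", "start": s1, "end": s1 + 500,
                        "n_reads": 10})
    meth = pd.DataFrame({"chrom": "chr1", "start": s2, "end": s2 + 500,
                         "weight": 10})
    res = sirna.sirna_methylation_correlation(sir, meth, {"chr1": 1_000_000},
                                              window=50_000)
    assert abs(res.r) < 0.35


def test_sirna_methylation_anticorrelated_negative():
    # siRNA in first half, methylation in second half
    s = np.arange(0, 500_000, 2000)
    sir = pd.DataFrame({"chrom": "chr1", "start": s, "end": s + 500, "n_reads": 20})
    m = s + 500_000
    meth = pd.DataFrame({"chrom": "chr1", "start": m, "end": m + 500, "weight": 20})
    res = sirna.sirna_methylation_correlation(sir, meth, {"chr1": 1_000_000})
    assert res.r < 0
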