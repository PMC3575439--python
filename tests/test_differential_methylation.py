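import numpy as np
import pytest
from scipy.stats import hypergeom

from medipmap.differential_methylation import (
    GeneRegionCoverage,
    call_methylated_genes,
    compare_contrast,
    gene_region_counts,
    intersect_contrasts,
)
from medipmap.genome_model import TranscriptModel, build_feature_partition
from medipmap.medip_peaks import AlignedRead, Peak


def _peak(chrom, s, e):
    return Peak(chrom, s, e, (s + e) // 2, 1, 1.0, 1e-9)


def _cov(counts: dict, lib: int) -> dict:
    return {
        (g, r): GeneRegionCoverage(g, r, k, lib) for (g, r), k in counts.items()
    }


@pytest.fixture(scope="module")
def one_gene():
    t = TranscriptModel("g1", "t1", "chr1", "+", 10_000, 14_000, [(10_000, 11_000), (13_000, 14_000)])
    part = build_feature_partition([t], {"chr1": 100_000})
    return t, part


# ---------------------------------------------------------------------------
# methylated genes


def test_peak_in_intron_marks_gene_methylated(one_gene):
    t, part = one_gene
    (mg,) = call_methylated_genes([_peak("chr1", 11_500, 11_700)], part, [t])
    assert mg.gene_id == "g1" and mg.evidence == [0]


def test_distal_intergenic_peak_marks_nothing(one_gene):
    t, part = one_gene
    # > 2 kb from the TSS and outside the body
    assert call_methylated_genes([_peak("chr1", 50_000, 50_500)], part, [t]) == []


def test_methylated_genes_match_brute_force(dataset, partition):
    peaks = [
        _peak(m.chrom, m.tx_start + 100, m.tx_start + 400)
        for m in dataset.transcripts[::2]
    ] + [_peak("chr1", 1, 100)]
    got = {g.gene_id for g in call_methylated_genes(peaks, partition, dataset.transcripts)}
    expected = set()
    for m in dataset.transcripts:
        tss = m.tx_start if m.strand == "+" else m.tx_end
        windows = [(m.tx_start, m.tx_end), (max(0, tss - 2_000), tss + 2_000)]
        for p in peaks:
            if p.chrom == m.chrom and any(p.start < e and s < p.end for s, e in windows):
                expected.add(m.gene_id)
    assert got == expected


# ---------------------------------------------------------------------------
# region counts


def test_junction_read_counts_in_both_regions(one_gene):
    t, part = one_gene
    cov = gene_region_counts([AlignedRead("chr1", 10_950, 11_050)], [t], part)
    assert cov[("g1", "exon")].count == 1
    assert cov[("g1", "intron")].count == 1
    assert cov[("g1", "utr3")].count == 0


def test_region_counts_match_brute_force(dataset, partition):
    reads = dataset.reads["XH_h"][:3_000]
    cov = gene_region_counts(reads, dataset.transcripts, partition)
    from medipmap.differential_methylation import _gene_regions

    regions = _gene_regions(dataset.transcripts, partition.chrom_sizes)
    for m in dataset.transcripts[:5]:
        for region in ("exon", "intron", "promoter", "upstream2k"):
            ivs = regions[m.gene_id][region]
            expected = sum(
                1
                for r in reads
                if r.chrom == regions[m.gene_id]["chrom"]
                and any(r.start < e and s < r.end for s, e in ivs)
            )
            assert cov[(m.gene_id, region)].count == expected, (m.gene_id, region)


# ---------------------------------------------------------------------------
# contrast comparison


def test_identical_samples_yield_no_calls():
    counts = {("g1", "exon"): 40, ("g2", "exon"): 7}
    assert compare_contrast(_cov(counts, 10_000), _cov(counts, 10_000)) == []


def test_mismatched_universes_rejected():
    with pytest.raises(ValueError):
        compare_contrast(_cov({("g1", "exon"): 1}, 100), _cov({("g2", "exon"): 1}, 100))


def _fisher_two_sided_oracle(ka, la, kb, lb):
    """Exhaustive two-sided Fisher on the 2x2 table via the hypergeometric:
    sum of all table probabilities <= the observed one."""
    k = ka + kb
    dist = hypergeom(la + lb, k, la)
    support = np.arange(max(0, k - lb), min(k, la) + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(ka)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


def test_strong_difference_called_up_with_exact_test_pvalue():
    cov_a = _cov({("g1", "exon"): 10}, 1_000_000)
    cov_b = _cov({("g1", "exon"): 100}, 1_000_000)
    (call,) = compare_contrast(cov_a, cov_b, ("A", "B"))
    assert call.direction == "up"
    assert call.fold_change == pytest.approx((100.5) / (10.5), rel=1e-12)
    oracle = _fisher_two_sided_oracle(10, 1_000_000, 100, 1_000_000)
    assert call.pvalue == pytest.approx(oracle, abs=1e-10)


def test_fold_gate_blocks_small_changes():
    cov_a = _cov({("g1", "exon"): 100}, 1_000_000)
    cov_b = _cov({("g1", "exon"): 150}, 1_000_000)
    assert compare_contrast(cov_a, cov_b) == []


def test_swapping_samples_flips_every_direction(dataset, partition):
    cov_a = gene_region_counts(dataset.reads["WRR_h"], dataset.transcripts, partition)
    cov_b = gene_region_counts(dataset.reads["WRR_l"], dataset.transcripts, partition)
    fwd = compare_contrast(cov_a, cov_b, ("A", "B"))
    rev = compare_contrast(cov_b, cov_a, ("B", "A"))
    fwd_keys = {(c.gene_id, c.region): c.direction for c in fwd}
    rev_keys = {(c.gene_id, c.region): c.direction for c in rev}
    assert set(fwd_keys) == set(rev_keys)
    assert all(rev_keys[k] != d for k, d in fwd_keys.items())


def test_planted_genes_recovered_with_correct_direction(dataset, partition):
    """Four-group dataset: per contrast, planted genes are called at p<0.01
    with the 'up = greater in second sample' direction convention."""
    covs = {
        s: gene_region_counts(dataset.reads[s], dataset.transcripts, partition)
        for s in dataset.config.samples
    }
    all_genes = {m.gene_id for m in dataset.transcripts}
    for a, b in (("WRR_h", "WRR_l"), ("XH_h", "XH_l")):
        calls = compare_contrast(covs[a], covs[b], (a, b))
        by_gene = {}
        for c in calls:
            by_gene.setdefault(c.gene_id, set()).add(c.direction)
        truth = {
            r["gene_id"]: r["direction"]
            for r in dataset.dmg_truth
            if r["contrast"] == f"{a}_vs_{b}"
        }
        recovered = sum(1 for g, d in truth.items() if d in by_gene.get(g, set()))
        assert recovered / len(truth) >= 0.9
        null_called = set(by_gene) - set(truth)
        assert len(null_called) / len(all_genes - set(truth)) <= 0.1


# ---------------------------------------------------------------------------
# contrast intersection


def _mkcall(gene, region="exon", direction="up"):
    from medipmap.differential_methylation import DifferentialCall

    return DifferentialCall(gene, region, ("A", "B"), 1, 10, 1.0, 10.0, 10.0, 1e-5, 1e-4, direction)


def test_disjoint_call_sets_have_empty_intersections():
    calls = {"c1": [_mkcall("g1")], "c2": [_mkcall("g2")]}
    out = intersect_contrasts(calls)
    assert out["pairwise"][("c1", "c2")] == 0
    assert out["shared_all"] == []


def test_identical_call_sets_fully_shared():
    calls = {"c1": [_mkcall("g1"), _mkcall("g2")], "c2": [_mkcall("g1"), _mkcall("g2")]}
    out = intersect_contrasts(calls)
    assert out["pairwise"][("c1", "c2")] == 2
    assert out["shared_all"] == ["g1", "g2"]


def test_four_contrast_intersection_matches_set_algebra():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(30)]
    calls = {
        f"c{j}": [_mkcall(g) for g in rng.choice(genes, size=12, replace=False)]
        for j in range(4)
    }
    out = intersect_contrasts(calls, grouping="gene")
    sets = {n: {c.gene_id for c in cl} for n, cl in calls.items()}
    for (a, b), n in out["pairwise"].items():
        assert n == len(sets[a] & sets[b])
    assert set(out["shared_all"]) == set.intersection(*sets.values())


def test_fine_grouping_separates_regions_and_directions():
    calls = {
        "c1": [_mkcall("g1", "exon", "up")],
        "c2": [_mkcall("g1", "intron", "up")],
    }
    assert intersect_contrasts(calls, grouping="gene")["pairwise"][("c1", "c2")] == 1
    assert (
        intersect_contrasts(calls, grouping="gene_region_direction")["pairwise"][("c1", "c2")]
        == 0
    )


def test_single_contrast_rejected():
    with pytest.raises(ValueError):
        intersect_contrasts({"c1": [_mkcall("g1")]})
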