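import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medipmap.genome_model import (
    ParseError,
    TranscriptModel,
    build_feature_partition,
    load_gene_models,
    write_gene_models_bed12,
)
from medipmap.intervals import (
    complement_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)
from medipmap.synthetic_data import write_gtf


# ---------------------------------------------------------------------------
# interval arithmetic properties

intervals_strategy = st.lists(
    st.tuples(st.integers(0, 500), st.integers(0, 500)).map(lambda t: (min(t), max(t) + 1)),
    max_size=20,
)


@settings(deadline=None, max_examples=50)
@given(intervals_strategy, intervals_strategy)
def test_interval_algebra_against_basewise_sets(a, b):
    """merge/subtract/complement agree with per-base set arithmetic."""
    set_a = {p for s, e in a for p in range(s, e)}
    set_b = {p for s, e in b for p in range(s, e)}
    assert {p for s, e in merge_intervals(a) for p in range(s, e)} == set_a
    assert {p for s, e in subtract_intervals(a, b) for p in range(s, e)} == set_a - set_b
    assert {p for s, e in complement_intervals(a, 600) for p in range(s, e)} == (
        set(range(600)) - set_a
    )


# ---------------------------------------------------------------------------
# gene model I/O


def test_gtf_coordinates_convert_to_half_open(tmp_path):
    gtf = tmp_path / "one.gtf"
    gtf.write_text(
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    )
    (model,) = load_gene_models(gtf)
    assert model.exons == [(100, 200)]
    assert (model.tx_start, model.tx_end) == (100, 200)


def test_empty_file_yields_no_models(tmp_path):
    path = tmp_path / "empty.gtf"
    path.write_text("")
    assert load_gene_models(path) == []


def test_malformed_line_reports_line_number(tmp_path):
    gtf = tmp_path / "bad.gtf"
    gtf.write_text(
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        "chr1\tonly-two-fields\n"
    )
    with pytest.raises(ParseError, match=r"bad\.gtf:2"):
        load_gene_models(gtf)


def test_exon_outside_transcript_span_rejected():
    with pytest.raises(ValueError, match="outside transcript"):
        TranscriptModel("g", "t", "chr1", "+", 100, 200, [(50, 150)])


def test_gene_models_round_trip_gtf_and_bed12(tmp_path, dataset):
    """Writing then loading is lossless for coordinates, strand and ids."""
    models = dataset.transcripts[:3]
    for writer, name in ((write_gtf, "rt.gtf"), (write_gene_models_bed12, "rt.bed")):
        path = tmp_path / name
        writer(models, path)
        loaded = load_gene_models(path)
        assert len(loaded) == len(models)
        for orig, back in zip(models, loaded):
            assert (back.chrom, back.strand) == (orig.chrom, orig.strand)
            assert (back.tx_start, back.tx_end) == (orig.tx_start, orig.tx_end)
            assert back.exons == orig.exons
            assert (back.gene_id, back.transcript_id) == (orig.gene_id, orig.transcript_id)


# ---------------------------------------------------------------------------
# feature partition


def test_two_exon_transcript_partition_by_hand():
    t = TranscriptModel("g", "t", "chr1", "+", 1000, 2000, [(1000, 1200), (1800, 2000)])
    part = build_feature_partition([t], {"chr1": 10_000})
    assert part.intervals["intron"]["chr1"] == [(1200, 1800)]
    assert part.intervals["gene_body"]["chr1"] == [(1000, 2000)]
    assert part.total_bp["intergenic"] == 10_000 - 1_000
    # promoter TSS +/- 2kb clipped at chromosome start
    assert part.intervals["promoter"]["chr1"] == [(0, 3000)]
    assert part.intervals["upstream2k"]["chr1"] == [(0, 1000)]
    assert part.intervals["downstream2k"]["chr1"] == [(2000, 4000)]


def test_no_transcripts_means_all_intergenic():
    part = build_feature_partition([], {"chr1": 5_000, "chr2": 2_000})
    assert part.total_bp["intergenic"] == 7_000
    assert part.total_bp["gene_body"] == 0
    assert part.total_bp["exon"] == 0


def test_partition_errors():
    t = TranscriptModel("g", "t", "chrX", "+", 0, 100, [(0, 100)])
    with pytest.raises(KeyError):
        build_feature_partition([t], {"chr1": 1_000})
    with pytest.raises(ValueError):
        build_feature_partition([], {"chr1": 1_000}, promoter_flank=0)


def _basewise_totals(transcripts, chrom_sizes, flank=2000):
    """Independent per-base labelling oracle."""
    marks = {
        label: {c: np.zeros(L, dtype=bool) for c, L in chrom_sizes.items()}
        for label in ("promoter", "utr5", "exon", "intron", "utr3", "gene_body",
                      "upstream2k", "downstream2k")
    }
    for t in transcripts:
        L = chrom_sizes[t.chrom]
        tss = t.tx_start if t.strand == "+" else t.tx_end
        marks["promoter"][t.chrom][max(0, tss - flank): min(L, tss + flank)] = True
        marks["gene_body"][t.chrom][t.tx_start: t.tx_end] = True
        if t.strand == "+":
            marks["upstream2k"][t.chrom][max(0, t.tx_start - flank): t.tx_start] = True
            marks["downstream2k"][t.chrom][t.tx_end: min(L, t.tx_end + flank)] = True
        else:
            marks["upstream2k"][t.chrom][t.tx_end: min(L, t.tx_end + flank)] = True
            marks["downstream2k"][t.chrom][max(0, t.tx_start - flank): t.tx_start] = True
        exonic = np.zeros(L, dtype=bool)
        for s, e in t.exons:
            exonic[s:e] = True
            marks["exon"][t.chrom][s:e] = True
        body = np.zeros(L, dtype=bool)
        body[t.tx_start: t.tx_end] = True
        marks["intron"][t.chrom][body & ~exonic] = True
        u5, u3 = t.utr_intervals()
        for s, e in u5:
            marks["utr5"][t.chrom][s:e] = True
        for s, e in u3:
            marks["utr3"][t.chrom][s:e] = True
    totals = {lab: int(sum(m.sum() for m in per.values())) for lab, per in marks.items()}
    totals["intergenic"] = sum(chrom_sizes.values()) - totals["gene_body"]
    return totals


def test_partition_totals_match_basewise_oracle(dataset, partition):
    from medipmap.genome_model import chrom_sizes as cs

    sizes = cs(dataset.genome)
    oracle = _basewise_totals(dataset.transcripts, sizes)
    for label, expected in oracle.items():
        assert partition.total_bp[label] == expected, label


def test_gene_body_plus_intergenic_covers_genome(partition, dataset):
    genome_len = sum(g.length for g in dataset.genome.values())
    assert partition.total_bp["gene_body"] + partition.total_bp["intergenic"] == genome_len


def test_transcript_tiles_into_utr_cds_exon_intron(dataset):
    """utr5 + exonic CDS + utr3 + intron tile [tx_start, tx_end) exactly."""
    for t in dataset.transcripts:
        u5, u3 = t.utr_intervals()
        cds_exonic = subtract_intervals(
            t.exons, u5 + u3
        )
        intron = subtract_intervals([(t.tx_start, t.tx_end)], t.exons)
        pieces = u5 + u3 + cds_exonic + intron
        assert total_length(pieces) == t.tx_end - t.tx_start
        assert total_length(merge_intervals(pieces)) == t.tx_end - t.tx_start
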