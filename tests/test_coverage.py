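import numpy as np
import pytest

from polwave import (
    AnalysisWindow,
    CoverageMatrix,
    FormatError,
    ParameterError,
    SignalTrack,
    classify_by_occupancy,
    gene_matrix,
    heatmap_sort,
    metagene,
    normalize_depth,
)
from polwave.coverage import read_matrix, write_matrix


def _win(tss=5000, strand="+", **kw):
    return AnalysisWindow("tx", "chr1", tss, strand, **kw)


# ---------------------------------------------------------------------------
# SignalTrack


def test_bedgraph_interval_sum(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t100\t2.0\n")
    track = SignalTrack.from_bedgraph(p)
    assert track.interval_sum("chr1", 0, 100) == pytest.approx(200.0)
    assert track.total_signal == pytest.approx(200.0)


def test_query_beyond_coverage_is_zero(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t1000\t2000\t3.5\n")
    track = SignalTrack.from_bedgraph(p)
    assert track.interval_sum("chr1", 5000, 6000) == 0.0
    assert track.interval_sum("chr1", 0, 500) == 0.0
    assert track.interval_sum("chr2", 0, 500) == 0.0  # unknown chrom -> 0


def test_partition_additivity(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t100\t2.0\n")
    track = SignalTrack.from_bedgraph(p)
    edges = np.array([0, 13, 40, 77, 100])
    assert track.bin_sums("chr1", edges).sum() == pytest.approx(200.0)


def test_partial_overlap_is_prorated(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t100\t200\t4.0\n")
    track = SignalTrack.from_bedgraph(p)
    assert track.interval_sum("chr1", 150, 250) == pytest.approx(200.0)


def test_overlapping_bedgraph_rejected(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t100\t1.0\nchr1\t50\t150\t1.0\n")
    with pytest.raises(FormatError, match="overlapping"):
        SignalTrack.from_bedgraph(p)


def test_bed_reads_total_is_count(tmp_path):
    p = tmp_path / "reads.bed"
    p.write_text("chr1\t0\t50\nchr1\t25\t75\nchr1\t1000\t1100\n")
    track = SignalTrack.from_bed_reads(p)
    assert track.total_signal == 3.0
    # overlapping reads stack as coverage
    assert track.interval_sum("chr1", 25, 50) == pytest.approx(50.0)


def test_gap_between_intervals_counts_zero(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("chr1\t0\t10\t1\nchr1\t90\t100\t1\n")
    track = SignalTrack.from_bedgraph(p)
    assert track.interval_sum("chr1", 10, 90) == 0.0
    assert track.interval_sum("chr1", 0, 100) == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# gene_matrix


def _uniform_track(value=1.0, end=10_000_000):
    return SignalTrack.from_intervals(["chr1"], [0], [end], [value])


def test_uniform_signal_gives_constant_bins():
    mat = gene_matrix(_uniform_track(), [_win()])
    assert mat.values.shape == (1, 160)
    assert np.allclose(mat.values, 200.0)


def test_empty_window_list():
    mat = gene_matrix(_uniform_track(), [])
    assert mat.values.shape[0] == 0


def test_stranded_tracks_route_by_gene_strand():
    plus = _uniform_track(2.0)
    minus = _uniform_track(5.0)
    wins = [_win(), _win(tss=500_000, strand="-")]
    mat = gene_matrix({"+": plus, "-": minus}, wins)
    assert np.allclose(mat.values[0], 400.0)
    assert np.allclose(mat.values[1], 1000.0)
    assert mat.library_size == plus.total_signal + minus.total_signal


def test_minus_strand_rows_reversed():
    # signal only in [498_500, 500_000): the 1.5 kb immediately 5' of a
    # minus-strand TSS at 500_000 -> must appear in downstream-of-TSS bins
    track = SignalTrack.from_intervals(["chr1"], [498_500], [500_000], [1.0])
    mat = gene_matrix(track, [_win(tss=500_000, strand="-")])
    centers = mat.bin_centers_bp
    downstream = (centers > 0) & (centers < 1500)
    assert np.all(mat.values[0, downstream] > 0)
    assert np.all(mat.values[0, centers < 0] == 0)


def test_strand_symmetric_signal_gives_identical_rows():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 5, size=400)
    starts = 100_000 + 100 * np.arange(400)
    track = SignalTrack.from_intervals(
        ["chr1"] * 400, starts, starts + 100, vals
    )
    tss = 120_000
    plus = gene_matrix(track, [_win(tss=tss)])
    # mirror the track around the TSS for the minus-strand version
    m_starts = 2 * tss - (starts + 100)
    mtrack = SignalTrack.from_intervals(["chr1"] * 400, m_starts, m_starts + 100, vals)
    minus = gene_matrix(mtrack, [_win(tss=tss, strand="-")])
    assert np.allclose(plus.values, minus.values)


def test_matrix_linearity():
    a = SignalTrack.from_intervals(["chr1"], [0], [1_000_000], [1.5])
    b = SignalTrack.from_intervals(["chr1"], [0], [1_000_000], [2.5])
    both = SignalTrack.from_intervals(["chr1"], [0], [1_000_000], [4.0])
    wins = [_win()]
    assert np.allclose(
        gene_matrix(a, wins).values + gene_matrix(b, wins).values,
        gene_matrix(both, wins).values,
    )


def test_mixed_bin_schemes_rejected():
    with pytest.raises(ParameterError):
        gene_matrix(_uniform_track(), [_win(), _win(tss=400_000, bin_bp=100)])


# ---------------------------------------------------------------------------
# normalization


def _matrix(values, library=2e6, normalized=False):
    values = np.asarray(values, dtype=float)
    return CoverageMatrix(
        condition="WT",
        assay="nascent",
        timepoint_min=10.0,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        bin_offsets_bp=200.0 * np.arange(values.shape[1]),
        bin_bp=200,
        values=values,
        normalized=normalized,
        library_size=library,
    )


def test_normalize_per_million():
    mat = normalize_depth(_matrix([[4.0, 8.0]], library=2e6))
    assert np.allclose(mat.values, [[2.0, 4.0]])
    assert mat.normalized


def test_double_normalization_guard():
    mat = normalize_depth(_matrix([[4.0]]))
    with pytest.raises(ParameterError, match="already"):
        normalize_depth(mat)


def test_zero_library_rejected():
    with pytest.raises(ParameterError):
        normalize_depth(_matrix([[1.0]], library=0.0))


def test_scale_invariance_of_normalization():
    base = normalize_depth(_matrix([[4.0, 1.0]], library=8.0))
    scaled = normalize_depth(_matrix([[4.0 * 7, 1.0 * 7]], library=8.0 * 7))
    assert np.allclose(base.values, scaled.values)


# ---------------------------------------------------------------------------
# metagene / sorting / classification


def test_metagene_and_sort():
    mat = _matrix([[1.0, 2.0], [3.0, 4.0]])
    prof = metagene(mat)
    assert np.allclose(prof.mean_signal, [2.0, 3.0])
    assert prof.n_genes == 2
    ordered = heatmap_sort(mat)
    assert ordered.gene_ids == ["g1", "g0"]
    assert np.allclose(ordered.values[0], [3.0, 4.0])


def test_metagene_identical_rows():
    row = [5.0, 1.0, 2.0]
    mat = _matrix([row] * 7)
    assert np.allclose(metagene(mat).mean_signal, row)
    assert np.allclose(metagene(mat, stat="median").mean_signal, row)


def test_metagene_empty_matrix_errors():
    mat = gene_matrix(_uniform_track(), [])
    with pytest.raises(ParameterError):
        metagene(mat)


def test_heatmap_sort_is_stable():
    mat = _matrix([[1.0, 1.0], [2.0, 2.0], [1.0, 1.0]])
    ordered = heatmap_sort(mat)
    assert ordered.gene_ids == ["g1", "g0", "g2"]


def test_classify_thresholds():
    mat = _matrix([[0.0], [1.0], [10.0]], normalized=True)
    labels = classify_by_occupancy(mat, thresholds=(0.5, 5.0))
    assert labels == {"g0": "No", "g1": "Low", "g2": "High"}


def test_classify_all_zero(caplog):
    mat = _matrix([[0.0], [0.0]], normalized=True)
    labels = classify_by_occupancy(mat)
    assert set(labels.values()) == {"No"}


def test_classify_partitions_gene_set():
    rng = np.random.default_rng(1)
    mat = _matrix(rng.uniform(0, 10, size=(30, 4)), normalized=True)
    labels = classify_by_occupancy(mat)
    assert sorted(labels) == sorted(mat.gene_ids)
    assert set(labels.values()) <= {"High", "Low", "No"}
    # tertiles of 30 nonzero genes -> 10 per group
    counts = {lab: list(labels.values()).count(lab) for lab in ("No", "Low", "High")}
    assert counts == {"No": 10, "Low": 10, "High": 10}


def test_classify_requires_normalized():
    with pytest.raises(ParameterError):
        classify_by_occupancy(_matrix([[1.0]]))


# ---------------------------------------------------------------------------
# persistence


def test_matrix_roundtrip(tmp_path):
    mat = normalize_depth(_matrix([[1.0, 2.0], [3.5, 0.0]]))
    path = tmp_path / "m.tsv.gz"
    write_matrix(mat, path)
    back = read_matrix(path)
    assert back.gene_ids == mat.gene_ids
    assert np.allclose(back.values, mat.values)
    assert back.normalized == mat.normalized
    assert back.library_size == mat.library_size
    assert back.timepoint_min == mat.timepoint_min
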