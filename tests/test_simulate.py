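import math

import numpy as np
import pandas as pd
import pytest

from polwave import (
    LayoutError,
    ParameterError,
    SimParams,
    SimTruth,
    TranscriptModel,
    filter_transcripts,
    render_nascent_track,
    render_polii_track,
    simulate_cohort,
    simulate_polymerases,
)
from polwave._rng import child_rng

GENE = TranscriptModel("g", "chr1", 0, 40_000, "+")
LONG_GENE = TranscriptModel("g", "chr1", 0, 400_000, "+")


# ---------------------------------------------------------------------------
# parameters


def test_param_validation():
    with pytest.raises(ParameterError):
        SimParams(speed_kb_per_min=float("nan"))
    with pytest.raises(ParameterError):
        SimParams(termination_hazard_per_kb=-0.1)
    with pytest.raises(ParameterError):
        SimParams(release_rate_per_min=0.0)
    with pytest.raises(ParameterError):
        SimParams(timepoints_min=(5.0, 0.0))
    with pytest.raises(ParameterError):
        SimParams(timepoints_min=(0.0, 10.0), label_windows=[(0, 0), (0, 10)])


def test_label_window_defaults_to_release_interval():
    params = SimParams(timepoints_min=(0.0, 5.0))
    assert params.label_window_for(5.0) == (0.0, 5.0)
    with pytest.raises(ParameterError):
        params.label_window_for(7.0)


def test_truth_invariant():
    with pytest.raises(ParameterError):
        SimTruth("t", 2.0, 0.0, n_polymerases_released=5, n_terminated=6)


# ---------------------------------------------------------------------------
# trajectories


def test_deterministic_limit_hazard_zero():
    # v = 2.5 kb/min, t = 10 min -> every position at 25 kb (gene end if shorter)
    params = SimParams(speed_kb_per_min=2.5, termination_hazard_per_kb=0.0, seed=1)
    ens = simulate_polymerases(params, LONG_GENE, 500)
    assert np.all(ens.positions_at(10.0) == 50.0 + 25_000.0)
    short = simulate_polymerases(
        params, TranscriptModel("s", "chr1", 0, 10_000, "+"), 500
    )
    assert np.all(short.positions_at(10.0) == 10_000.0)


def test_zero_speed_stays_at_pause_site():
    params = SimParams(speed_kb_per_min=0.0, seed=1)
    ens = simulate_polymerases(params, GENE, 100)
    for t in (0.0, 5.0, 50.0):
        assert np.all(ens.positions_at(t) == params.pause_site_offset_bp)


def test_survival_matches_exponential():
    hazard = 0.05
    n = 10_000
    params = SimParams(
        speed_kb_per_min=2.0, termination_hazard_per_kb=hazard,
        pause_site_offset_bp=0, seed=2,
    )
    ens = simulate_polymerases(params, TranscriptModel("g", "chr1", 0, 10_000_000, "+"), n)
    for d_kb in (5.0, 10.0, 20.0):
        expected = math.exp(-hazard * d_kb)
        observed = np.mean(ens.stop_bp > d_kb * 1000)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se


def test_n_pol_must_be_positive():
    with pytest.raises(ParameterError):
        simulate_polymerases(SimParams(), GENE, 0)


# ---------------------------------------------------------------------------
# nascent rendering


def _noiseless(**kw):
    defaults = dict(
        speed_kb_per_min=2.0,
        termination_hazard_per_kb=0.0,
        read_depth_per_kb=50.0,
        timepoints_min=(0.0, 5.0, 10.0),
        poisson_noise=False,
        seed=0,
    )
    defaults.update(kw)
    return SimParams(**defaults)


def test_zero_depth_gives_zero_track():
    params = _noiseless(read_depth_per_kb=0.0)
    ens = simulate_polymerases(params, GENE, 50)
    expected, counts = render_nascent_track(ens, params, 10.0, 200)
    assert np.all(expected == 0) and np.all(counts == 0)


def test_uniform_plateau_up_to_wave_front():
    params = _noiseless()
    ens = simulate_polymerases(params, GENE, 50)
    expected, _ = render_nascent_track(ens, params, 10.0, 200)
    # front at pause + v*t = 50 + 20,000; bins fully inside the plateau are
    # equal at depth * bin_kb; bins beyond the front are exactly zero
    full = expected[1:100]  # bins [200, 20000)
    assert np.allclose(full, 50.0 * 0.2)
    assert np.all(expected[101:] == 0.0)


def test_wave_front_position_noiseless():
    for t, v in ((5.0, 2.0), (10.0, 1.0)):
        params = _noiseless(speed_kb_per_min=v)
        ens = simulate_polymerases(params, LONG_GENE, 20)
        expected, _ = render_nascent_track(ens, params, t, 200)
        front_bin = np.flatnonzero(expected > 0)[-1]
        true_front = params.pause_site_offset_bp + v * 1000 * t
        assert abs((front_bin + 1) * 200 - true_front) <= 200


def test_depth_linearity():
    p1 = _noiseless(read_depth_per_kb=50.0)
    p2 = _noiseless(read_depth_per_kb=100.0)
    ens = simulate_polymerases(p1, GENE, 50)
    e1, _ = render_nascent_track(ens, p1, 10.0, 200)
    e2, _ = render_nascent_track(ens, p2, 10.0, 200)
    assert np.allclose(e2, 2.0 * e1)


def test_timepoint_zero_is_promoter_pulse_only():
    params = _noiseless()
    ens = simulate_polymerases(params, GENE, 50)
    expected, _ = render_nascent_track(ens, params, 0.0, 200)
    assert expected[0] > 0  # pause-site pulse
    assert np.all(expected[1:] == 0.0)


def test_dropping_terminated_rna_reduces_signal():
    base = _noiseless(termination_hazard_per_kb=0.2)
    drop = _noiseless(termination_hazard_per_kb=0.2, keep_terminated_rna=False)
    ens = simulate_polymerases(base, GENE, 200, rng=child_rng(5, "x"))
    e_keep, _ = render_nascent_track(ens, base, 10.0, 200)
    e_drop, _ = render_nascent_track(ens, drop, 10.0, 200)
    assert e_drop.sum() < e_keep.sum()


def test_bad_bin_rejected():
    params = _noiseless()
    ens = simulate_polymerases(params, GENE, 10)
    with pytest.raises(ParameterError):
        render_nascent_track(ens, params, 10.0, 0)


# ---------------------------------------------------------------------------
# Pol II rendering


def test_polii_all_at_pause_bin_at_t0():
    params = _noiseless()
    ens = simulate_polymerases(params, GENE, 80)
    expected, _ = render_polii_track(ens, params, 0.0, 200)
    assert expected[0] == 80.0
    assert np.all(expected[1:] == 0.0)


def test_polii_conservation_without_hazard():
    params = _noiseless()
    ens = simulate_polymerases(params, LONG_GENE, 80)
    totals = [render_polii_track(ens, params, t, 200)[0].sum() for t in (0.0, 5.0, 10.0)]
    assert totals == [80.0, 80.0, 80.0]


def test_polii_body_occupancy_declines_with_hazard():
    params = _noiseless(termination_hazard_per_kb=0.1, release_rate_per_min=0.5)
    ens = simulate_polymerases(params, LONG_GENE, 5000, rng=child_rng(6, "y"))
    occ5, _ = render_polii_track(ens, params, 5.0, 200)
    occ10, _ = render_polii_track(ens, params, 10.0, 200)
    assert occ10.sum() < occ5.sum()


def test_runoff_removes_polymerases():
    params = _noiseless(speed_kb_per_min=5.0)
    ens = simulate_polymerases(params, GENE, 40)  # 40 kb gene, 50 kb travelled
    expected, _ = render_polii_track(ens, params, 10.0, 200)
    assert expected.sum() == 0.0


# ---------------------------------------------------------------------------
# cohort


def test_cohort_deterministic_bytes(tmp_path):
    params = {
        "WT": SimParams(timepoints_min=(0.0, 10.0), read_depth_per_kb=20.0, seed=9)
    }
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_cohort(params, n_genes=12, seed=9, outdir=d1)
    simulate_cohort(params, n_genes=12, seed=9, outdir=d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    for name in files:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_cohort_gene_lengths_and_filter_survival(small_cohort):
    lengths = np.array([t.length for t in small_cohort.transcripts])
    assert np.all(lengths > 30_000) and np.all(lengths <= 300_000)
    res = filter_transcripts(small_cohort.transcripts)
    assert len(res.survivors) == len(small_cohort.transcripts)


def test_cohort_truth_roundtrip(small_cohort):
    back = pd.read_csv(small_cohort.outdir / "truth.tsv", sep="\t")
    pd.testing.assert_frame_equal(back, small_cohort.truth)
    assert (back["n_terminated"] <= back["n_polymerases_released"]).all()


def test_cohort_ko_less_labeled_signal_than_wt(wtko_cohort):
    totals = {}
    for cond in ("WT", "KO"):
        t = 0.0
        for strand in ("+", "-"):
            path = wtko_cohort.files[cond]["nascent"][10.0][strand]
            df = pd.read_csv(path, sep="\t", header=None)
            t += df[3].sum()
        totals[cond] = t
    assert totals["KO"] < totals["WT"]


def test_cohort_layout_error_when_space_exhausted():
    params = {"WT": SimParams(timepoints_min=(0.0,), seed=0)}
    with pytest.raises(LayoutError):
        simulate_cohort(params, n_genes=5, seed=0, chrom_size_bp=200_000)


def test_cohort_in_memory_tracks(noiseless_cohort):
    tracks = noiseless_cohort.files["WT"]["nascent"][10.0]
    assert set(tracks) == {"+", "-"}
    total = tracks["+"].total_signal + tracks["-"].total_signal
    assert total > 0
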