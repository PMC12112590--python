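import numpy as np
import pytest

from polwave import (
    CoverageMatrix,
    EstimationError,
    ParameterError,
    SimParams,
    WaveFit,
    estimate_rate,
    fit_wave,
    fit_wave_at_timepoint,
    gene_matrix,
    make_windows,
    metagene_rate,
    normalize_depth,
    per_gene_rates,
    simulate_cohort,
)

CENTERS = np.arange(-2000 + 100.0, 30_000, 200.0)


def _fit(timepoint, peak, front=None):
    return WaveFit(
        timepoint_min=timepoint,
        bin_centers_bp=CENTERS,
        smoothed=np.zeros_like(CENTERS),
        peak_pos_bp=peak,
        peak_height=1.0,
        front_pos_bp=front if front is not None else peak,
        smoothing_parameter=0.0,
        exclusion_zone_bp=0.0,
    )


# ---------------------------------------------------------------------------
# fit_wave


def test_triangular_peak_recovered_within_one_bin():
    true_peak = 12_000.0
    y = np.clip(1.0 - np.abs(CENTERS - true_peak) / 4000.0, 0.0, None)
    # independent oracle: dense argmax of the analytic profile
    dense = np.linspace(CENTERS[0], CENTERS[-1], 100_001)
    oracle = dense[np.argmax(np.clip(1.0 - np.abs(dense - true_peak) / 4000.0, 0, None))]
    fit = fit_wave((CENTERS, y), exclusion_zone_bp=0.0)
    assert fit.has_peak
    assert abs(fit.peak_pos_bp - oracle) <= 200.0


def test_single_bin_mass_peaks_at_that_bin():
    y = np.zeros_like(CENTERS)
    y[10] = 5.0
    fit = fit_wave((CENTERS, y), exclusion_zone_bp=0.0)
    assert abs(fit.peak_pos_bp - CENTERS[10]) <= 200.0


def test_constant_offset_leaves_peak_unchanged():
    rng = np.random.default_rng(4)
    y = np.exp(-0.5 * ((CENTERS - 9000) / 2500.0) ** 2) * 10 + rng.poisson(2.0, CENTERS.size)
    f1 = fit_wave((CENTERS, y.astype(float)), exclusion_zone_bp=0.0)
    f2 = fit_wave((CENTERS, y.astype(float) + 100.0), exclusion_zone_bp=0.0)
    assert abs(f1.peak_pos_bp - f2.peak_pos_bp) <= 200.0


def test_flat_zero_profile_flagged_not_raised():
    fit = fit_wave((CENTERS, np.zeros_like(CENTERS)))
    assert not fit.has_peak
    assert fit.peak_pos_bp is None and fit.front_pos_bp is None


def test_exclusion_zone_skips_promoter_spike():
    y = np.zeros_like(CENTERS)
    y[np.argmin(np.abs(CENTERS - 100))] = 100.0  # pause spike
    bump = 10.0 * np.exp(-0.5 * ((CENTERS - 15_000) / 2000.0) ** 2)
    fit = fit_wave((CENTERS, y + bump), exclusion_zone_bp=500.0)
    assert abs(fit.peak_pos_bp - 15_000) < 1000.0
    fit0 = fit_wave((CENTERS, y + bump), exclusion_zone_bp=0.0)
    assert fit0.peak_pos_bp < 500.0


def test_front_downstream_of_peak():
    y = np.where((CENTERS > 0) & (CENTERS < 20_000), 10.0, 0.0)
    fit = fit_wave((CENTERS, y), exclusion_zone_bp=500.0)
    assert 19_000 < fit.front_pos_bp < 21_000


def test_front_clamps_at_window_end():
    y = np.full_like(CENTERS, 10.0)
    fit = fit_wave((CENTERS, y), exclusion_zone_bp=0.0)
    assert fit.front_pos_bp == pytest.approx(CENTERS[-1])


def test_fit_wave_input_validation():
    with pytest.raises(ParameterError):
        fit_wave((CENTERS[:5], np.ones(5)))
    with pytest.raises(ParameterError):
        fit_wave((CENTERS, -np.ones_like(CENTERS)))


def test_exclusion_disabled_at_time_zero():
    y = np.zeros_like(CENTERS)
    y[np.argmin(np.abs(CENTERS - 100))] = 50.0
    fit0 = fit_wave_at_timepoint((CENTERS, y), 0.0, exclusion_zone_bp=500.0)
    assert fit0.peak_pos_bp < 500.0
    fit10 = fit_wave_at_timepoint((CENTERS, y), 10.0, exclusion_zone_bp=500.0)
    assert fit10.peak_pos_bp is None or fit10.peak_pos_bp > 500.0


# ---------------------------------------------------------------------------
# estimate_rate


def test_two_point_slope():
    est = estimate_rate([_fit(0.0, 300.0), _fit(10.0, 20_300.0)])
    assert est.rate_kb_per_min == pytest.approx(2.0)
    assert est.intercept_bp == pytest.approx(300.0)


def test_identical_peaks_give_zero_rate():
    est = estimate_rate([_fit(0.0, 5000.0), _fit(10.0, 5000.0)])
    assert est.rate_kb_per_min == pytest.approx(0.0)


def test_three_collinear_points_exact():
    est = estimate_rate([_fit(0.0, 500.0), _fit(5.0, 10_500.0), _fit(10.0, 20_500.0)])
    assert est.rate_kb_per_min == pytest.approx(2.0)
    fitted = est.intercept_bp + 1000.0 * est.rate_kb_per_min * np.array([0.0, 5.0, 10.0])
    assert np.allclose(fitted, [500.0, 10_500.0, 20_500.0])


def test_insufficient_points_raise():
    with pytest.raises(EstimationError):
        estimate_rate([_fit(0.0, 100.0)])
    with pytest.raises(EstimationError):
        estimate_rate([_fit(0.0, 100.0), _fit(0.0, 200.0)])  # same timepoint


def test_unknown_feature_rejected():
    with pytest.raises(ParameterError):
        estimate_rate([_fit(0.0, 1.0), _fit(10.0, 2.0)], feature="midpoint")


# ---------------------------------------------------------------------------
# per-gene rates


def _spike_matrix(timepoint, positions_bp):
    values = np.zeros((len(positions_bp), CENTERS.size))
    for i, pos in enumerate(positions_bp):
        values[i, np.argmin(np.abs(CENTERS - pos))] = 10.0
    return CoverageMatrix(
        condition="WT",
        assay="nascent",
        timepoint_min=timepoint,
        gene_ids=[f"g{i}" for i in range(len(positions_bp))],
        bin_offsets_bp=CENTERS - 100.0,
        bin_bp=200,
        values=values,
        normalized=True,
        library_size=1e6,
    )


def test_per_gene_rates_arithmetic():
    mats = {
        0.0: _spike_matrix(0.0, [100.0, 100.0]),
        10.0: _spike_matrix(10.0, [20_100.0, 30_100.0]),
    }
    est = per_gene_rates(mats, feature="peak")
    assert est.n_genes == 2 and est.n_excluded == 0
    assert np.allclose(sorted(est.per_gene_rates), [2.0, 3.0], atol=0.05)
    assert est.sd_across_genes == pytest.approx(0.7071, abs=0.05)
    assert est.rate_kb_per_min == pytest.approx(2.5, abs=0.05)


def test_per_gene_excludes_flagged_genes():
    m0 = _spike_matrix(0.0, [100.0, 100.0])
    m10 = _spike_matrix(10.0, [20_100.0, 30_100.0])
    m10.values[1, :] = 0.0  # gene 2 has no signal at 10 min
    est = per_gene_rates({0.0: m0, 10.0: m10}, feature="peak")
    assert est.n_genes == 1 and est.n_excluded == 1


def test_per_gene_all_excluded_raises():
    m0 = _spike_matrix(0.0, [100.0])
    m10 = _spike_matrix(10.0, [20_100.0])
    m0.values[:] = 0.0
    with pytest.raises(EstimationError):
        per_gene_rates({0.0: m0, 10.0: m10}, feature="peak")


# ---------------------------------------------------------------------------
# simulator recovery


def _matrices_from_cohort(cohort, timepoints, condition="WT"):
    res = make_windows(cohort.transcripts, cohort.chrom_sizes)
    mats = {}
    for tp in timepoints:
        tracks = cohort.files[condition]["nascent"][tp]
        mats[tp] = normalize_depth(
            gene_matrix(tracks, res.windows, condition=condition, timepoint_min=tp)
        )
    return mats


def test_rate_recovery_on_simulated_cohort(small_cohort):
    from polwave.coverage import SignalTrack

    res = make_windows(small_cohort.transcripts, small_cohort.chrom_sizes)
    mats = {}
    for tp in (0.0, 10.0):
        paths = small_cohort.files["WT"]["nascent"][tp]
        tracks = {s: SignalTrack.from_bedgraph(paths[s]) for s in "+-"}
        mats[tp] = normalize_depth(gene_matrix(tracks, res.windows, timepoint_min=tp))
    est, fits = metagene_rate(mats, feature="front")
    assert abs(est.rate_kb_per_min - 2.0) / 2.0 <= 0.10
    pg = per_gene_rates(mats, feature="front")
    assert abs(pg.rate_kb_per_min - 2.0) / 2.0 <= 0.10
    assert pg.n_genes >= 25


def test_noiseless_per_gene_dispersion_below_bin_resolution(noiseless_cohort):
    mats = _matrices_from_cohort(noiseless_cohort, (0.0, 10.0))
    est = per_gene_rates(mats, feature="front")
    # one bin width (200 bp) over the 10-min spacing = 0.02 kb/min
    assert est.sd_across_genes <= 0.02
    assert est.rate_kb_per_min == pytest.approx(2.0, rel=0.05)


def test_front_monotone_in_time_noiseless(noiseless_cohort):
    mats = _matrices_from_cohort(noiseless_cohort, (0.0, 5.0, 10.0))
    from polwave.coverage import metagene

    fronts = []
    peaks = []
    for tp in (0.0, 5.0, 10.0):
        fit = fit_wave_at_timepoint(metagene(mats[tp]), tp)
        fronts.append(fit.front_pos_bp)
        peaks.append(fit.peak_pos_bp)
    assert fronts == sorted(fronts)
    assert peaks == sorted(peaks)
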