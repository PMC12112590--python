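import pytest

from polwave import SimParams, simulate_cohort

WT_KWARGS = dict(
    speed_kb_per_min=2.0,
    termination_hazard_per_kb=0.01,
    release_rate_per_min=0.5,
    read_depth_per_kb=50.0,
)
KO_KWARGS = dict(
    speed_kb_per_min=2.6,
    termination_hazard_per_kb=0.05,
    release_rate_per_min=0.5,
    read_depth_per_kb=50.0,
)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """30 WT genes, instantaneous release, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("cohort_wt")
    params = {
        "WT": SimParams(
            speed_kb_per_min=2.0,
            termination_hazard_per_kb=0.02,
            read_depth_per_kb=50.0,
            timepoints_min=(0.0, 5.0, 10.0),
            seed=7,
        )
    }
    return simulate_cohort(params, n_genes=30, seed=7, outdir=outdir)


@pytest.fixture(scope="session")
def wtko_cohort(tmp_path_factory):
    """40 genes under WT and KO kinetics with spread release."""
    outdir = tmp_path_factory.mktemp("cohort_wtko")
    params = {
        "WT": SimParams(timepoints_min=(0.0, 5.0, 10.0), seed=11, **WT_KWARGS),
        "KO": SimParams(timepoints_min=(0.0, 5.0, 10.0), seed=11, **KO_KWARGS),
    }
    return simulate_cohort(params, n_genes=40, seed=11, outdir=outdir)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small in-memory cohort with Poisson noise disabled (exact expectations)."""
    params = {
        "WT": SimParams(
            speed_kb_per_min=2.0,
            termination_hazard_per_kb=0.0,
            read_depth_per_kb=50.0,
            timepoints_min=(0.0, 5.0, 10.0),
            poisson_noise=False,
            seed=3,
        )
    }
    return simulate_cohort(params, n_genes=10, seed=3, outdir=None)
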