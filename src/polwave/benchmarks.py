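"""Self-contained verification benchmarks.

Each function simulates (or constructs) its own inputs from a seed, runs the
relevant slice of the pipeline, and returns measured quantities together
with the bounds they are expected to satisfy. They back both the acceptance
test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from ._rng import child_rng
from .annotation import TranscriptModel, filter_transcripts, make_windows
from .config import validate_config
from .coverage import CoverageMatrix, SignalTrack, gene_matrix, normalize_depth
from .pipeline import run_all
from .processivity import occupancy_timecourse, processivity_index
from .simulate import SimParams, simulate_polymerases
from .wave import fit_wave, metagene_rate


# ---------------------------------------------------------------------------
# 1. elongation-rate recovery


def rate_recovery(seed: int, outdir: str | Path, n_genes: int = 200) -> dict:
    """Full-pipeline rate estimate on an instantaneous-release cohort with
    v = 2.0 kb/min, hazard = 0.02 /kb, depth 50 reads/kb, timepoints {0, 10}."""
    cfg = validate_config(
        {
            "seed": seed,
            "outdir": str(outdir),
            "timepoints_min": [0, 10],
            "simulate": {
                "n_genes": n_genes,
                "params": {
                    "WT": {
                        "speed_kb_per_min": 2.0,
                        "termination_hazard_per_kb": 0.02,
                        "read_depth_per_kb": 50.0,
                    }
                },
                "assays": ["nascent"],
            },
        }
    )
    manifest = run_all(cfg)
    entry = manifest["results"]["rates"]["WT"]
    return {
        "true_speed_kb_per_min": 2.0,
        "rate_kb_per_min": entry["metagene_rate_kb_per_min"],
        "per_gene_mean_rate_kb_per_min": entry["per_gene_mean_rate_kb_per_min"],
        "bounds": (1.8, 2.2),
        "n_genes": n_genes,
    }


# ---------------------------------------------------------------------------
# 2. speed-processivity dissociation


def dissociation(seed: int, outdir: str | Path, n_genes: int = 200) -> dict:
    """WT (v=2.0, hazard=0.01) vs KO (v=2.6, hazard=0.05) under spread
    release; returns the rate / nascent / occupancy orderings."""
    cfg = validate_config(
        {
            "seed": seed,
            "outdir": str(outdir),
            "timepoints_min": [0, 5, 10],
            "per_gene": False,
            "simulate": {
                "n_genes": n_genes,
                "params": {
                    "WT": {
                        "speed_kb_per_min": 2.0,
                        "termination_hazard_per_kb": 0.01,
                        "release_rate_per_min": 0.5,
                        "read_depth_per_kb": 50.0,
                    },
                    "KO": {
                        "speed_kb_per_min": 2.6,
                        "termination_hazard_per_kb": 0.05,
                        "release_rate_per_min": 0.5,
                        "read_depth_per_kb": 50.0,
                    },
                },
            },
        }
    )
    manifest = run_all(cfg)
    res = manifest["results"]
    rates = {c: r["metagene_rate_kb_per_min"] for c, r in res["rates"].items()}
    nascent = {c: d["10.0"] for c, d in res["nascent_totals"].items()}
    from .coverage import read_matrix

    body: dict = {}
    for cond in ("WT", "KO"):
        mats = {
            tp: read_matrix(Path(outdir) / f"matrix_{cond}_polii_t{tp:g}.tsv.gz")
            for tp in (0.0, 5.0, 10.0)
        }
        tc = occupancy_timecourse(mats)
        body[cond] = dict(zip(tc.timepoints, tc.gene_body_totals))
    ratio5 = body["KO"][5.0] / body["WT"][5.0]
    return {
        "rate_wt_kb_per_min": rates["WT"],
        "rate_ko_kb_per_min": rates["KO"],
        "nascent_total_10min_wt": nascent["WT"],
        "nascent_total_10min_ko": nascent["KO"],
        "body_occupancy_5min_ko_over_wt": ratio5,
        "body_occupancy_10min_wt": body["WT"][10.0],
        "body_occupancy_10min_ko": body["KO"][10.0],
        "checks": {
            "rate_ko_gt_wt": rates["KO"] > rates["WT"],
            "nascent_10min_ko_lt_wt": nascent["KO"] < nascent["WT"],
            "body_10min_ko_lt_wt": body["KO"][10.0] < body["WT"][10.0],
            "body_5min_within_15pct": abs(ratio5 - 1.0) <= 0.15,
        },
        "n_genes": n_genes,
    }


# ---------------------------------------------------------------------------
# 3. survival law


def survival_law(
    seed: int,
    hazard_per_kb: float = 0.05,
    n_pol: int = 10000,
    distances_kb: tuple = (5.0, 10.0, 20.0),
) -> dict:
    """Monte-Carlo survival past fixed distances vs exp(-hazard * d)."""
    params = SimParams(
        speed_kb_per_min=2.0,
        termination_hazard_per_kb=hazard_per_kb,
        pause_site_offset_bp=0,
        seed=seed,
    )
    gene = TranscriptModel("g", "chr1", 0, 10_000_000, "+")
    ens = simulate_polymerases(params, gene, n_pol, rng=child_rng(seed, "survival"))
    out = {"n_pol": n_pol, "hazard_per_kb": hazard_per_kb, "distances": {}}
    ok = True
    for d in distances_kb:
        expected = math.exp(-hazard_per_kb * d)
        observed = float(np.mean(ens.stop_bp > d * 1000.0))
        se = math.sqrt(expected * (1 - expected) / n_pol)
        within = abs(observed - expected) <= 3 * se
        ok = ok and within
        out["distances"][d] = {
            "observed": observed,
            "expected": expected,
            "se": se,
            "within_3se": within,
        }
    out["all_within_3se"] = ok
    return out


# ---------------------------------------------------------------------------
# 4. spline peak vs dense-grid argmax oracle


def _analytic_profile(rng: np.random.Generator):
    """Random smooth unimodal wave over a (-2 kb, +30 kb) window."""
    center = rng.uniform(4000.0, 26000.0)
    width = rng.uniform(1500.0, 6000.0)
    amp = rng.uniform(1.0, 20.0)
    base = rng.uniform(0.0, 0.2 * amp)
    kind = rng.choice(["gauss", "triangle"])

    def f(x):
        x = np.asarray(x, dtype=float)
        if kind == "gauss":
            bump = amp * np.exp(-0.5 * ((x - center) / width) ** 2)
        else:
            bump = amp * np.clip(1.0 - np.abs(x - center) / width, 0.0, None)
        return base + bump

    return f, center


def spline_oracle_equivalence(seed: int, n_trials: int = 20, bin_bp: int = 200) -> dict:
    """Noiseless analytic profiles: spline peak must match the dense-grid
    argmax of the generating function within one bin."""
    rng = child_rng(seed, "oracle")
    centers = np.arange(-2000 + bin_bp / 2.0, 30000, bin_bp)
    dense = np.linspace(-2000, 30000, 64001)
    errors = []
    for _ in range(n_trials):
        f, _true_center = _analytic_profile(rng)
        oracle_peak = float(dense[np.argmax(f(dense))])
        fit = fit_wave((centers, f(centers)), exclusion_zone_bp=0.0)
        errors.append(abs(fit.peak_pos_bp - oracle_peak))
    return {
        "n_trials": n_trials,
        "bin_bp": bin_bp,
        "max_abs_error_bp": float(max(errors)),
        "all_within_one_bin": max(errors) <= bin_bp,
    }


# ---------------------------------------------------------------------------
# 5. filter determinism on the hand-written fixture


def toy_annotation() -> list[TranscriptModel]:
    """Five transcripts covering every rejection rule by hand enumeration."""
    return [
        TranscriptModel("tx_short", "chr1", 1_000_000, 1_020_000, "+"),  # 20 kb
        TranscriptModel("tx_badchrom", "chrUn_scaffold", 0, 50_000, "+"),
        TranscriptModel("tx_ovl_a", "chr1", 2_000_000, 2_040_000, "+"),
        TranscriptModel("tx_ovl_b", "chr1", 2_030_000, 2_080_000, "-"),
        TranscriptModel("tx_boundary", "chr1", 500, 40_500, "+"),  # window < 0
    ]


def filter_determinism(seed: int = 0) -> dict:
    """Hand-enumerated expectation: chrom=1, length=1, overlap=2 rejected;
    the one filter survivor is then dropped at the window boundary."""
    txs = toy_annotation()
    res = filter_transcripts(txs, chrom_whitelist=["chr1"])
    wres = make_windows(res.survivors, {"chr1": 10_000_000})
    return {
        "survivor_ids": sorted(t.transcript_id for t in res.survivors),
        "rejections": res.rejections,
        "n_windows": len(wres.windows),
        "n_dropped_boundary": wres.n_dropped_boundary,
        "expected": {
            "survivor_ids": ["tx_boundary"],
            "rejections": {"chrom": 1, "length": 1, "overlap": 2},
            "n_windows": 0,
            "n_dropped_boundary": 1,
        },
    }


# ---------------------------------------------------------------------------
# 6. closed-form processivity index


def exponential_occupancy_matrix(
    decay_per_kb: float = 0.1, bin_bp: int = 10, span_bp: int = 15000
) -> CoverageMatrix:
    offsets = np.arange(0.0, span_bp, bin_bp)
    centers_kb = (offsets + bin_bp / 2.0) / 1000.0
    values = np.exp(-decay_per_kb * centers_kb)[None, :]
    return CoverageMatrix(
        condition="analytic",
        assay="polii",
        timepoint_min=10.0,
        gene_ids=["g1"],
        bin_offsets_bp=offsets,
        bin_bp=bin_bp,
        values=values,
        normalized=True,
        library_size=1e6,
    )


def closed_form_index(seed: int = 0) -> dict:
    mat = exponential_occupancy_matrix()
    idx = processivity_index(
        mat, proximal_window_bp=(0.0, 5000.0), distal_window_bp=(10000.0, 15000.0)
    )
    expected = math.exp(-1.0)
    return {
        "index": idx.index,
        "expected": expected,
        "abs_error": abs(idx.index - expected),
        "within_tolerance": abs(idx.index - expected) <= 1e-3,
    }


# ---------------------------------------------------------------------------
# 7. normalization invariance


def _scaled_copy(src: Path, dst: Path, factor: float) -> None:
    with open(src) as fin, open(dst, "w") as fout:
        for line in fin:
            chrom, start, end, value = line.split("\t")
            fout.write(f"{chrom}\t{start}\t{end}\t{float(value) * factor:.10g}\n")


def normalization_invariance(
    seed: int, outdir: str | Path, factor: float = 7.0, n_genes: int = 40
) -> dict:
    """Scaling every track (and hence every library size) by ``factor`` must
    leave rates and processivity indices unchanged to 1e-9 relative."""
    outdir = Path(outdir)
    cfg = validate_config(
        {
            "seed": seed,
            "outdir": str(outdir / "base"),
            "timepoints_min": [0, 5, 10],
            "per_gene": False,
            "simulate": {
                "n_genes": n_genes,
                "params": {
                    "WT": {
                        "speed_kb_per_min": 2.0,
                        "termination_hazard_per_kb": 0.02,
                        "release_rate_per_min": 0.5,
                        "read_depth_per_kb": 50.0,
                    }
                },
            },
        }
    )
    run_all(cfg)

    sim_dir = outdir / "base" / "sim"
    scaled_dir = outdir / "scaled_tracks"
    scaled_dir.mkdir(parents=True, exist_ok=True)
    tracks: dict = {"WT": {"nascent": {}, "polii": {}}}
    for tp in (0, 5, 10):
        pair = {}
        for strand_key, strand_tag in (("plus", "plus"), ("minus", "minus")):
            src = sim_dir / f"WT_nascent_t{tp}_{strand_tag}.bedgraph"
            dst = scaled_dir / src.name
            _scaled_copy(src, dst, factor)
            pair[strand_key] = str(dst)
        tracks["WT"]["nascent"][tp] = pair
        src = sim_dir / f"WT_polii_t{tp}.bedgraph"
        dst = scaled_dir / src.name
        _scaled_copy(src, dst, factor)
        tracks["WT"]["polii"][tp] = str(dst)
    cfg_scaled = validate_config(
        {
            "seed": seed,
            "outdir": str(outdir / "scaled"),
            "timepoints_min": [0, 5, 10],
            "per_gene": False,
            "annotation": str(sim_dir / "annotation.bed"),
            "chrom_sizes": str(sim_dir / "chrom.sizes"),
            "conditions": ["WT"],
            "tracks": tracks,
        }
    )
    run_all(cfg_scaled)

    def extract(out):
        import json

        manifest = json.loads((Path(out) / "manifest.json").read_text())
        rate = manifest["results"]["rates"]["WT"]["metagene_rate_kb_per_min"]
        indices = {
            f"{row['timepoint_min']:g}": row["index"]
            for row in manifest["results"]["processivity"]
            if row["defined"]
        }
        return rate, indices

    rate_a, idx_a = extract(outdir / "base")
    rate_b, idx_b = extract(outdir / "scaled")
    rel = lambda a, b: abs(a - b) / max(abs(a), 1e-300)
    rate_rel = rel(rate_a, rate_b)
    idx_rel = max((rel(idx_a[k], idx_b[k]) for k in idx_a), default=0.0)
    return {
        "factor": factor,
        "rate_base": rate_a,
        "rate_scaled": rate_b,
        "rate_rel_diff": rate_rel,
        "index_rel_diff_max": idx_rel,
        "within_tolerance": rate_rel <= 1e-9 and idx_rel <= 1e-9,
        "n_genes": n_genes,
    }
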