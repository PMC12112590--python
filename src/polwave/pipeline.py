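"""End-to-end runner: simulate -> filter -> matrix -> wave -> processivity.

Every stage failure is re-raised as a :class:`StageError` naming the stage;
partial outputs already written are left in place. A run manifest records
the seed, resolved parameters, input checksums and outputs, so every number
in the artifact directory is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    AnalysisWindow,
    make_windows,
    read_annotation,
    read_chrom_sizes,
    write_bed6,
)
from .annotation import filter_transcripts
from .config import RunConfig
from .coverage import (
    CoverageMatrix,
    SignalTrack,
    gene_matrix,
    metagene,
    normalize_depth,
    write_matrix,
)
from .errors import StageError
from .processivity import (
    ConditionSummary,
    compare_conditions,
    occupancy_timecourse,
    processivity_index,
)
from .simulate import SimParams, simulate_cohort
from .wave import metagene_rate, per_gene_rates

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


class _Stage:
    """Context manager wrapping a pipeline stage with a named failure."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(self.name, exc) from exc
        logger.info("stage %s: done", self.name)
        return False


def run_all(cfg: RunConfig) -> dict:
    """Run the whole pipeline; returns the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "polwave_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config": _jsonable(vars(cfg)),
        "inputs": {},
        "outputs": [],
        "results": {},
    }

    # -- simulate ---------------------------------------------------------
    tracks_spec = cfg.tracks
    annotation_path = cfg.annotation
    chrom_sizes_path = cfg.chrom_sizes
    if cfg.simulate is not None:
        with _Stage("simulate"):
            sim_dir = outdir / "sim"
            params = {
                cond: SimParams(timepoints_min=cfg.timepoints_min, seed=cfg.seed, **kw)
                for cond, kw in cfg.simulate["params"].items()
            }
            cohort = simulate_cohort(
                params,
                n_genes=int(cfg.simulate.get("n_genes", 50)),
                length_range_kb=tuple(
                    cfg.simulate.get("length_range_kb", (30.0, 300.0))
                ),
                bin_bp=int(cfg.windows["bin_bp"]),
                seed=cfg.seed,
                outdir=sim_dir,
                assays=tuple(cfg.simulate.get("assays", ("nascent", "polii"))),
            )
            annotation_path = sim_dir / "annotation.bed"
            chrom_sizes_path = sim_dir / "chrom.sizes"
            tracks_spec = cohort.files
            manifest["results"]["simulated_genes"] = len(cohort.transcripts)

    # -- filter -----------------------------------------------------------
    with _Stage("filter"):
        transcripts = read_annotation(annotation_path)
        chrom_sizes = read_chrom_sizes(chrom_sizes_path)
        manifest["inputs"]["annotation"] = {
            "path": str(annotation_path),
            "sha256": _sha256(Path(annotation_path)),
        }
        fres = filter_transcripts(
            transcripts,
            min_len_bp=int(cfg.filter["min_len_bp"]),
            max_len_bp=cfg.filter["max_len_bp"],
            chrom_whitelist=cfg.filter["chrom_whitelist"],
        )
        write_bed6(fres.survivors, outdir / "survivors.bed")
        pd.Series(fres.rejections).rename("n_rejected").to_csv(
            outdir / "rejections.tsv", sep="\t"
        )
        manifest["results"]["n_survivors"] = len(fres.survivors)
        manifest["results"]["rejections"] = fres.rejections

    # -- windows + matrices ----------------------------------------------
    with _Stage("matrix"):
        windows_by_assay: dict[str, list[AnalysisWindow]] = {}
        for assay, downstream in (
            ("nascent", int(cfg.windows["downstream_bp"])),
            ("polii", int(cfg.windows["polii_downstream_bp"])),
        ):
            wres = make_windows(
                fres.survivors,
                chrom_sizes,
                upstream_bp=int(cfg.windows["upstream_bp"]),
                downstream_bp=downstream,
                bin_bp=int(cfg.windows["bin_bp"]),
            )
            windows_by_assay[assay] = wres.windows
            manifest["results"][f"n_windows_{assay}"] = len(wres.windows)
            manifest["results"][f"n_dropped_boundary_{assay}"] = wres.n_dropped_boundary

        matrices: dict[str, dict[str, dict[float, CoverageMatrix]]] = {}
        nascent_totals: dict[str, dict[float, float]] = {}
        for condition, by_assay in tracks_spec.items():
            matrices[condition] = {}
            nascent_totals[condition] = {}
            for assay, by_tp in by_assay.items():
                matrices[condition][assay] = {}
                for tp, entry in by_tp.items():
                    signal = _load_entry(entry, manifest)
                    mat = gene_matrix(
                        signal,
                        windows_by_assay[assay],
                        condition=condition,
                        assay=assay,
                        timepoint_min=float(tp),
                    )
                    if assay == "nascent":
                        nascent_totals[condition][float(tp)] = mat.library_size
                    mat = normalize_depth(mat)
                    matrices[condition][assay][float(tp)] = mat
                    mpath = outdir / f"matrix_{condition}_{assay}_t{tp:g}.tsv.gz"
                    write_matrix(mat, mpath)
                    manifest["outputs"].append(str(mpath))

    # -- wave -------------------------------------------------------------
    rates: dict[str, Any] = {}
    fits_by_condition = {}
    with _Stage("wave"):
        rate_tps = cfg.fit.get("rate_timepoints") or [0.0, 10.0]
        fit_kwargs = dict(
            smoothing=cfg.fit["smoothing"],
            exclusion_zone_bp=float(cfg.fit["exclusion_zone_bp"]),
            front_fraction=float(cfg.fit["front_fraction"]),
        )
        feature = cfg.fit["feature"]
        for condition in matrices:
            nascent = matrices[condition].get("nascent")
            if not nascent:
                continue
            est, fits = metagene_rate(
                nascent, timepoints=rate_tps, feature=feature, **fit_kwargs
            )
            fits_by_condition[condition] = fits
            entry = {
                "metagene_rate_kb_per_min": est.rate_kb_per_min,
                "intercept_bp": est.intercept_bp,
                "feature": feature,
                "timepoints_used": est.timepoints_used,
            }
            if cfg.per_gene:
                pg = per_gene_rates(
                    nascent, timepoints=rate_tps, feature=feature, **fit_kwargs
                )
                entry.update(
                    {
                        "per_gene_mean_rate_kb_per_min": pg.rate_kb_per_min,
                        "per_gene_sd_kb_per_min": pg.sd_across_genes,
                        "n_genes": pg.n_genes,
                        "n_excluded": pg.n_excluded,
                    }
                )
            rates[condition] = entry
        if rates:
            pd.DataFrame(rates).T.to_csv(outdir / "rates.tsv", sep="\t")
            manifest["outputs"].append(str(outdir / "rates.tsv"))
        manifest["results"]["rates"] = _jsonable(rates)

    # -- processivity -----------------------------------------------------
    with _Stage("processivity"):
        proc = cfg.processivity
        summaries: dict[str, ConditionSummary] = {}
        index_rows = []
        for condition in matrices:
            polii = matrices[condition].get("polii")
            if not polii:
                continue
            tc = occupancy_timecourse(
                polii,
                pause_window_bp=tuple(proc["pause_window_bp"]),
                body_window_bp=tuple(proc["body_window_bp"]),
            )
            for tp, mat in sorted(polii.items()):
                idx = processivity_index(
                    mat,
                    proximal_window_bp=tuple(proc["proximal_window_bp"]),
                    distal_window_bp=tuple(proc["distal_window_bp"]),
                )
                index_rows.append(
                    {
                        "condition": condition,
                        "timepoint_min": tp,
                        "proximal_mean": idx.proximal_mean,
                        "distal_mean": idx.distal_mean,
                        "index": idx.index,
                        "defined": idx.defined,
                    }
                )
            if condition in rates:
                summaries[condition] = ConditionSummary(
                    condition=condition,
                    rate_kb_per_min=rates[condition]["metagene_rate_kb_per_min"],
                    nascent_totals=nascent_totals.get(condition, {}),
                    timecourse=tc,
                )
        if index_rows:
            pd.DataFrame(index_rows).to_csv(
                outdir / "processivity.tsv", sep="\t", index=False
            )
            manifest["outputs"].append(str(outdir / "processivity.tsv"))
            manifest["results"]["processivity"] = _jsonable(index_rows)
        if len(summaries) >= 2:
            names = list(summaries)
            report = compare_conditions(
                summaries[names[0]],
                summaries[names[1]],
                headline_timepoint_min=float(proc["headline_timepoint_min"]),
            )
            (outdir / "comparison.json").write_text(
                json.dumps(_jsonable(report.as_dict()), indent=2) + "\n"
            )
            manifest["outputs"].append(str(outdir / "comparison.json"))
            manifest["results"]["comparison"] = _jsonable(report.as_dict())

    # -- plots ------------------------------------------------------------
    if cfg.plots:
        with _Stage("plots"):
            _plot_metagenes(matrices, fits_by_condition, outdir, manifest)

    manifest["results"]["nascent_totals"] = _jsonable(nascent_totals)
    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2) + "\n")
    return manifest


def _load_entry(entry, manifest: dict):
    """Load one track spec: a path, a stranded path pair, or in-memory tracks."""
    if isinstance(entry, SignalTrack):
        return entry
    if isinstance(entry, Mapping):
        out = {}
        for strand, sub in entry.items():
            out[strand] = _load_entry(sub, manifest)
        return out
    path = Path(entry)
    manifest["inputs"][str(path)] = {"sha256": _sha256(path)}
    return SignalTrack.load(path)


def _plot_metagenes(matrices, fits_by_condition, outdir: Path, manifest: dict) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        logger.warning("matplotlib not available; skipping plots")
        return
    for condition, by_assay in matrices.items():
        nascent = by_assay.get("nascent")
        if not nascent:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        for tp, mat in sorted(nascent.items()):
            prof = metagene(mat)
            ax.plot(prof.bin_centers_bp / 1000.0, prof.mean_signal, alpha=0.4,
                    label=f"{tp:g} min")
        for fit in fits_by_condition.get(condition, []):
            ax.plot(fit.bin_centers_bp / 1000.0, fit.smoothed, "k-", lw=1)
        ax.set_xlabel("distance from TSS (kb)")
        ax.set_ylabel("nascent signal (per million)")
        ax.set_title(condition)
        ax.legend()
        path = outdir / f"metagene_{condition}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        manifest["outputs"].append(str(path))
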