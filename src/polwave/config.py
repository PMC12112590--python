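"""Run configuration: schema, validation, and defaults.

``validate_config`` resolves a YAML/JSON mapping against the schema and
collects *every* violation before failing, so a user fixes one round of
errors, not one error per round.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

_TOP_LEVEL_KEYS = {
    "seed",
    "outdir",
    "conditions",
    "annotation",
    "chrom_sizes",
    "tracks",
    "simulate",
    "filter",
    "windows",
    "fit",
    "timepoints_min",
    "processivity",
    "plots",
    "per_gene",
}

_SIM_KEYS = {
    "n_genes",
    "length_range_kb",
    "params",  # condition -> SimParams kwargs
    "assays",
}

_FILTER_DEFAULTS = {"min_len_bp": 30000, "max_len_bp": 300000, "chrom_whitelist": None}
_WINDOW_DEFAULTS = {
    "upstream_bp": 2000,
    "downstream_bp": 30000,
    "polii_downstream_bp": 15000,
    "bin_bp": 200,
}
_FIT_DEFAULTS = {
    "smoothing": None,
    "exclusion_zone_bp": 500.0,
    "front_fraction": 0.1,
    "feature": "front",
    "rate_timepoints": None,
}
_PROC_DEFAULTS = {
    "pause_window_bp": [-200, 500],
    "body_window_bp": [2000, 15000],
    "proximal_window_bp": [0, 5000],
    "distal_window_bp": [10000, 15000],
    "headline_timepoint_min": 10.0,
}


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("polwave_out")
    conditions: list[str] = field(default_factory=lambda: ["WT"])
    annotation: Path | None = None
    chrom_sizes: Path | None = None
    #: tracks[condition][assay][timepoint] -> path or {"plus": ..., "minus": ...}
    tracks: dict = field(default_factory=dict)
    simulate: dict | None = None
    filter: dict = field(default_factory=lambda: dict(_FILTER_DEFAULTS))
    windows: dict = field(default_factory=lambda: dict(_WINDOW_DEFAULTS))
    fit: dict = field(default_factory=lambda: dict(_FIT_DEFAULTS))
    timepoints_min: list[float] = field(default_factory=lambda: [0.0, 10.0])
    processivity: dict = field(default_factory=lambda: dict(_PROC_DEFAULTS))
    plots: bool = False
    per_gene: bool = True


def _merge_section(
    raw: Mapping[str, Any] | None, defaults: Mapping[str, Any], name: str, errors: list[str]
) -> dict:
    out = dict(defaults)
    if raw is None:
        return out
    if not isinstance(raw, Mapping):
        errors.append(f"{name}: expected a mapping")
        return out
    for key, value in raw.items():
        if key not in defaults:
            errors.append(f"{name}: unknown key {key!r}")
        else:
            out[key] = value
    return out


def load_config_mapping(path: str | Path) -> Mapping[str, Any]:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return data


def validate_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Resolve and validate a config; raises ConfigError listing every
    violation found (unknown keys, missing files, inconsistent sections)."""
    raw = load_config_mapping(source) if isinstance(source, (str, Path)) else dict(source)
    errors: list[str] = []
    for key in raw:
        if key not in _TOP_LEVEL_KEYS:
            errors.append(f"unknown top-level key {key!r}")
    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", 0))
    cfg.outdir = Path(raw.get("outdir", "polwave_out"))
    cfg.plots = bool(raw.get("plots", False))
    cfg.per_gene = bool(raw.get("per_gene", True))
    cfg.timepoints_min = [float(t) for t in raw.get("timepoints_min", [0.0, 10.0])]
    if len(cfg.timepoints_min) < 2:
        errors.append("timepoints_min: need at least two timepoints")
    cfg.filter = _merge_section(raw.get("filter"), _FILTER_DEFAULTS, "filter", errors)
    cfg.windows = _merge_section(raw.get("windows"), _WINDOW_DEFAULTS, "windows", errors)
    cfg.fit = _merge_section(raw.get("fit"), _FIT_DEFAULTS, "fit", errors)
    cfg.processivity = _merge_section(
        raw.get("processivity"), _PROC_DEFAULTS, "processivity", errors
    )
    if cfg.fit.get("feature") not in ("peak", "front"):
        errors.append("fit.feature: must be 'peak' or 'front'")

    sim_raw = raw.get("simulate")
    if sim_raw is not None:
        if not isinstance(sim_raw, Mapping):
            errors.append("simulate: expected a mapping")
            sim_raw = {}
        for key in sim_raw:
            if key not in _SIM_KEYS:
                errors.append(f"simulate: unknown key {key!r}")
        cfg.simulate = dict(sim_raw)
        params = cfg.simulate.get("params")
        if not isinstance(params, Mapping) or not params:
            errors.append("simulate.params: need a mapping of condition -> parameters")
        else:
            cfg.conditions = list(params)
    else:
        cfg.conditions = list(raw.get("conditions", ["WT"]))
        for key, label in (("annotation", "annotation"), ("chrom_sizes", "chrom_sizes")):
            value = raw.get(key)
            if value is None:
                errors.append(f"{label}: required when no simulate section is given")
            else:
                p = Path(value)
                setattr(cfg, key, p)
                if not p.exists():
                    errors.append(f"{label}: file not found: {p}")
        tracks = raw.get("tracks")
        if not isinstance(tracks, Mapping) or not tracks:
            errors.append("tracks: required when no simulate section is given")
        else:
            cfg.tracks = _resolve_tracks(tracks, errors)
    if errors:
        raise ConfigError(errors)
    return cfg


def _resolve_tracks(tracks: Mapping, errors: list[str]) -> dict:
    out: dict = {}
    for condition, by_assay in tracks.items():
        if not isinstance(by_assay, Mapping):
            errors.append(f"tracks.{condition}: expected a mapping of assays")
            continue
        out[condition] = {}
        for assay, by_tp in by_assay.items():
            if assay not in ("nascent", "polii"):
                errors.append(f"tracks.{condition}: unknown assay {assay!r}")
                continue
            if not isinstance(by_tp, Mapping):
                errors.append(f"tracks.{condition}.{assay}: expected timepoint -> path")
                continue
            out[condition][assay] = {}
            for tp, entry in by_tp.items():
                try:
                    tpf = float(tp)
                except (TypeError, ValueError):
                    errors.append(f"tracks.{condition}.{assay}: bad timepoint {tp!r}")
                    continue
                if isinstance(entry, Mapping):
                    resolved = {}
                    for strand_key, strand in (("plus", "+"), ("minus", "-")):
                        if strand_key not in entry:
                            errors.append(
                                f"tracks.{condition}.{assay}.{tp}: missing {strand_key!r}"
                            )
                            continue
                        p = Path(entry[strand_key])
                        if not p.exists():
                            errors.append(
                                f"tracks.{condition}.{assay}.{tp}.{strand_key}: "
                                f"file not found: {p}"
                            )
                        resolved[strand] = p
                    out[condition][assay][tpf] = resolved
                else:
                    p = Path(entry)
                    if not p.exists():
                        errors.append(
                            f"tracks.{condition}.{assay}.{tp}: file not found: {p}"
                        )
                    out[condition][assay][tpf] = p
    return out
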