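"""Stochastic Pol II release/elongation simulator.

Kinetic law
-----------
Polymerases sit arrested at a promoter-proximal pause site. At t = 0 they
are released either instantaneously or as a Poisson process with rate
``release_rate_per_min``. Each polymerase then elongates deterministically
at a constant speed ``v`` (optional per-polymerase Gaussian jitter) and
carries an exponentially distributed termination distance, so survival to a
distance ``d`` beyond the pause site equals ``exp(-hazard * d)``. A
polymerase disappears from the template when it reaches its termination
point or runs off the gene end.

Two read-out tracks are rendered per timepoint:

* nascent RNA — metabolic labeling during a label window ``(a, b)``; the
  expected signal in a genomic bin is proportional to the RNA synthesized
  inside that bin during the window (RNA 5' of a termination point still
  counts unless ``keep_terminated_rna`` is off). A constant promoter pulse
  over ``[TSS, pause_site]`` models pause-site turnover by newly initiated
  polymerases; it is what the analysis-side exclusion zone is for.
* Pol II occupancy — the number of template-engaged polymerases per bin at
  the harvest time (paused, not-yet-released polymerases count at the pause
  site).

Counts are Poisson-sampled per bin from the expected signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .annotation import TranscriptModel, write_bed12
from .errors import LayoutError, ParameterError

__all__ = [
    "SimParams",
    "SimTruth",
    "PolymeraseEnsemble",
    "simulate_polymerases",
    "render_nascent_track",
    "render_polii_track",
    "simulate_cohort",
    "CohortResult",
]


@dataclass
class SimParams:
    """Parameters of the release/elongation/termination model."""

    speed_kb_per_min: float = 2.0
    termination_hazard_per_kb: float = 0.0
    #: None means instantaneous release of the whole paused pool at t=0.
    release_rate_per_min: float | None = None
    pause_site_offset_bp: int = 50
    #: One (start_min, end_min) label window per timepoint; None -> (0, t).
    label_windows: Sequence[tuple[float, float]] | None = None
    timepoints_min: Sequence[float] = (0.0, 5.0, 10.0)
    read_depth_per_kb: float = 50.0
    seed: int = 0
    # --- secondary knobs -------------------------------------------------
    n_pol_per_gene: int = 200
    #: amplitude of the pause-site turnover pulse, in units of full coverage.
    pause_signal_boost: float = 5.0
    speed_jitter_sd_kb_per_min: float = 0.0
    keep_terminated_rna: bool = True
    poisson_noise: bool = True
    polii_depth_scale: float = 1.0

    def __post_init__(self):
        self.timepoints_min = tuple(float(t) for t in self.timepoints_min)
        for name in (
            "speed_kb_per_min",
            "termination_hazard_per_kb",
            "read_depth_per_kb",
            "pause_signal_boost",
            "speed_jitter_sd_kb_per_min",
            "polii_depth_scale",
        ):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise ParameterError(f"{name} must be finite, got {val!r}")
        if self.speed_kb_per_min < 0:
            raise ParameterError("speed_kb_per_min must be non-negative")
        if self.termination_hazard_per_kb < 0:
            raise ParameterError("termination_hazard_per_kb must be non-negative")
        if self.release_rate_per_min is not None:
            if not math.isfinite(self.release_rate_per_min) or self.release_rate_per_min <= 0:
                raise ParameterError("release_rate_per_min must be positive or None")
        if self.pause_site_offset_bp < 0:
            raise ParameterError("pause_site_offset_bp must be non-negative")
        if self.read_depth_per_kb < 0:
            raise ParameterError("read_depth_per_kb must be non-negative")
        if self.n_pol_per_gene <= 0:
            raise ParameterError("n_pol_per_gene must be positive")
        if any(self.timepoints_min[i] > self.timepoints_min[i + 1]
               for i in range(len(self.timepoints_min) - 1)):
            raise ParameterError("timepoints_min must be sorted ascending")
        if any(t < 0 for t in self.timepoints_min):
            raise ParameterError("timepoints_min must be non-negative")
        if self.label_windows is not None:
            self.label_windows = tuple((float(a), float(b)) for a, b in self.label_windows)
            if len(self.label_windows) != len(self.timepoints_min):
                raise ParameterError("need one label window per timepoint")
            for a, b in self.label_windows:
                if not a < b:
                    raise ParameterError(f"label window ({a}, {b}) must have start < end")

    def label_window_for(self, timepoint: float) -> tuple[float, float]:
        if timepoint not in self.timepoints_min:
            raise ParameterError(f"timepoint {timepoint} not in timepoints_min")
        if self.label_windows is None:
            return (0.0, float(timepoint))
        return self.label_windows[self.timepoints_min.index(timepoint)]


@dataclass
class SimTruth:
    """Ground truth for one simulated gene."""

    transcript_id: str
    true_speed_kb_per_min: float
    true_hazard_per_kb: float
    n_polymerases_released: int
    n_terminated: int

    def __post_init__(self):
        if self.n_terminated > self.n_polymerases_released:
            raise ParameterError("n_terminated cannot exceed n_polymerases_released")


class PolymeraseEnsemble:
    """Trajectories of ``n`` polymerases on one gene (vectorized storage).

    All positions are bp downstream of the TSS. ``stop_bp`` is where each
    polymerase leaves the template: its termination point or the gene end.
    """

    def __init__(
        self,
        gene_length_bp: int,
        pause_bp: float,
        release_min: np.ndarray,
        speed_bp_per_min: np.ndarray,
        stop_bp: np.ndarray,
        terminated: np.ndarray,
    ):
        self.gene_length_bp = int(gene_length_bp)
        self.pause_bp = float(pause_bp)
        self.release_min = np.asarray(release_min, dtype=float)
        self.speed_bp_per_min = np.asarray(speed_bp_per_min, dtype=float)
        self.stop_bp = np.asarray(stop_bp, dtype=float)
        self.terminated = np.asarray(terminated, dtype=bool)

    def __len__(self) -> int:
        return len(self.release_min)

    def positions_at(self, t_min: float) -> np.ndarray:
        """Front position of every polymerase at time ``t`` (bp from TSS)."""
        travelled = self.speed_bp_per_min * np.clip(t_min - self.release_min, 0.0, None)
        return np.minimum(self.pause_bp + travelled, self.stop_bp)

    def engaged_at(self, t_min: float) -> np.ndarray:
        """True where a polymerase is still on the template at time ``t``."""
        travelled = self.speed_bp_per_min * np.clip(t_min - self.release_min, 0.0, None)
        return self.pause_bp + travelled < self.stop_bp

    @property
    def n_terminated(self) -> int:
        return int(self.terminated.sum())


def simulate_polymerases(
    params: SimParams,
    gene: TranscriptModel | int,
    n_pol: int,
    rng: np.random.Generator | None = None,
) -> PolymeraseEnsemble:
    """Draw release times, speeds and stopping points for ``n_pol`` polymerases.

    ``gene`` may be a :class:`TranscriptModel` or a plain length in bp.
    """
    if n_pol <= 0:
        raise ParameterError("n_pol must be positive")
    length = gene if isinstance(gene, int) else gene.length
    if length <= params.pause_site_offset_bp:
        raise ParameterError("gene shorter than the pause-site offset")
    if rng is None:
        rng = child_rng(params.seed, "polymerases")
    if params.release_rate_per_min is None:
        release = np.zeros(n_pol)
    else:
        release = rng.exponential(1.0 / params.release_rate_per_min, size=n_pol)
    speed = np.full(n_pol, params.speed_kb_per_min * 1000.0)
    if params.speed_jitter_sd_kb_per_min > 0:
        jitter = rng.normal(0.0, params.speed_jitter_sd_kb_per_min * 1000.0, size=n_pol)
        speed = np.clip(speed + jitter, 1.0, None)
    if params.termination_hazard_per_kb > 0:
        term_dist = rng.exponential(1000.0 / params.termination_hazard_per_kb, size=n_pol)
    else:
        term_dist = np.full(n_pol, np.inf)
    stop = np.minimum(params.pause_site_offset_bp + term_dist, float(length))
    terminated = params.pause_site_offset_bp + term_dist < length
    return PolymeraseEnsemble(
        gene_length_bp=length,
        pause_bp=float(params.pause_site_offset_bp),
        release_min=release,
        speed_bp_per_min=speed,
        stop_bp=stop,
        terminated=terminated,
    )


def _bin_edges(gene_length_bp: int, bin_bp: int) -> np.ndarray:
    n_bins = -(-gene_length_bp // bin_bp)  # ceil
    return bin_bp * np.arange(n_bins + 1, dtype=float)


def render_nascent_track(
    trajectories: PolymeraseEnsemble,
    params: SimParams,
    timepoint: float,
    bin_bp: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected and Poisson-sampled labeled-RNA signal per gene bin.

    Returns ``(expected, counts)`` over bins tiling [0, gene length). The
    expected count in a fully traversed bin equals
    ``read_depth_per_kb * bin_kb`` when every polymerase synthesized through
    it; per-polymerase contributions are overlap fractions, so doubling
    depth doubles every expectation exactly.
    """
    if bin_bp <= 0:
        raise ParameterError("bin_bp must be positive")
    a, b = params.label_window_for(timepoint)
    edges = _bin_edges(trajectories.gene_length_bp, bin_bp)
    n_pol = len(trajectories)
    start = trajectories.positions_at(a)
    end = trajectories.positions_at(b)
    if not params.keep_terminated_rna:
        gone = trajectories.terminated & (trajectories.positions_at(b) >= trajectories.stop_bp)
        keep = ~gone
        start, end = start[keep], end[keep]
    # overlap of each polymerase's labeled segment with each bin
    lo = np.maximum(start[:, None], edges[None, :-1])
    hi = np.minimum(end[:, None], edges[None, 1:])
    overlap_bp = np.clip(hi - lo, 0.0, None).sum(axis=0)
    per_kb = params.read_depth_per_kb / 1000.0
    expected = per_kb * overlap_bp / n_pol
    # pause-site turnover pulse over [0, pause_bp]
    pulse_overlap = np.clip(
        np.minimum(trajectories.pause_bp, edges[1:]) - edges[:-1], 0.0, None
    )
    expected = expected + params.pause_signal_boost * per_kb * pulse_overlap
    if not params.poisson_noise:
        return expected, expected.copy()
    if rng is None:
        rng = child_rng(params.seed, "nascent", timepoint)
    return expected, rng.poisson(expected).astype(float)


def render_polii_track(
    trajectories: PolymeraseEnsemble,
    params: SimParams,
    timepoint: float,
    bin_bp: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected and Poisson-sampled engaged-polymerase occupancy per bin."""
    if bin_bp <= 0:
        raise ParameterError("bin_bp must be positive")
    edges = _bin_edges(trajectories.gene_length_bp, bin_bp)
    engaged = trajectories.engaged_at(timepoint)
    pos = trajectories.positions_at(timepoint)[engaged]
    counts, _ = np.histogram(pos, bins=edges)
    expected = counts.astype(float) * params.polii_depth_scale
    if not params.poisson_noise:
        return expected, expected.copy()
    if rng is None:
        rng = child_rng(params.seed, "polii", timepoint)
    return expected, rng.poisson(expected).astype(float)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortResult:
    outdir: Path | None
    transcripts: list[TranscriptModel]
    chrom_sizes: dict[str, int]
    truth: pd.DataFrame  # one row per (condition, transcript)
    #: files[condition][assay][timepoint] -> path or {"+" : path, "-" : path}
    files: dict = field(default_factory=dict)


def _layout_genes(
    n_genes: int,
    length_range_kb: tuple[float, float],
    bin_bp: int,
    rng: np.random.Generator,
    genes_per_chrom: int = 25,
    flank_bp: int = 40000,
    chrom_size_bp: int | None = None,
) -> tuple[list[TranscriptModel], dict[str, int]]:
    """Place non-overlapping genes on synthetic chromosomes.

    Lengths are strictly inside (min, max] kb and quantized to the bin grid
    so simulated track bins align with TSS-anchored analysis bins.
    """
    if n_genes <= 0:
        raise ParameterError("n_genes must be positive")
    lo_bins = int(length_range_kb[0] * 1000) // bin_bp + 1
    hi_bins = int(length_range_kb[1] * 1000) // bin_bp
    if hi_bins < lo_bins:
        raise ParameterError("length range too narrow for the bin size")
    lengths = bin_bp * rng.integers(lo_bins, hi_bins + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    transcripts: list[TranscriptModel] = []
    chrom_sizes: dict[str, int] = {}
    cursor = flank_bp
    chrom_idx = 1
    placed_on_chrom = 0
    for i in range(n_genes):
        chrom = f"chr{chrom_idx}"
        start = cursor
        end = start + int(lengths[i])
        if chrom_size_bp is not None and end + flank_bp > chrom_size_bp:
            raise LayoutError(
                f"cannot place gene {i + 1}/{n_genes} within chrom size {chrom_size_bp}"
            )
        transcripts.append(
            TranscriptModel(
                transcript_id=f"simgene_{i + 1:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=str(strands[i]),
            )
        )
        chrom_sizes[chrom] = end + flank_bp
        cursor = end + flank_bp
        placed_on_chrom += 1
        if placed_on_chrom == genes_per_chrom and i != n_genes - 1:
            chrom_idx += 1
            cursor = flank_bp
            placed_on_chrom = 0
    return transcripts, chrom_sizes


def _to_genomic(tx: TranscriptModel, edges_rel: np.ndarray) -> np.ndarray:
    """Map TSS-relative bin edges to ascending genomic coordinates."""
    if tx.strand == "+":
        return tx.start + edges_rel
    return tx.end - edges_rel[::-1]


def _write_bedgraph(path: Path, records: list[tuple[str, int, int, float]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            if value == 0:
                continue
            if float(value).is_integer():
                fh.write(f"{chrom}\t{start}\t{end}\t{int(value)}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def simulate_cohort(
    params_by_condition: Mapping[str, SimParams],
    n_genes: int = 50,
    length_range_kb: tuple[float, float] = (30.0, 300.0),
    bin_bp: int = 200,
    seed: int = 0,
    outdir: str | Path | None = None,
    assays: Sequence[str] = ("nascent", "polii"),
    chrom_size_bp: int | None = None,
) -> CohortResult:
    """Simulate a shared gene layout under one or more parameter sets.

    Writes (when ``outdir`` is given) a BED12 annotation, a chrom.sizes
    file, per condition/assay/timepoint bedGraph tracks (nascent tracks are
    stranded: ``*_plus`` / ``*_minus``) and a tab-separated truth table.
    The layout, per-gene trajectories and noise are all forked from ``seed``
    by stable labels, so outputs are byte-identical across re-runs.
    """
    layout_rng = child_rng(seed, "layout")
    transcripts, chrom_sizes = _layout_genes(
        n_genes, length_range_kb, bin_bp, layout_rng, chrom_size_bp=chrom_size_bp
    )
    truth_rows = []
    files: dict = {}
    tracks: dict = {}
    for condition, params in params_by_condition.items():
        files[condition] = {}
        tracks[condition] = {
            assay: {
                tp: ({"+": [], "-": []} if assay == "nascent" else [])
                for tp in params.timepoints_min
            }
            for assay in assays
        }
        for gi, tx in enumerate(transcripts):
            pol_rng = child_rng(seed, condition, "pol", tx.transcript_id)
            ens = simulate_polymerases(params, tx, params.n_pol_per_gene, rng=pol_rng)
            truth_rows.append(
                {
                    "condition": condition,
                    "transcript_id": tx.transcript_id,
                    "true_speed_kb_per_min": params.speed_kb_per_min,
                    "true_hazard_per_kb": params.termination_hazard_per_kb,
                    "n_polymerases_released": len(ens),
                    "n_terminated": ens.n_terminated,
                }
            )
            edges_rel = _bin_edges(tx.length, bin_bp)
            for tp in params.timepoints_min:
                for assay in assays:
                    noise_rng = child_rng(
                        seed, condition, assay, tx.transcript_id, tp
                    )
                    if assay == "nascent":
                        _, counts = render_nascent_track(
                            ens, params, tp, bin_bp, rng=noise_rng
                        )
                    else:
                        _, counts = render_polii_track(
                            ens, params, tp, bin_bp, rng=noise_rng
                        )
                    gedges = _to_genomic(tx, edges_rel)
                    vals = counts[::-1] if tx.strand == "-" else counts
                    recs = [
                        (tx.chrom, int(gedges[k]), int(gedges[k + 1]), float(vals[k]))
                        for k in range(len(vals))
                    ]
                    if assay == "nascent":
                        tracks[condition][assay][tp][tx.strand].extend(recs)
                    else:
                        tracks[condition][assay][tp].extend(recs)
    truth = pd.DataFrame(truth_rows)
    result = CohortResult(
        outdir=Path(outdir) if outdir is not None else None,
        transcripts=transcripts,
        chrom_sizes=chrom_sizes,
        truth=truth,
        files=files,
    )
    if outdir is None:
        result.files = _in_memory_tracks(tracks)
        return result
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed12(transcripts, outdir / "annotation.bed")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    for condition, by_assay in tracks.items():
        for assay, by_tp in by_assay.items():
            for tp, recs in by_tp.items():
                tag = f"{condition}_{assay}_t{tp:g}"
                if assay == "nascent":
                    plus = outdir / f"{tag}_plus.bedgraph"
                    minus = outdir / f"{tag}_minus.bedgraph"
                    _write_bedgraph(plus, sorted(recs["+"]))
                    _write_bedgraph(minus, sorted(recs["-"]))
                    files[condition].setdefault(assay, {})[tp] = {
                        "+": plus,
                        "-": minus,
                    }
                else:
                    path = outdir / f"{tag}.bedgraph"
                    _write_bedgraph(path, sorted(recs))
                    files[condition].setdefault(assay, {})[tp] = path
    return result


def _in_memory_tracks(tracks: dict) -> dict:
    """Convert record lists into SignalTrack objects keyed like files."""
    from .coverage import SignalTrack

    def build(recs):
        recs = [r for r in sorted(recs) if r[3] != 0]
        if not recs:
            return SignalTrack({}, 0.0)
        chroms, starts, ends, values = zip(*recs)
        return SignalTrack.from_intervals(chroms, starts, ends, values)

    out: dict = {}
    for condition, by_assay in tracks.items():
        out[condition] = {}
        for assay, by_tp in by_assay.items():
            out[condition][assay] = {}
            for tp, recs in by_tp.items():
                if assay == "nascent":
                    out[condition][assay][tp] = {
                        "+": build(recs["+"]),
                        "-": build(recs["-"]),
                    }
                else:
                    out[condition][assay][tp] = build(recs)
    return out
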