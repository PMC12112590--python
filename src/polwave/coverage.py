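"""Signal tracks and strand-oriented gene x bin coverage matrices.

A :class:`SignalTrack` is an exact piecewise-constant view of a bedGraph
track (or a value-1 coverage view of BED read intervals); interval sums are
computed from a cumulative integral so binning is exact, not approximate.
Matrices are TSS-anchored and strand-oriented: bin 0 is the most upstream
bin in transcription direction for every gene.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnalysisWindow
from .errors import FormatError, ParameterError, ParseError

logger = logging.getLogger(__name__)


class SignalTrack:
    """Genome-wide piecewise-constant signal with exact interval sums.

    Internally each chromosome stores node positions ``xs`` and the
    cumulative integral ``cum`` of the signal at those positions; the
    integral at any coordinate is linear interpolation between nodes, which
    is exact for piecewise-constant signal.
    """

    def __init__(self, nodes: Mapping[str, tuple[np.ndarray, np.ndarray]], total_signal: float):
        self._nodes = dict(nodes)
        self.total_signal = float(total_signal)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._nodes)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_intervals(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        values: Sequence[float],
        total_signal: float | None = None,
        source: str = "<memory>",
    ) -> "SignalTrack":
        """Build from non-overlapping (per chromosome) value intervals."""
        df = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": ends, "value": values}
        )
        if ((df["end"] - df["start"]) <= 0).any():
            raise FormatError(f"{source}: interval with non-positive span")
        nodes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        total = 0.0
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values(["start", "end"], kind="stable")
            s = sub["start"].to_numpy(dtype=np.int64)
            e = sub["end"].to_numpy(dtype=np.int64)
            v = sub["value"].to_numpy(dtype=np.float64)
            if np.any(s[1:] < e[:-1]):
                bad = int(np.flatnonzero(s[1:] < e[:-1])[0])
                raise FormatError(
                    f"{source}: overlapping intervals on {chrom} near position {s[bad + 1]}"
                )
            # node list: start/end of each covered segment; flat across gaps
            xs = np.empty(2 * len(s), dtype=np.float64)
            xs[0::2] = s
            xs[1::2] = e
            inc = np.zeros(2 * len(s), dtype=np.float64)
            inc[1::2] = v * (e - s)
            cum = np.cumsum(inc)
            keep = np.ones(len(xs), dtype=bool)
            keep[1:] = xs[1:] > xs[:-1]  # drop duplicate node when e[i] == s[i+1]
            nodes[str(chrom)] = (xs[keep], cum[keep])
            total += float(cum[-1])
        if total_signal is None:
            total_signal = total
        return cls(nodes, total_signal)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SignalTrack":
        """Read a 4-column bedGraph; intervals must not overlap per chrom."""
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        values: list[float] = []
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
                try:
                    chroms.append(fields[0])
                    starts.append(int(fields[1]))
                    ends.append(int(fields[2]))
                    values.append(float(fields[3]))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if not chroms:
            logger.warning("bedGraph %s is empty", path)
            return cls({}, 0.0)
        return cls.from_intervals(chroms, starts, ends, values, source=str(path))

    @classmethod
    def from_bed_reads(cls, path: str | Path) -> "SignalTrack":
        """Read BED intervals as unit-weight reads.

        The signal is read coverage (reads may overlap); ``total_signal`` is
        the read *count*, matching depth normalization by mapped reads.
        """
        events: dict[str, list[tuple[int, int]]] = {}
        n_reads = 0
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if end <= start:
                    raise ParseError(f"{path}:{lineno}: non-positive read span")
                events.setdefault(fields[0], []).append((start, end))
                n_reads += 1
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        values: list[float] = []
        for chrom, ivals in events.items():
            edges = np.unique(np.concatenate([[s for s, _ in ivals], [e for _, e in ivals]]))
            depth = np.zeros(len(edges) - 1, dtype=np.float64)
            idx_s = np.searchsorted(edges, [s for s, _ in ivals])
            idx_e = np.searchsorted(edges, [e for _, e in ivals])
            for a, b in zip(idx_s, idx_e):
                depth[a:b] += 1.0
            covered = depth > 0
            for i in np.flatnonzero(covered):
                chroms.append(chrom)
                starts.append(int(edges[i]))
                ends.append(int(edges[i + 1]))
                values.append(float(depth[i]))
        return cls.from_intervals(
            chroms, starts, ends, values, total_signal=float(n_reads), source=str(path)
        )

    @classmethod
    def load(cls, path: str | Path, fmt: str | None = None) -> "SignalTrack":
        """Dispatch on format: bedGraph, BED read intervals, or bigWig."""
        if fmt is None:
            name = str(path).lower().removesuffix(".gz")
            if name.endswith((".bedgraph", ".bdg", ".bg")):
                fmt = "bedgraph"
            elif name.endswith(".bed"):
                fmt = "bed"
            elif name.endswith((".bw", ".bigwig")):
                fmt = "bigwig"
            else:
                raise ParameterError(f"cannot infer signal format from {path!r}")
        fmt = fmt.lower()
        if fmt == "bedgraph":
            return cls.from_bedgraph(path)
        if fmt == "bed":
            return cls.from_bed_reads(path)
        if fmt == "bigwig":
            return cls._from_bigwig(path)
        raise ParameterError(f"unknown signal format {fmt!r}")

    @classmethod
    def _from_bigwig(cls, path: str | Path) -> "SignalTrack":
        try:
            import pyBigWig  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise FormatError(
                "bigWig input requires the optional pyBigWig package; "
                "convert the track to bedGraph instead"
            ) from exc
        bw = pyBigWig.open(str(path))  # pragma: no cover
        chroms, starts, ends, values = [], [], [], []
        for chrom in bw.chroms():
            for s, e, v in bw.intervals(chrom) or []:
                chroms.append(chrom)
                starts.append(s)
                ends.append(e)
                values.append(v)
        bw.close()
        return cls.from_intervals(chroms, starts, ends, values, source=str(path))

    # -- queries ----------------------------------------------------------

    def _cumulative(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        if chrom not in self._nodes:
            logger.warning("query on unknown chromosome %r returns zero", chrom)
            return np.zeros(len(positions))
        xs, cum = self._nodes[chrom]
        return np.interp(positions, xs, cum, left=0.0, right=float(cum[-1]))

    def interval_sum(self, chrom: str, start: float, end: float) -> float:
        """Exact integral of the signal over [start, end)."""
        lo, hi = self._cumulative(chrom, np.array([start, end], dtype=float))
        return float(hi - lo)

    def bin_sums(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Exact integrals over consecutive bins given ascending edges."""
        cum = self._cumulative(chrom, np.asarray(edges, dtype=float))
        return np.diff(cum)


# ---------------------------------------------------------------------------
# matrices


@dataclass
class CoverageMatrix:
    """Genes x bins signal for one condition/assay/timepoint."""

    condition: str
    assay: str
    timepoint_min: float
    gene_ids: list[str]
    bin_offsets_bp: np.ndarray  # 5'->3' bin start offsets relative to TSS
    bin_bp: int
    values: np.ndarray  # shape (n_genes, n_bins), non-negative
    normalized: bool = False
    library_size: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ParameterError("values must be 2-D (genes x bins)")
        if self.values.shape[0] != len(self.gene_ids):
            raise ParameterError("row count does not match gene_ids")
        if self.values.size and self.values.min() < 0:
            raise ParameterError("coverage values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def bin_centers_bp(self) -> np.ndarray:
        return np.asarray(self.bin_offsets_bp, dtype=float) + self.bin_bp / 2.0


@dataclass
class MetageneProfile:
    bin_centers_bp: np.ndarray
    mean_signal: np.ndarray
    n_genes: int

    def __post_init__(self):
        if len(self.bin_centers_bp) != len(self.mean_signal):
            raise ParameterError("profile arrays must align")
        if self.n_genes <= 0:
            raise ParameterError("metagene requires at least one gene")


StrandedSignal = Mapping[str, SignalTrack]


def gene_matrix(
    signal: SignalTrack | StrandedSignal,
    windows: Sequence[AnalysisWindow],
    condition: str = "",
    assay: str = "",
    timepoint_min: float = 0.0,
) -> CoverageMatrix:
    """Bin signal into each window; minus-strand rows are reversed so that
    bin 0 is the most upstream bin for every gene.

    ``signal`` may be a single track (unstranded assays) or a mapping
    ``{"+": track, "-": track}`` for stranded ones; each gene then reads the
    track matching its own strand.
    """
    if windows and len({(w.upstream_bp, w.downstream_bp, w.bin_bp) for w in windows}) != 1:
        raise ParameterError("all windows must share the same bin scheme")
    stranded = not isinstance(signal, SignalTrack)
    rows = []
    library = None
    for win in windows:
        track = signal[win.strand] if stranded else signal
        sums = track.bin_sums(win.chrom, win.genomic_bin_edges())
        if win.strand == "-":
            sums = sums[::-1]
        rows.append(sums)
    if stranded:
        library = sum(t.total_signal for t in signal.values())
    elif isinstance(signal, SignalTrack):
        library = signal.total_signal
    if windows:
        offsets = windows[0].offsets_bp()
        bin_bp = windows[0].bin_bp
        values = np.vstack(rows)
    else:
        offsets = np.array([], dtype=float)
        bin_bp = 1
        values = np.zeros((0, 0))
    return CoverageMatrix(
        condition=condition,
        assay=assay,
        timepoint_min=timepoint_min,
        gene_ids=[w.transcript_id for w in windows],
        bin_offsets_bp=offsets,
        bin_bp=bin_bp,
        values=values,
        normalized=False,
        library_size=float(library or 0.0),
    )


def normalize_depth(matrix: CoverageMatrix) -> CoverageMatrix:
    """Scale to signal-per-million of the track's total mapped signal."""
    if matrix.normalized:
        raise ParameterError("matrix is already depth-normalized")
    if matrix.library_size <= 0:
        raise ParameterError("library_size must be positive to normalize")
    scaled = matrix.values * (1e6 / matrix.library_size)
    return replace(matrix, values=scaled, normalized=True)


def metagene(matrix: CoverageMatrix, stat: str = "mean") -> MetageneProfile:
    """Average (or median) profile across genes."""
    if matrix.n_genes == 0:
        raise ParameterError("cannot build a metagene from an empty matrix")
    if stat == "mean":
        prof = matrix.values.mean(axis=0)
    elif stat == "median":
        prof = np.median(matrix.values, axis=0)
    else:
        raise ParameterError(f"unknown metagene stat {stat!r}")
    return MetageneProfile(
        bin_centers_bp=matrix.bin_centers_bp,
        mean_signal=prof,
        n_genes=matrix.n_genes,
    )


def heatmap_sort(matrix: CoverageMatrix) -> CoverageMatrix:
    """Stable sort of rows by mean signal, descending (high to low)."""
    if matrix.n_genes == 0:
        raise ParameterError("cannot sort an empty matrix")
    means = matrix.values.mean(axis=1)
    order = np.argsort(-means, kind="stable")
    return replace(
        matrix,
        gene_ids=[matrix.gene_ids[i] for i in order],
        values=matrix.values[order],
    )


def classify_by_occupancy(
    matrix: CoverageMatrix,
    thresholds: tuple[float, float] | None = None,
    body_range_bp: tuple[float, float] | None = None,
) -> dict[str, str]:
    """Label genes High / Low / No by gene-body mean occupancy.

    A gene with zero body signal is always 'No'; otherwise the two
    thresholds split the range into No (<= low), Low (<= high) and High.
    Default thresholds are the tertile boundaries of nonzero genes.
    """
    if not matrix.normalized:
        raise ParameterError("classification expects a depth-normalized matrix")
    centers = matrix.bin_centers_bp
    if body_range_bp is None:
        mask = centers >= 0
    else:
        mask = (centers >= body_range_bp[0]) & (centers < body_range_bp[1])
    if not mask.any():
        raise ParameterError("body range selects no bins")
    means = matrix.values[:, mask].mean(axis=1)
    nonzero = means[means > 0]
    if thresholds is None:
        if len(nonzero) == 0:
            logger.warning("all genes have zero occupancy; labelling everything 'No'")
            return {g: "No" for g in matrix.gene_ids}
        lo, hi = np.quantile(nonzero, [1 / 3, 2 / 3])
    else:
        lo, hi = thresholds
        if hi < lo:
            raise ParameterError("thresholds must be ordered (low, high)")
    labels: dict[str, str] = {}
    for gene, m in zip(matrix.gene_ids, means):
        if m <= 0 or m <= lo:
            labels[gene] = "No"
        elif m <= hi:
            labels[gene] = "Low"
        else:
            labels[gene] = "High"
    return labels


# ---------------------------------------------------------------------------
# persistence


def write_matrix(matrix: CoverageMatrix, path: str | Path) -> None:
    """Write a matrix as (optionally gzipped) TSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.gene_ids, name="transcript_id"),
        columns=[str(int(o)) for o in matrix.bin_offsets_bp],
    )
    df.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "condition": matrix.condition,
        "assay": matrix.assay,
        "timepoint_min": matrix.timepoint_min,
        "bin_bp": matrix.bin_bp,
        "normalized": matrix.normalized,
        "library_size": matrix.library_size,
        "n_genes": matrix.n_genes,
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")


def read_matrix(path: str | Path) -> CoverageMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    offsets = np.array([float(c) for c in df.columns])
    return CoverageMatrix(
        condition=meta["condition"],
        assay=meta["assay"],
        timepoint_min=meta["timepoint_min"],
        gene_ids=[str(g) for g in df.index],
        bin_offsets_bp=offsets,
        bin_bp=meta["bin_bp"],
        values=df.to_numpy(dtype=float),
        normalized=meta["normalized"],
        library_size=meta["library_size"],
    )
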