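"""Transcript annotation: parsing, filtering, and TSS-anchored windowing.

The analysis gene set is built from a BED12/BED6 or GTF annotation by
(1) restricting to a chromosome whitelist, (2) keeping transcription units
strictly longer than a minimum length (and at most a maximum length),
(3) removing every transcript that overlaps any other transcript on either
strand, and (4) anchoring fixed-size strand-oriented windows on the TSS,
dropping transcripts whose window would extend past a chromosome boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, ParameterError, ParseError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class TranscriptModel:
    """One transcription unit in 0-based half-open genomic coordinates."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ParameterError(
                f"{self.transcript_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ParameterError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (left end on '+', right end on '-')."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class AnalysisWindow:
    """A TSS-anchored, strand-oriented, exactly-binned analysis interval.

    Bin 0 is always the most upstream bin in transcription direction; for a
    minus-strand transcript the genomic order of bins is therefore reversed.
    """

    transcript_id: str
    chrom: str
    tss: int
    strand: str
    upstream_bp: int = 2000
    downstream_bp: int = 30000
    bin_bp: int = 200

    def __post_init__(self):
        if self.bin_bp <= 0:
            raise ParameterError("bin_bp must be positive")
        if (self.upstream_bp + self.downstream_bp) % self.bin_bp != 0:
            raise ParameterError(
                f"window length {self.upstream_bp + self.downstream_bp} "
                f"not divisible by bin_bp={self.bin_bp}"
            )

    @property
    def n_bins(self) -> int:
        return (self.upstream_bp + self.downstream_bp) // self.bin_bp

    @property
    def genomic_start(self) -> int:
        if self.strand == "+":
            return self.tss - self.upstream_bp
        return self.tss - self.downstream_bp

    @property
    def genomic_end(self) -> int:
        if self.strand == "+":
            return self.tss + self.downstream_bp
        return self.tss + self.upstream_bp

    def genomic_bin_edges(self) -> np.ndarray:
        """Bin edges in ascending genomic order (n_bins + 1 values)."""
        return self.genomic_start + self.bin_bp * np.arange(self.n_bins + 1)

    def offsets_bp(self) -> np.ndarray:
        """5'->3' bin start offsets relative to the TSS."""
        return -self.upstream_bp + self.bin_bp * np.arange(self.n_bins)

    def bin_centers_bp(self) -> np.ndarray:
        return self.offsets_bp() + self.bin_bp / 2.0


# ---------------------------------------------------------------------------
# parsing


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".bed", ".bed6", ".bed12"}:
        return "bed"
    if suffix in {".gtf", ".gff"}:
        return "gtf"
    raise ParameterError(f"cannot infer annotation format from {path!r}")

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path: str | Path, fmt: str | None = None) -> list[TranscriptModel]:
    """Read BED (>=6 columns) or GTF transcripts as 0-based half-open models.

    GTF coordinates (1-based closed) are converted. When a GTF gene has
    multiple transcript records, only the longest isoform is kept (ties break
    to the lexicographically smallest transcript_id).
    """
    fmt = (fmt or _infer_format(path)).lower()
    if fmt not in {"bed", "bed6", "bed12", "gtf", "gff"}:
        raise ParameterError(f"unknown annotation format {fmt!r}")
    if fmt.startswith("bed"):
        out = _read_bed(path)
    else:
        out = _read_gtf(path)
    if not out:
        logger.warning("annotation %s contained no transcripts", path)
    return out


def _read_bed(path: str | Path) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BED columns")
            try:
                model = TranscriptModel(
                    transcript_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                )
            except (ValueError, ParameterError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(model)
    return out


def _read_gtf(path: str | Path) -> list[TranscriptModel]:
    # gene_id -> best (length, transcript_id, model)
    best: dict[str, tuple[int, str, TranscriptModel]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "transcript":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}:{lineno}: missing transcript_id attribute")
            gene = attrs.get("gene_id", tid)
            try:
                model = TranscriptModel(
                    transcript_id=tid,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,  # GTF is 1-based closed
                    end=int(fields[4]),
                    strand=fields[6],
                )
            except (ValueError, ParameterError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            key = (-model.length, model.transcript_id)
            incumbent = best.get(gene)
            if incumbent is None or key < (-incumbent[0], incumbent[1]):
                best[gene] = (model.length, model.transcript_id, model)
    return [entry[2] for entry in sorted(best.values(), key=lambda e: e[1])]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad size {fields[1]!r}") from exc
    return sizes


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterResult:
    survivors: list[TranscriptModel]
    rejections: dict[str, int] = field(
        default_factory=lambda: {"chrom": 0, "length": 0, "overlap": 0}
    )

    @property
    def n_rejected(self) -> int:
        return sum(self.rejections.values())


def _overlapping_ids(transcripts: Sequence[TranscriptModel]) -> set[str]:
    """Transcripts intersecting any other input transcript, strand-blind."""
    flagged: set[str] = set()
    by_pos = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.end))
    cur_chrom = None
    max_end = -1
    max_owner: TranscriptModel | None = None
    for tx in by_pos:
        if tx.chrom != cur_chrom:
            cur_chrom, max_end, max_owner = tx.chrom, tx.end, tx
            continue
        if tx.start < max_end:  # half-open intervals intersect
            flagged.add(tx.transcript_id)
            flagged.add(max_owner.transcript_id)
        if tx.end > max_end:
            max_end, max_owner = tx.end, tx
    return flagged


def filter_transcripts(
    transcripts: Iterable[TranscriptModel],
    min_len_bp: int = 30000,
    max_len_bp: int | None = 300000,
    chrom_whitelist: Iterable[str] | None = None,
) -> FilterResult:
    """Apply the chromosome / length / non-overlap rules.

    Length is strict at the lower bound (``length > min_len_bp``) and
    inclusive at the upper. Overlap is tested against the *whole* input set,
    strand-blind, and removes both members of every overlapping pair. Each
    removed transcript is counted under its first failing rule, in the order
    chrom, length, overlap.
    """
    transcripts = list(transcripts)
    whitelist = set(chrom_whitelist) if chrom_whitelist is not None else None
    flagged = _overlapping_ids(transcripts)
    result = FilterResult(survivors=[])
    for tx in transcripts:
        if whitelist is not None and tx.chrom not in whitelist:
            result.rejections["chrom"] += 1
        elif tx.length <= min_len_bp or (max_len_bp is not None and tx.length > max_len_bp):
            result.rejections["length"] += 1
        elif tx.transcript_id in flagged:
            result.rejections["overlap"] += 1
        else:
            result.survivors.append(tx)
    return result


# ---------------------------------------------------------------------------
# windowing


@dataclass
class WindowResult:
    windows: list[AnalysisWindow]
    n_dropped_boundary: int = 0


def make_windows(
    transcripts: Iterable[TranscriptModel],
    chrom_sizes: Mapping[str, int],
    upstream_bp: int = 2000,
    downstream_bp: int = 30000,
    bin_bp: int = 200,
) -> WindowResult:
    """Anchor strand-oriented windows on each TSS.

    A transcript whose extended window would leave ``[0, chrom_size)`` is
    dropped entirely (never clipped) and counted in ``n_dropped_boundary``.
    """
    result = WindowResult(windows=[])
    for tx in transcripts:
        if tx.chrom not in chrom_sizes:
            raise ConfigError(f"no chromosome size for {tx.chrom!r}")
        win = AnalysisWindow(
            transcript_id=tx.transcript_id,
            chrom=tx.chrom,
            tss=tx.tss,
            strand=tx.strand,
            upstream_bp=upstream_bp,
            downstream_bp=downstream_bp,
            bin_bp=bin_bp,
        )
        if win.genomic_start < 0 or win.genomic_end > chrom_sizes[tx.chrom]:
            result.n_dropped_boundary += 1
            continue
        result.windows.append(win)
    return result


# ---------------------------------------------------------------------------
# output helpers


def write_bed6(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(
                f"{tx.chrom}\t{tx.start}\t{tx.end}\t{tx.transcript_id}\t0\t{tx.strand}\n"
            )


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write single-block BED12 records."""
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(
                "\t".join(
                    [
                        tx.chrom,
                        str(tx.start),
                        str(tx.end),
                        tx.transcript_id,
                        "0",
                        tx.strand,
                        str(tx.start),
                        str(tx.end),
                        "0",
                        "1",
                        f"{tx.length},",
                        "0,",
                    ]
                )
                + "\n"
            )
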