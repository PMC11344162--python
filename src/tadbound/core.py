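"""Core genomic data types, interval/track algebra, and text-format I/O.

Coordinates are 0-based half-open everywhere (BED convention): an interval
``chrN:[start, end)`` covers bases ``start .. end-1``.  Region strings
printed as ``chrN:a-b`` are parsed as ``start=a, end=b`` under the same
convention, so a printed 30 Kb span is exactly 30,000 bp wide.

Signal tracks are piecewise-constant (bedGraph semantics); bases not covered
by any segment carry an implicit value of 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tadbound")

__all__ = [
    "GenomicInterval",
    "TranscriptRecord",
    "PeakRecord",
    "SignalTrack",
    "TadMap",
    "GeneCategorySet",
    "parse_region",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_transcripts",
    "write_transcripts",
    "read_peaks",
    "write_peaks",
    "track_stat",
    "peaks_overlapping",
]


class FormatError(ValueError):
    """Raised when a text file does not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region(text: str) -> GenomicInterval:
    """Parse a ``chrN:a-b`` region string (0-based half-open)."""
    try:
        chrom, span = text.strip().split(":")
        a, b = span.replace(",", "").split("-")
        return GenomicInterval(chrom, int(a), int(b))
    except ValueError as exc:
        raise FormatError(f"cannot parse region string {text!r}") from exc


Strand = Literal["+", "-"]


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript with its strand-resolved TSS/TTS.

    TSS is ``interval.start`` on the plus strand and ``interval.end - 1``
    (the last covered base) on the minus strand; TTS is the opposite
    terminus.
    """

    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    strand: Strand

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tts(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class PeakRecord:
    """A called peak with enrichment statistics and optional motif call.

    ``signal_max`` is the maximum of the underlying coverage track within
    the peak.  ``motif_strand``/``motif_q`` describe the best (lowest-q)
    motif overlapping the peak, or are both None when no motif overlaps.
    """

    interval: GenomicInterval
    fold_enrichment: float = 0.0
    q_value: float = 1.0
    signal_max: float = 0.0
    motif_strand: Strand | None = None
    motif_q: float | None = None

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0 or self.signal_max < 0:
            raise ValueError("fold_enrichment and signal_max must be >= 0")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError("q_value must be in [0, 1]")
        if self.motif_strand is None and self.motif_q is not None:
            raise ValueError("motif_q requires motif_strand")
        if self.motif_strand is not None and self.motif_strand not in ("+", "-"):
            raise ValueError(f"motif_strand must be '+', '-' or None")

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


class SignalTrack:
    """Piecewise-constant per-base signal (bedGraph semantics).

    Stored per chromosome as parallel numpy arrays (starts, ends, values),
    sorted and non-overlapping.  Uncovered bases carry implicit value 0.
    """

    def __init__(self, segments: Iterable[tuple[GenomicInterval, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, val in segments:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(val)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, segs in per_chrom.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            values = np.array([v for _, _, v in segs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise FormatError(
                    f"overlapping segments on {chrom} near position {starts[i + 1]}"
                )
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_arrays(
        cls, chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray
    ) -> "SignalTrack":
        track = cls()
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"overlapping segments on {chrom}")
        if np.any(starts >= ends) or np.any(starts < 0):
            raise FormatError(f"invalid segment coordinates on {chrom}")
        track._data[chrom] = (starts, ends, values)
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._data:
            empty = np.empty(0)
            return empty.astype(np.int64), empty.astype(np.int64), empty
        return self._data[chrom]

    def segments(self) -> Iterator[tuple[GenomicInterval, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield GenomicInterval(chrom, int(s), int(e)), float(v)

    def scaled(self, factor: float) -> "SignalTrack":
        out = SignalTrack()
        for chrom, (s, e, v) in self._data.items():
            out._data[chrom] = (s.copy(), e.copy(), v * factor)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c][0], other._data[c][0])
            and np.array_equal(self._data[c][1], other._data[c][1])
            and np.allclose(self._data[c][2], other._data[c][2])
            for c in self._data
        )


def track_stat(
    track: SignalTrack,
    region: GenomicInterval,
    stat: Literal["mean", "min", "max", "sum"],
) -> float:
    """Base-weighted statistic of ``track`` over ``region``.

    ``mean`` averages per-base values over every base of the region,
    counting uncovered bases as 0; ``min``/``max`` range over per-base
    values including implicit zeros; ``sum`` is the integral of the signal
    over covered bases.
    """
    if stat not in ("mean", "min", "max", "sum"):
        raise ValueError(f"unknown stat {stat!r}")
    starts, ends, values = track.arrays(region.chrom)
    if starts.size == 0 and region.chrom not in track.chroms:
        logger.warning(
            "region %s on chromosome absent from track; treating as all-zero", region
        )
    lo = np.searchsorted(ends, region.start, side="right")
    hi = np.searchsorted(starts, region.end, side="left")
    s = starts[lo:hi]
    e = ends[lo:hi]
    v = values[lo:hi]
    ov = np.minimum(e, region.end) - np.maximum(s, region.start)
    keep = ov > 0
    ov, v = ov[keep], v[keep]
    covered = int(ov.sum())
    total = float(np.dot(ov, v))
    width = region.width
    if stat == "sum":
        return total
    if stat == "mean":
        return total / width
    has_zero = covered < width
    if stat == "max":
        best = float(v.max()) if v.size else 0.0
        return max(best, 0.0) if has_zero else best
    best = float(v.min()) if v.size else 0.0
    return min(best, 0.0) if has_zero else best


def peaks_overlapping(
    peaks: Sequence[PeakRecord],
    region: GenomicInterval,
    mode: Literal["any_overlap", "midpoint"] = "any_overlap",
) -> list[PeakRecord]:
    """Select peaks intersecting ``region``.

    ``any_overlap`` keeps peaks sharing at least one base with the region;
    ``midpoint`` keeps peaks whose midpoint ``floor((start+end)/2)`` lies in
    the region.
    """
    if mode == "any_overlap":
        return [p for p in peaks if p.interval.overlaps(region)]
    if mode == "midpoint":
        return [
            p
            for p in peaks
            if p.interval.chrom == region.chrom and region.contains(p.midpoint)
        ]
    raise ValueError(f"unknown mode {mode!r}")


class TadMap:
    """Per-chromosome sorted, non-overlapping TAD intervals plus genome sizes.

    Adjacent TADs may share a coordinate (a common boundary).  Overlapping
    TADs are rejected unless ``repair=True``, in which case the later TAD is
    truncated to start at the previous TAD's end (every repair is logged).
    """

    def __init__(
        self,
        tads: Iterable[GenomicInterval],
        genome: dict[str, int],
        repair: bool = False,
    ):
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for tad in tads:
            per_chrom.setdefault(tad.chrom, []).append(tad)
        self.genome = dict(genome)
        self.tads: dict[str, list[GenomicInterval]] = {}
        for chrom, ivs in per_chrom.items():
            if chrom not in self.genome:
                raise ValueError(f"TAD on unknown chromosome {chrom!r}")
            length = self.genome[chrom]
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            cleaned: list[GenomicInterval] = []
            for iv in ivs:
                if iv.end > length:
                    raise ValueError(f"TAD {iv} exceeds chromosome length {length}")
                if cleaned and iv.start < cleaned[-1].end:
                    if not repair:
                        raise ValueError(
                            f"overlapping TADs on {chrom}: {cleaned[-1]} and {iv}"
                        )
                    if iv.end <= cleaned[-1].end:
                        logger.warning("repair: dropping TAD %s nested in %s", iv, cleaned[-1])
                        continue
                    new = GenomicInterval(chrom, cleaned[-1].end, iv.end)
                    logger.warning("repair: truncating TAD %s to %s", iv, new)
                    iv = new
                cleaned.append(iv)
            self.tads[chrom] = cleaned

    @property
    def chroms(self) -> list[str]:
        return sorted(self.tads)

    def all_tads(self) -> list[GenomicInterval]:
        return [tad for chrom in self.chroms for tad in self.tads[chrom]]

    def n_tads(self) -> int:
        return sum(len(v) for v in self.tads.values())

    def find_tad(self, chrom: str, pos: int) -> GenomicInterval | None:
        """TAD whose half-open interval contains ``pos``, or None (inter-TAD)."""
        ivs = self.tads.get(chrom)
        if not ivs:
            return None
        starts = [iv.start for iv in ivs]
        import bisect

        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and ivs[i].contains(pos):
            return ivs[i]
        return None


@dataclass
class GeneCategorySet:
    """Gene-id sets for the three analysis categories.

    ``developmental`` and ``housekeeping`` are subsets of ``all_genes``;
    the 'all' category used in comparisons is the full universe.
    """

    developmental: set[str] = field(default_factory=set)
    housekeeping: set[str] = field(default_factory=set)
    all_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.all_genes |= self.developmental | self.housekeeping

    def members(self, label: str) -> set[str]:
        if label in ("all", "all_genes"):
            return self.all_genes
        if label in ("developmental", "dev"):
            return self.developmental
        if label in ("housekeeping", "hk"):
            return self.housekeeping
        raise KeyError(f"unknown gene category {label!r}")

    @property
    def labels(self) -> list[str]:
        return ["all", "housekeeping", "developmental"]


# ---------------------------------------------------------------------------
# Text-format I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3+ column BED file (tab-separated, 0-based half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (overlaps rejected)."""
    segments: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                val = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            segments.append((iv, val))
    return SignalTrack(segments)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, val in track.segments():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val:.6g}\n")


_TRANSCRIPT_COLS = ["chrom", "start", "end", "strand", "gene_id", "transcript_id"]


def read_transcripts(path: str | Path) -> list[TranscriptRecord]:
    """Read a transcript table (TSV with header) into records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str, "transcript_id": str})
    missing = [c for c in _TRANSCRIPT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        TranscriptRecord(
            gene_id=row.gene_id,
            transcript_id=row.transcript_id,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            strand=row.strand,
        )
        for row in df.itertuples()
    ]


def write_transcripts(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "strand": t.strand,
            "gene_id": t.gene_id,
            "transcript_id": t.transcript_id,
        }
        for t in transcripts
    ]
    pd.DataFrame(rows, columns=_TRANSCRIPT_COLS).to_csv(path, sep="\t", index=False)


_PEAK_COLS = [
    "chrom",
    "start",
    "end",
    "fold_enrichment",
    "q_value",
    "signal_max",
    "motif_strand",
    "motif_q",
]


def read_peaks(path: str | Path) -> list[PeakRecord]:
    """Read a peak table (narrowPeak-like TSV with header) into records.

    ``motif_strand`` values of '.', '' or NaN mean "no motif"; ``motif_q``
    is then ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _PEAK_COLS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    peaks: list[PeakRecord] = []
    for row in df.itertuples():
        strand = getattr(row, "motif_strand", None)
        if pd.isna(strand) or strand in (".", "", None):
            strand, motif_q = None, None
        else:
            motif_q = float(getattr(row, "motif_q"))
        peaks.append(
            PeakRecord(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                fold_enrichment=float(row.fold_enrichment),
                q_value=float(row.q_value),
                signal_max=float(row.signal_max),
                motif_strand=strand,
                motif_q=motif_q,
            )
        )
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "fold_enrichment": p.fold_enrichment,
            "q_value": p.q_value,
            "signal_max": p.signal_max,
            "motif_strand": p.motif_strand if p.motif_strand else ".",
            "motif_q": p.motif_q if p.motif_q is not None else "",
        }
        for p in peaks
    ]
    pd.DataFrame(rows, columns=_PEAK_COLS).to_csv(path, sep="\t", index=False)
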