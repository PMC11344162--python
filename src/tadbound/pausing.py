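"""RNA Pol2 pausing index from strand-specific nascent-transcription tracks.

The pausing index (PI) of a transcript is the ratio of the mean signal in
its promoter window (50 bp upstream to 250 bp downstream of the TSS) to
the mean signal in its gene body (250 bp downstream of the TSS to the
TTS).  Windows follow transcription direction: on the minus strand
"downstream" means decreasing genomic coordinates.  Signal is read from
the track matching the transcript's strand and taken as magnitudes, so
minus-strand coverage conventionally stored as negative values behaves
identically.  Transcripts whose body mean is zero have a non-finite PI and
are excluded from gene-level summaries; per gene, the largest finite PI
across transcripts is kept.  Merged (non-strand-specific) data is handled
by passing the same track for both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .core import GenomicInterval, SignalTrack, TranscriptRecord, track_stat

logger = logging.getLogger("tadbound")

__all__ = [
    "PausingRecord",
    "promoter_body_windows",
    "pausing_index",
    "gene_pausing",
    "pausing_summary",
]

PROMOTER_UPSTREAM = 50
PROMOTER_DOWNSTREAM = 250


@dataclass(frozen=True)
class PausingRecord:
    transcript_id: str
    gene_id: str
    promoter_mean: float
    body_mean: float
    pi: float  # may be non-finite (inf/nan) when the body mean is 0

    @property
    def finite(self) -> bool:
        return math.isfinite(self.pi)


def promoter_body_windows(
    transcript: TranscriptRecord,
) -> tuple[GenomicInterval, GenomicInterval]:
    """Strand-aware promoter and body windows in genome coordinates.

    Plus strand: promoter [TSS-50, TSS+250), body [TSS+250, TTS+1).
    Minus strand is the exact mirror, so strand-mirrored transcripts with
    mirror-image signal produce identical means.  The body must be
    non-empty (transcript longer than 250 bp past the promoter); otherwise
    a ValueError is raised.
    """
    chrom = transcript.interval.chrom
    tss = transcript.tss
    if transcript.strand == "+":
        prom = GenomicInterval(chrom, max(0, tss - PROMOTER_UPSTREAM), tss + PROMOTER_DOWNSTREAM)
        body_start, body_end = tss + PROMOTER_DOWNSTREAM, transcript.interval.end
    else:
        prom = GenomicInterval(
            chrom, max(0, tss - PROMOTER_DOWNSTREAM + 1), tss + PROMOTER_UPSTREAM + 1
        )
        body_start, body_end = transcript.interval.start, tss - PROMOTER_DOWNSTREAM + 1
    if body_start >= body_end:
        raise ValueError(
            f"transcript {transcript.transcript_id} too short for a body window"
        )
    return prom, GenomicInterval(chrom, body_start, body_end)


def pausing_index(
    transcript: TranscriptRecord,
    track_plus: SignalTrack,
    track_minus: SignalTrack,
) -> PausingRecord:
    """PI of one transcript, reading only the track of its strand."""
    track = track_plus if transcript.strand == "+" else track_minus
    try:
        prom, body = promoter_body_windows(transcript)
    except ValueError:
        return PausingRecord(
            transcript.transcript_id, transcript.gene_id, math.nan, math.nan, math.nan
        )
    promoter_mean = abs(track_stat(track, prom, "mean"))
    body_mean = abs(track_stat(track, body, "mean"))
    if body_mean > 0:
        pi = promoter_mean / body_mean
    elif promoter_mean > 0:
        pi = math.inf
    else:
        pi = math.nan
    return PausingRecord(
        transcript.transcript_id, transcript.gene_id, promoter_mean, body_mean, pi
    )


def gene_pausing(
    records: Sequence[PausingRecord],
    expression: Mapping[str, float],
    active_threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-gene PI: the largest finite PI over transcripts, plus activity.

    A gene is active iff its expression is strictly above the threshold
    (FPKM/RPKM > 5 by default); genes missing from the expression table are
    treated as inactive (logged).  Genes with no finite-PI transcript are
    omitted.
    """
    best: dict[str, float] = {}
    for rec in records:
        if not rec.finite:
            continue
        if rec.gene_id not in best or rec.pi > best[rec.gene_id]:
            best[rec.gene_id] = rec.pi
    missing = [g for g in best if g not in expression]
    if missing:
        logger.warning(
            "%d genes missing from the expression table; treated as inactive",
            len(missing),
        )
    rows = [
        {
            "gene_id": gene,
            "pi": pi,
            "expression": float(expression.get(gene, 0.0)),
            "active": float(expression.get(gene, 0.0)) > active_threshold,
        }
        for gene, pi in sorted(best.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "pi", "expression", "active"])


def pausing_summary(
    gene_table: pd.DataFrame,
    categories,
    bin1_genes: set[str],
) -> pd.DataFrame:
    """Median PI by gene category x activity x boundary proximity (bin 1)."""
    rows = []
    for label in categories.labels:
        members = categories.members(label)
        sub = gene_table[gene_table.gene_id.isin(members)]
        for active in (True, False):
            for in_bin1 in (True, False):
                sel = sub[
                    (sub.active == active) & (sub.gene_id.isin(bin1_genes) == in_bin1)
                ]
                if len(sel):
                    rows.append(
                        {
                            "category": label,
                            "active": active,
                            "bin1": in_bin1,
                            "n": len(sel),
                            "median_pi": float(sel.pi.median()),
                        }
                    )
    return pd.DataFrame(rows, columns=["category", "active", "bin1", "n", "median_pi"])
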