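"""Locus-level quantification for engineered cell lines.

Two independent layers:

* relative expression by the 2^-ddCt method: per biological replicate the
  target Ct is normalized to the arithmetic mean of two reference-gene Cts
  (dCt), re-referenced to the mean dCt of the baseline (wild-type) line
  (ddCt), and expressed as a fold-change 2^-ddCt.  Per line the mean
  fold-change is taken in log2 space and compared to the baseline by a
  two-sided unpaired t-test on the log2 values.  A change is significant
  only when the fold-change is at least 2 in either direction AND p <= 0.05
  (the contrapositive of the "NS: fold-change < 2 or p > 0.05" rule).

* viewpoint interaction (Capture-C style) profiles on a fragment grid:
  reads-per-million normalization (profile total = 1e6), replicate
  averaging, subtraction of the wild-type profile, rolling-mean smoothing
  for display, and per-region mean signals with log2 fold-changes against
  the wild type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, SignalTrack

__all__ = [
    "FoldChangeResult",
    "CaptureProfile",
    "read_ct_table",
    "ddct_fold_change",
    "normalize_profile",
    "average_replicates",
    "subtract_reference",
    "smooth_profile",
    "region_log2fc",
    "profile_from_track",
]

CT_COLUMNS = ["line", "replicate", "gene", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns line, replicate, gene, ct.

    Rows with a ``technical`` column are averaged (arithmetic mean of Ct
    over technical replicates) into one Ct per biological replicate.
    """
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "technical" in df.columns:
        df = (
            df.groupby(["line", "replicate", "gene"], as_index=False)["ct"].mean()
        )
    return df[CT_COLUMNS]


@dataclass
class FoldChangeResult:
    line: str
    gene: str
    log2_fold_changes: np.ndarray  # per biological replicate, vs baseline mean
    fold_change: float  # 2 ** mean(log2 fold-changes)
    p_value: float
    significant: bool


def _delta_ct(
    ct: pd.DataFrame, target: str, refs: Sequence[str], line: str
) -> np.ndarray:
    sub = ct[ct.line == line]
    out = []
    for rep, grp in sub.groupby("replicate"):
        by_gene = grp.set_index("gene").ct
        for ref in refs:
            if ref not in by_gene.index:
                raise ValueError(
                    f"missing reference gene {ref!r} Ct for line {line!r}, "
                    f"replicate {rep!r}"
                )
        if target not in by_gene.index:
            raise ValueError(
                f"missing target {target!r} Ct for line {line!r}, replicate {rep!r}"
            )
        ref_mean = float(np.mean([by_gene[r] for r in refs]))
        out.append(float(by_gene[target]) - ref_mean)
    return np.array(out)


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    refs: Sequence[str] = ("Eef1a1", "Hprt1"),
    baseline_line: str = "WT",
) -> dict[str, FoldChangeResult]:
    """2^-ddCt fold-changes of ``target`` for every line vs the baseline."""
    lines = list(dict.fromkeys(ct.line))
    if baseline_line not in lines:
        raise ValueError(f"baseline line {baseline_line!r} not in table")
    base_dct = _delta_ct(ct, target, refs, baseline_line)
    if base_dct.size < 2:
        raise ValueError("need >= 2 baseline biological replicates")
    base_mean = base_dct.mean()
    base_log2fc = -(base_dct - base_mean)
    results: dict[str, FoldChangeResult] = {}
    for line in lines:
        dct = _delta_ct(ct, target, refs, line)
        if dct.size < 2:
            raise ValueError(f"need >= 2 biological replicates for line {line!r}")
        log2fc = -(dct - base_mean)
        fold = float(2.0 ** log2fc.mean())
        if np.ptp(log2fc) == 0 and np.ptp(base_log2fc) == 0:
            p = 1.0 if math.isclose(log2fc.mean(), base_log2fc.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(log2fc, base_log2fc).pvalue)
        significant = (fold >= 2.0 or fold <= 0.5) and p <= 0.05
        results[line] = FoldChangeResult(
            line=line,
            gene=target,
            log2_fold_changes=log2fc,
            fold_change=fold,
            p_value=p,
            significant=significant,
        )
    return results


# ---------------------------------------------------------------------------
# viewpoint interaction profiles
# ---------------------------------------------------------------------------


@dataclass
class CaptureProfile:
    """Per-fragment interaction pileup restricted to one locus.

    Fragments tile the locus contiguously; fragments without detected
    interactions carry 0 (zero-fill is inherent to the complete grid).
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    viewpoint: int | None = None
    genotype: str = ""
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.starts.size == self.ends.size == self.values.size):
            raise ValueError("fragment arrays must have equal length")

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def same_grid(self, other: "CaptureProfile") -> bool:
        return (
            self.chrom == other.chrom
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    def to_track(self) -> SignalTrack:
        return SignalTrack.from_arrays(self.chrom, self.starts, self.ends, self.values)


def profile_from_track(
    track: SignalTrack, chrom: str, start: int, end: int, fragment_size: int
) -> CaptureProfile:
    """Project a bedGraph-backed track onto a complete fragment grid.

    Fragments absent from the track get value 0 (zero-fill); each fragment
    takes the base-weighted mean of the track over its span.
    """
    from .core import track_stat

    starts = np.arange(start, end - fragment_size + 1, fragment_size, dtype=np.int64)
    ends = starts + fragment_size
    values = np.array(
        [track_stat(track, GenomicInterval(chrom, int(s), int(e)), "mean") for s, e in zip(starts, ends)]
    )
    return CaptureProfile(chrom=chrom, starts=starts, ends=ends, values=values)


def normalize_profile(profile: CaptureProfile, total: float = 1e6) -> CaptureProfile:
    """Scale the profile so its total equals ``total`` (reads per million)."""
    s = profile.values.sum()
    if s <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return replace(profile, values=profile.values * (total / s))


def average_replicates(*profiles: CaptureProfile) -> CaptureProfile:
    """Per-fragment arithmetic mean of replicate profiles (same grid)."""
    if len(profiles) < 2:
        raise ValueError("need at least two replicates")
    first = profiles[0]
    for p in profiles[1:]:
        if not first.same_grid(p):
            raise ValueError("replicate profiles are on different fragment grids")
    mean = np.mean([p.values for p in profiles], axis=0)
    return replace(first, values=mean, replicate=None)


def subtract_reference(
    profile: CaptureProfile, reference: CaptureProfile
) -> CaptureProfile:
    """Per-fragment difference profile (signal minus reference); may be negative."""
    if not profile.same_grid(reference):
        raise ValueError("profiles are on different fragment grids")
    return replace(
        profile,
        values=profile.values - reference.values,
        genotype=f"{profile.genotype}-{reference.genotype}",
        replicate=None,
    )


def smooth_profile(profile: CaptureProfile, window: int = 16) -> CaptureProfile:
    """Centered rolling mean over ``window`` fragments (edges use what exists).

    Intended for display tracks only; quantification always uses the
    unsmoothed per-fragment values.
    """
    smoothed = (
        pd.Series(profile.values)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(profile, values=smoothed)


def region_log2fc(
    mut_profile: CaptureProfile,
    wt_profile: CaptureProfile,
    regions: Sequence[GenomicInterval],
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Region mean signals and log2 fold-changes of mutant vs wild type.

    The region mean is the unweighted mean over fragments whose midpoints
    fall inside the region.  The pseudocount defaults to 1e-3 of the
    wild-type locus-mean signal and guards the ratio against empty regions
    of signal.
    """
    if not mut_profile.same_grid(wt_profile):
        raise ValueError("profiles are on different fragment grids")
    if pseudocount is None:
        pseudocount = 1e-3 * float(wt_profile.values.mean())
    mids = mut_profile.midpoints
    rows = []
    for region in regions:
        if region.chrom != mut_profile.chrom:
            raise ValueError(f"region {region} not on profile chromosome")
        mask = (mids >= region.start) & (mids < region.end)
        if not mask.any():
            raise ValueError(f"region {region} contains no fragment midpoint")
        m = float(mut_profile.values[mask].mean())
        w = float(wt_profile.values[mask].mean())
        rows.append(
            {
                "region": str(region),
                "n_fragments": int(mask.sum()),
                "mut_mean": m,
                "wt_mean": w,
                "log2fc": math.log2((m + pseudocount) / (w + pseudocount)),
            }
        )
    return pd.DataFrame(
        rows, columns=["region", "n_fragments", "mut_mean", "wt_mean", "log2fc"]
    )
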