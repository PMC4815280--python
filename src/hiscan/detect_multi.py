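"""Sliding-window multipoint scan: WAP statistics, smoothing and region joining.

The window-based aberrant proportion (WAP) at an anchor marker is the
fraction of markers in the window that belong to a run of at least ``n_c``
consecutive single-point-significant markers. Significance is assessed
either against the Q%-quantile of smoothed reference WAPs (procedure 1) or
by a one-sided normal test against the reference WAP mean/SD (procedure 2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.nonparametric.smoothers_lowess import lowess

from hiscan.data_io import MarkerAnnotation

log = logging.getLogger(__name__)

COMBINE_MODES = ("quantile", "test", "both")


@dataclass(frozen=True)
class WindowConfig:
    v: int  # half-width; window size w = 2v + 1
    n_c: int  # required consecutive significant markers
    q_percent: float = 95.0
    loess_span: float = 0.02
    combine_mode: str = "both"

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("v must be >= 0")
        if not 1 <= self.n_c <= 2 * self.v + 1:
            raise ValueError("n_c must satisfy 1 <= n_c <= 2v+1")
        if self.combine_mode not in COMBINE_MODES:
            raise ValueError(f"combine_mode must be one of {COMBINE_MODES}")

    @property
    def window_size(self) -> int:
        return 2 * self.v + 1

    @classmethod
    def from_window_size(cls, w: int, n_c: int, **kwargs) -> "WindowConfig":
        if w < 1 or w % 2 == 0:
            raise ValueError("window size w must be a positive odd integer")
        return cls(v=(w - 1) // 2, n_c=n_c, **kwargs)


@dataclass
class MultipointTrack:
    wap: np.ndarray
    smoothed: np.ndarray
    z: np.ndarray
    p: np.ndarray
    flag_quantile: np.ndarray
    flag_test: np.ndarray
    combined: np.ndarray
    n_sd_zero: int = 0


def run_indicator(flags: np.ndarray, n_c: int) -> np.ndarray:
    """J track: 1 iff the marker lies in a run of >= n_c consecutive flags.

    Equivalently, at least one placement of ``n_c`` consecutive significant
    markers covering the position is fully significant. On chromosomes
    shorter than ``n_c`` the placements are truncated to the in-bounds
    markers (J = 1 only if every marker is flagged).
    """
    f = np.asarray(flags, dtype=float)
    sig = np.isfinite(f) & (f > 0)
    n = len(sig)
    if n == 0:
        return np.zeros(0)
    eff = min(n_c, n)
    # run length at every position
    changes = np.flatnonzero(np.diff(sig.astype(np.int8)))
    starts = np.r_[0, changes + 1]
    lengths = np.diff(np.r_[starts, n])
    run_len = np.repeat(lengths, lengths)
    return (sig & (run_len >= eff)).astype(float)


def compute_wap(j_track: np.ndarray, v: int) -> np.ndarray:
    """Mean of J over the window of size 2v+1 anchored at each marker.

    Windows at chromosome ends are truncated to the available markers, with
    the actual marker count as denominator, so every anchor gets a WAP.
    """
    j = np.asarray(j_track, dtype=float)
    n = len(j)
    if n == 0:
        return np.zeros(0)
    csum = np.concatenate([[0.0], np.cumsum(j)])
    anchors = np.arange(n)
    lo = np.maximum(0, anchors - v)
    hi = np.minimum(n, anchors + v + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def wap_track(
    flags: np.ndarray,
    chromosomes: np.ndarray,
    v: int,
    n_c: int,
) -> np.ndarray:
    """Per-chromosome J + WAP over a genome-length binary flag track."""
    flags = np.asarray(flags, dtype=float)
    chromosomes = np.asarray(chromosomes)
    out = np.zeros(len(flags))
    for chrom in np.unique(chromosomes):
        sel = chromosomes == chrom
        sub = flags[sel]
        if len(sub) < n_c:
            log.warning("chromosome %s has fewer markers (%d) than n_c=%d; WAP set to 0",
                        chrom, len(sub), n_c)
            out[sel] = 0.0
            continue
        out[sel] = compute_wap(run_indicator(sub, n_c), v)
    return out


def smooth_track(
    track: np.ndarray,
    span: float = 0.02,
    clip: tuple[float, float] | None = (0.0, 1.0),
) -> np.ndarray:
    """LOESS smoothing over marker index (local linear, tricube weights).

    ``span`` is the fraction of the chromosome's markers in each local fit;
    it is floored so at least 3 markers enter every fit. Tracks with fewer
    than 4 markers are returned unchanged (with a warning). Missing values
    are ignored during fitting and stay missing.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    y = np.asarray(track, dtype=float)
    n = len(y)
    finite = np.isfinite(y)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 markers: smoothing skipped", stacklevel=2)
        return y.copy()
    x = np.flatnonzero(finite).astype(float)
    frac = min(1.0, max(span, 3.0 / finite.sum()))
    fitted = lowess(y[finite], x, frac=frac, it=0, return_sorted=False)
    out = np.full(n, np.nan)
    out[finite] = fitted
    if clip is not None:
        out = np.clip(out, clip[0], clip[1])
    return out


def smooth_track_by_chromosome(
    track: np.ndarray,
    chromosomes: np.ndarray,
    span: float = 0.02,
    clip: tuple[float, float] | None = (0.0, 1.0),
) -> np.ndarray:
    track = np.asarray(track, dtype=float)
    chromosomes = np.asarray(chromosomes)
    out = np.full(len(track), np.nan)
    for chrom in np.unique(chromosomes):
        sel = chromosomes == chrom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[sel] = smooth_track(track[sel], span=span, clip=clip)
    return out


def detect_multipoint(
    wap: np.ndarray,
    smoothed: np.ndarray,
    reference,
    chromosomes: np.ndarray,
    cfg: WindowConfig,
    p_threshold: float = 0.05,
) -> MultipointTrack:
    """Evaluate the two multipoint significance procedures per anchor.

    Procedure 1 flags anchors whose smoothed WAP strictly exceeds the
    reference quantile track. Procedure 2 computes
    Z = (W - mu + 1/M) / S against the reference WAP mean/SD and flags
    anchors with Bonferroni-adjusted one-sided p < ``p_threshold``; anchors
    with S = 0 get no test flag (counted and logged). ``combined`` follows
    ``cfg.combine_mode`` with a missing test flag treated as 0.
    """
    wap = np.asarray(wap, dtype=float)
    smoothed = np.asarray(smoothed, dtype=float)
    chromosomes = np.asarray(chromosomes)
    m_track = np.zeros(len(wap))
    finite = np.isfinite(wap)
    for chrom in np.unique(chromosomes):
        sel = chromosomes == chrom
        m_track[sel] = finite[sel].sum()

    flag1 = np.where(
        np.isfinite(smoothed) & np.isfinite(reference.quantile),
        (smoothed > reference.quantile).astype(float),
        np.nan,
    )
    sd_ok = np.isfinite(reference.sd) & (reference.sd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd_ok, (wap - reference.mean + 1.0 / m_track) / reference.sd, np.nan)
        p = np.minimum(norm.sf(z) * m_track, 1.0)
    flag2 = np.where(np.isfinite(p), (p < p_threshold).astype(float), np.nan)
    n_sd_zero = int((~sd_ok & finite).sum())
    if n_sd_zero:
        log.info("hypothesis-test flag unavailable at %d anchors (reference SD = 0)", n_sd_zero)

    f1 = np.nan_to_num(flag1)
    f2 = np.nan_to_num(flag2)
    if cfg.combine_mode == "quantile":
        combined = f1
    elif cfg.combine_mode == "test":
        combined = f2
    else:
        combined = f1 * f2
    return MultipointTrack(
        wap=wap, smoothed=smoothed, z=z, p=p,
        flag_quantile=flag1, flag_test=flag2, combined=combined, n_sd_zero=n_sd_zero,
    )


def run_multipoint(
    flags: np.ndarray,
    reference,
    annotation: MarkerAnnotation,
    cfg: WindowConfig,
) -> MultipointTrack:
    """Convenience path: binary single-point flags -> WAP -> smooth -> detect."""
    wap = wap_track(flags, annotation.chromosome, v=cfg.v, n_c=cfg.n_c)
    smoothed = smooth_track_by_chromosome(wap, annotation.chromosome, span=cfg.loess_span)
    return detect_multipoint(wap, smoothed, reference, annotation.chromosome, cfg)


# ---------------------------------------------------------------------------
# region joining


@dataclass
class AberrantRegion:
    """A joined genomic interval typed as AI, LOH, GAIN or LOSS.

    ``start_idx``/``end_idx`` are inclusive indices into the annotation;
    ``start_bp``/``end_bp`` are 1-based inclusive genomic coordinates.
    """

    chromosome: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    kind: str
    n_markers: int
    min_p: float = np.nan
    mean_wap: float = np.nan


def _make_region(annotation, lo, hi, kind, p_track, wap_track_values):
    min_p = np.nan
    mean_wap = np.nan
    if p_track is not None:
        window = np.asarray(p_track, dtype=float)[lo : hi + 1]
        if np.isfinite(window).any():
            min_p = float(np.nanmin(window))
    if wap_track_values is not None:
        window = np.asarray(wap_track_values, dtype=float)[lo : hi + 1]
        if np.isfinite(window).any():
            mean_wap = float(np.nanmean(window))
    return AberrantRegion(
        chromosome=str(annotation.chromosome[lo]),
        start_idx=int(lo),
        end_idx=int(hi),
        start_bp=int(annotation.position_bp[lo]),
        end_bp=int(annotation.position_bp[hi]),
        kind=kind,
        n_markers=hi - lo + 1,
        min_p=min_p,
        mean_wap=mean_wap,
    )


def join_regions(
    flags: np.ndarray,
    annotation: MarkerAnnotation,
    kind: str,
    mode: str = "single",
    v: int = 0,
    p_track: np.ndarray | None = None,
    wap_values: np.ndarray | None = None,
) -> list[AberrantRegion]:
    """Join flagged markers into typed regions.

    ``mode="single"`` joins maximal runs of flagged markers. ``mode="multi"``
    takes the union of the windows [m-v, m+v] of flagged anchors (clipped to
    the chromosome) and merges overlapping windows. Gains and losses are
    never merged: callers pass direction-separated binary tracks.
    """
    if mode not in ("single", "multi"):
        raise ValueError("mode must be 'single' or 'multi'")
    f = np.asarray(flags, dtype=float)
    sig = np.isfinite(f) & (f > 0)
    regions: list[AberrantRegion] = []
    chroms = annotation.chromosome
    for chrom in dict.fromkeys(chroms):  # preserve annotation order
        sel = np.flatnonzero(chroms == chrom)
        lo_g, hi_g = sel[0], sel[-1]
        hits = sel[sig[sel]]
        if hits.size == 0:
            continue
        if mode == "single":
            breaks = np.flatnonzero(np.diff(hits) > 1)
            starts = np.r_[hits[0], hits[breaks + 1]]
            ends = np.r_[hits[breaks], hits[-1]]
            intervals = list(zip(starts, ends))
        else:
            windows = [(max(lo_g, m - v), min(hi_g, m + v)) for m in hits]
            windows.sort()
            intervals = [windows[0]]
            for lo, hi in windows[1:]:
                if lo <= intervals[-1][1]:
                    intervals[-1] = (intervals[-1][0], max(intervals[-1][1], hi))
                else:
                    intervals.append((lo, hi))
        for lo, hi in intervals:
            regions.append(_make_region(annotation, int(lo), int(hi), kind, p_track, wap_values))
    return regions
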