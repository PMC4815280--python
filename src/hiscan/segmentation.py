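"""Copy-number segmentation: circular binary segmentation and its quick variant.

Full CBS circularizes the intensity track, searches all contiguous arcs for
the largest standardized mean difference between an arc and its complement,
and accepts a split when a permutation test (re-maximizing the statistic on
shuffled data) is significant. The quick variant restricts the recursion to
previously detected AI / LOH regions and replaces the plain statistic with a
weighted one whose weights come from the WAP excess over the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from hiscan.data_io import MarkerAnnotation
from hiscan.detect_multi import AberrantRegion

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CbsParams:
    alpha_change: float = 0.01
    min_markers: int = 5
    n_permutations: int = 1000
    trim_fraction: float = 0.025
    significant_segment_cutoff: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha_change < 1:
            raise ValueError("alpha_change must lie in (0, 1)")
        if self.min_markers < 1 or self.n_permutations < 1:
            raise ValueError("min_markers and n_permutations must be positive")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")


@dataclass
class Segment:
    chromosome: str
    start_idx: int  # inclusive, indices into the segmented track
    end_idx: int  # inclusive
    start_bp: int
    end_bp: int
    mean_t: float
    n_markers: int
    p_change: float = np.nan
    significant: bool = False


def _trimmed_sd(x: np.ndarray, trim_fraction: float) -> float:
    """SD after symmetric trimming of the most extreme values."""
    x = np.sort(x)
    k = int(np.floor(trim_fraction * len(x) / 2.0))
    if k > 0 and len(x) - 2 * k >= 2:
        x = x[k : len(x) - k]
    return float(x.std(ddof=1))


def _max_arc_stat(x: np.ndarray, min_markers: int, sd: float, weights: np.ndarray | None = None):
    """Best contiguous arc (i, j) maximizing the |mean difference| statistic.

    Arcs wrapping the circular join equal the complement of a contiguous
    window, and the statistic is symmetric under complementation, so the
    scan over contiguous windows is exhaustive. Returns (i, j, stat) with
    the arc x[i:j], or (None, None, 0.0) if no admissible arc exists.
    """
    n = len(x)
    if n < 2 * min_markers or sd <= 0:
        return None, None, 0.0
    if weights is None:
        csum = np.concatenate([[0.0], np.cumsum(x)])
        total = csum[-1]
        wsum = np.concatenate([[0.0], np.cumsum(np.ones(n))])
        wtotal = float(n)
    else:
        csum = np.concatenate([[0.0], np.cumsum(weights * x)])
        total = csum[-1]
        wsum = np.concatenate([[0.0], np.cumsum(weights)])
        wtotal = wsum[-1]
    best = (None, None, 0.0)
    for k in range(min_markers, n - min_markers + 1):
        seg = csum[k:] - csum[:-k]
        wseg = wsum[k:] - wsum[:-k]
        comp = total - seg
        wcomp = wtotal - wseg
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = seg / wseg - comp / wcomp
            stat = np.abs(diff) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
        stat[~np.isfinite(stat)] = 0.0
        idx = int(np.argmax(stat))
        if stat[idx] > best[2]:
            best = (idx, idx + k, float(stat[idx]))
    return best


def _split_p_value(x, obs, min_markers, params, rng, weights=None):
    """Permutation p for the best split: re-maximize on shuffled data.

    Stops early once the exceedance count guarantees p >= alpha_change.
    """
    n_perm = params.n_permutations
    limit = params.alpha_change * (n_perm + 1)
    sd = _trimmed_sd(x, params.trim_fraction)
    count = 0
    for b in range(n_perm):
        if weights is None:
            xp = rng.permutation(x)
            wp = None
        else:
            order = rng.permutation(len(x))
            xp, wp = x[order], weights[order]
        _, _, stat = _max_arc_stat(xp, min_markers, sd, weights=wp)
        if stat >= obs:
            count += 1
            if count >= limit:
                return (1.0 + count) / (2.0 + b), False
    p = (1.0 + count) / (1.0 + n_perm)
    return p, p < params.alpha_change


def _segment_indices(x, params, rng, weights=None):
    """Recursive circular splitting; returns sorted boundary indices."""
    boundaries: set[int] = set()
    pvals: dict[int, float] = {}

    def recurse(lo: int, hi: int) -> None:
        sub = x[lo:hi]
        n = hi - lo
        if n < 2 * params.min_markers:
            return
        sd = _trimmed_sd(sub, params.trim_fraction)
        w_sub = weights[lo:hi] if weights is not None else None
        i, j, obs = _max_arc_stat(sub, params.min_markers, sd, weights=w_sub)
        if i is None or obs <= 0:
            return
        p, significant = _split_p_value(sub, obs, params.min_markers, params, rng, weights=w_sub)
        if not significant:
            return
        cuts = [c for c in (lo + i, lo + j) if lo < c < hi]
        for c in cuts:
            boundaries.add(c)
            pvals[c] = p
        pieces = sorted({lo, hi} | set(cuts))
        for a, b in zip(pieces[:-1], pieces[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(boundaries), pvals


def _build_segments(t, boundaries, pvals, annotation_slice, params, offset=0):
    chrom, positions = annotation_slice
    edges = [0] + [b - offset for b in boundaries] + [len(t)]
    segments = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mean_t = float(np.nanmean(t[lo:hi]))
        p = pvals.get(lo + offset, np.nan)
        segments.append(
            Segment(
                chromosome=str(chrom),
                start_idx=lo + offset,
                end_idx=hi - 1 + offset,
                start_bp=int(positions[lo]),
                end_bp=int(positions[hi - 1]),
                mean_t=mean_t,
                n_markers=hi - lo,
                p_change=p,
                significant=abs(mean_t) > params.significant_segment_cutoff,
            )
        )
    return segments


def cbs_segment(
    t_track: np.ndarray,
    params: CbsParams = CbsParams(),
    positions: np.ndarray | None = None,
    chromosome: str = "NA",
) -> list[Segment]:
    """Full circular binary segmentation of one chromosome's intensity track.

    Deterministic given ``params.rng_seed``. Tracks shorter than
    2 * min_markers come back as a single segment.
    """
    t = np.asarray(t_track, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("intensity track must be finite; drop missing markers first")
    if positions is None:
        positions = np.arange(1, len(t) + 1)
    rng = np.random.default_rng(params.rng_seed)
    boundaries, pvals = _segment_indices(t, params, rng)
    return _build_segments(t, boundaries, pvals, (chromosome, positions), params)


# ---------------------------------------------------------------------------
# quick CBS


def quick_cbs_weights(d_ai: np.ndarray, d_loh: np.ndarray) -> np.ndarray:
    """Per-marker weights from the AI/LOH WAP excess over the reference.

    Each difference track is rescaled to [-1, 1] (a constant track rescales
    to 0 by convention); the weight is 1e-10 plus the positive part of the
    elementwise max of the two rescaled tracks, normalized to sum to 1.
    """
    d_ai = np.asarray(d_ai, dtype=float)
    d_loh = np.asarray(d_loh, dtype=float)
    if d_ai.shape != d_loh.shape:
        raise ValueError("difference tracks must be aligned")

    def rescale(d):
        c_min, c_max = np.nanmin(d), np.nanmax(d)
        if not np.isfinite(c_min) or c_max == c_min:
            return np.zeros_like(d)
        return 2.0 * (d - c_min) / (c_max - c_min) - 1.0

    best = np.maximum(rescale(d_ai), rescale(d_loh))
    w = 1e-10 + np.where(best > 0, best, 0.0)
    return w / w.sum()


def weighted_t_permutation(
    x_left: np.ndarray,
    x_right: np.ndarray,
    weights: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for a weighted two-sample mean difference.

    The statistic is the difference of weighted means over a pooled weighted
    variance (weights normalized to mean 1, so uniform weights reduce to the
    ordinary pooled two-sample t). Permutations shuffle data-weight pairs
    between the two sides; p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).
    """
    x_left = np.asarray(x_left, dtype=float)
    x_right = np.asarray(x_right, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n_l, n_r = len(x_left), len(x_right)
    if n_l == 0 or n_r == 0:
        raise ValueError("both sides must be non-empty")
    if len(weights) != n_l + n_r:
        raise ValueError("weights must align with the concatenated data")
    x = np.concatenate([x_left, x_right])
    w = weights / weights.mean()

    def statistic(order):
        xl, wl = x[order[:n_l]], w[order[:n_l]]
        xr, wr = x[order[n_l:]], w[order[n_l:]]
        ml = np.sum(wl * xl) / np.sum(wl)
        mr = np.sum(wr * xr) / np.sum(wr)
        ss = np.sum(wl * (xl - ml) ** 2) + np.sum(wr * (xr - mr) ** 2)
        dof = n_l + n_r - 2
        var = ss / dof if dof > 0 else 0.0
        if var <= 0:
            return np.inf if ml != mr else 0.0
        return (ml - mr) / np.sqrt(var * (1.0 / n_l + 1.0 / n_r))

    identity = np.arange(n_l + n_r)
    obs = statistic(identity)
    if not np.isfinite(obs):
        return 1.0 / (1.0 + n_perm) if obs != 0 else 1.0
    if obs == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        stat = statistic(rng.permutation(identity))
        if abs(stat) >= abs(obs):
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def quick_cbs_applicability(region_intervals, chromosome_span_bp: float) -> tuple[int, int, bool]:
    """The b/a < 5% rule: a = number of AI/LOH fragments, b = fragments
    shorter than 1% of the chromosome length. Returns (a, b, recommended)."""
    a = len(region_intervals)
    b = sum(
        1 for lo_bp, hi_bp in region_intervals if (hi_bp - lo_bp + 1) < 0.01 * chromosome_span_bp
    )
    recommended = a == 0 or (b / a) < 0.05
    return a, b, recommended


def quick_cbs_segment(
    t_track: np.ndarray,
    ai_regions: list[AberrantRegion],
    loh_regions: list[AberrantRegion],
    weights: np.ndarray,
    params: CbsParams = CbsParams(),
    annotation: MarkerAnnotation | None = None,
    positions: np.ndarray | None = None,
    chromosome: str = "NA",
) -> list[Segment]:
    """Weighted CBS restricted to AI / LOH regions of one chromosome.

    ``t_track``/``weights``/``positions`` cover one chromosome; the region
    lists carry marker index intervals into that chromosome (``start_idx`` /
    ``end_idx``; regions from a genome-wide scan must be re-indexed by the
    caller). Markers outside every AI/LOH region are grouped into single
    flanking segments. When b/a >= 5% (many small fragments) a warning is
    logged and segmentation still runs.
    """
    t = np.asarray(t_track, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(t)
    if positions is None:
        positions = np.arange(1, n + 1)
    if len(w) != n:
        raise ValueError("weights must align with the intensity track")

    intervals = sorted(
        (max(0, r.start_idx), min(n - 1, r.end_idx)) for r in list(ai_regions) + list(loh_regions)
    )
    merged: list[list[int]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    span = float(positions[-1] - positions[0] + 1)
    a, b, recommended = quick_cbs_applicability(
        [(positions[lo], positions[hi]) for lo, hi in merged], span
    )
    if not recommended:
        log.warning(
            "quick CBS not recommended here: %d of %d AI/LOH fragments are shorter than "
            "1%% of the chromosome (b/a >= 5%%); running anyway", b, a,
        )

    rng = np.random.default_rng(params.rng_seed)
    boundaries: list[int] = []
    pvals: dict[int, float] = {}
    for lo, hi in merged:
        if lo > 0:
            boundaries.append(lo)
        if hi + 1 < n:
            boundaries.append(hi + 1)
        sub = t[lo : hi + 1]
        sub_w = w[lo : hi + 1]
        inner, inner_p = _segment_indices(sub, params, rng, weights=sub_w)
        for c in inner:
            boundaries.append(lo + c)
            pvals[lo + c] = inner_p[c]
    boundaries = sorted(set(boundaries))
    return _build_segments(t, boundaries, pvals, (chromosome, positions), params)
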