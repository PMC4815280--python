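"""Single-point confidence-interval detectors for AI, LOH/LCSH and CNV/CNA.

All detectors compare one marker of one sample against normal-reference
statistics using standard-normal quantiles that carry a per-chromosome
Bonferroni factor M (the number of evaluable markers on the chromosome;
CN probes get their own M separate from SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from hiscan.data_io import GT_AA, GT_AB, GT_BB, GT_NOCALL


@dataclass(frozen=True)
class DetectionConfig:
    alpha: float = 0.05
    genotype_specific: bool = False
    paired: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SinglePointResult:
    """Per-marker flags with NaN where a marker could not be evaluated.

    AI/LOH flags are {0, 1}; CNV flags are {-1, 0, +1} with ``z`` the test
    statistic and ``p`` the Bonferroni-adjusted two-sided p-value.
    """

    flags: np.ndarray
    valid: np.ndarray
    m_track: np.ndarray
    z: np.ndarray | None = None
    p: np.ndarray | None = None


def per_group_counts(valid: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Map each marker to the count of valid markers sharing its group label."""
    valid = np.asarray(valid, dtype=bool)
    groups = np.asarray(groups)
    out = np.zeros(len(groups))
    for label in np.unique(groups):
        sel = groups == label
        out[sel] = valid[sel].sum()
    return out


def _z_upper(tail: np.ndarray) -> np.ndarray:
    """z(1 - tail), guarded against tail >= 1 or M = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        q = 1.0 - np.asarray(tail, dtype=float)
    return norm.ppf(np.clip(q, 0.0, 1.0))


def ai_flags(
    f_track: np.ndarray,
    af_mean: np.ndarray,
    af_sd: np.ndarray,
    counts: np.ndarray,
    chromosomes: np.ndarray,
    alpha: float = 0.05,
    eval_mask: np.ndarray | None = None,
) -> SinglePointResult:
    """Unpaired single-point AI: flag markers outside all three genotype intervals.

    Intervals: [mean_AA - z(1-a/3M) S_AA, 1], mean_AB +- z(1-a/6M) S_AB,
    and [0, mean_BB + z(1-a/3M) S_BB].
    """
    f = np.asarray(f_track, dtype=float)
    valid = np.isfinite(f)
    for g in (GT_AA, GT_AB, GT_BB):
        valid &= (counts[g] >= 2) & (af_sd[g] > 0) & np.isfinite(af_mean[g])
    if eval_mask is not None:
        valid &= np.asarray(eval_mask, dtype=bool)
    m_track = per_group_counts(valid, chromosomes)
    with np.errstate(invalid="ignore", divide="ignore"):
        z3 = _z_upper(alpha / (3.0 * m_track))
        z6 = _z_upper(alpha / (6.0 * m_track))
        in_aa = f >= af_mean[GT_AA] - z3 * af_sd[GT_AA]
        in_bb = f <= af_mean[GT_BB] + z3 * af_sd[GT_BB]
        in_ab = np.abs(f - af_mean[GT_AB]) <= z6 * af_sd[GT_AB]
    flagged = ~(in_aa | in_ab | in_bb)
    flags = np.where(valid, flagged.astype(float), np.nan)
    return SinglePointResult(flags=flags, valid=valid, m_track=m_track)


def ai_flags_paired(
    f_track: np.ndarray,
    paired_f: np.ndarray,
    paired_genotype: np.ndarray,
    af_sd: np.ndarray,
    counts: np.ndarray,
    chromosomes: np.ndarray,
    alpha: float = 0.05,
    eval_mask: np.ndarray | None = None,
) -> SinglePointResult:
    """Paired single-point AI: one interval, centred on the paired-normal AF.

    Only the interval of the paired-normal genotype is used, with quantiles
    a/M for homozygotes and a/2M for heterozygotes. The dispersion comes
    from the reference panel (a single paired sample has none of its own).
    """
    f = np.asarray(f_track, dtype=float)
    pf = np.asarray(paired_f, dtype=float)
    pg = np.asarray(paired_genotype)
    valid = np.isfinite(f) & np.isfinite(pf) & (pg != GT_NOCALL)
    sd_sel = np.full(len(f), np.nan)
    for g in (GT_AA, GT_AB, GT_BB):
        sel = pg == g
        sd_sel[sel] = af_sd[g][sel]
        valid[sel] &= (counts[g][sel] >= 2) & (af_sd[g][sel] > 0)
    if eval_mask is not None:
        valid &= np.asarray(eval_mask, dtype=bool)
    m_track = per_group_counts(valid, chromosomes)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_hom = _z_upper(alpha / m_track)
        z_het = _z_upper(alpha / (2.0 * m_track))
        in_aa = f >= pf - z_hom * sd_sel
        in_bb = f <= pf + z_hom * sd_sel
        in_ab = np.abs(f - pf) <= z_het * sd_sel
    inside = np.where(pg == GT_AB, in_ab, np.where(pg == GT_AA, in_aa, in_bb))
    flags = np.where(valid, (~inside).astype(float), np.nan)
    return SinglePointResult(flags=flags, valid=valid, m_track=m_track)


def loh_flags(
    f_track: np.ndarray,
    af_mean: np.ndarray,
    af_sd: np.ndarray,
    counts: np.ndarray,
    chromosomes: np.ndarray,
    alpha: float = 0.05,
    eval_mask: np.ndarray | None = None,
    paired_f: np.ndarray | None = None,
) -> SinglePointResult:
    """Single-point LOH/LCSH: flag AFs outside mean_AB +- z(1-a/2M) S_AB.

    In paired mode ``paired_f`` replaces the heterozygote reference mean as
    the interval centre (centre-only substitution).
    """
    f = np.asarray(f_track, dtype=float)
    valid = np.isfinite(f) & (counts[GT_AB] >= 2) & (af_sd[GT_AB] > 0)
    center = af_mean[GT_AB]
    if paired_f is not None:
        center = np.asarray(paired_f, dtype=float)
        valid &= np.isfinite(center)
    if eval_mask is not None:
        valid &= np.asarray(eval_mask, dtype=bool)
    m_track = per_group_counts(valid, chromosomes)
    with np.errstate(invalid="ignore", divide="ignore"):
        z2 = _z_upper(alpha / (2.0 * m_track))
        outside = np.abs(f - center) > z2 * af_sd[GT_AB]
    flags = np.where(valid, outside.astype(float), np.nan)
    return SinglePointResult(flags=flags, valid=valid, m_track=m_track)


def cnv_flags(
    t_track: np.ndarray,
    genotype: np.ndarray,
    t_mean_g: np.ndarray,
    t_sd_g: np.ndarray,
    counts_g: np.ndarray,
    pooled_mean: np.ndarray,
    pooled_sd: np.ndarray,
    pooled_n: np.ndarray,
    chromosomes: np.ndarray,
    probe_class: np.ndarray | None = None,
    alpha: float = 0.05,
    genotype_specific: bool = False,
    paired_t: np.ndarray | None = None,
) -> SinglePointResult:
    """Single-point CNV/CNA detector (+1 gain / -1 loss / 0 neutral).

    A marker is a gain iff t > mean + z(1-a/2M) SD and a loss iff
    t < mean - z(1-a/2M) SD (strict inequalities). In genotype-specific
    mode the sample's own called genotype selects the reference mean/SD,
    falling back to the pooled statistics at NoCall markers. The adjusted
    p-value is min{2 (1 - Phi(|Z|)) M, 1}. In paired mode ``paired_t``
    replaces the reference mean (dispersion stays with the panel).
    """
    t = np.asarray(t_track, dtype=float)
    g = np.asarray(genotype)
    n = len(t)
    mean = pooled_mean.astype(float).copy()
    sd = pooled_sd.astype(float).copy()
    have_stats = (pooled_n >= 2) & (pooled_sd > 0)
    if genotype_specific:
        for gt in (GT_AA, GT_AB, GT_BB):
            sel = (g == gt) & (counts_g[gt] >= 2) & (t_sd_g[gt] > 0)
            mean[sel] = t_mean_g[gt][sel]
            sd[sel] = t_sd_g[gt][sel]
            have_stats[sel] = True
        # NoCall markers keep pooled statistics (per-marker fallback)
    if paired_t is not None:
        paired_t = np.asarray(paired_t, dtype=float)
        mean = paired_t
    valid = np.isfinite(t) & np.isfinite(mean) & have_stats
    groups = np.asarray(chromosomes).astype(str)
    if probe_class is not None:
        groups = np.char.add(np.char.add(groups, ":"), np.asarray(probe_class).astype(str))
    m_track = per_group_counts(valid, groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_q = _z_upper(alpha / (2.0 * m_track))
        z = (t - mean) / sd
        flags = np.where(z > z_q, 1.0, np.where(z < -z_q, -1.0, 0.0))
        p = np.minimum(2.0 * norm.sf(np.abs(z)) * m_track, 1.0)
    flags = np.where(valid, flags, np.nan)
    z = np.where(valid, z, np.nan)
    p = np.where(valid, p, np.nan)
    return SinglePointResult(flags=flags, valid=valid, m_track=m_track, z=z, p=p)


# ---------------------------------------------------------------------------
# panel-level convenience wrappers


def detect_ai_single(f_track, panel, cfg: DetectionConfig = DetectionConfig(),
                     paired_f=None, paired_genotype=None) -> SinglePointResult:
    ann = panel.annotation
    if cfg.paired:
        if paired_f is None or paired_genotype is None:
            raise ValueError("paired mode needs paired_f and paired_genotype")
        return ai_flags_paired(
            f_track, paired_f, paired_genotype, panel.af_sd, panel.af_counts,
            ann.chromosome, alpha=cfg.alpha, eval_mask=ann.is_snp,
        )
    return ai_flags(
        f_track, panel.af_mean, panel.af_sd, panel.af_counts, ann.chromosome,
        alpha=cfg.alpha, eval_mask=ann.is_snp,
    )


def detect_loh_single(f_track, panel, cfg: DetectionConfig = DetectionConfig(),
                      paired_f=None) -> SinglePointResult:
    ann = panel.annotation
    if cfg.paired and paired_f is None:
        raise ValueError("paired mode needs paired_f")
    return loh_flags(
        f_track, panel.af_mean, panel.af_sd, panel.af_counts, ann.chromosome,
        alpha=cfg.alpha, eval_mask=ann.is_snp,
        paired_f=paired_f if cfg.paired else None,
    )


def detect_cnv_single(t_track, genotype_track, panel,
                      cfg: DetectionConfig = DetectionConfig(),
                      paired_t=None) -> SinglePointResult:
    ann = panel.annotation
    if cfg.paired and paired_t is None:
        raise ValueError("paired mode needs paired_t")
    return cnv_flags(
        t_track, genotype_track, panel.t_mean, panel.t_sd, panel.t_counts,
        panel.t_pooled_mean, panel.t_pooled_sd, panel.t_pooled_n,
        ann.chromosome, ann.probe_class, alpha=cfg.alpha,
        genotype_specific=cfg.genotype_specific,
        paired_t=paired_t if cfg.paired else None,
    )
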