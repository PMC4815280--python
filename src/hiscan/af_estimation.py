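"""Individual-level allele-frequency estimation.

Two-step calibration of the relative allele-A intensity h = h_A/(h_A+h_B):
first a correction for preferential amplification/hybridization using the
per-marker coefficient kappa estimated from heterozygous reference samples,
then a piecewise-linear recalibration anchored at the genotype cluster
means so that (mean_BB, mean_AB, mean_AA) map to (0, 1/2, 1).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

log = logging.getLogger(__name__)


def estimate_cpa(het_raw_afs: np.ndarray, leave_one_out_correction: bool = False) -> float:
    """Estimate the preferential-hybridization coefficient kappa at one marker.

    ``het_raw_afs`` are raw AFs of heterozygous reference samples, each
    strictly inside (0, 1). kappa is the mean over heterozygotes of
    h/(1-h). With fewer than two heterozygotes there is no information and
    kappa falls back to 1 (with a warning).

    ``leave_one_out_correction`` additionally averages the bracketed
    deviations of each ratio from their mean, which is identically zero; it
    is exposed for completeness and does not change the estimate.
    """
    h = np.asarray(het_raw_afs, dtype=float)
    h = h[np.isfinite(h)]
    if h.size < 2:
        warnings.warn("fewer than 2 heterozygous references: kappa set to 1", stacklevel=2)
        return 1.0
    if np.any(h <= 0) or np.any(h >= 1):
        raise ValueError("heterozygous raw AFs must lie strictly in (0, 1)")
    ratios = h / (1.0 - h)
    kappa = float(ratios.mean())
    if leave_one_out_correction:
        n = ratios.size
        kappa += float((n / (n - 1)) * (ratios - ratios.mean()).mean())  # == 0 exactly
    return kappa


def cpa_adjust(h, kappa):
    """Adjust a raw AF for preferential hybridization: h / (h + kappa (1-h))."""
    h_arr = np.asarray(h, dtype=float)
    kappa_arr = np.asarray(kappa, dtype=float)
    if np.any(kappa_arr <= 0):
        raise ValueError("kappa must be positive")
    with np.errstate(invalid="ignore"):
        out = h_arr / (h_arr + kappa_arr * (1.0 - h_arr))
    return float(out) if np.ndim(h) == 0 and np.ndim(kappa) == 0 else out


def lim_calibrate(h_hat, mean_aa, mean_ab, mean_bb):
    """Piecewise-linear AF recalibration anchored at the genotype cluster means.

    Branches (lower boundary assigned to the lower branch):

    * ``f = 1``                                     if  h > mean_AA
    * ``f = 1/2 + (h - mean_AB)/(2 (mean_AA - mean_AB))``  if mean_AB < h <= mean_AA
    * ``f = (h - mean_BB)/(2 (mean_AB - mean_BB))``        if mean_BB < h <= mean_AB
    * ``f = 0``                                     if  h <= mean_BB

    Markers whose cluster means are not strictly ordered
    (mean_BB < mean_AB < mean_AA) are uncalibratable; the result is NaN there.
    """
    h = np.asarray(h_hat, dtype=float)
    aa = np.broadcast_to(np.asarray(mean_aa, dtype=float), h.shape).astype(float)
    ab = np.broadcast_to(np.asarray(mean_ab, dtype=float), h.shape).astype(float)
    bb = np.broadcast_to(np.asarray(mean_bb, dtype=float), h.shape).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        ordered = (bb < ab) & (ab < aa)
        upper = 0.5 + 0.5 * (h - ab) / (aa - ab)
        lower = 0.5 * (h - bb) / (ab - bb)
        out = np.where(h > aa, 1.0, np.where(h > ab, upper, np.where(h > bb, lower, 0.0)))
    out = np.where(ordered & np.isfinite(h), out, np.nan)
    return float(out) if np.ndim(h_hat) == 0 else out


def estimate_af(raw_af, kappa, mean_aa, mean_ab, mean_bb):
    """Full CPA + LIM pipeline: raw AF -> adjusted -> calibrated final AF."""
    adjusted = cpa_adjust(raw_af, kappa)
    final = lim_calibrate(adjusted, mean_aa, mean_ab, mean_bb)
    return adjusted, final
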