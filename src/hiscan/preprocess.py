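"""Normalization of total hybridization intensities into the final track ``t``.

Steps (each optional, applied in this order): log2 scale transform,
per-chip centering (subtract the chip mean or median, divide by the chip
SD), quantile normalization across samples, and removal of the
aberrant-probe perturbation (subtract the mean intensity over allelically
balanced autosomal SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PreprocessOptions:
    log2: bool = True
    center: str = "mean"  # "mean" | "median" | "none"
    quantile_norm: bool = False
    fallback_all_snps: bool = False
    include_x_in_centering: bool = True

    def __post_init__(self) -> None:
        if self.center not in ("mean", "median", "none"):
            raise ValueError(f"center must be mean|median|none, got {self.center!r}")


def log2_transform(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(values)
    out[~np.isfinite(out)] = np.nan
    return out


def center_chip(
    values: np.ndarray,
    mode: str = "mean",
    center_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Remove the chip effect: subtract mean/median and divide by the chip SD.

    Location and scale are estimated over ``center_mask`` (default: all
    non-missing markers); the transform is applied to every marker.
    """
    values = np.asarray(values, dtype=float)
    sel = np.isfinite(values)
    if center_mask is not None:
        sel &= np.asarray(center_mask, dtype=bool)
    if sel.sum() < 2:
        raise ValueError("too few markers to estimate the chip effect")
    basis = values[sel]
    loc = np.median(basis) if mode == "median" else basis.mean()
    scale = basis.std(ddof=1)
    if scale == 0:
        raise ValueError("degenerate chip: zero intensity standard deviation")
    return (values - loc) / scale


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Map each column's sorted values to the across-column mean of sorted values.

    ``matrix`` is markers x samples. Ties within a column receive the mean of
    their target slots. Rows with any missing value are left untouched (they
    are excluded from the target distribution).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a markers x samples matrix")
    complete = np.all(np.isfinite(matrix), axis=1)
    sub = matrix[complete]
    if sub.shape[0] == 0:
        return matrix.copy()
    order = np.argsort(sub, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(sub, order, axis=0)
    target = sorted_vals.mean(axis=1)

    out = matrix.copy()
    normed = np.empty_like(sub)
    for j in range(sub.shape[1]):
        col_sorted_target = target.copy()
        # average target slots over tied input values
        vals = sorted_vals[:, j]
        start = 0
        while start < len(vals):
            end = start + 1
            while end < len(vals) and vals[end] == vals[start]:
                end += 1
            if end - start > 1:
                col_sorted_target[start:end] = col_sorted_target[start:end].mean()
            start = end
        normed[order[:, j], j] = col_sorted_target
    out[complete] = normed
    return out


def quantile_map_to_reference(values: np.ndarray, reference_sorted: np.ndarray) -> np.ndarray:
    """Map a single sample's values onto a frozen sorted reference distribution."""
    values = np.asarray(values, dtype=float)
    reference_sorted = np.asarray(reference_sorted, dtype=float)
    out = np.full_like(values, np.nan)
    sel = np.isfinite(values)
    n = sel.sum()
    if n == 0:
        return out
    ranks = np.empty(n)
    order = np.argsort(values[sel], kind="mergesort")
    ranks[order] = np.arange(n)
    grid = np.linspace(0, len(reference_sorted) - 1, n)
    out[sel] = np.interp(np.interp(ranks, np.arange(n), grid),
                         np.arange(len(reference_sorted)), reference_sorted)
    return out


def preprocess_intensities(
    total_intensity: np.ndarray,
    options: PreprocessOptions = PreprocessOptions(),
    center_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Apply log2 / chip centering / quantile normalization in that fixed order.

    ``total_intensity`` is a markers x samples matrix (a single sample may be
    passed as a 1-D vector). Quantile normalization requires >= 2 samples.
    """
    values = np.asarray(total_intensity, dtype=float)
    single = values.ndim == 1
    if single:
        values = values[:, None]
    out = values.copy()
    if options.log2:
        out = log2_transform(out)
    if options.center != "none":
        out = np.column_stack(
            [center_chip(out[:, j], options.center, center_mask) for j in range(out.shape[1])]
        )
    if options.quantile_norm:
        if out.shape[1] < 2:
            raise ValueError("quantile normalization needs at least 2 samples")
        out = quantile_normalize(out)
    return out[:, 0] if single else out


def remove_aberrant_probe_perturbation(
    s: np.ndarray,
    balance_flags: np.ndarray,
    autosomal_snp_mask: np.ndarray | None = None,
    fallback_all_snps: bool = False,
) -> np.ndarray:
    """Subtract the mean intensity over allelically balanced autosomal SNPs.

    ``balance_flags`` is True where a marker was NOT flagged as allelically
    imbalanced by the single-point AI detector on raw AF. The subtraction is
    applied to every marker (SNP and CN alike); afterwards a value near zero
    means copy-neutral, positive means gain, negative means loss.
    """
    s = np.asarray(s, dtype=float)
    balance = np.asarray(balance_flags, dtype=bool) & np.isfinite(s)
    if autosomal_snp_mask is not None:
        balance &= np.asarray(autosomal_snp_mask, dtype=bool)
    if not balance.any():
        if not fallback_all_snps:
            raise ValueError(
                "no allelically balanced autosomal SNPs; enable fallback_all_snps "
                "to subtract the all-SNP mean instead"
            )
        balance = np.isfinite(s)
        if autosomal_snp_mask is not None:
            balance &= np.asarray(autosomal_snp_mask, dtype=bool)
        if not balance.any():
            raise ValueError("no usable autosomal SNPs at all")
    return s - s[balance].mean()
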