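"""Normal-reference statistics for all detectors.

A :class:`ReferencePanel` carries, per marker: genotype counts, the
preferential-hybridization coefficient kappa, genotype cluster means of the
CPA-adjusted AF, per-genotype mean/SD of the calibrated AF and of the final
intensity t, pooled intensity mean/SD, and (on demand) per-anchor WAP
mean/SD/quantile tracks derived from the normal samples by a leave-one-out
scan. Panels serialize to a single HDF5 container.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from hiscan import detect_multi, detect_single
from hiscan.af_estimation import cpa_adjust, lim_calibrate
from hiscan.data_io import GT_AA, GT_AB, GT_BB, MarkerAnnotation, SampleData
from hiscan.preprocess import (
    PreprocessOptions,
    preprocess_intensities,
    remove_aberrant_probe_perturbation,
)

log = logging.getLogger(__name__)

GENOTYPES = (GT_AA, GT_AB, GT_BB)
ABERRATIONS = ("ai", "loh", "gain", "loss")


@dataclass
class WapReference:
    """Per-anchor multipoint reference tracks for one (aberration, v, n_c, Q) cell."""

    aberration: str
    v: int
    n_c: int
    q_percent: float
    loess_span: float
    mean: np.ndarray  # mean of normal-sample WAPs per anchor
    sd: np.ndarray  # SD (ddof=1) of normal-sample WAPs
    quantile: np.ndarray  # Q%-quantile of LOESS-smoothed normal WAPs


@dataclass
class ReferencePanel:
    annotation: MarkerAnnotation
    preprocess_options: PreprocessOptions
    counts: np.ndarray  # (3, M) per-genotype sample counts
    af_counts: np.ndarray  # (3, M) samples contributing calibrated-AF stats
    t_counts: np.ndarray  # (3, M) samples contributing genotype intensity stats
    kappa: np.ndarray  # (M,)
    cluster_mean: np.ndarray  # (3, M) genotype means of CPA-adjusted AF
    raw_af_mean: np.ndarray  # (3, M)
    raw_af_sd: np.ndarray
    af_mean: np.ndarray  # (3, M) stats of the calibrated AF
    af_sd: np.ndarray
    t_mean: np.ndarray  # (3, M) genotype-specific intensity stats
    t_sd: np.ndarray
    t_pooled_mean: np.ndarray  # (M,)
    t_pooled_sd: np.ndarray
    t_pooled_n: np.ndarray
    # retained per-sample matrices (n, M); needed for leave-one-out WAP tracks
    f_matrix: np.ndarray
    raw_af_matrix: np.ndarray
    t_matrix: np.ndarray
    genotype_matrix: np.ndarray
    quantile_template: np.ndarray | None = None
    wap_reference: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.f_matrix.shape[0]

    @property
    def degenerate_af(self) -> np.ndarray:
        """SNP markers unusable for AF-based detection (n(g)<2 or SD=0 in any class)."""
        bad = np.zeros(len(self.annotation), dtype=bool)
        for g in range(3):
            bad |= (self.af_counts[g] < 2) | ~(self.af_sd[g] > 0)
        return bad

    def get_wap_reference(self, aberration: str, v: int, n_c: int, q_percent: float) -> WapReference:
        key = (aberration, int(v), int(n_c), float(q_percent))
        if key not in self.wap_reference:
            raise KeyError(
                f"no WAP reference for {key}; call build_wap_reference first"
            )
        return self.wap_reference[key]


def _genotype_stats(values: np.ndarray, genotypes: np.ndarray):
    """Per-genotype count/mean/SD (ddof=1) of an (n, M) value matrix."""
    n, m = values.shape
    counts = np.zeros((3, m))
    means = np.full((3, m), np.nan)
    sds = np.full((3, m), np.nan)
    finite = np.isfinite(values)
    for g in GENOTYPES:
        mask = (genotypes == g) & finite
        cnt = mask.sum(axis=0)
        total = np.where(mask, values, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt >= 1, total / cnt, np.nan)
            sq = np.where(mask, (values - np.where(np.isfinite(mean), mean, 0.0)) ** 2, 0.0).sum(
                axis=0
            )
            sd = np.where(cnt >= 2, np.sqrt(sq / np.maximum(cnt - 1, 1)), np.nan)
        counts[g] = cnt
        means[g] = mean
        sds[g] = sd
    return counts, means, sds


def _pooled_stats(values: np.ndarray):
    finite = np.isfinite(values)
    cnt = finite.sum(axis=0)
    total = np.where(finite, values, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt >= 1, total / cnt, np.nan)
        sq = np.where(finite, (values - np.where(np.isfinite(mean), mean, 0.0)) ** 2, 0.0).sum(
            axis=0
        )
        sd = np.where(cnt >= 2, np.sqrt(sq / np.maximum(cnt - 1, 1)), np.nan)
    return cnt, mean, sd


def estimate_kappa_track(raw_af: np.ndarray, genotypes: np.ndarray) -> np.ndarray:
    """Per-marker kappa from heterozygous raw AFs; 1 where < 2 informative hets."""
    het = (genotypes == GT_AB) & np.isfinite(raw_af) & (raw_af > 0) & (raw_af < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(het, raw_af / (1.0 - raw_af), 0.0)
    n_het = het.sum(axis=0)
    kappa = np.where(n_het >= 2, ratios.sum(axis=0) / np.maximum(n_het, 1), 1.0)
    n_uninformative = int((n_het < 2).sum())
    if n_uninformative:
        log.warning("kappa fell back to 1 at %d markers with < 2 heterozygotes", n_uninformative)
    return kappa


def build_reference_panel(
    normal_samples: list[SampleData],
    annotation: MarkerAnnotation,
    options: PreprocessOptions = PreprocessOptions(),
) -> ReferencePanel:
    """Build the single-point reference statistics from >= 2 normal samples.

    NoCall genotypes are excluded from every per-genotype statistic; SDs use
    the n-1 denominator. Balance flags feeding the aberrant-probe
    perturbation removal are derived from the single-point AI detector on
    raw AF against the panel's own raw-AF statistics.
    """
    if len(normal_samples) < 2:
        raise ValueError("a reference panel needs at least 2 normal samples")
    m = len(annotation)
    for s in normal_samples:
        if len(s) != m:
            raise ValueError(f"sample {s.sample_id!r} length {len(s)} != annotation {m}")

    raw = np.vstack([s.raw_af for s in normal_samples])
    geno = np.vstack([s.genotype for s in normal_samples])
    snp = annotation.is_snp
    raw[:, ~snp] = np.nan  # CN probes carry no genotype / AF

    kappa = estimate_kappa_track(raw, geno)
    with np.errstate(invalid="ignore"):
        h_hat = cpa_adjust(raw, kappa[None, :])
    _, cluster_mean, _ = _genotype_stats(h_hat, geno)
    f_hat = lim_calibrate(h_hat, cluster_mean[GT_AA], cluster_mean[GT_AB], cluster_mean[GT_BB])

    af_counts, af_mean, af_sd = _genotype_stats(f_hat, geno)
    counts, raw_af_mean, raw_af_sd = _genotype_stats(raw, geno)

    # intensity track
    totals = np.vstack([s.total_intensity for s in normal_samples]).T  # (M, n)
    center_mask = annotation.is_autosomal.copy()
    if options.include_x_in_centering:
        center_mask |= annotation.chromosome == "X"
    s_matrix = preprocess_intensities(totals, options, center_mask=center_mask)
    quantile_template = None
    if options.quantile_norm:
        complete = np.all(np.isfinite(s_matrix), axis=1)
        quantile_template = np.sort(s_matrix[complete], axis=0).mean(axis=1)

    auto_snp = annotation.is_autosomal & snp
    alpha = 0.05
    t_matrix = np.empty_like(s_matrix.T)
    for i in range(len(normal_samples)):
        ai = detect_single.ai_flags(
            raw[i],
            raw_af_mean,
            raw_af_sd,
            counts,
            annotation.chromosome,
            alpha=alpha,
            eval_mask=snp,
        )
        balanced = ai.flags != 1  # NaN (not evaluable) counts as balanced
        t_matrix[i] = remove_aberrant_probe_perturbation(
            s_matrix[:, i], balanced, autosomal_snp_mask=auto_snp, fallback_all_snps=True
        )

    t_counts, t_mean, t_sd = _genotype_stats(t_matrix, geno)
    t_pooled_n, t_pooled_mean, t_pooled_sd = _pooled_stats(t_matrix)

    n_degenerate = int(((t_pooled_sd == 0) | (t_pooled_n < 2)).sum())
    if n_degenerate:
        log.warning("%d markers have degenerate pooled intensity statistics", n_degenerate)

    return ReferencePanel(
        annotation=annotation,
        preprocess_options=options,
        counts=counts,
        af_counts=af_counts,
        t_counts=t_counts,
        kappa=kappa,
        cluster_mean=cluster_mean,
        raw_af_mean=raw_af_mean,
        raw_af_sd=raw_af_sd,
        af_mean=af_mean,
        af_sd=af_sd,
        t_mean=t_mean,
        t_sd=t_sd,
        t_pooled_mean=t_pooled_mean,
        t_pooled_sd=t_pooled_sd,
        t_pooled_n=t_pooled_n,
        f_matrix=f_hat,
        raw_af_matrix=raw,
        t_matrix=t_matrix,
        genotype_matrix=geno,
        quantile_template=quantile_template,
    )


# ---------------------------------------------------------------------------
# leave-one-out single-point flags for the WAP reference


def _loo_genotype_stats(values, genotypes, counts, means, sds, i):
    """Downdate per-genotype stats to exclude sample ``i`` (streaming LOO)."""
    v = values[i]
    g = genotypes[i]
    finite = np.isfinite(v)
    cnt = counts.copy()
    mean = means.copy()
    sd = sds.copy()
    for gt in GENOTYPES:
        hit = (g == gt) & finite
        if not hit.any():
            continue
        n = counts[gt][hit]
        mu = means[gt][hit]
        s2 = np.where(np.isfinite(sds[gt][hit]), sds[gt][hit] ** 2, 0.0)
        n_new = n - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            mu_new = np.where(n_new >= 1, (n * mu - v[hit]) / np.maximum(n_new, 1), np.nan)
            ss = s2 * (n - 1)  # sum of squared deviations about mu
            ss_new = ss - (v[hit] - mu) * (v[hit] - mu_new)
            ss_new = np.maximum(ss_new, 0.0)
            sd_new = np.where(n_new >= 2, np.sqrt(ss_new / np.maximum(n_new - 1, 1)), np.nan)
        cnt[gt][hit] = n_new
        mean[gt][hit] = mu_new
        sd[gt][hit] = sd_new
    return cnt, mean, sd


def _loo_pooled_stats(values, pooled_n, pooled_mean, pooled_sd, i):
    v = values[i]
    finite = np.isfinite(v)
    n = pooled_n.astype(float).copy()
    mean = pooled_mean.copy()
    sd = pooled_sd.copy()
    hit = finite
    nn = n[hit]
    mu = mean[hit]
    s2 = np.where(np.isfinite(sd[hit]), sd[hit] ** 2, 0.0)
    n_new = nn - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_new = np.where(n_new >= 1, (nn * mu - v[hit]) / np.maximum(n_new, 1), np.nan)
        ss_new = np.maximum(s2 * (nn - 1) - (v[hit] - mu) * (v[hit] - mu_new), 0.0)
        sd_new = np.where(n_new >= 2, np.sqrt(ss_new / np.maximum(n_new - 1, 1)), np.nan)
    n[hit] = n_new
    mean[hit] = mu_new
    sd[hit] = sd_new
    return n, mean, sd


def _loo_single_point_flags(panel: ReferencePanel, i: int, aberration: str, alpha: float = 0.05,
                            genotype_specific: bool = False) -> np.ndarray:
    """Binary single-point flags for normal sample ``i`` against LOO panel stats."""
    ann = panel.annotation
    snp = ann.is_snp
    if aberration in ("ai", "loh"):
        counts, means, sds = _loo_genotype_stats(
            panel.f_matrix, panel.genotype_matrix, panel.af_counts, panel.af_mean, panel.af_sd, i
        )
        if aberration == "ai":
            res = detect_single.ai_flags(
                panel.f_matrix[i], means, sds, counts, ann.chromosome, alpha=alpha, eval_mask=snp
            )
        else:
            res = detect_single.loh_flags(
                panel.f_matrix[i], means, sds, counts, ann.chromosome, alpha=alpha, eval_mask=snp
            )
        flags = np.where(np.isfinite(res.flags), res.flags, 0.0)
        return flags
    if aberration in ("gain", "loss"):
        pn, pm, ps = _loo_pooled_stats(
            panel.t_matrix, panel.t_pooled_n, panel.t_pooled_mean, panel.t_pooled_sd, i
        )
        gcnt, gmean, gsd = _loo_genotype_stats(
            panel.t_matrix, panel.genotype_matrix, panel.t_counts, panel.t_mean, panel.t_sd, i
        )
        res = detect_single.cnv_flags(
            panel.t_matrix[i],
            panel.genotype_matrix[i],
            gmean,
            gsd,
            gcnt,
            pm,
            ps,
            pn,
            ann.chromosome,
            ann.probe_class,
            alpha=alpha,
            genotype_specific=genotype_specific,
        )
        want = 1.0 if aberration == "gain" else -1.0
        return np.where(np.isfinite(res.flags), res.flags == want, 0.0).astype(float)
    raise ValueError(f"unknown aberration {aberration!r}")


def build_wap_reference(
    panel: ReferencePanel,
    aberration: str,
    v: int,
    n_c: int,
    q_percent: float = 95.0,
    loess_span: float = 0.02,
    alpha: float = 0.05,
    genotype_specific: bool = False,
) -> WapReference:
    """Build the multipoint WAP mean/SD/quantile tracks from the normal samples.

    Each normal sample's single-point flags are computed leave-one-out
    against the remaining panel, turned into a (smoothed) WAP track, and
    aggregated per anchor: the mean/SD of the raw WAPs feed the
    hypothesis-test procedure, the Q%-quantile (type-7) of the smoothed WAPs
    feeds the confidence-interval procedure.
    """
    if aberration not in ABERRATIONS:
        raise ValueError(f"aberration must be one of {ABERRATIONS}")
    ann = panel.annotation
    n = panel.n_samples
    m = len(ann)
    waps = np.empty((n, m))
    smoothed = np.empty((n, m))
    for i in range(n):
        flags = _loo_single_point_flags(
            panel, i, aberration, alpha=alpha, genotype_specific=genotype_specific
        )
        waps[i] = detect_multi.wap_track(flags, ann.chromosome, v=v, n_c=n_c)
        smoothed[i] = detect_multi.smooth_track_by_chromosome(
            waps[i], ann.chromosome, span=loess_span
        )
    mean = waps.mean(axis=0)
    sd = waps.std(axis=0, ddof=1)
    needed = 100.0 / max(100.0 - q_percent, 1e-12)
    if n < needed:
        warnings.warn(
            f"only {n} normal samples for the {q_percent}% quantile (need >= {needed:.0f}); "
            "using the maximum",
            stacklevel=2,
        )
        quant = smoothed.max(axis=0)
    else:
        quant = np.quantile(smoothed, q_percent / 100.0, axis=0)
    ref = WapReference(
        aberration=aberration,
        v=int(v),
        n_c=int(n_c),
        q_percent=float(q_percent),
        loess_span=float(loess_span),
        mean=mean,
        sd=sd,
        quantile=quant,
    )
    panel.wap_reference[(aberration, int(v), int(n_c), float(q_percent))] = ref
    return ref


# ---------------------------------------------------------------------------
# persistence


def save_panel(panel: ReferencePanel, path: str) -> None:
    import h5py

    ann = panel.annotation
    with h5py.File(path, "w") as fh:
        str_dt = h5py.string_dtype()
        grp = fh.create_group("annotation")
        for name in ("marker_id", "chromosome", "allele_a", "allele_b", "probe_class"):
            grp.create_dataset(
                name, data=[str(x) for x in getattr(ann, name)], dtype=str_dt
            )
        grp.create_dataset("position_bp", data=ann.position_bp)

        opts = fh.create_group("preprocess")
        o = panel.preprocess_options
        opts.attrs.update(
            {
                "log2": o.log2,
                "center": o.center,
                "quantile_norm": o.quantile_norm,
                "fallback_all_snps": o.fallback_all_snps,
                "include_x_in_centering": o.include_x_in_centering,
            }
        )

        stats = fh.create_group("stats")
        for name in (
            "counts",
            "af_counts",
            "t_counts",
            "kappa",
            "cluster_mean",
            "raw_af_mean",
            "raw_af_sd",
            "af_mean",
            "af_sd",
            "t_mean",
            "t_sd",
            "t_pooled_mean",
            "t_pooled_sd",
            "t_pooled_n",
            "f_matrix",
            "raw_af_matrix",
            "t_matrix",
            "genotype_matrix",
        ):
            stats.create_dataset(name, data=getattr(panel, name))
        if panel.quantile_template is not None:
            stats.create_dataset("quantile_template", data=panel.quantile_template)

        wgrp = fh.create_group("wap_reference")
        for (ab, v, n_c, q), ref in panel.wap_reference.items():
            sub = wgrp.create_group(f"{ab}/{v}/{n_c}/{q}")
            sub.attrs["loess_span"] = ref.loess_span
            sub.create_dataset("mean", data=ref.mean)
            sub.create_dataset("sd", data=ref.sd)
            sub.create_dataset("quantile", data=ref.quantile)


def load_panel(path: str) -> ReferencePanel:
    import h5py

    with h5py.File(path, "r") as fh:
        grp = fh["annotation"]
        ann = MarkerAnnotation(
            marker_id=grp["marker_id"].asstr()[:],
            chromosome=grp["chromosome"].asstr()[:],
            position_bp=grp["position_bp"][:],
            allele_a=grp["allele_a"].asstr()[:],
            allele_b=grp["allele_b"].asstr()[:],
            probe_class=grp["probe_class"].asstr()[:],
        )
        oa = fh["preprocess"].attrs
        options = PreprocessOptions(
            log2=bool(oa["log2"]),
            center=str(oa["center"]),
            quantile_norm=bool(oa["quantile_norm"]),
            fallback_all_snps=bool(oa["fallback_all_snps"]),
            include_x_in_centering=bool(oa["include_x_in_centering"]),
        )
        stats = fh["stats"]
        kwargs = {name: stats[name][:] for name in stats if name != "quantile_template"}
        template = stats["quantile_template"][:] if "quantile_template" in stats else None
        panel = ReferencePanel(
            annotation=ann,
            preprocess_options=options,
            quantile_template=template,
            **kwargs,
        )
        panel.genotype_matrix = panel.genotype_matrix.astype(np.int8)
        if "wap_reference" in fh:
            def visit(name, obj):
                import h5py as _h5

                if isinstance(obj, _h5.Group) and "mean" in obj:
                    ab, v, n_c, q = name.split("/")
                    panel.wap_reference[(ab, int(v), int(n_c), float(q))] = WapReference(
                        aberration=ab,
                        v=int(v),
                        n_c=int(n_c),
                        q_percent=float(q),
                        loess_span=float(obj.attrs["loess_span"]),
                        mean=obj["mean"][:],
                        sd=obj["sd"][:],
                        quantile=obj["quantile"][:],
                    )

            fh["wap_reference"].visititems(visit)
    return panel
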