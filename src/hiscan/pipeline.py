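"""End-to-end per-sample analysis: preprocess -> AF -> detect -> segment -> export.

The six-panel numeric output per sample comprises the AF track, AI
flags/WAP, LOH/LCSH flags/WAP, the final intensity t with segments, the
CNV/CNA WAP and the CNV/CNA p-value track, plus joined region files per
aberration type.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from hiscan import data_io, detect_multi, detect_single, segmentation
from hiscan.af_estimation import cpa_adjust, lim_calibrate
from hiscan.data_io import GT_AA, GT_AB, GT_BB, SampleData
from hiscan.detect_multi import WindowConfig
from hiscan.detect_single import DetectionConfig
from hiscan.preprocess import (
    log2_transform,
    quantile_map_to_reference,
    remove_aberrant_probe_perturbation,
)
from hiscan.reference_panel import ABERRATIONS, ReferencePanel
from hiscan.segmentation import CbsParams

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    detection: DetectionConfig = DetectionConfig()
    window: WindowConfig = WindowConfig(v=5, n_c=2)  # (w, n_c) = (11, 2)
    cbs: CbsParams = CbsParams()
    segmentation_method: str = "original"  # "original" | "quick" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segmentation_method not in ("original", "quick", "none"):
            raise ValueError("segmentation_method must be original|quick|none")


@dataclass
class SampleAnalysis:
    sample_id: str
    raw_af: np.ndarray
    adjusted_af: np.ndarray
    final_af: np.ndarray
    t: np.ndarray
    balance_flags: np.ndarray
    single: dict = field(default_factory=dict)
    multipoint: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)
    segments: list = field(default_factory=list)


def sample_preprocess_constants(sample: SampleData, panel: ReferencePanel):
    """Chip-level location/scale for this sample under the panel's options."""
    opts = panel.preprocess_options
    ann = panel.annotation
    s = sample.total_intensity.astype(float)
    if opts.log2:
        s = log2_transform(s)
    center_mask = ann.is_autosomal.copy()
    if opts.include_x_in_centering:
        center_mask |= ann.chromosome == "X"
    loc, scale = 0.0, 1.0
    if opts.center != "none":
        basis = s[np.isfinite(s) & center_mask]
        if basis.size < 2:
            raise ValueError("too few markers to estimate the chip effect")
        loc = float(np.median(basis) if opts.center == "median" else basis.mean())
        scale = float(basis.std(ddof=1))
        if scale == 0:
            raise ValueError("degenerate chip: zero intensity standard deviation")
        s = (s - loc) / scale
    if opts.quantile_norm:
        if panel.quantile_template is None:
            raise ValueError("panel lacks a quantile template")
        s = quantile_map_to_reference(s, panel.quantile_template)
    return s, loc, scale


def balance_flags_raw_af(sample: SampleData, panel: ReferencePanel, alpha: float = 0.05):
    """Allelic-balance flags from the single-point AI detector on raw AF."""
    ann = panel.annotation
    res = detect_single.ai_flags(
        sample.raw_af,
        panel.raw_af_mean,
        panel.raw_af_sd,
        panel.counts,
        ann.chromosome,
        alpha=alpha,
        eval_mask=ann.is_snp,
    )
    return res.flags != 1  # not-evaluable markers count as balanced


def preprocess_sample(sample: SampleData, panel: ReferencePanel, alpha: float = 0.05):
    """Full intensity preprocessing of one test sample against a panel.

    Returns (t, info) where ``info`` carries the chip constants and the
    balanced-SNP mean so later stages (and the simulator) can map raw
    intensities onto the t scale.
    """
    ann = panel.annotation
    opts = panel.preprocess_options
    s, loc, scale = sample_preprocess_constants(sample, panel)
    balanced = balance_flags_raw_af(sample, panel, alpha=alpha)
    auto_snp = ann.is_autosomal & ann.is_snp
    t = remove_aberrant_probe_perturbation(
        s, balanced, autosomal_snp_mask=auto_snp, fallback_all_snps=opts.fallback_all_snps
    )
    basis = balanced & auto_snp & np.isfinite(s)
    balanced_mean = float(s[basis].mean()) if basis.any() else float(np.nanmean(s[auto_snp]))
    info = {"loc": loc, "scale": scale, "balanced_mean": balanced_mean, "balanced": balanced}
    return t, info


def estimate_af_tracks(sample: SampleData, panel: ReferencePanel):
    """CPA + LIM calibrated AF of a test sample using the panel's kappa/clusters."""
    raw = sample.raw_af.copy()
    raw[~panel.annotation.is_snp] = np.nan
    adjusted = cpa_adjust(raw, panel.kappa)
    final = lim_calibrate(
        adjusted,
        panel.cluster_mean[GT_AA],
        panel.cluster_mean[GT_AB],
        panel.cluster_mean[GT_BB],
    )
    return raw, adjusted, final


def analyze_sample(
    sample: SampleData,
    panel: ReferencePanel,
    cfg: RunConfig = RunConfig(),
    paired: SampleData | None = None,
    multipoint: bool = True,
) -> SampleAnalysis:
    """Run the detector stack for one sample (optionally against a paired normal)."""
    det = cfg.detection
    if det.paired and paired is None:
        raise ValueError("config requests paired analysis but no paired sample was given")

    raw, adjusted, final = estimate_af_tracks(sample, panel)
    t, info = preprocess_sample(sample, panel, alpha=det.alpha)

    paired_final = paired_t = paired_geno = None
    if det.paired:
        _, _, paired_final = estimate_af_tracks(paired, panel)
        paired_t, _ = preprocess_sample(paired, panel, alpha=det.alpha)
        paired_geno = paired.genotype

    ai = detect_single.detect_ai_single(
        final, panel, det, paired_f=paired_final, paired_genotype=paired_geno
    )
    loh = detect_single.detect_loh_single(final, panel, det, paired_f=paired_final)
    cnv = detect_single.detect_cnv_single(t, sample.genotype, panel, det, paired_t=paired_t)

    analysis = SampleAnalysis(
        sample_id=sample.sample_id,
        raw_af=raw,
        adjusted_af=adjusted,
        final_af=final,
        t=t,
        balance_flags=info["balanced"],
        single={"ai": ai, "loh": loh, "cnv": cnv},
    )

    if multipoint:
        binary = {
            "ai": np.where(np.isfinite(ai.flags), ai.flags, 0.0),
            "loh": np.where(np.isfinite(loh.flags), loh.flags, 0.0),
            "gain": np.where(np.isfinite(cnv.flags), cnv.flags == 1, 0.0).astype(float),
            "loss": np.where(np.isfinite(cnv.flags), cnv.flags == -1, 0.0).astype(float),
        }
        kinds = {"ai": "AI", "loh": "LOH", "gain": "GAIN", "loss": "LOSS"}
        for ab in ABERRATIONS:
            ref = panel.get_wap_reference(ab, cfg.window.v, cfg.window.n_c, cfg.window.q_percent)
            track = detect_multi.run_multipoint(binary[ab], ref, panel.annotation, cfg.window)
            analysis.multipoint[ab] = track
            analysis.regions[ab] = detect_multi.join_regions(
                track.combined,
                panel.annotation,
                kinds[ab],
                mode="multi",
                v=cfg.window.v,
                p_track=track.p,
                wap_values=track.wap,
            )

    if cfg.segmentation_method != "none":
        analysis.segments = segment_sample(analysis, panel, cfg)
    return analysis


def segment_sample(analysis: SampleAnalysis, panel: ReferencePanel, cfg: RunConfig):
    """Per-chromosome (quick) CBS on the finite part of the t track."""
    ann = panel.annotation
    params = cfg.cbs if cfg.cbs.rng_seed is not None else CbsParams(
        alpha_change=cfg.cbs.alpha_change,
        min_markers=cfg.cbs.min_markers,
        n_permutations=cfg.cbs.n_permutations,
        trim_fraction=cfg.cbs.trim_fraction,
        significant_segment_cutoff=cfg.cbs.significant_segment_cutoff,
        rng_seed=cfg.seed,
    )
    segments = []
    for chrom in ann.chromosomes():
        sl = ann.chromosome_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        finite = np.isfinite(analysis.t[sl])
        if finite.sum() < 2:
            continue
        idx = idx[finite]
        t = analysis.t[idx]
        positions = ann.position_bp[idx]
        if cfg.segmentation_method == "original":
            segs = segmentation.cbs_segment(t, params, positions=positions, chromosome=chrom)
        else:
            if not analysis.multipoint:
                raise ValueError("quick CBS needs multipoint AI/LOH results")
            local = {}
            for ab in ("ai", "loh"):
                ref = panel.get_wap_reference(
                    ab, cfg.window.v, cfg.window.n_c, cfg.window.q_percent
                )
                d = analysis.multipoint[ab].wap - ref.quantile
                local[ab] = d[idx]
            weights = segmentation.quick_cbs_weights(local["ai"], local["loh"])
            pos_of = {g: i for i, g in enumerate(idx)}
            regions = []
            for ab in ("ai", "loh"):
                for r in analysis.regions[ab]:
                    if r.chromosome != chrom:
                        continue
                    sub_idx = [pos_of[g] for g in range(r.start_idx, r.end_idx + 1) if g in pos_of]
                    if sub_idx:
                        regions.append(
                            detect_multi.AberrantRegion(
                                chromosome=chrom,
                                start_idx=min(sub_idx),
                                end_idx=max(sub_idx),
                                start_bp=r.start_bp,
                                end_bp=r.end_bp,
                                kind=r.kind,
                                n_markers=len(sub_idx),
                            )
                        )
            segs = segmentation.quick_cbs_segment(
                t,
                [r for r in regions if r.kind == "AI"],
                [r for r in regions if r.kind == "LOH"],
                weights,
                params,
                positions=positions,
                chromosome=chrom,
            )
        # re-map contiguous indices back to annotation indices
        for s in segs:
            s.start_idx = int(idx[s.start_idx])
            s.end_idx = int(idx[s.end_idx])
        segments.extend(segs)
    return segments


def export_sample_analysis(analysis: SampleAnalysis, panel: ReferencePanel, cfg: RunConfig,
                           out_dir: str):
    """Write the six-panel tracks, joined regions and run parameters."""
    ann = panel.annotation
    tracks = {
        "raw_af": analysis.raw_af,
        "adjusted_af": analysis.adjusted_af,
        "final_af": analysis.final_af,
        "ai_flag": analysis.single["ai"].flags,
        "loh_flag": analysis.single["loh"].flags,
        "t": analysis.t,
        "cnv_flag": analysis.single["cnv"].flags,
        "cnv_p": analysis.single["cnv"].p,
    }
    for ab, track in analysis.multipoint.items():
        tracks[f"{ab}_wap"] = track.wap
        tracks[f"{ab}_wap_smoothed"] = track.smoothed
        tracks[f"{ab}_mp_p"] = track.p
        tracks[f"{ab}_mp_flag"] = track.combined
    regions = [r for rs in analysis.regions.values() for r in rs]
    params = {
        "sample_id": analysis.sample_id,
        "alpha": cfg.detection.alpha,
        "genotype_specific": cfg.detection.genotype_specific,
        "paired": cfg.detection.paired,
        "window": cfg.window.window_size,
        "n_c": cfg.window.n_c,
        "q_percent": cfg.window.q_percent,
        "loess_span": cfg.window.loess_span,
        "combine_mode": cfg.window.combine_mode,
        "segmentation": cfg.segmentation_method,
        "seed": cfg.seed,
    }
    paths = data_io.export_results(
        ann, tracks, regions, out_dir, params=params, prefix=analysis.sample_id
    )
    if analysis.segments:
        seg_path = os.path.join(out_dir, f"{analysis.sample_id}.segments.tsv")
        with open(seg_path, "w") as fh:
            fh.write("chromosome\tstart\tend\tn_markers\tmean_t\tp_change\tsignificant\n")
            for s in analysis.segments:
                p = "NA" if not np.isfinite(s.p_change) else f"{s.p_change:.6g}"
                fh.write(
                    f"{s.chromosome}\t{s.start_bp}\t{s.end_bp}\t{s.n_markers}\t"
                    f"{s.mean_t:.6g}\t{p}\t{int(s.significant)}\n"
                )
        paths["segments"] = seg_path
    return paths


def run_pipeline(
    samples: list[SampleData],
    panel: ReferencePanel,
    cfg: RunConfig,
    out_dir: str,
    paired: dict[str, SampleData] | None = None,
) -> dict[str, dict[str, str]]:
    """Analyze and export each sample; returns the emitted paths per sample."""
    os.makedirs(out_dir, exist_ok=True)
    outputs = {}
    for sample in samples:
        mate = (paired or {}).get(sample.sample_id)
        try:
            analysis = analyze_sample(sample, panel, cfg, paired=mate)
        except Exception as exc:
            raise RuntimeError(f"analysis failed for sample {sample.sample_id!r}: {exc}") from exc
        outputs[sample.sample_id] = export_sample_analysis(analysis, panel, cfg, out_dir)
    return outputs
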