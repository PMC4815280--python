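"""Synthetic reference populations and the CNV/CNA detection power study.

The generator draws genotypes under Hardy-Weinberg equilibrium at per-marker
allele frequencies and produces allele intensities whose raw AF clusters
near 1 / 0.5 / 0 (with configurable preferential-hybridization bias kappa)
and whose total intensity carries the copy-number signal. The study injects
loss / gain / neutral aberrations truncated at an effect size ``r`` (in
units of the reference panel's per-marker SD) into the centre of a
2001-marker template and measures SNP- and region-level false/true positive
rates of the single-point and multipoint detectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from hiscan import detect_multi, detect_single, pipeline
from hiscan.data_io import GT_AA, GT_AB, GT_BB, GT_NOCALL, MarkerAnnotation, SampleData
from hiscan.detect_multi import WindowConfig
from hiscan.detect_single import DetectionConfig
from hiscan.preprocess import PreprocessOptions
from hiscan.reference_panel import ReferencePanel, build_reference_panel, build_wap_reference

log = logging.getLogger(__name__)

SCENARIOS = ("loss", "gain", "neutral")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic population generator.

    ``separation_sd`` is the log2 total-intensity offset of a one-copy loss
    (and, symmetrically, of a gain) expressed in units of the per-marker
    total-intensity noise SD; it is the single knob controlling detection
    difficulty.
    """

    n_markers: int = 2001
    chromosome: str = "2"
    marker_spacing_bp: int = 1000
    allele_freq_range: tuple[float, float] = (0.2, 0.8)
    kappa_log2_range: tuple[float, float] = (-0.5, 0.5)
    background: float = 0.05
    ratio_log2_sd: float = 0.30
    total_log2_sd: float = 0.25
    marker_baseline_log2_sd: float = 0.30  # fixed per-marker probe affinity spread
    separation_sd: float = 5.0
    per_copy_scale: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("allele_freq_range must satisfy 0 < lo < hi < 1")
        if self.total_log2_sd <= 0 or self.ratio_log2_sd < 0:
            raise ValueError("noise SDs must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    scenario: str = "neutral"
    n_target: int = 51  # markers in the centred target region
    r: float = 0.0  # effect size (truncation, in reference-SD units)
    q_percent: float = 0.0  # proportion of noise-interference draws
    window: WindowConfig = WindowConfig(v=5, n_c=2)
    alpha: float = 0.05
    n_reps: int = 100
    seed: int = 0
    max_rejection_draws: int = 100_000

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0 <= self.q_percent <= 100:
            raise ValueError("q_percent must lie in [0, 100]")
        if self.scenario == "neutral" and self.r != 0:
            raise ValueError("the neutral scenario has effect size r = 0")


@dataclass
class SimulationResult:
    config: SimulationConfig
    snp_rate: np.ndarray  # per target SNP: flag rate over replicates
    region_rate: float  # mean over target SNPs
    n_reps: int
    detector: str  # "single" | "multi"
    target_slice: slice


def make_annotation(params: GeneratorParams) -> MarkerAnnotation:
    n = params.n_markers
    return MarkerAnnotation(
        marker_id=np.array([f"sim{m:06d}" for m in range(n)], dtype=object),
        chromosome=np.repeat(params.chromosome, n),
        position_bp=(np.arange(n) + 1) * params.marker_spacing_bp,
        allele_a=np.repeat("A", n),
        allele_b=np.repeat("B", n),
        probe_class=np.repeat("SNP", n),
    )


@dataclass
class PopulationModel:
    """Frozen per-marker latent parameters shared by panel and test samples."""

    params: GeneratorParams
    annotation: MarkerAnnotation
    allele_freq: np.ndarray
    kappa: np.ndarray
    baseline_log2: np.ndarray


def _draw_intensities(model: PopulationModel, n_a, n_b, log2_offset, rng):
    """Allele intensities given allele copy counts and a log2 total offset."""
    p = model.params
    n = len(model.allele_freq)
    total = (
        2.0
        * p.per_copy_scale
        * np.exp2(model.baseline_log2 + log2_offset + rng.normal(0.0, p.total_log2_sd, size=n))
    )
    with np.errstate(divide="ignore"):
        ratio = (
            model.kappa
            * (n_a + p.background)
            / (n_b + p.background)
            * np.exp2(rng.normal(0.0, p.ratio_log2_sd, size=n))
        )
    h_a = total * ratio / (1.0 + ratio)
    h_b = total / (1.0 + ratio)
    return h_a, h_b


def _genotype_from_counts(n_a: np.ndarray, n_b: np.ndarray) -> np.ndarray:
    """Called genotype from true allele copies (hemizygous calls look homozygous)."""
    geno = np.full(len(n_a), GT_NOCALL, dtype=np.int8)
    geno[(n_a > 0) & (n_b > 0)] = GT_AB
    geno[(n_a > 0) & (n_b == 0)] = GT_AA
    geno[(n_a == 0) & (n_b > 0)] = GT_BB
    return geno


def _draw_normal_sample(model: PopulationModel, rng, sample_id: str) -> SampleData:
    n_a = rng.binomial(2, model.allele_freq)
    n_b = 2 - n_a
    h_a, h_b = _draw_intensities(model, n_a, n_b, 0.0, rng)
    return SampleData(sample_id=sample_id, h_a=h_a, h_b=h_b,
                      genotype=_genotype_from_counts(n_a, n_b))


def generate_reference_population(
    params: GeneratorParams,
    n_samples: int,
    seed: int,
) -> tuple[MarkerAnnotation, list[SampleData], PopulationModel]:
    """Seeded synthetic normal population with HWE genotypes and kappa bias."""
    rng = np.random.default_rng(seed)
    annotation = make_annotation(params)
    model = PopulationModel(
        params=params,
        annotation=annotation,
        allele_freq=rng.uniform(*params.allele_freq_range, params.n_markers),
        kappa=np.exp2(rng.uniform(*params.kappa_log2_range, params.n_markers)),
        baseline_log2=rng.normal(0.0, params.marker_baseline_log2_sd, params.n_markers),
    )
    samples = [_draw_normal_sample(model, rng, f"normal{i:04d}") for i in range(n_samples)]
    return annotation, samples, model


def target_slice(n_markers: int, n_target: int) -> slice:
    """Centred target region within the template."""
    if n_target > n_markers:
        raise ValueError("target larger than the template")
    start = (n_markers - n_target) // 2
    return slice(start, start + n_target)


def _donor_draw(model, scenario, rng):
    """One round of donor draws for every still-unfilled target marker."""
    p = model.params
    n = len(model.allele_freq)
    if scenario == "loss":
        a = rng.random(n) < model.allele_freq
        n_a = a.astype(int)
        n_b = 1 - n_a
        offset = -p.separation_sd * p.total_log2_sd
    elif scenario == "gain":
        n_a = rng.binomial(2, model.allele_freq)
        n_b = 2 - n_a
        offset = p.separation_sd * p.total_log2_sd
    else:
        n_a = rng.binomial(2, model.allele_freq)
        n_b = 2 - n_a
        offset = 0.0
    h_a, h_b = _draw_intensities(model, n_a, n_b, offset, rng)
    return h_a, h_b, _genotype_from_counts(n_a, n_b)


def _truncation_stats(panel: ReferencePanel, genotype: np.ndarray):
    """Reference mean/SD of t for each marker's recipient genotype class."""
    mu = panel.t_pooled_mean.copy()
    sd = panel.t_pooled_sd.copy()
    for g in (GT_AA, GT_AB, GT_BB):
        sel = (genotype == g) & (panel.t_counts[g] >= 2) & np.isfinite(panel.t_sd[g])
        mu[sel] = panel.t_mean[g][sel]
        sd[sel] = panel.t_sd[g][sel]
    return mu, sd


def inject_aberration(
    template: SampleData,
    panel: ReferencePanel,
    model: PopulationModel,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> SampleData:
    """Replace the centred target markers of ``template`` by truncated donor draws.

    Loss draws must satisfy t <= mu - r sd, gain draws t >= mu + r sd,
    neutral draws |t - mu| <= 3 sd, where (mu, sd) are the reference
    statistics of the recipient's genotype class and t is evaluated with the
    template chip's pre-injection preprocessing constants. With probability
    ``q_percent`` a marker instead receives an unconstrained neutral draw
    within mu +- 2 sd (noise interference).
    """
    opts = panel.preprocess_options
    if opts.quantile_norm:
        raise ValueError("aberration injection does not support quantile normalization")
    t_template, info = pipeline.preprocess_sample(template, panel, alpha=cfg.alpha)
    shift = info["balanced_mean"]
    loc, scale = info["loc"], info["scale"]

    def t_of(h_a, h_b):
        x = h_a + h_b
        if opts.log2:
            with np.errstate(divide="ignore"):
                x = np.log2(x)
        if opts.center != "none":
            x = (x - loc) / scale
        return x - shift

    sl = target_slice(len(panel.annotation), cfg.n_target)
    mu, sd = _truncation_stats(panel, template.genotype)
    mu, sd = mu[sl], sd[sl]

    is_noise = rng.random(cfg.n_target) < cfg.q_percent / 100.0
    new_ha = np.empty(cfg.n_target)
    new_hb = np.empty(cfg.n_target)
    new_geno = np.empty(cfg.n_target, dtype=np.int8)
    pending = np.ones(cfg.n_target, dtype=bool)
    draws = 0
    while pending.any():
        if draws >= cfg.max_rejection_draws:
            bad = int(np.flatnonzero(pending)[0])
            raise RuntimeError(
                f"truncation region empty after {cfg.max_rejection_draws} draws at "
                f"target marker {bad} (r = {cfg.r})"
            )
        h_a, h_b, geno = _donor_draw(model, cfg.scenario, rng)
        h_a, h_b, geno = h_a[sl], h_b[sl], geno[sl]
        nh_a, nh_b, ngeno = _donor_draw(model, "neutral", rng)
        nh_a, nh_b, ngeno = nh_a[sl], nh_b[sl], ngeno[sl]
        t_signal = t_of(h_a, h_b)
        t_noise = t_of(nh_a, nh_b)
        if cfg.scenario == "loss":
            ok_signal = t_signal <= mu - cfg.r * sd
        elif cfg.scenario == "gain":
            ok_signal = t_signal >= mu + cfg.r * sd
        else:
            ok_signal = np.abs(t_signal - mu) <= 3.0 * sd
        ok_noise = np.abs(t_noise - mu) <= 2.0 * sd
        take_signal = pending & ~is_noise & ok_signal
        take_noise = pending & is_noise & ok_noise
        for take, (ha, hb, g) in (
            (take_signal, (h_a, h_b, geno)),
            (take_noise, (nh_a, nh_b, ngeno)),
        ):
            new_ha[take] = ha[take]
            new_hb[take] = hb[take]
            new_geno[take] = g[take]
            pending &= ~take
        draws += 1

    h_a = template.h_a.copy()
    h_b = template.h_b.copy()
    geno = template.genotype.copy()
    h_a[sl], h_b[sl], geno[sl] = new_ha, new_hb, new_geno
    return SampleData(
        sample_id=f"{template.sample_id}:{cfg.scenario}", h_a=h_a, h_b=h_b, genotype=geno
    )


def build_simulation_panel(
    params: GeneratorParams,
    n_panel: int,
    seed: int,
    options: PreprocessOptions = PreprocessOptions(log2=True, center="mean", quantile_norm=False),
    wap_configs: list[WindowConfig] | None = None,
    wap_aberrations: tuple[str, ...] = ("gain", "loss"),
) -> tuple[ReferencePanel, PopulationModel]:
    """Generate a synthetic normal population and build its reference panel."""
    _, normals, model = generate_reference_population(params, n_panel, seed)
    panel = build_reference_panel(normals, model.annotation, options)
    for cfg in wap_configs or []:
        for ab in wap_aberrations:
            build_wap_reference(
                panel, ab, cfg.v, cfg.n_c, q_percent=cfg.q_percent, loess_span=cfg.loess_span
            )
    return panel, model


def run_simulation_study(
    cfg: SimulationConfig,
    panel: ReferencePanel,
    model: PopulationModel,
    detector: str = "single",
    genotype_specific: bool = False,
) -> SimulationResult:
    """Monte-Carlo FPR/TPR of the CNV/CNA detectors on injected aberrations.

    SNP-level rate: per target SNP, the proportion of replicates in which it
    is flagged (with the correct direction for loss/gain; in either
    direction for neutral). Region-level rate: mean over target SNPs.
    """
    if detector not in ("single", "multi"):
        raise ValueError("detector must be 'single' or 'multi'")
    if cfg.n_reps < 10:
        warnings.warn("fewer than 10 replicates: rate estimates are unstable", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    sl = target_slice(len(panel.annotation), cfg.n_target)
    det_cfg = DetectionConfig(alpha=cfg.alpha, genotype_specific=genotype_specific)
    ann = panel.annotation

    refs = None
    if detector == "multi":
        w = cfg.window
        refs = {
            ab: panel.get_wap_reference(ab, w.v, w.n_c, w.q_percent) for ab in ("gain", "loss")
        }

    hits = np.zeros((cfg.n_reps, cfg.n_target))
    for rep in range(cfg.n_reps):
        template = _draw_normal_sample(model, rng, f"rep{rep:05d}")
        test = inject_aberration(template, panel, model, cfg, rng)
        t, _ = pipeline.preprocess_sample(test, panel, alpha=cfg.alpha)
        res = detect_single.detect_cnv_single(t, test.genotype, panel, det_cfg)
        flags = np.where(np.isfinite(res.flags), res.flags, 0.0)
        if detector == "single":
            if cfg.scenario == "loss":
                hit = flags[sl] == -1
            elif cfg.scenario == "gain":
                hit = flags[sl] == 1
            else:
                hit = flags[sl] != 0
        else:
            tracks = {}
            for ab, want in (("gain", 1.0), ("loss", -1.0)):
                binary = (flags == want).astype(float)
                mp = detect_multi.run_multipoint(binary, refs[ab], ann, cfg.window)
                tracks[ab] = mp.combined
            if cfg.scenario == "loss":
                hit = tracks["loss"][sl] > 0
            elif cfg.scenario == "gain":
                hit = tracks["gain"][sl] > 0
            else:
                hit = (tracks["gain"][sl] > 0) | (tracks["loss"][sl] > 0)
        hits[rep] = hit

    snp_rate = hits.mean(axis=0)
    return SimulationResult(
        config=cfg,
        snp_rate=snp_rate,
        region_rate=float(snp_rate.mean()),
        n_reps=cfg.n_reps,
        detector=detector,
        target_slice=sl,
    )


def mix_samples(aberrant: SampleData, normal: SampleData, p_percent: float) -> SampleData:
    """Admixture titration: linear mixing of intensities on the linear scale."""
    if not 0 <= p_percent <= 100:
        raise ValueError("p_percent must lie in [0, 100]")
    w = p_percent / 100.0
    return SampleData(
        sample_id=f"mix{p_percent:g}",
        h_a=w * aberrant.h_a + (1 - w) * normal.h_a,
        h_b=w * aberrant.h_b + (1 - w) * normal.h_b,
        genotype=normal.genotype.copy(),
    )


# ---------------------------------------------------------------------------
# evaluation metrics


def _intervals(regions) -> list[tuple[str, float, float]]:
    out = []
    for r in regions:
        out.append((str(r.chromosome), float(r.start_bp), float(r.end_bp) + 1.0))
    return out


def _overlap(a_lo, a_hi, b_lo, b_hi) -> float:
    return max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))


def overlap_metrics(regions_test, regions_benchmark, mode: str = "S") -> float | None:
    """Region-overlap metrics (percent).

    ``mode="S"``: total benchmark length overlapped by test regions divided
    by total benchmark length. ``mode="C"``: proportion of test-region
    length contributed by test regions whose overlap with the benchmark is
    >= 50% of their own length. Undefined (None) when the benchmark is empty.
    """
    if mode not in ("S", "C"):
        raise ValueError("mode must be 'S' or 'C'")
    bench = _intervals(regions_benchmark)
    test = _intervals(regions_test)
    if mode == "S":
        total = sum(hi - lo for _, lo, hi in bench)
        if total == 0:
            return None
        covered = 0.0
        for chrom, lo, hi in bench:
            cuts = sorted({lo, hi} | {x for c, a, b in test if c == chrom for x in (a, b)
                           if lo < x < hi})
            for a, b in zip(cuts[:-1], cuts[1:]):
                if any(c == chrom and _overlap(a, b, tl, th) > 0 for c, tl, th in test):
                    covered += b - a
        return 100.0 * covered / total
    if not bench:
        return None
    total_test = sum(hi - lo for _, lo, hi in test)
    if total_test == 0:
        return 0.0
    good = 0.0
    for chrom, lo, hi in test:
        length = hi - lo
        ov = sum(_overlap(lo, hi, bl, bh) for c, bl, bh in bench if c == chrom)
        if ov / length >= 0.5:
            good += length
    return 100.0 * good / total_test


def qpcr_copy_number(
    t_target: np.ndarray,
    t_control: np.ndarray,
    r_target: float,
    r_control: float,
    diploid_scale: bool = False,
) -> tuple[float, float | None]:
    """Relative copy number from qPCR cycle thresholds (delta-delta-Ct).

    Per replicate, CN = 2**(-[(T_target - T_control) - (R_target - R_control)]);
    the mean and sample SD over replicates are returned on the haploid scale
    (``diploid_scale`` doubles both).
    """
    t_target = np.asarray(t_target, dtype=float)
    t_control = np.asarray(t_control, dtype=float)
    if t_target.shape != t_control.shape:
        raise ValueError("replicate vectors must align")
    if not (np.all(np.isfinite(t_target)) and np.all(np.isfinite(t_control))):
        raise ValueError("Ct values must be finite")
    ddct = (t_target - t_control) - (float(r_target) - float(r_control))
    ratios = np.exp2(-ddct)
    scale = 2.0 if diploid_scale else 1.0
    mean = scale * float(ratios.mean())
    se = scale * float(ratios.std(ddof=1)) if len(ratios) >= 2 else None
    return mean, se
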