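import numpy as np
import pytest

from hiscan import pipeline
from hiscan.data_io import GT_AB, GT_NOCALL
from hiscan.detect_multi import AberrantRegion
from hiscan.simulate import (
    GeneratorParams,
    SimulationConfig,
    generate_reference_population,
    inject_aberration,
    mix_samples,
    overlap_metrics,
    qpcr_copy_number,
    run_simulation_study,
    target_slice,
)


class TestGenerator:
    def test_same_seed_identical_population(self):
        params = GeneratorParams(n_markers=100)
        _, a, model_a = generate_reference_population(params, 5, seed=3)
        _, b, model_b = generate_reference_population(params, 5, seed=3)
        np.testing.assert_array_equal(model_a.allele_freq, model_b.allele_freq)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.h_a, sb.h_a)
            np.testing.assert_array_equal(sa.genotype, sb.genotype)

    def test_hwe_heterozygote_fraction(self):
        params = GeneratorParams(n_markers=3000)
        _, samples, model = generate_reference_population(params, 200, seed=4)
        geno = np.vstack([s.genotype for s in samples])
        observed = (geno == GT_AB).mean(axis=0)
        expected = 2 * model.allele_freq * (1 - model.allele_freq)
        # aggregate z-score over markers
        resid = (observed - expected).mean()
        se = np.sqrt((expected * (1 - expected)).mean() / (200 * 3000))
        assert abs(resid) < 4 * se

    def test_raw_af_clusters(self):
        params = GeneratorParams(n_markers=500, kappa_log2_range=(0.0, 0.0),
                                 ratio_log2_sd=0.05)
        _, samples, _ = generate_reference_population(params, 10, seed=5)
        s = samples[0]
        af = s.raw_af
        het = s.genotype == GT_AB
        assert abs(np.median(af[het]) - 0.5) < 0.05
        assert np.median(af[s.genotype == 0]) > 0.9
        assert np.median(af[s.genotype == 2]) < 0.1

    def test_invalid_frequency_range(self):
        with pytest.raises(ValueError):
            GeneratorParams(allele_freq_range=(0.9, 0.1))

    def test_no_nocall_in_clean_generator(self):
        _, samples, _ = generate_reference_population(GeneratorParams(n_markers=50), 3, seed=6)
        assert all((s.genotype != GT_NOCALL).all() for s in samples)


class TestTargetSlice:
    def test_centering_arithmetic(self):
        sl = target_slice(2001, 501)
        assert (sl.start, sl.stop) == (750, 1251)  # markers 751-1251, 1-based

    def test_odd_small(self):
        assert target_slice(7, 3) == slice(2, 5)

    def test_too_large_rejected(self):
        with pytest.raises(ValueError):
            target_slice(10, 11)


@pytest.fixture(scope="module")
def injection_setup(request):
    from hiscan.simulate import build_simulation_panel

    params = GeneratorParams(n_markers=401)
    panel, model = build_simulation_panel(params, 60, seed=21)
    return panel, model


def template_t_mapper(template, panel):
    """Recompute the pre-injection constants used by the injector."""
    t, info = pipeline.preprocess_sample(template, panel)

    def t_of(h_a, h_b):
        x = np.log2(h_a + h_b)
        x = (x - info["loc"]) / info["scale"]
        return x - info["balanced_mean"]

    return t_of


class TestInjectAberration:
    def test_loss_truncation_respected(self, injection_setup):
        panel, model = injection_setup
        rng = np.random.default_rng(31)
        from hiscan.simulate import _draw_normal_sample, _truncation_stats

        template = _draw_normal_sample(model, rng, "tpl")
        cfg = SimulationConfig(scenario="loss", n_target=51, r=4.0, seed=1)
        t_of = template_t_mapper(template, panel)
        test = inject_aberration(template, panel, model, cfg, rng)
        sl = target_slice(401, 51)
        mu, sd = _truncation_stats(panel, template.genotype)
        t_inj = t_of(test.h_a, test.h_b)[sl]
        assert np.all(t_inj <= (mu - 4.0 * sd)[sl] + 1e-9)

    def test_neutral_draws_within_three_sd(self, injection_setup):
        panel, model = injection_setup
        rng = np.random.default_rng(32)
        from hiscan.simulate import _draw_normal_sample, _truncation_stats

        template = _draw_normal_sample(model, rng, "tpl")
        cfg = SimulationConfig(scenario="neutral", n_target=51, r=0.0, seed=1)
        t_of = template_t_mapper(template, panel)
        test = inject_aberration(template, panel, model, cfg, rng)
        sl = target_slice(401, 51)
        mu, sd = _truncation_stats(panel, template.genotype)
        t_inj = t_of(test.h_a, test.h_b)[sl]
        assert np.all(np.abs(t_inj - mu[sl]) <= 3.0 * sd[sl] + 1e-9)

    def test_noise_fraction_binomial(self, injection_setup):
        panel, model = injection_setup
        from hiscan.simulate import _draw_normal_sample, _truncation_stats

        # at r = 4 loss draws sit <= mu - 4 sd while noise draws sit within
        # mu +- 2 sd, so the two donor classes are separable
        n_target, q = 301, 25.0
        counts = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            template = _draw_normal_sample(model, rng, "tpl")
            cfg = SimulationConfig(scenario="loss", n_target=n_target, r=4.0,
                                   q_percent=q, seed=seed)
            t_of = template_t_mapper(template, panel)
            test = inject_aberration(template, panel, model, cfg, rng)
            sl = target_slice(401, n_target)
            mu, sd = _truncation_stats(panel, template.genotype)
            t_inj = t_of(test.h_a, test.h_b)[sl]
            counts.append(int((t_inj > (mu - 3.0 * sd)[sl]).sum()))
        mean_noise = np.mean(counts)
        expected = n_target * q / 100.0
        sd_exp = np.sqrt(n_target * 0.25 * 0.75 / len(counts))
        assert abs(mean_noise - expected) < 4 * sd_exp

    def test_deterministic_under_seed(self, injection_setup):
        panel, model = injection_setup
        from hiscan.simulate import _draw_normal_sample

        out = []
        for _ in range(2):
            rng = np.random.default_rng(55)
            template = _draw_normal_sample(model, rng, "tpl")
            cfg = SimulationConfig(scenario="gain", n_target=21, r=2.0, seed=5)
            out.append(inject_aberration(template, panel, model, cfg, rng))
        np.testing.assert_array_equal(out[0].h_a, out[1].h_a)
        np.testing.assert_array_equal(out[0].genotype, out[1].genotype)


class TestSimulationStudy:
    def test_bit_reproducible(self, injection_setup):
        panel, model = injection_setup
        cfg = SimulationConfig(scenario="loss", n_target=21, r=2.0, n_reps=15, seed=7)
        a = run_simulation_study(cfg, panel, model, detector="single")
        b = run_simulation_study(cfg, panel, model, detector="single")
        np.testing.assert_array_equal(a.snp_rate, b.snp_rate)

    def test_few_reps_warns(self, injection_setup):
        panel, model = injection_setup
        cfg = SimulationConfig(scenario="neutral", n_target=11, n_reps=5, seed=8)
        with pytest.warns(UserWarning, match="replicates"):
            run_simulation_study(cfg, panel, model, detector="single")

    def test_neutral_fpr_controlled(self, injection_setup):
        panel, model = injection_setup
        cfg = SimulationConfig(scenario="neutral", n_target=51, n_reps=40, seed=9)
        res = run_simulation_study(cfg, panel, model, detector="single")
        assert res.region_rate <= 0.05


class TestMixSamples:
    def test_endpoints(self, injection_setup):
        _, model = injection_setup
        from hiscan.simulate import _draw_normal_sample

        rng = np.random.default_rng(60)
        tumor = _draw_normal_sample(model, rng, "t")
        normal = _draw_normal_sample(model, rng, "n")
        np.testing.assert_array_equal(mix_samples(tumor, normal, 0).h_a, normal.h_a)
        np.testing.assert_array_equal(mix_samples(tumor, normal, 100).h_a, tumor.h_a)
        mixed = mix_samples(tumor, normal, 30)
        np.testing.assert_allclose(mixed.h_b, 0.3 * tumor.h_b + 0.7 * normal.h_b)
        np.testing.assert_array_equal(mixed.genotype, normal.genotype)


def region(chrom, start, end, kind="LOSS"):
    return AberrantRegion(chromosome=chrom, start_idx=0, end_idx=0, start_bp=start,
                          end_bp=end, kind=kind, n_markers=1)


class TestOverlapMetrics:
    def test_identical_sets(self):
        regions = [region("1", 100, 199), region("2", 50, 149)]
        assert overlap_metrics(regions, regions, mode="S") == pytest.approx(100.0)
        assert overlap_metrics(regions, regions, mode="C") == pytest.approx(100.0)

    def test_half_overlap_s(self):
        bench = [region("1", 0, 99)]  # length 100 (bp 0..99 inclusive)
        test = [region("1", 50, 149)]
        assert overlap_metrics(test, bench, mode="S") == pytest.approx(50.0)

    def test_sub_threshold_excluded_from_c(self):
        bench = [region("1", 0, 999)]
        test = [region("1", 951, 2000)]  # 49/1050 of its own length overlaps
        assert overlap_metrics(test, bench, mode="C") == pytest.approx(0.0)

    def test_threshold_included_in_c(self):
        bench = [region("1", 0, 999)]
        test = [region("1", 500, 1499)]  # exactly 50% of its length overlaps
        assert overlap_metrics(test, bench, mode="C") == pytest.approx(100.0)

    def test_empty_benchmark_undefined(self):
        assert overlap_metrics([region("1", 0, 10)], [], mode="S") is None
        assert overlap_metrics([region("1", 0, 10)], [], mode="C") is None

    def test_chromosomes_not_conflated(self):
        bench = [region("1", 0, 99)]
        test = [region("2", 0, 99)]
        assert overlap_metrics(test, bench, mode="S") == pytest.approx(0.0)


class TestQpcr:
    def test_reference_identity(self):
        mean, se = qpcr_copy_number([20.0, 20.0, 20.0], [18.0, 18.0, 18.0], 20.0, 18.0)
        assert mean == pytest.approx(1.0)
        assert se == pytest.approx(0.0)
        mean2, _ = qpcr_copy_number([20.0] * 3, [18.0] * 3, 20.0, 18.0, diploid_scale=True)
        assert mean2 == pytest.approx(2.0)

    def test_one_doubling(self):
        mean, _ = qpcr_copy_number([19.0, 19.0], [18.0, 18.0], 20.0, 18.0)
        assert mean == pytest.approx(2.0)  # ddCt = -1 -> ratio 2

    def test_hand_se(self):
        # replicate ratios {1.0, 1.2, 0.8}: mean 1.0, sample SD 0.2
        ddct = -np.log2([1.0, 1.2, 0.8])
        mean, se = qpcr_copy_number(18.0 + ddct, np.full(3, 18.0), 20.0, 20.0)
        assert mean == pytest.approx(1.0)
        assert se == pytest.approx(0.2)

    def test_single_replicate_has_no_se(self):
        mean, se = qpcr_copy_number([20.0], [18.0], 20.0, 18.0)
        assert se is None

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            qpcr_copy_number([np.nan], [18.0], 20.0, 18.0)
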