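import numpy as np
import pytest

from hiscan.data_io import MarkerAnnotation
from hiscan.detect_multi import WindowConfig
from hiscan.preprocess import PreprocessOptions
from hiscan.reference_panel import ABERRATIONS, build_reference_panel, build_wap_reference
from hiscan.simulate import GeneratorParams, build_simulation_panel, generate_reference_population


@pytest.fixture(scope="session")
def sim_params():
    return GeneratorParams(n_markers=401)


@pytest.fixture(scope="session")
def sim_panel(sim_params):
    """Synthetic 401-marker panel (n=60) with WAP references for all aberrations."""
    panel, model = build_simulation_panel(
        sim_params,
        n_panel=60,
        seed=11,
        wap_configs=[WindowConfig(v=5, n_c=2)],
        wap_aberrations=ABERRATIONS,
    )
    return panel, model


@pytest.fixture(scope="session")
def multi_chrom_setup():
    """A 3-chromosome annotation with a matching panel, for pipeline tests."""
    params = GeneratorParams(n_markers=180)
    ann0, samples, model = generate_reference_population(params, 40, seed=5)
    per_chrom = 60
    ann = MarkerAnnotation(
        marker_id=ann0.marker_id,
        chromosome=np.repeat(["1", "2", "3"], per_chrom),
        position_bp=np.tile((np.arange(per_chrom) + 1) * 1000, 3),
        allele_a=ann0.allele_a,
        allele_b=ann0.allele_b,
        probe_class=ann0.probe_class,
    )
    panel = build_reference_panel(samples, ann, PreprocessOptions())
    for ab in ABERRATIONS:
        build_wap_reference(panel, ab, v=5, n_c=2, loess_span=0.1)
    return ann, samples, model, panel


@pytest.fixture
def tiny_annotation():
    return MarkerAnnotation(
        marker_id=np.array(["rs1", "rs2", "rs3"], dtype=object),
        chromosome=np.array(["1", "1", "2"], dtype=object),
        position_bp=np.array([100, 200, 150]),
        allele_a=np.array(["A", "C", "G"], dtype=object),
        allele_b=np.array(["G", "T", "A"], dtype=object),
        probe_class=np.array(["SNP", "SNP", "SNP"], dtype=object),
    )
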