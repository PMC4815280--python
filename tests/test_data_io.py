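import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiscan.data_io import (
    GT_AA,
    GT_AB,
    GT_BB,
    GT_NOCALL,
    MarkerAnnotation,
    SampleData,
    convert_log_ratio_strength,
    read_annotation,
    read_genotype_intensity_tables,
    read_log_ratio_strength,
    write_regions_bed,
    write_regions_tsv,
    write_tracks_tsv,
)
from hiscan.detect_multi import AberrantRegion


def write_fixture_tables(tmp_path, calls_rows, summary_rows, samples=("s1", "s2")):
    calls = tmp_path / "calls.txt"
    summary = tmp_path / "summary.txt"
    header = "probeset_id\t" + "\t".join(samples)
    calls.write_text("\n".join([header] + calls_rows) + "\n")
    summary.write_text("\n".join([header] + summary_rows) + "\n")
    return calls, summary


@pytest.fixture
def fixture_tables(tmp_path):
    calls_rows = ["rs1\t0\t1", "rs2\t2\t-1", "rs3\t1\t0"]
    summary_rows = [
        "rs1-A\t100\t50",
        "rs1-B\t5\t55",
        "rs2-A\t10\t20",
        "rs2-B\t90\t30",
        "rs3-A\t40\t80",
        "rs3-B\t45\t8",
    ]
    return write_fixture_tables(tmp_path, calls_rows, summary_rows)


class TestReadGenotypeIntensityTables:
    def test_basic_parse(self, fixture_tables, tiny_annotation):
        calls, summary = fixture_tables
        samples = read_genotype_intensity_tables(calls, summary, tiny_annotation)
        assert [s.sample_id for s in samples] == ["s1", "s2"]
        s1, s2 = samples
        assert len(s1) == 3
        # annotation order: rs1(1:100), rs2(1:200), rs3(2:150)
        assert s1.h_a.tolist() == [100, 10, 40]
        assert s1.h_b.tolist() == [5, 90, 45]
        assert s2.h_a.tolist() == [50, 20, 80]
        assert s1.genotype.tolist() == [GT_AA, GT_BB, GT_AB]

    def test_nocall_keeps_intensities(self, fixture_tables, tiny_annotation):
        calls, summary = fixture_tables
        _, s2 = read_genotype_intensity_tables(calls, summary, tiny_annotation)
        assert s2.genotype[1] == GT_NOCALL
        assert s2.h_a[1] == 20 and s2.h_b[1] == 30

    def test_missing_allele_row_names_marker(self, tmp_path, tiny_annotation):
        calls, summary = write_fixture_tables(
            tmp_path, ["rs1\t0\t1"], ["rs1-A\t1\t2"]
        )
        with pytest.raises(ValueError, match="rs1"):
            read_genotype_intensity_tables(calls, summary, tiny_annotation)

    def test_unknown_marker_is_hard_error(self, tmp_path, tiny_annotation):
        calls, summary = write_fixture_tables(
            tmp_path, ["rs9\t0\t1"], ["rs9-A\t1\t2", "rs9-B\t3\t4"]
        )
        with pytest.raises(ValueError, match="rs9"):
            read_genotype_intensity_tables(calls, summary, tiny_annotation)

    def test_mismatched_sample_columns(self, tmp_path, tiny_annotation):
        calls = tmp_path / "calls.txt"
        summary = tmp_path / "summary.txt"
        calls.write_text("probeset_id\ts1\ts2\nrs1\t0\t1\n")
        summary.write_text("probeset_id\ts1\ts3\nrs1-A\t1\t2\nrs1-B\t3\t4\n")
        with pytest.raises(ValueError, match="columns differ"):
            read_genotype_intensity_tables(calls, summary, tiny_annotation)

    def test_custom_code_map(self, fixture_tables, tiny_annotation):
        calls, summary = fixture_tables
        code_map = {0: GT_BB, 1: GT_AB, 2: GT_AA, -1: GT_NOCALL}
        s1, _ = read_genotype_intensity_tables(calls, summary, tiny_annotation, code_map=code_map)
        assert s1.genotype.tolist() == [GT_BB, GT_AA, GT_AB]


class TestConvertLogRatioStrength:
    def test_equal_alleles(self):
        assert convert_log_ratio_strength(1.0, 0.0) == (2.0, 2.0)

    def test_simple_inversion(self):
        h_a, h_b = convert_log_ratio_strength(0.5, 1.0)
        assert h_a == pytest.approx(2.0)
        assert h_b == pytest.approx(1.0)

    def test_negative_ratio(self):
        # S = mean(log2 h) = 3, L = log2(hA/hB) = -2  =>  hA = 4, hB = 16
        h_a, h_b = convert_log_ratio_strength(3.0, -2.0)
        assert h_a == pytest.approx(4.0)
        assert h_b == pytest.approx(16.0)
        assert 0.5 * (np.log2(h_a) + np.log2(h_b)) == pytest.approx(3.0)
        assert np.log2(h_a / h_b) == pytest.approx(-2.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            convert_log_ratio_strength(np.nan, 0.0)
        with pytest.raises(ValueError):
            convert_log_ratio_strength(1.0, np.inf)

    def test_round_trip_bulk(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(-10, 10, 10_000)
        l = rng.uniform(-10, 10, 10_000)
        h_a, h_b = convert_log_ratio_strength(s, l)
        np.testing.assert_allclose(0.5 * (np.log2(h_a) + np.log2(h_b)), s, rtol=0, atol=1e-9)
        np.testing.assert_allclose(np.log2(h_a / h_b), l, rtol=0, atol=1e-9)

    @given(st.floats(-20, 20), st.floats(-20, 20))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, s, l):
        h_a, h_b = convert_log_ratio_strength(s, l)
        assert h_a > 0 and h_b > 0
        assert 0.5 * (np.log2(h_a) + np.log2(h_b)) == pytest.approx(s, abs=1e-8)
        assert np.log2(h_a / h_b) == pytest.approx(l, abs=1e-8)


class TestAnnotation:
    def test_sorted_and_normalized(self):
        ann = MarkerAnnotation(
            marker_id=np.array(["m2", "m1", "m3"], dtype=object),
            chromosome=np.array(["chr2", "chr1", "chrX"], dtype=object),
            position_bp=np.array([10, 20, 5]),
            allele_a=np.array(["A"] * 3, dtype=object),
            allele_b=np.array(["B"] * 3, dtype=object),
            probe_class=np.array(["SNP"] * 3, dtype=object),
        )
        assert ann.chromosome.tolist() == ["1", "2", "X"]
        assert ann.marker_id.tolist() == ["m1", "m2", "m3"]
        assert not ann.is_autosomal[2]

    def test_duplicate_marker_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MarkerAnnotation(
                marker_id=np.array(["m1", "m1"], dtype=object),
                chromosome=np.array(["1", "1"], dtype=object),
                position_bp=np.array([1, 2]),
                allele_a=np.array(["A", "A"], dtype=object),
                allele_b=np.array(["B", "B"], dtype=object),
                probe_class=np.array(["SNP", "SNP"], dtype=object),
            )

    def test_read_annotation(self, tmp_path):
        path = tmp_path / "anno.tsv"
        path.write_text(
            "marker_id\tchromosome\tposition\tallele_A\tallele_B\tprobe_class\n"
            "rs1\tchr2\t500\tA\tG\tSNP\n"
            "cn1\t1\t100\t-\t-\tCN\n"
        )
        ann = read_annotation(path)
        assert ann.marker_id.tolist() == ["cn1", "rs1"]
        assert ann.is_snp.tolist() == [False, True]


class TestSampleData:
    def test_raw_af(self):
        s = SampleData("x", h_a=[3.0, 0.0, 1.0], h_b=[1.0, 0.0, 3.0], genotype=[0, -1, 2])
        np.testing.assert_allclose(s.raw_af[[0, 2]], [0.75, 0.25])
        assert np.isnan(s.raw_af[1])  # zero total intensity -> undefined

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            SampleData("x", h_a=[-1.0], h_b=[1.0], genotype=[0])


class TestLogRatioStrengthReader:
    def test_reader(self, tmp_path, tiny_annotation):
        path = tmp_path / "s1.txt"
        path.write_text("marker_id\tLog Ratio\tStrength\nrs1\t0\t1\nrs3\t1\t0.5\n")
        sample = read_log_ratio_strength(path, tiny_annotation)
        assert sample.h_a[0] == pytest.approx(2.0) and sample.h_b[0] == pytest.approx(2.0)
        assert np.isnan(sample.h_a[1])  # rs2 missing for this sample
        assert sample.h_a[2] == pytest.approx(2.0) and sample.h_b[2] == pytest.approx(1.0)


def _region(chrom, start, end, kind, p=1e-3):
    return AberrantRegion(
        chromosome=chrom, start_idx=0, end_idx=0, start_bp=start, end_bp=end,
        kind=kind, n_markers=1, min_p=p,
    )


class TestExports:
    def test_bed_coordinates(self, tmp_path):
        path = tmp_path / "r.bed"
        write_regions_bed([_region("2", 100, 200, "LOSS")], path)
        lines = path.read_text().strip().splitlines()
        assert lines[1].startswith("2\t99\t200\tLOSS")

    def test_empty_bed_has_header(self, tmp_path):
        path = tmp_path / "r.bed"
        write_regions_bed([], path)
        assert path.read_text().startswith("#chrom")

    def test_bed_sorted(self, tmp_path):
        path = tmp_path / "r.bed"
        write_regions_bed(
            [_region("10", 5, 9, "GAIN"), _region("2", 1, 3, "LOSS")], path
        )
        lines = path.read_text().strip().splitlines()[1:]
        assert [ln.split("\t")[0] for ln in lines] == ["2", "10"]

    def test_regions_tsv_one_based(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_regions_tsv([_region("2", 100, 200, "LOSS")], path)
        line = path.read_text().strip().splitlines()[1].split("\t")
        assert line[:4] == ["2", "100", "200", "LOSS"]

    def test_tracks_round_trip(self, tmp_path, tiny_annotation):
        import pandas as pd

        path = tmp_path / "tracks.tsv"
        values = np.array([0.125, np.nan, 3.5])
        write_tracks_tsv(tiny_annotation, {"t": values}, path)
        df = pd.read_csv(path, sep="\t", na_values="NA")
        np.testing.assert_allclose(df["t"].to_numpy(), values)
        assert df["marker_id"].tolist() == tiny_annotation.marker_id.tolist()
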