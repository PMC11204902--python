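import numpy as np
import pytest

from prscad.association import AssociationResult
from prscad.data_io import (
    FormatError,
    ScoreSet,
    ScoreVariant,
    ValidationError,
    read_genotypes_vcf,
    read_phenotypes,
    read_score_file,
    write_genotypes_vcf,
    write_report,
    write_score_file,
)
from prscad.synthetic import SimulationConfig, simulate_panel

from conftest import make_panel


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


class TestScoreFile:
    def test_basic_parse(self, tmp_path):
        f = tmp_path / "pgs.txt"
        write_lines(f, [
            "#pgs_id=PGS999999",
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight",
            "rs1\t1\t100\tA\tG\t0.5",
            "rs2\t1\t200\tC\tT\t-0.2",
        ])
        ss = read_score_file(f)
        assert ss.pgs_id == "PGS999999"
        assert ss.n_variants == 2
        assert np.allclose(ss.weights, [0.5, -0.2])

    def test_absent_other_allele(self, tmp_path):
        f = tmp_path / "pgs.txt"
        write_lines(f, [
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight",
            "rs1\t1\t100\tA\t\t0.5",
        ])
        ss = read_score_file(f)
        assert ss.variants[0].other_allele is None

    def test_non_numeric_weight_names_line(self, tmp_path):
        f = tmp_path / "pgs.txt"
        write_lines(f, [
            "#pgs_id=X",
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight",
            "rs1\t1\t100\tA\tG\t0.5",
            "rs2\t1\t200\tC\tT\tabc",
        ])
        with pytest.raises(FormatError, match="line 4"):
            read_score_file(f)

    def test_missing_mandatory_column(self, tmp_path):
        f = tmp_path / "pgs.txt"
        write_lines(f, ["rsID\tchr_name\tother_allele", "rs1\t1\tG"])
        with pytest.raises(FormatError, match="effect_allele|effect_weight"):
            read_score_file(f)

    def test_round_trip_preserves_weights_exactly(self, tmp_path, rng):
        variants = [
            ScoreVariant(variant_id=f"rs{j}", chrom="2", pos=1000 + j,
                         effect_allele="A", other_allele="G",
                         weight=float(w))
            for j, w in enumerate(rng.normal(size=25))
        ]
        ss = ScoreSet(pgs_id="SIMRT", variants=variants)
        f = tmp_path / "rt.txt"
        write_score_file(ss, f)
        back = read_score_file(f)
        assert back.pgs_id == "SIMRT"
        assert [v.variant_id for v in back.variants] == [v.variant_id for v in variants]
        assert np.array_equal(back.weights, ss.weights)  # machine precision


class TestVCF:
    def test_round_trip_and_gt_fallback(self, tmp_path, rng):
        p = rng.uniform(0.1, 0.5, 20)
        miss = rng.random((15, 20)) < 0.1
        panel = make_panel(rng.binomial(2, p, (15, 20)).astype(float), missing=miss)
        f = tmp_path / "panel.vcf"
        write_genotypes_vcf(panel, f)
        back = read_genotypes_vcf(f)
        assert back.sample_ids == panel.sample_ids
        assert np.array_equal(back.missing_mask, panel.missing_mask)
        ok = ~panel.missing_mask
        assert np.allclose(back.dosage[ok], panel.dosage[ok], atol=1e-4)

    def test_dosage_against_string_parse_oracle(self, tmp_path):
        cfg = SimulationConfig(n_samples=40, n_variants=100, seed=7,
                               dosage_jitter_sd=0.05, missing_rate=0.05)
        panel, _ = simulate_panel(cfg)
        f = tmp_path / "p.vcf"
        write_genotypes_vcf(panel, f)
        loaded = read_genotypes_vcf(f)
        # oracle: parse the DS field out of the raw text directly
        body = [ln for ln in f.read_text().splitlines() if not ln.startswith("#")]
        rec_rng = np.random.default_rng(0)
        for _ in range(100):
            j = int(rec_rng.integers(len(body)))
            i = int(rec_rng.integers(panel.n_samples))
            cell = body[j].split("\t")[9 + i]
            gt, ds = cell.split(":")
            if gt == "./.":
                assert loaded.missing_mask[i, j]
            else:
                assert loaded.dosage[i, j] == pytest.approx(float(ds), abs=1e-6)

    def test_ds_takes_precedence_over_gt(self, tmp_path):
        f = tmp_path / "ds.vcf"
        f.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="d">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT:DS\t0/1:1.7\t0/0:0.1\n"
        )
        panel = read_genotypes_vcf(f)
        assert panel.dosage[0, 0] == pytest.approx(1.7)
        assert panel.dosage[1, 0] == pytest.approx(0.1)

    def test_multiallelic_skipped_with_warning(self, tmp_path):
        f = tmp_path / "ma.vcf"
        f.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
            "1\t200\trs2\tA\tG\t.\t.\t.\tGT\t./.\n"
        )
        with pytest.warns(UserWarning, match="multiallelic"):
            panel = read_genotypes_vcf(f)
        assert panel.n_variants == 1
        assert panel.missing_mask[0, 0]


class TestPhenotypes:
    def test_well_formed(self, tmp_path, small_phenotypes):
        f = tmp_path / "ph.tsv"
        small_phenotypes.df.to_csv(f, sep="\t", index=False)
        table = read_phenotypes(f)
        assert len(table) == 30
        assert table.sample_ids == small_phenotypes.sample_ids

    def test_bad_case_status_rejected(self, tmp_path, small_phenotypes):
        df = small_phenotypes.df.copy()
        df.loc[0, "case_status"] = 2
        f = tmp_path / "ph.tsv"
        df.to_csv(f, sep="\t", index=False)
        with pytest.raises(ValidationError, match="case_status"):
            read_phenotypes(f)

    def test_unknown_column_warns(self, tmp_path, small_phenotypes):
        df = small_phenotypes.df.copy()
        df["bmi"] = 28.3
        f = tmp_path / "ph.tsv"
        df.to_csv(f, sep="\t", index=False)
        with pytest.warns(UserWarning, match="bmi"):
            read_phenotypes(f)


class TestReport:
    @staticmethod
    def result(pgs_id="PGS1", r2_full=0.502, r2_null=0.222, p=2.41e-78):
        return AssociationResult(
            pgs_id=pgs_id, model="model1", r2_null=r2_null, r2_full=r2_full,
            adjusted_prs_r2=r2_full - r2_null, odds_ratio=1.096,
            ci_low=1.05, ci_high=1.15, p_value=p, bonferroni_significant=True)

    def test_row_count_and_formatting(self, tmp_path):
        f = tmp_path / "rep.tsv"
        write_report([self.result(pgs_id=f"P{k}") for k in range(9)], f)
        lines = f.read_text().splitlines()
        assert len(lines) == 10
        cells = lines[1].split("\t")
        assert cells[2] == "50.2%"
        assert cells[3] == "28.0%"  # adjusted R2 0.28 printed as percentage
        assert cells[4] == "1.096"
        assert "e-78" in cells[6]

    def test_empty_results_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_report([], tmp_path / "rep.tsv")
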