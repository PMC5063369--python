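from fractions import Fraction

import numpy as np
import pytest

from lrpldx.cohort import (
    Cohort,
    CohortValidationError,
    NodeRecord,
    Stage,
    read_cohort,
    summarize_cohort,
    write_cohort,
)

from conftest import make_cohort


def _write_csv(path, rows, header="node_id,patient_id,miad_mm,maad_mm,macd_mm,nsuv_mean,nsuv_qual_neg,label,cohort_tag"):
    path.write_text("\n".join([header] + rows) + "\n")


class TestReadCohort:
    def test_well_formed_csv_loads_all_rows(self, tmp_path):
        f = tmp_path / "c.csv"
        _write_csv(
            f,
            [
                "n1,p1,6.2,10.6,16.9,2.5,0,positive,tw",
                "n2,p1,4.0,5.5,9.1,,1,negative,tw",
                "n3,p2,5.1,8.0,12.0,1.1,0,negative,cn",
            ],
        )
        cohort = read_cohort(f, stage=Stage.STAGE_II)
        assert len(cohort) == 3
        assert cohort.records[0].miad == 6.2
        assert cohort.records[0].label is True

    def test_transposed_diameters_rejected_with_row_number(self, tmp_path):
        # MIAD must not exceed MAAD: it is measured perpendicular to it
        f = tmp_path / "c.csv"
        _write_csv(
            f,
            [
                "n1,p1,6.2,10.6,16.9,,0,positive,",
                "n2,p1,10.6,6.2,16.9,,0,positive,",
            ],
        )
        with pytest.raises(CohortValidationError) as exc:
            read_cohort(f, stage=Stage.STAGE_I)
        assert exc.value.errors[0][0] == 2
        assert "miad" in exc.value.errors[0][1]

    def test_qualitative_negative_suv_imputed_to_zero(self, tmp_path):
        f = tmp_path / "c.csv"
        _write_csv(f, ["n1,p1,4.0,5.5,9.1,,1,negative,"])
        cohort = read_cohort(f, stage=Stage.STAGE_II)
        assert cohort.records[0].nsuv == 0.0
        assert cohort.records[0].nsuv_qualitative_negative

    def test_stage2_requires_suv_or_flag(self, tmp_path):
        f = tmp_path / "c.csv"
        _write_csv(f, ["n1,p1,4.0,5.5,9.1,,0,negative,"])
        with pytest.raises(CohortValidationError):
            read_cohort(f, stage=Stage.STAGE_II)
        # same file is fine in stage I, where SUV is optional
        assert len(read_cohort(f, stage=Stage.STAGE_I)) == 1

    def test_missing_column_and_non_numeric_value(self, tmp_path):
        f = tmp_path / "c.csv"
        _write_csv(f, ["n1,p1,4.0,5.5"], header="node_id,patient_id,miad_mm,maad_mm")
        with pytest.raises(CohortValidationError, match="missing required column"):
            read_cohort(f)
        g = tmp_path / "d.csv"
        _write_csv(g, ["n1,p1,big,5.5,9.1,,0,negative,"])
        with pytest.raises(CohortValidationError):
            read_cohort(g)

    def test_roundtrip_is_bit_identical_and_imputation_idempotent(self, tmp_path):
        rows = [
            (6.2, 10.6, 16.9, 2.5, True),
            (4.0, 5.5, 9.1, 0.0, False),
            (5.1, 8.0, 12.0, 1.17, False),
        ]
        cohort = make_cohort(rows, stage=Stage.STAGE_II)
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(cohort, f1)
        again = read_cohort(f1, stage=Stage.STAGE_II)
        write_cohort(again, f2)
        assert f1.read_bytes() == f2.read_bytes()
        for a, b in zip(cohort.records, again.records):
            assert (a.miad, a.maad, a.macd, a.nsuv, a.label) == (
                b.miad,
                b.maad,
                b.macd,
                b.nsuv,
                b.label,
            )


class TestSummarize:
    def test_published_cohort_composition(self):
        # 337 positive + 326 negative nodes -> prevalence 50.8%
        rows = [(7.0, 9.0, 15.0, None, True)] * 337 + [
            (4.0, 6.0, 10.0, None, False)
        ] * 326
        s = summarize_cohort(make_cohort(rows))
        assert s.total == 663
        assert (s.positives, s.negatives) == (337, 326)
        assert s.prevalence == Fraction(337, 663)
        assert round(float(s.prevalence), 3) == 0.508

    def test_all_positive_prevalence_one(self):
        s = summarize_cohort(make_cohort([(5, 6, 7, None, True)] * 5))
        assert s.prevalence == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(Cohort((), stage=Stage.STAGE_I))

    def test_matches_generator_bookkeeping(self, planted_stage2_cohort):
        cohort, sidecar = planted_stage2_cohort
        s = summarize_cohort(cohort)
        assert s.positives == int(sidecar["label"].sum())
        assert s.total == len(sidecar)


class TestRecordValidation:
    def test_measurements_snapped_to_grid(self):
        r = NodeRecord("n", "p", miad=6.1499, maad=10.649, macd=16.96, nsuv=1.764)
        assert (r.miad, r.maad, r.macd, r.nsuv) == (6.1, 10.6, 17.0, 1.76)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(CohortValidationError):
            Cohort((NodeRecord("n", "p", miad=0.0, maad=5.0, macd=6.0),))

    def test_flagged_node_with_measured_suv_rejected(self):
        rec = NodeRecord(
            "n", "p", miad=4, maad=5, macd=6, nsuv=2.0, nsuv_qualitative_negative=True
        )
        with pytest.raises(CohortValidationError):
            Cohort((rec,), stage=Stage.STAGE_II)
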