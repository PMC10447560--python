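"""Cohort I/O, APOE classification and summary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogtraj import (
    Cohort,
    CohortValidationError,
    SchemaError,
    apoe_group_counts,
    classify_apoe,
    demographics_table,
    genotype_table,
    read_cohort,
    write_cohort,
)
from cogtraj.cohort import ALLELES, GENOTYPES

from conftest import make_participant


class TestReadWrite:
    def test_round_trip_identity(self, tiny_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(tiny_cohort, path)
        back = read_cohort(path)
        assert len(back) == 3
        assert [p.id for p in back] == [p.id for p in tiny_cohort]
        assert back.to_frame().equals(tiny_cohort.to_frame())

    def test_missing_column_names_it(self, tiny_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(tiny_cohort, path)
        df = pd.read_csv(path).drop(columns=["mmse"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="mmse"):
            read_cohort(path)

    @pytest.mark.parametrize(
        "column,value,match",
        [
            ("mmse", 31, "MMSE"),
            ("apoe_allele_1", "e5", "allele"),
            ("age", 12, "age"),
            ("education_years", -1, "education"),
        ],
    )
    def test_invalid_row_rejected_with_id(self, tiny_cohort, tmp_path, column, value, match):
        path = tmp_path / "cohort.csv"
        write_cohort(tiny_cohort, path)
        df = pd.read_csv(path)
        df.loc[1, column] = value
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match=match) as err:
            read_cohort(path)
        assert "B" in str(err.value)  # row id appears in the message

    def test_missing_value_rejected(self, tiny_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(tiny_cohort, path)
        df = pd.read_csv(path)
        df.loc[0, "education_years"] = np.nan
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="missing"):
            read_cohort(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(CohortValidationError, match="duplicate"):
            Cohort((make_participant(id="X"), make_participant(id="X")))


class TestClassifyApoe:
    @pytest.mark.parametrize("a1", ALLELES)
    @pytest.mark.parametrize("a2", ALLELES)
    def test_flags_and_symmetry_exhaustive(self, a1, a2):
        groups = classify_apoe(a1, a2)
        assert groups.e4_positive == ("e4" in (a1, a2))
        assert groups.e2_positive == ("e2" in (a1, a2))
        assert classify_apoe(a2, a1) == groups

    def test_e2e4_in_both_groups(self):
        groups = classify_apoe("e2", "e4")
        assert groups.e4_positive and groups.e2_positive

    def test_unknown_allele(self):
        with pytest.raises(CohortValidationError):
            classify_apoe("e3", "e5")


class TestGenotypeTable:
    def test_counts_partition_into_marginals(self, small_cohort):
        cohort, _ = small_cohort
        table = genotype_table(cohort)
        counts = apoe_group_counts(cohort)
        for stratum, col in (("carriers", "carrier_n"), ("noncarriers", "noncarrier_n")):
            e4_from_table = sum(
                int(table.loc[g, col]) for g in GENOTYPES if "e4" in g
            )
            e2_from_table = sum(
                int(table.loc[g, col]) for g in GENOTYPES if "e2" in g
            )
            assert e4_from_table == counts.loc[stratum, "e4_positive"]
            assert e2_from_table == counts.loc[stratum, "e2_positive"]
            assert int(table[col].sum()) == counts.loc[stratum, "n"]

    def test_single_participant(self):
        cohort = Cohort((make_participant(),))
        table = genotype_table(cohort)
        assert int(table.loc["e3/e3", "carrier_n"]) == 1
        assert table.loc["e3/e3", "carrier_pct"] == 100.00


class TestDemographics:
    def _two_group_cohort(self, shift=0.0):
        rows = []
        for i in range(12):
            rows.append(
                make_participant(
                    id=f"pos{i}",
                    age=30 + i,
                    education_years=8.0 + shift + (i % 3),
                    apoe_allele_1="e4",
                )
            )
            rows.append(
                make_participant(
                    id=f"neg{i}", age=30 + i, education_years=8.0 + (i % 3)
                )
            )
        return Cohort(tuple(rows))

    def test_identical_groups_p_one(self):
        table = demographics_table(self._two_group_cohort(), allele="e4")
        assert table.age.mean_pos == table.age.mean_neg
        assert table.age.p_value == 1.0
        assert table.education_years.p_value == 1.0

    def test_sample_sd_convention(self):
        # group of {10, 20, 30}: mean 20, SD 10 with the n−1 denominator
        rows = [
            make_participant(id=f"p{v}", education_years=v, apoe_allele_1="e4")
            for v in (10, 20, 30)
        ] + [make_participant(id=f"n{i}", education_years=8) for i in range(3)]
        table = demographics_table(Cohort(tuple(rows)), allele="e4")
        assert table.education_years.mean_pos == pytest.approx(20.0)
        assert table.education_years.sd_pos == pytest.approx(10.0)

    def test_education_shift_detected(self):
        table = demographics_table(self._two_group_cohort(shift=1.0), allele="e4")
        assert table.education_years.mean_pos > table.education_years.mean_neg

    def test_empty_group_errors(self):
        rows = [make_participant(id=f"p{i}", apoe_allele_1="e4") for i in range(4)]
        with pytest.raises(CohortValidationError, match="empty"):
            demographics_table(Cohort(tuple(rows)), allele="e4")


@given(
    st.lists(
        st.tuples(st.sampled_from(ALLELES), st.sampled_from(ALLELES)),
        min_size=1,
        max_size=40,
    )
)
def test_marginals_property_random_cohorts(pairs):
    """e4+/e2+ marginals always equal the sums of matching genotype counts."""
    rows = tuple(
        make_participant(id=f"r{i}", apoe_allele_1=a, apoe_allele_2=b)
        for i, (a, b) in enumerate(pairs)
    )
    cohort = Cohort(rows)
    table = genotype_table(cohort)
    counts = apoe_group_counts(cohort)
    assert counts.loc["carriers", "e4_positive"] == sum(
        int(table.loc[g, "carrier_n"]) for g in GENOTYPES if "e4" in g
    )
    assert counts.loc["carriers", "e2_positive"] == sum(
        int(table.loc[g, "carrier_n"]) for g in GENOTYPES if "e2" in g
    )
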