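"""Cohort table validation, AD-continuum selection, normative reference, cutoffs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from suvtraj import (
    NormativeReference,
    SyntheticCohortSpec,
    compute_cutoff,
    derive_normative_reference,
    flag_amyloid_positive,
    generate_cohort,
    load_long_table,
    select_ad_continuum,
    write_long_table,
)
from suvtraj.exceptions import (
    CohortValidationError,
    InsufficientNormativeGroupError,
)

from conftest import make_table


class TestLoadValidate:
    def test_single_subject_read_back(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "subject_id,visit_time,suvr,sex,apoe4_carrier,diagnosis,amyloid_positive\n"
            "s1,0,1.0,female,true,CN,false\n"
            "s1,2,1.1,female,true,CN,false\n"
            "s1,4,1.3,female,true,MCI,true\n"
        )
        t = load_long_table(p)
        assert t["subject_id"].nunique() == 1
        assert len(t) == 3
        assert list(t["visit_time"]) == [0.0, 2.0, 4.0]

    def test_duplicate_subject_time_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "subject_id,visit_time,suvr,sex,apoe4_carrier,diagnosis,amyloid_positive\n"
            "s1,0,1.0,female,,CN,\n"
            "s1,0,1.1,female,,CN,\n"
        )
        with pytest.raises(CohortValidationError, match="s1"):
            load_long_table(p)

    def test_non_numeric_suvr_reports_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "subject_id,visit_time,suvr,sex,apoe4_carrier,diagnosis,amyloid_positive\n"
            "s1,0,abc,female,,CN,\n"
        )
        with pytest.raises(CohortValidationError, match="suvr"):
            load_long_table(p)

    def test_column_map_and_unknowns(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,t,value,sex,apoe4_carrier,diagnosis,amyloid_positive\n"
                     "s1,0,1.0,,,CN,\n"
                     "s2,0,1.1,male,false,CN,false\n")
        t = load_long_table(p, column_map={"subject_id": "id", "visit_time": "t", "suvr": "value"})
        assert t.loc[t.subject_id == "s1", "sex"].iloc[0] == "unknown"
        assert t.loc[t.subject_id == "s1", "apoe4_carrier"].isna().all()

    def test_synthetic_round_trip(self, tmp_path, small_cohort):
        _, table, _ = small_cohort
        p = tmp_path / "cohort.csv"
        write_long_table(table, p)
        back = load_long_table(p)
        pd.testing.assert_frame_equal(back, table)

    def test_varying_sex_within_subject_rejected(self):
        with pytest.raises(CohortValidationError, match="sex"):
            make_table(
                [
                    ("s1", 0, 1.0, "female", True, "CN", False),
                    ("s1", 1, 1.0, "male", True, "CN", False),
                ]
            )


class TestAdContinuum:
    def table(self):
        return make_table(
            [
                # always CN, never positive -> included
                ("cn_neg", 0, 0.85, "female", False, "CN", False),
                ("cn_neg", 2, 0.86, "female", False, "CN", False),
                # MCI at one visit, never positive -> excluded
                ("mci_neg", 0, 0.9, "male", False, "MCI", False),
                ("mci_neg", 2, 0.92, "male", False, "CN", False),
                # demented but positive once -> included
                ("dem_pos", 0, 1.4, "male", True, "Dementia", False),
                ("dem_pos", 2, 1.5, "male", True, "Dementia", True),
                # impaired, amyloid status wholly unknown -> excluded, logged
                ("mci_unk", 0, 1.0, "female", False, "MCI", None),
            ]
        )

    def test_inclusion_rules(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="suvtraj.cohort"):
            kept = select_ad_continuum(self.table())
        ids = set(kept["subject_id"])
        assert ids == {"cn_neg", "dem_pos"}
        assert "mci_unk" in caplog.text

    def test_idempotent_and_row_preserving(self):
        once = select_ad_continuum(self.table())
        twice = select_ad_continuum(once)
        pd.testing.assert_frame_equal(once, twice)
        # all rows of retained subjects are preserved
        tab = self.table()
        for sid in once["subject_id"].unique():
            assert (once["subject_id"] == sid).sum() == (tab["subject_id"] == sid).sum()


class TestNormativeReference:
    def test_recovers_generator_values(self):
        # normative subjects sit flat at the floor with measurement noise,
        # so the derived reference estimates (floor, noise sd)
        spec = SyntheticCohortSpec(
            n_subjects=250, floor=0.86, noise_sd=0.09, normative_fraction=0.8, seed=3
        )
        table, _ = generate_cohort(spec)
        ref = derive_normative_reference(table)
        # all 200 normative subjects qualify; a few pre-onset accumulators
        # that stayed CN and amyloid-negative may join them
        assert ref.n >= 200
        se_mean = 0.09 / np.sqrt(ref.n)
        assert abs(ref.mean - 0.86) < 3 * se_mean
        se_sd = 0.09 / np.sqrt(2 * (ref.n - 1))
        assert abs(ref.sd - 0.09) < 3 * se_sd

    def test_single_subject_errors(self):
        t = make_table(
            [
                ("n1", 0, 0.85, "female", False, "CN", False),
                ("n1", 1, 0.86, "female", False, "CN", False),
                ("acc", 0, 1.2, "male", False, "MCI", True),
            ]
        )
        with pytest.raises(InsufficientNormativeGroupError):
            derive_normative_reference(t)

    def test_uses_baseline_visit_only(self):
        t = make_table(
            [
                ("n1", 0, 0.80, "female", False, "CN", False),
                ("n1", 1, 2.80, "female", False, "CN", False),  # later visit ignored
                ("n2", 0, 0.90, "male", False, "CN", False),
            ]
        )
        ref = derive_normative_reference(t)
        assert ref.mean == pytest.approx(0.85)

    def test_json_round_trip(self, tmp_path):
        ref = NormativeReference("suvr", 204, 0.863, 0.091)
        p = tmp_path / "ref.json"
        ref.to_json(p)
        assert NormativeReference.from_json(p) == ref


class TestCutoff:
    @pytest.mark.parametrize(
        "mean,sd,z,expected",
        [
            (0.863, 0.091, 2.0, 1.045),  # cortical amyloid scale
            (1.58, 0.159, 2.0, 1.898),  # striatal amyloid scale
            (0.863, 0.091, 0.0, 0.863),  # z = 0: cutoff equals the mean
        ],
    )
    def test_cutoff_arithmetic(self, mean, sd, z, expected):
        ref = NormativeReference("suvr", 204, mean, sd)
        assert compute_cutoff(ref, z).cutoff_value == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(
        mean=hst.floats(0.5, 3.0),
        sd=hst.floats(0.01, 0.5),
        z=hst.floats(0.0, 5.0),
        delta=hst.floats(-1.0, 1.0),
    )
    def test_affine_equivariance_and_exact_z(self, mean, sd, z, delta):
        ref = NormativeReference("b", 10, mean, sd)
        cut = compute_cutoff(ref, z)
        shifted = compute_cutoff(NormativeReference("b", 10, mean + delta, sd), z)
        assert shifted.cutoff_value - cut.cutoff_value == pytest.approx(delta, abs=1e-9)
        # the cutoff's z-score under its own reference is exactly z
        assert ref.z_score(cut.cutoff_value) == pytest.approx(z, abs=1e-9)

    def test_negative_z_rejected(self):
        ref = NormativeReference("suvr", 10, 0.863, 0.091)
        with pytest.raises(ValueError):
            compute_cutoff(ref, -2.0)


def test_flag_amyloid_positive_fills_only_unknown():
    t = make_table(
        [
            ("s1", 0, 1.2, "female", False, "CN", None),
            ("s2", 0, 0.9, "male", False, "CN", False),
            ("s3", 0, 1.2, "male", False, "CN", False),  # explicit flag kept
        ]
    )
    from suvtraj import CutoffSpec

    out = flag_amyloid_positive(t, CutoffSpec(2.0, 1.045))
    get = lambda sid: out.loc[out.subject_id == sid, "amyloid_positive"].iloc[0]
    assert get("s1") == True  # noqa: E712
    assert get("s2") == False  # noqa: E712
    assert get("s3") == False  # noqa: E712
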