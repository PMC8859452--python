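"""Synthetic cohort generator: determinism, noiseless limit, oracles."""

import io

import numpy as np
import pytest
from scipy.integrate import quad

from suvtraj import (
    SyntheticCohortSpec,
    generate_cohort,
    oracle_time_to_level,
    spec_with_time_shift,
    write_long_table,
)
from suvtraj.exceptions import ConfigError, DomainError


class TestGeneration:
    def test_noiseless_observations_lie_on_logistic(self):
        spec = SyntheticCohortSpec(n_subjects=40, noise_sd=0.0, seed=2)
        table, truth = generate_cohort(spec)
        for i, sid in enumerate(truth.subject_ids):
            sub = table[table.subject_id == sid]
            if truth.is_normative[i]:
                np.testing.assert_allclose(sub["suvr"], spec.floor, atol=1e-12)
            else:
                expect = truth.trajectory_value(
                    sub["visit_time"].to_numpy(), truth.onset[i]
                )
                np.testing.assert_allclose(sub["suvr"], expect, atol=1e-12)

    def test_same_seed_byte_identical(self):
        spec = SyntheticCohortSpec(n_subjects=50, seed=9)
        t1, _ = generate_cohort(spec)
        t2, _ = generate_cohort(spec)
        b1, b2 = io.StringIO(), io.StringIO()
        write_long_table(t1, b1)
        write_long_table(t2, b2)
        assert b1.getvalue() == b2.getvalue()

    def test_row_and_slope_counts(self):
        from suvtraj import compute_interval_slopes

        spec = SyntheticCohortSpec(n_subjects=500, visits_per_subject=4, seed=0)
        table, _ = generate_cohort(spec)
        assert len(table) == 2000
        slopes = compute_interval_slopes(table, min_interval=1e-9)
        assert len(slopes) == 1500

    def test_normative_subjects_are_cn_and_negative(self):
        spec = SyntheticCohortSpec(n_subjects=60, seed=5)
        table, truth = generate_cohort(spec)
        norm_ids = {
            sid for sid, n in zip(truth.subject_ids, truth.is_normative) if n
        }
        sub = table[table.subject_id.isin(norm_ids)]
        assert (sub["diagnosis"] == "CN").all()
        assert (sub["amyloid_positive"] == False).all()  # noqa: E712

    def test_positivity_flag_follows_noise_free_level(self):
        spec = SyntheticCohortSpec(n_subjects=80, noise_sd=0.0, seed=6)
        table, truth = generate_cohort(spec)
        cut = spec.positivity_cutoff
        acc = table[~table.subject_id.isin(
            {s for s, n in zip(truth.subject_ids, truth.is_normative) if n}
        )]
        assert ((acc["suvr"] >= cut) == acc["amyloid_positive"]).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticCohortSpec(floor=1.9, ceiling=0.8)
        with pytest.raises(ConfigError):
            SyntheticCohortSpec(visits_per_subject=0)
        with pytest.raises(ConfigError):
            SyntheticCohortSpec(noise_sd=-0.1)


class TestOracles:
    def test_closed_form_agrees_with_quadrature(self):
        """Dual-oracle check: the closed-form time-at-level matches fine
        quadrature of dS/g(S) between the same levels."""
        spec = SyntheticCohortSpec(seed=0)
        _, truth = generate_cohort(SyntheticCohortSpec(n_subjects=1, normative_fraction=0.0))
        anchor, level = 0.863, 1.045
        closed = truth.oracle_time_to_level(anchor, level)
        brute, err = quad(lambda s: 1.0 / truth.rate(s), anchor, level, limit=200)
        assert abs(closed - brute) < 1e-6

    def test_identity_and_domain(self):
        _, truth = generate_cohort(SyntheticCohortSpec(n_subjects=1, normative_fraction=0.0))
        assert truth.oracle_time_to_level(1.0, 1.0) == 0.0
        with pytest.raises(DomainError):
            truth.oracle_time_to_level(0.7, 1.0)
        with pytest.raises(DomainError):
            oracle_time_to_level(truth, 1.0, 2.5)

    def test_logistic_symmetry_around_midpoint(self):
        _, truth = generate_cohort(SyntheticCohortSpec(n_subjects=1, normative_fraction=0.0))
        mid = (0.8 + 1.9) / 2
        t_mid = truth.time_at_level(mid)
        for delta in (0.1, 0.3, 0.5):
            below = truth.time_at_level(mid - delta)
            above = truth.time_at_level(mid + delta)
            assert (t_mid - below) == pytest.approx(above - t_mid, rel=1e-9)

    def test_rate_vanishes_at_asymptotes_and_peaks_at_midpoint(self):
        _, truth = generate_cohort(SyntheticCohortSpec(n_subjects=1, normative_fraction=0.0))
        assert truth.rate(0.8) == 0.0
        assert truth.rate(1.9) == 0.0
        grid = np.linspace(0.8, 1.9, 501)
        assert abs(grid[np.argmax(truth.rate(grid))] - 1.35) < 0.01


class TestTimeShiftSpec:
    def test_shift_changes_oracle_time_by_delta(self):
        base = SyntheticCohortSpec(seed=0)
        _, truth0 = generate_cohort(SyntheticCohortSpec(n_subjects=1, normative_fraction=0.0))
        for delta in (1.0, 3.0, 8.0):
            shifted = spec_with_time_shift(base, delta, 0.863, 1.045)
            _, truth1 = generate_cohort(
                SyntheticCohortSpec(
                    n_subjects=1, normative_fraction=0.0, growth_rate=shifted.growth_rate
                )
            )
            t0 = truth0.oracle_time_to_level(0.863, 1.045)
            t1 = truth1.oracle_time_to_level(0.863, 1.045)
            assert t1 - t0 == pytest.approx(delta, abs=1e-9)

    def test_onset_window_widens_for_slower_strata(self):
        base = SyntheticCohortSpec(seed=0)
        shifted = spec_with_time_shift(base, 8.0, 0.863, 1.045)
        assert shifted.resolved_onset_range[1] > base.resolved_onset_range[1]
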