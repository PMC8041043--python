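"""Risk grouping, exclusions, covariate adjustment, orientation, screening."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ebmflow import (
    CohortTable,
    adjust_covariates,
    assign_risk_groups,
    exclude_rbd_controls,
    fit_covariate_model,
    orient_markers,
    screen_markers_mannwhitney,
)
from ebmflow.errors import ValidationError


class TestRiskGroups:
    def test_threshold_is_inclusive(self, small_cohort):
        t = assign_risk_groups(small_cohort, 65.0)
        rg = t.data.set_index("subject_id")["risk_group"]
        assert rg["p2"] == "PDD-HR"      # onset 70.1
        assert rg["p3"] == "PDD-LR"      # onset 64.99: strictly below
        assert rg["p1"] == "PDD-LR"
        assert (rg[["c1", "c2", "c3"]] == "control").all()

    def test_idempotent(self, small_cohort):
        once = assign_risk_groups(small_cohort, 65.0)
        twice = assign_risk_groups(once, 65.0)
        pd.testing.assert_series_equal(once.data["risk_group"], twice.data["risk_group"])

    def test_missing_onset_raises_with_subject(self, small_cohort):
        small_cohort.data.loc[3, "age_at_onset"] = np.nan
        with pytest.raises(ValidationError, match="p1"):
            assign_risk_groups(small_cohort, 65.0)


class TestRbdExclusion:
    def test_cutoff_is_inclusive_and_patients_kept(self, small_cohort):
        t = exclude_rbd_controls(small_cohort, 5)
        ids = set(t.data["subject_id"])
        assert "c3" not in ids          # control, rbdsq 5 -> excluded
        assert {"c1", "c2"} <= ids      # rbdsq 1, 4 -> retained
        assert "p1" in ids              # patient, rbdsq 9 -> never removed

    def test_idempotent(self, small_cohort):
        once = exclude_rbd_controls(small_cohort, 5)
        twice = exclude_rbd_controls(once, 5)
        assert list(once.data["subject_id"]) == list(twice.data["subject_id"])

    def test_missing_rbdsq_control_retained(self, small_cohort):
        small_cohort.data.loc[0, "rbdsq"] = np.nan
        t = exclude_rbd_controls(small_cohort, 5)
        assert "c1" in set(t.data["subject_id"])


def _simulated_controls_cohort(n=200, seed=0, age_slope=0.5, sigma=0.01):
    rng = np.random.default_rng(seed)
    n_pat = 30
    age = np.concatenate([rng.uniform(50, 80, n), rng.uniform(50, 80, n_pat)])
    edu = np.concatenate([rng.uniform(8, 20, n), rng.uniform(8, 20, n_pat)])
    gender = rng.choice(["female", "male"], size=n + n_pat)
    y = 2.0 + age_slope * age + rng.normal(0, sigma, n + n_pat)
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n + n_pat)],
        "group": ["control"] * n + ["patient"] * n_pat,
        "age": age, "gender": gender, "education": edu,
        "age_at_onset": [np.nan] * n + [60.0] * n_pat,
        "rbdsq": 1, "m": y,
    })
    return CohortTable(df, {"m": "clinical_cognitive"})


class TestCovariateModel:
    def test_recovers_injected_age_slope(self):
        table = _simulated_controls_cohort()
        model = fit_covariate_model(table)
        age_coef = model.coefficients["m"][2]
        assert age_coef == pytest.approx(0.5, abs=0.02)

    def test_control_residuals_have_zero_mean(self):
        table = _simulated_controls_cohort(sigma=1.0)
        model = fit_covariate_model(table)
        adj = adjust_covariates(table, model)
        resid = adj.data.loc[adj.data["group"] == "control", "m"]
        assert abs(resid.mean()) < 1e-8

    def test_constant_marker_gives_zero_slopes(self):
        table = _simulated_controls_cohort(age_slope=0.0, sigma=0.0)
        table.data["m"] = 3.7
        model = fit_covariate_model(table)
        coefs = model.coefficients["m"]
        assert coefs[0] == pytest.approx(3.7, abs=1e-8)
        np.testing.assert_allclose(coefs[1:], 0.0, atol=1e-8)

    def test_adjustment_removes_age_correlation(self):
        table = _simulated_controls_cohort(n=300, seed=3, age_slope=0.5, sigma=1.0)
        model = fit_covariate_model(table)
        adj = adjust_covariates(table, model)
        ctl = adj.data[adj.data["group"] == "control"]
        assert abs(np.corrcoef(ctl["age"], ctl["m"])[0, 1]) < 0.05

    def test_adjustment_preserves_missingness_and_same_design_row(self):
        table = _simulated_controls_cohort(sigma=1.0)
        table.data.loc[5, "m"] = np.nan
        # give a patient the covariates of control row 0
        for c in ("age", "gender", "education"):
            table.data.loc[200, c] = table.data.loc[0, c]
        model = fit_covariate_model(table)
        adj = adjust_covariates(table, model)
        assert np.isnan(adj.data.loc[5, "m"])
        shift_control = table.data.loc[0, "m"] - adj.data.loc[0, "m"]
        shift_patient = table.data.loc[200, "m"] - adj.data.loc[200, "m"]
        assert shift_control == pytest.approx(shift_patient, rel=1e-10)

    def test_too_few_controls_raises(self):
        table = _simulated_controls_cohort(n=5)
        with pytest.raises(ValidationError, match="m"):
            fit_covariate_model(table)


class TestOrientation:
    @pytest.mark.parametrize(
        "controls, patients, expected",
        [
            ([0, 0, 1], [3, 4, 5], 1),
            ([28.6, 28.6, 28.6], [27.6, 27.6, 27.6], -1),  # MoCA-like decline
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1),          # tie -> +1
        ],
    )
    def test_sign_follows_patient_vs_control_mean(self, controls, patients, expected):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["control"] * 3 + ["patient"] * 3,
            "age": 60.0, "gender": "female", "education": 12.0,
            "m": controls + patients,
        })
        table = CohortTable(df, {"m": "vision"})
        assert orient_markers(table).sign["m"] == expected

    def test_all_missing_group_raises(self):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["control"] * 3 + ["patient"] * 3,
            "age": 60.0, "gender": "female", "education": 12.0,
            "m": [1.0, 2.0, 3.0, np.nan, np.nan, np.nan],
        })
        table = CohortTable(df, {"m": "vision"})
        with pytest.raises(ValidationError, match="m"):
            orient_markers(table)


def _screening_cohort(hr_values, control_values, marker="m"):
    n_hr, n_c = len(hr_values), len(control_values)
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n_hr + n_c)],
        "group": ["patient"] * n_hr + ["control"] * n_c,
        "risk_group": ["PDD-HR"] * n_hr + ["control"] * n_c,
        "age": 70.0, "gender": "male", "education": 12.0,
        marker: list(hr_values) + list(control_values),
    })
    return CohortTable(df, {marker: "qsm"})


def _exact_mannwhitney_p(hr, ctl):
    """Enumerate all rank assignments for the exact two-sided p-value."""
    pooled = np.asarray(list(hr) + list(ctl), dtype=float)
    n1 = len(hr)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(ctl)
    u_obs = min(u_obs, n1n2 - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        if min(u, n1n2 - u) <= u_obs:
            count += 1
        total += 1
    return count / total


class TestScreening:
    def test_exact_small_sample_not_retained_at_005(self):
        """U separating {4,5,6} from {1,2,3} gives exact two-sided p = 0.1."""
        table = _screening_cohort([4, 5, 6], [1, 2, 3])
        assert _exact_mannwhitney_p([4, 5, 6], [1, 2, 3]) == pytest.approx(0.1)
        assert screen_markers_mannwhitney(table, ["m"], alpha=0.05) == []
        assert screen_markers_mannwhitney(table, ["m"], alpha=0.11) == ["m"]

    def test_identical_constant_samples_not_retained(self):
        table = _screening_cohort([2.0] * 5, [2.0] * 5)
        assert screen_markers_mannwhitney(table, ["m"], alpha=0.05) == []

    def test_type_i_error_matches_alpha(self):
        """Null retention over 1000 markers stays within the binomial 99% CI."""
        rng = np.random.default_rng(42)
        n_hr, n_c, n_markers = 30, 30, 1000
        data = {"subject_id": [f"s{i}" for i in range(n_hr + n_c)],
                "group": ["patient"] * n_hr + ["control"] * n_c,
                "risk_group": ["PDD-HR"] * n_hr + ["control"] * n_c,
                "age": 70.0, "gender": "male", "education": 12.0}
        markers = {f"m{i}": rng.normal(size=n_hr + n_c) for i in range(n_markers)}
        table = CohortTable(
            pd.DataFrame({**data, **markers}),
            {m: "qsm" for m in markers},
        )
        retained = screen_markers_mannwhitney(table, list(markers), alpha=0.05)
        frac = len(retained) / n_markers
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_markers)
        assert abs(frac - 0.05) < half_width

    def test_small_group_dropped_with_warning(self):
        table = _screening_cohort([4.0], [1, 2, 3])
        assert screen_markers_mannwhitney(table, ["m"], alpha=0.05) == []
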