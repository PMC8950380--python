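from fractions import Fraction
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
import pytest

from synsurv import comsynsur
from synsurv.comsynsur import (
    SurvCurve,
    argmin_selection,
    brier_censored,
    censoring_km,
    ibs,
    km_estimate,
    partition,
    score_matrix,
    select_and_merge,
)


def curve(values):
    return SurvCurve(times=np.arange(len(values)), surv=np.asarray(values, dtype=float))


def oracle_product_limit(times, events, horizon, deaths_first_in_risk_set=False):
    """Independent exact product-limit in rational arithmetic.

    With ``deaths_first_in_risk_set`` the risk set at t excludes subjects
    whose event of the *other* kind (death) occurs at t, i.e. the reversed
    Kaplan-Meier convention for the censoring distribution.
    """
    surv = [Fraction(1)]
    s = Fraction(1)
    for t in range(1, horizon + 1):
        risk = sum(1 for ti in times if ti >= t)
        if deaths_first_in_risk_set:
            risk -= sum(1 for ti, e in zip(times, events) if ti == t and not e)
        d = sum(1 for ti, e in zip(times, events) if ti == t and e)
        if risk > 0:
            s *= 1 - Fraction(d, risk)
        surv.append(s)
    return [float(x) for x in surv]


class TestKaplanMeier:
    def test_all_censored(self):
        df = pd.DataFrame({"followup": [10] * 5, "exitus": ["survived"] * 5})
        assert np.allclose(km_estimate(df).surv, 1.0)

    def test_hand_product_limit(self, toy_subset):
        km = km_estimate(toy_subset)
        assert km.at(2) == pytest.approx(0.75)
        assert km.at(5) == pytest.approx(0.375)

    def test_all_die_year_one(self):
        df = pd.DataFrame({"followup": [1, 1], "exitus": ["died", "died"]})
        assert km_estimate(df).at(1) == 0.0

    def test_empty_subset(self):
        with pytest.raises(ValueError):
            km_estimate(pd.DataFrame({"followup": [], "exitus": []}))

    def test_monotone_and_bounded(self, cohort_frame):
        km = km_estimate(cohort_frame)
        assert km.surv[0] == 1.0
        assert np.all(np.diff(km.surv) <= 0)
        assert np.all((km.surv >= 0) & (km.surv <= 1))


class TestCensoringKM:
    def test_no_censoring(self):
        df = pd.DataFrame({"followup": [1, 2, 3], "exitus": ["died"] * 3})
        g = censoring_km(df)
        assert np.allclose(g.surv, 1.0)

    def test_hand_reversed_product_limit(self, toy_subset):
        g = censoring_km(toy_subset)
        assert g.at(3) == pytest.approx(2 / 3)

    def test_all_censored_year_one(self):
        df = pd.DataFrame({"followup": [1, 1], "exitus": ["survived"] * 2})
        assert censoring_km(df).at(1) == 0.0


def test_exhaustive_product_limit_equivalence():
    """Both estimators match the exact oracle on every <=6-record cohort
    with times 1..4 (exhaustive over multisets)."""
    options = [(t, e) for t in (1, 2, 3, 4) for e in (True, False)]
    checked = 0
    for n in range(1, 7):
        for combo in combinations_with_replacement(options, n):
            times = [t for t, _ in combo]
            events = [e for _, e in combo]
            df = pd.DataFrame(
                {
                    "followup": times,
                    "exitus": ["died" if e else "survived" for e in events],
                }
            )
            km = km_estimate(df)
            expected = oracle_product_limit(times, events, 10)
            assert np.allclose(km.surv, expected, atol=1e-12)
            g = censoring_km(df)
            censor_events = [not e for e in events]
            expected_g = oracle_product_limit(
                times, censor_events, 10, deaths_first_in_risk_set=True
            )
            assert np.allclose(g.surv, expected_g, atol=1e-12)
            checked += 1
    assert checked == 3002  # all multisets of size 1..6 over 8 options


def test_km_cross_checked_against_lifelines():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(5, 60)
        times = rng.integers(1, 11, size=n)
        died = rng.random(n) < 0.5
        df = pd.DataFrame(
            {"followup": times, "exitus": np.where(died, "died", "survived")}
        )
        km = km_estimate(df)
        fitter = KaplanMeierFitter().fit(times, died)
        reference = fitter.predict(np.arange(11)).to_numpy()
        assert np.allclose(km.surv, reference, atol=1e-12)


def test_censoring_km_cross_checked_against_sksurv():
    from sksurv.nonparametric import CensoringDistributionEstimator
    from sksurv.util import Surv

    rng = np.random.default_rng(1)
    for _ in range(50):
        n = rng.integers(5, 60)
        times = rng.integers(1, 11, size=n)
        died = rng.random(n) < 0.5
        df = pd.DataFrame(
            {"followup": times, "exitus": np.where(died, "died", "survived")}
        )
        g = censoring_km(df)
        est = CensoringDistributionEstimator().fit(Surv.from_arrays(died, times))
        grid = np.arange(1, times.max() + 1)
        reference = est.predict_proba(grid)
        assert np.allclose(g.surv[1 : times.max() + 1], reference, atol=1e-12)


class TestBrier:
    def test_perfect_prediction_zero(self):
        df = pd.DataFrame({"followup": [10] * 4, "exitus": ["survived"] * 4})
        assert brier_censored(df, curve([1.0] * 11), 5) == 0.0

    def test_all_dead_perfectly_predicted(self):
        df = pd.DataFrame({"followup": [1, 1], "exitus": ["died", "died"]})
        pred = curve([1.0] + [0.0] * 10)
        assert brier_censored(df, pred, 5) == 0.0

    def test_three_subject_hand_example(self):
        df = pd.DataFrame(
            {"followup": [1, 4, 4], "exitus": ["died", "survived", "survived"]}
        )
        pred = curve([1.0] + [0.8] * 10)
        # (0.64 + 0.04 + 0.04) / 3 with G == 1
        assert brier_censored(df, pred, 2) == pytest.approx(0.24)

    def test_cross_checked_against_sksurv(self):
        # sksurv weighs deaths by G at the death time instead of the left
        # limit G(t-); the fixture keeps death and censoring times disjoint
        # (deaths odd, censorings even) so the two conventions coincide
        from sksurv.metrics import brier_score as sks_brier
        from sksurv.util import Surv

        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(20, 80))
            died = rng.random(n) < 0.6
            times = np.where(
                died,
                rng.choice([1, 3, 5, 7, 9], size=n),
                rng.choice([2, 4, 6, 8, 10], size=n),
            )
            df = pd.DataFrame(
                {"followup": times, "exitus": np.where(died, "died", "survived")}
            )
            surv = np.concatenate([[1.0], np.linspace(0.95, 0.4, 10)])
            pred = curve(surv)
            y = Surv.from_arrays(died, times)
            eval_times = np.arange(1, times.max())
            estimate = np.tile(surv[eval_times], (n, 1))
            _, reference = sks_brier(y, y, estimate, eval_times)
            mine = [brier_censored(df, pred, t) for t in eval_times]
            assert np.allclose(mine, reference, atol=1e-10)


class TestIBS:
    def test_constant_bs_integrates_to_constant(self, monkeypatch, toy_subset):
        monkeypatch.setattr(comsynsur, "brier_censored", lambda *a, **k: 0.17)
        assert ibs(toy_subset, curve([1.0] * 11)) == pytest.approx(0.17)

    def test_linear_bs_integrates_to_half(self, monkeypatch, toy_subset):
        monkeypatch.setattr(
            comsynsur, "brier_censored", lambda subset, pred, t, **k: t / 10
        )
        assert ibs(toy_subset, curve([1.0] * 11)) == pytest.approx(0.5)

    def test_fine_grid_oracle(self):
        df = pd.DataFrame(
            {"followup": [1, 4, 4], "exitus": ["died", "survived", "survived"]}
        )
        pred = curve([1.0] + [0.8] * 10)
        grid = np.arange(11)
        bs = np.array([brier_censored(df, pred, t) for t in grid])
        fine = np.linspace(0, 10, 100001)
        oracle = np.trapezoid(np.interp(fine, grid, bs), fine) / 10
        assert ibs(df, pred) == pytest.approx(oracle, abs=1e-9)

    def test_in_unit_interval(self, cohort_frame):
        pred = km_estimate(cohort_frame)
        value = ibs(cohort_frame, pred)
        assert 0.0 <= value <= 1.0

    def test_duplication_invariance(self, cohort_frame):
        subset = cohort_frame.head(200)
        doubled = pd.concat([subset, subset], ignore_index=True)
        pred = curve([1.0] + [0.9] * 10)
        assert ibs(doubled, pred) == pytest.approx(ibs(subset, pred), abs=1e-12)


class TestPartition:
    def test_three_by_three(self, cohort_frame):
        parts = partition(cohort_frame)
        assert len(parts) == 9
        assert sum(len(p) for p in parts.values()) == len(cohort_frame)

    def test_single_stratum_is_whole_cohort(self, cohort_frame):
        parts = partition(cohort_frame, age_groups=["<=49", "50-59", "60-74"], stages=["I", "II", "III"])
        whole = partition(
            cohort_frame.assign(age_group="<=49", stage="I"),
            age_groups=["<=49"],
            stages=["I"],
        )
        assert len(whole) == 1
        assert len(next(iter(whole.values()))) == len(cohort_frame)
        assert len(parts) == 9

    def test_empty_strata_allowed(self, cohort_frame):
        no_stage3 = cohort_frame[cohort_frame["stage"] != "III"]
        parts = partition(no_stage3)
        assert all(len(parts[(g, "III")]) == 0 for g in ("<=49", "50-59", "60-74"))


class TestScoreMatrix:
    def test_single_candidate_selected_everywhere(self, cohort_frame):
        matrix = score_matrix(cohort_frame, {"only": cohort_frame})
        assert all(sel == "only" for sel in matrix.selection)

    def test_shape_and_range(self, cohort_frame):
        synds = {
            "A": cohort_frame.sample(frac=1.0, random_state=0),
            "B": cohort_frame.sample(n=1500, random_state=1),
        }
        matrix = score_matrix(cohort_frame, synds)
        assert matrix.values.shape == (9, 2)
        valid = matrix.values[~np.isnan(matrix.values)]
        assert np.all((valid >= 0) & (valid <= 1))

    def test_cohort_as_own_candidate_is_minimal(self):
        # the cohort's own KM curve is pointwise the weighted-Brier optimum
        # wherever survivors remain, so among candidates whose curves differ
        # it must win every stratum; scored to t* = 9 because at the maximal
        # follow-up time no survivors are left and the score degenerates
        from synsurv.cohort_io import cohort_to_frame
        from synsurv.synth_registry import RegistryConfig, generate_cohort

        config = RegistryConfig(n_patients=3000, seed=21, dropout_hazard=0.05)
        frame = cohort_to_frame(generate_cohort(config))
        distorted = frame.copy()
        distorted["exitus"] = "died"
        matrix = score_matrix(
            frame, {"self": frame, "bad": distorted}, t_star=9
        )
        for row, sel in zip(matrix.values, matrix.selection):
            if sel is None:
                continue
            assert row[0] <= row[1] + 1e-12
            assert sel == "self"

    def test_tie_break_first_label(self, cohort_frame):
        matrix = score_matrix(
            cohort_frame, {"first": cohort_frame, "second": cohort_frame.copy()}
        )
        assert all(sel == "first" for sel in matrix.selection)

    def test_empty_synthetic_stratum_never_selected(self, cohort_frame):
        crippled = cohort_frame[cohort_frame["stage"] != "III"]
        matrix = score_matrix(cohort_frame, {"full": cohort_frame, "partial": crippled})
        for (group, stage), sel, row in zip(
            matrix.strata, matrix.selection, matrix.values
        ):
            if stage == "III":
                assert np.isnan(row[1])
                assert sel == "full"


class TestSelectAndMerge:
    def test_merge_sizes_and_provenance(self, cohort_frame):
        synds = {
            "A": cohort_frame.sample(frac=1.0, random_state=0),
            "B": cohort_frame.sample(n=1500, random_state=1),
        }
        matrix = score_matrix(cohort_frame, synds)
        combined = select_and_merge(matrix, synds)
        expected = 0
        parts = {label: partition(df) for label, df in synds.items()}
        for stratum, sel in zip(matrix.strata, matrix.selection):
            expected += len(parts[sel][stratum])
        assert len(combined) == expected
        assert set(combined["source_model"]) <= set(synds)
        # every record traceable to exactly one (stratum, model)
        grouped = combined.groupby(
            ["stratum_age_group", "stratum_stage"]
        )["source_model"].nunique()
        assert (grouped == 1).all()


def test_argmin_selection_tie_break():
    values = np.array([[0.2, 0.2, 0.2], [0.3, 0.1, 0.1]])
    assert argmin_selection(values, ["GMK1", "GMTEST", "GMAIC"]) == ["GMK1", "GMTEST"]
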