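import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from karyotex.datatypes import PatientRecord
from karyotex.errors import ValidationError
from karyotex.stats import (
    aggregate_cohort,
    aggregate_patient,
    clopper_pearson_ci,
    cohort_report,
    cox_stratified,
    cox_univariate,
    mann_whitney,
    spearman,
)


# ---------------------------------------------------------------------------
# aggregation

class TestAggregatePatient:
    def test_odd_count_median(self):
        rows = pd.DataFrame({"fd": [2.10, 2.12, 2.14]})
        assert aggregate_patient(rows, min_nuclei=3)["fd"] == 2.12

    def test_even_count_convention(self):
        rows = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        assert aggregate_patient(rows, min_nuclei=4)["x"] == 2.5

    def test_too_few_nuclei_names_patient(self):
        rows = pd.DataFrame({"x": np.arange(99.0)})
        with pytest.raises(ValidationError, match="p7"):
            aggregate_patient(rows, min_nuclei=100, patient_id="p7")

    def test_cohort_aggregation(self):
        frame = pd.DataFrame(
            {
                "patient_id": ["a"] * 3 + ["b"] * 3,
                "x": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
            }
        )
        out = aggregate_cohort(frame, min_nuclei=3)
        assert out.loc["a", "x"] == 2.0
        assert out.loc["b", "x"] == 20.0


# ---------------------------------------------------------------------------
# Mann-Whitney

def brute_force_mw_p(x, y):
    """Enumeration oracle over all C(n_x+n_y, n_x) labelings (no ties)."""
    x, y = list(x), list(y)
    n_x = len(x)
    combined = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - n_x * (n_x + 1) / 2
    us = []
    for subset in itertools.combinations(range(len(combined)), n_x):
        r = sum(i + 1 for i in subset)
        us.append(r - n_x * (n_x + 1) / 2)
    us = np.array(us)
    p_low = (us <= u_obs + 1e-9).mean()
    p_high = (us >= u_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestMannWhitney:
    def test_spec_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "mw_exact"

    def test_identical_samples(self):
        x = [1.0, 2.0, 2.0, 3.0] * 5
        assert mann_whitney(x, x).p_value == 1.0

    def test_empty_sample(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_x = int(rng.integers(2, 7))
        n_y = int(rng.integers(2, 7))
        pool = rng.permutation(100)[: n_x + n_y].astype(float)  # distinct values
        x, y = pool[:n_x], pool[n_x:]
        res = mann_whitney(x, y)
        assert res.method == "mw_exact"
        assert res.p_value == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_normal_branch_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=25)
            y = rng.normal(0.4, size=30)
            res = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tie_correction_applied(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, 20).astype(float)
        y = rng.integers(1, 5, 22).astype(float)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Spearman

def brute_force_spearman(x, y):
    """Oracle via the d^2 formula and full permutation enumeration."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    d2 = ((rx - ry) ** 2).sum()
    rho = 1 - 6 * d2 / (n * (n**2 - 1))
    count = total = 0
    for perm in itertools.permutations(ry):
        d2p = ((rx - np.array(perm)) ** 2).sum()
        rho_p = 1 - 6 * d2p / (n * (n**2 - 1))
        total += 1
        if abs(rho_p) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_spec_example_rho(self):
        res = spearman([1, 2, 3], [3, 1, 2])
        assert res.statistic == pytest.approx(-0.5)  # 1 - 6*6/(3*8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 2], [3, 4])

    @given(st.integers(0, 10_000))
    @settings(max_examples=10, deadline=None)
    def test_exact_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        x = rng.permutation(50)[:n].astype(float)
        y = rng.permutation(50)[:n].astype(float)
        res = spearman(x, y)
        rho, p = brute_force_spearman(x, y)
        assert res.method == "spearman_exact"
        assert res.statistic == pytest.approx(rho, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_t_branch_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Clopper-Pearson

class TestClopperPearson:
    def test_2_of_19_printed_values(self):
        ci = clopper_pearson_ci(2, 19, 0.95)
        assert round(ci.lower, 3) == 0.013
        assert round(ci.upper, 3) == 0.331
        assert round(ci.lower, 4) == 0.0130
        assert round(ci.upper, 4) == 0.3314

    def test_4_of_19_printed_values(self):
        ci = clopper_pearson_ci(4, 19, 0.95)
        assert round(ci.lower, 4) == 0.0605
        assert round(ci.upper, 4) == 0.4557

    def test_boundary_rules(self):
        assert clopper_pearson_ci(0, 10).lower == 0.0
        assert clopper_pearson_ci(10, 10).upper == 1.0

    def test_matches_beta_quantiles(self):
        # independent closed form for the same interval
        for s, n in ((1, 7), (3, 11), (9, 20)):
            ci = clopper_pearson_ci(s, n, 0.95)
            assert ci.lower == pytest.approx(sps.beta.ppf(0.025, s, n - s + 1), abs=1e-8)
            assert ci.upper == pytest.approx(sps.beta.ppf(0.975, s + 1, n - s), abs=1e-8)

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            clopper_pearson_ci(5, 4)
        with pytest.raises(ValidationError):
            clopper_pearson_ci(1, 10, level=1.5)

    def test_coverage_conservative(self):
        # exact intervals cover the true p in >= 95% of 2000 simulations
        n, p_true = 19, 0.1
        intervals = [clopper_pearson_ci(s, n, 0.95) for s in range(n + 1)]
        rng = np.random.default_rng(0)
        draws = rng.binomial(n, p_true, size=2000)
        covered = sum(
            intervals[s].lower <= p_true <= intervals[s].upper for s in draws
        )
        assert covered / 2000 >= 0.95


# ---------------------------------------------------------------------------
# Cox regression

def make_patients(times, events, z, strata=None):
    patients = []
    for i, (t, e, zi) in enumerate(zip(times, events, z)):
        cov = {"z": float(zi)}
        if strata is not None:
            cov["s"] = float(strata[i])
        patients.append(
            PatientRecord(patient_id=f"p{i}", covariates=cov, time=float(t), event=int(e))
        )
    return patients


def breslow_loglik(beta, times, events, z):
    """Grid-search oracle: direct Breslow partial log-likelihood."""
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        d_idx = np.flatnonzero((times == t) & (events == 1))
        risk = np.flatnonzero(times >= t)
        ll += beta * z[d_idx].sum() - len(d_idx) * math.log(
            np.exp(beta * z[risk]).sum()
        )
    return ll


class TestCoxUnivariate:
    def test_grid_search_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        z = np.array([1.0, 0.0, 1.0, 0.0])
        res = cox_univariate(make_patients(times, events, z), "z")
        grid = np.arange(-5, 5, 1e-3)
        lls = [breslow_loglik(b, times, events, z) for b in grid]
        b_grid = grid[int(np.argmax(lls))]
        assert res.coefficient == pytest.approx(b_grid, abs=2e-3)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(1, 30)
        events = np.ones(30, dtype=int)
        z = rng.normal(size=30)
        r1 = cox_univariate(make_patients(times, events, z), "z")
        r2 = cox_univariate(make_patients(times, events, 2 * z), "z")
        assert r2.coefficient == pytest.approx(r1.coefficient / 2, abs=1e-6)

    def test_monotone_likelihood_flagged(self):
        # group 1's events all precede any group-0 exit
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.array([1, 1, 1, 1, 1, 1])
        z = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = cox_univariate(make_patients(times, events, z), "z")
        assert not res.converged

    def test_constant_covariate_rejected(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 1, 1])
        with pytest.raises(ValidationError):
            cox_univariate(make_patients(times, events, np.ones(3)), "z")

    def test_needs_two_events(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 0, 0])
        with pytest.raises(ValidationError):
            cox_univariate(make_patients(times, events, np.array([1.0, 0.0, 1.0])), "z")

    def test_hazard_ratio_recovery(self):
        # two-group exponential data with HR = e: recover B = 1 +- 0.25
        coefs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = (np.arange(200) % 2).astype(float)
            times = rng.exponential(1.0, 200) / np.exp(z)
            events = (times <= 2.0).astype(int)
            times = np.minimum(times, 2.0)
            res = cox_univariate(make_patients(times, events, z), "z")
            coefs.append(res.coefficient)
        assert np.mean(coefs) == pytest.approx(1.0, abs=0.25)


class TestCoxStratified:
    def test_single_stratum_reduces_to_univariate(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(1, 40)
        events = rng.integers(0, 2, 40)
        events[:5] = 1
        z = rng.normal(size=40)
        patients = make_patients(times, events, z, strata=np.ones(40))
        uni = cox_univariate(patients, "z")
        strat = cox_stratified(patients, "z", "s")
        assert strat.coefficient == pytest.approx(uni.coefficient, abs=1e-10)
        assert strat.stratified

    def test_constant_within_strata_rejected(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        z = np.array([1.0, 1.0, 0.0, 0.0])
        patients = make_patients(times, events, z, strata=z)  # covariate == stratum
        with pytest.raises(ValidationError):
            cox_stratified(patients, "z", "s")

    def test_stratification_removes_confounded_signal(self):
        # covariate = noisy copy of the stratum label; the stratum drives
        # the hazard (ratio 4), so the covariate is only significant
        # before stratification
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            strata = (np.arange(40) % 2).astype(float)
            z = strata + rng.normal(0, 0.3, 40)
            times = rng.exponential(1.0, 40) / 4.0**strata
            events = (times <= 1.5).astype(int)
            times = np.minimum(times, 1.5)
            if events.sum() < 2:
                continue
            patients = make_patients(times, events, z, strata=strata)
            uni = cox_univariate(patients, "z")
            strat = cox_stratified(patients, "z", "s")
            if uni.converged and strat.converged and uni.p_value < 0.05 < strat.p_value:
                hits += 1
        assert hits >= 16  # >= 80% of seeds

    def test_ordering_invariance(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(1, 30)
        events = rng.integers(0, 2, 30)
        events[:4] = 1
        z = rng.normal(size=30)
        strata = (np.arange(30) % 2).astype(float)
        patients = make_patients(times, events, z, strata=strata)
        shuffled = [patients[i] for i in rng.permutation(30)]
        a = cox_stratified(patients, "z", "s")
        b = cox_stratified(shuffled, "z", "s")
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-10)


# ---------------------------------------------------------------------------
# cohort report

def _report_inputs(rng, n_per_group=10, fd_leuko_coupling=0.0):
    rows = {}
    patients = []
    for g, label in ((0, "a"), (1, "b")):
        for i in range(n_per_group):
            pid = f"{label}{i}"
            leuko = float(rng.uniform(2, 50))
            rows[pid] = {
                "entropy": rng.normal(7 + 0.5 * g, 0.2),
                "fd": rng.normal(2.1, 0.02) + fd_leuko_coupling * (leuko - 26) / 50,
            }
            patients.append(
                {"patient_id": pid, "group": g, "leukocyte_count": leuko,
                 "time": float(rng.uniform(1, 30)), "event": int(rng.integers(0, 2))}
            )
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("patient_id"), pd.DataFrame(patients)


class TestCohortReport:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        medians, patients = _report_inputs(rng)
        comparison, correlations = cohort_report(medians, patients)
        assert len(comparison) == 3  # 2 features + leukocyte row
        assert set(correlations["feature"]) == {"entropy", "fd"}
        assert comparison.notna().all().all()

    def test_more_than_two_groups_rejected(self):
        rng = np.random.default_rng(1)
        medians, patients = _report_inputs(rng)
        patients.loc[0, "group"] = 2
        with pytest.raises(ValidationError):
            cohort_report(medians, patients)

    def test_id_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        medians, patients = _report_inputs(rng)
        with pytest.raises(ValidationError):
            cohort_report(medians, patients.iloc[:-3])

    def test_negative_fd_leukocyte_dependence(self):
        rng = np.random.default_rng(3)
        medians, patients = _report_inputs(rng, fd_leuko_coupling=-0.1)
        _, correlations = cohort_report(medians, patients)
        rho = correlations.set_index("feature").loc["fd", "rho"]
        assert rho < 0

    def test_null_p_values_uniform(self):
        # identically drawn groups: Mann-Whitney p approximately U(0,1)
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            medians, patients = _report_inputs(rng)
            medians["entropy"] = rng.normal(7, 0.2, len(medians))  # no group effect
            comparison, _ = cohort_report(medians, patients)
            pvals.append(
                comparison.set_index("feature").loc["entropy", "p"]
            )
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
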