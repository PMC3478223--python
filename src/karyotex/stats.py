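"""Cohort statistics: patient aggregation, Mann-Whitney, Spearman, exact
binomial confidence intervals, and univariate / stratified Cox regression.

The nonparametric tests implement explicit exact branches for small samples
(full enumeration of labelings / permutations) and standard large-sample
approximations otherwise, so every p-value path is auditable.  The Cox
solver maximizes the Breslow partial likelihood for a single covariate by
Newton-Raphson, optionally stratified, and flags monotone-likelihood
divergence instead of silently returning a huge coefficient.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import PatientRecord
from .errors import ValidationError

#: Per-patient aggregation requires this many nuclei by default.
DEFAULT_MIN_NUCLEI = 100

#: |coefficient| beyond which the Cox likelihood is treated as monotone.
COX_DIVERGENCE_BOUND = 50.0

#: Largest combined sample size for the exact Mann-Whitney branch.
MW_EXACT_LIMIT = 16

#: Largest n for the exact Spearman permutation branch.
SPEARMAN_EXACT_LIMIT = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class CoxResult:
    coefficient: float
    se: float
    p_value: float
    stratified: bool
    converged: bool


@dataclass(frozen=True)
class ProportionCI:
    successes: int
    n: int
    level: float
    lower: float
    upper: float


# ---------------------------------------------------------------------------
# aggregation

def aggregate_patient(
    feature_rows: pd.DataFrame,
    min_nuclei: int = DEFAULT_MIN_NUCLEI,
    patient_id: str = "",
) -> dict[str, float]:
    """Per-feature median over one patient's nucleus rows.

    Medians use the usual convention: for an even count, the mean of the
    two central order statistics.
    """
    if len(feature_rows) < min_nuclei:
        raise ValidationError(
            f"patient {patient_id or '?'}: {len(feature_rows)} nuclei, "
            f"need >= {min_nuclei}"
        )
    numeric = feature_rows.select_dtypes(include=[np.number])
    return {col: float(numeric[col].median()) for col in numeric.columns}


def aggregate_cohort(
    features: pd.DataFrame, min_nuclei: int = DEFAULT_MIN_NUCLEI
) -> pd.DataFrame:
    """Median feature table, one row per patient (index = patient_id)."""
    out = {}
    for pid, rows in features.groupby("patient_id", sort=True):
        out[pid] = aggregate_patient(rows, min_nuclei=min_nuclei, patient_id=str(pid))
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("patient_id")


# ---------------------------------------------------------------------------
# Mann-Whitney

def _u_distribution(n_x: int, n_y: int) -> np.ndarray:
    """Null distribution of U_x (counts) over all C(n_x+n_y, n_x) labelings.

    Dynamic program on N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1):
    the last-ranked observation is either an x (preceded by all n y's,
    adding n precedence pairs) or a y.
    """
    dist = [np.array([1.0]) for _ in range(n_x + 1)]  # n = 0: U is always 0
    for n in range(1, n_y + 1):
        new: list[np.ndarray] = []
        for m in range(n_x + 1):
            counts = np.zeros(m * n + 1)
            counts[: m * (n - 1) + 1] += dist[m]
            if m > 0:
                counts[n:] += new[m - 1]
            new.append(counts)
        dist = new
    return dist[n_x]


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Midranks handle ties.  Exact enumeration (via the count distribution of
    U) when n_x + n_y <= 16 and no ties are present; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    n_x, n_y = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r_x = ranks[:n_x].sum()
    u_x = r_x - n_x * (n_x + 1) / 2.0
    has_ties = np.unique(combined).size < combined.size
    if n_x + n_y <= MW_EXACT_LIMIT and not has_ties:
        dist = _u_distribution(n_x, n_y)
        total = dist.sum()
        u_int = int(round(u_x))
        p_low = dist[: u_int + 1].sum() / total
        p_high = dist[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(statistic=float(u_x), p_value=float(p), method="mw_exact")
    mu = n_x * n_y / 2.0
    n = n_x + n_y
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n_x * n_y / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(statistic=float(u_x), p_value=1.0, method="mw_normal")
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(statistic=float(u_x), p_value=float(p), method="mw_normal")


# ---------------------------------------------------------------------------
# Spearman

def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (Pearson of midranks), two-sided p.

    Exact permutation p for n <= 8, t approximation with n-2 df otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValidationError("samples must be paired")
    n = x.size
    if n < 3:
        raise ValidationError("need n >= 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("constant input: rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n <= SPEARMAN_EXACT_LIMIT:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_spearman_rho(rx, np.array(perm))) >= target:
                count += 1
        p = count / total
        return TestResult(statistic=rho, p_value=float(p), method="spearman_exact")
    if abs(rho) >= 1.0:
        return TestResult(statistic=rho, p_value=0.0, method="spearman_t")
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(statistic=rho, p_value=float(p), method="spearman_t")


# ---------------------------------------------------------------------------
# exact binomial CI

def _bisect_binom(f, lo: float, hi: float, tol: float = 1e-10) -> float:
    """Bisection for the monotone tail equation f(p) = 0 on [lo, hi]."""
    flo = f(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if hi - lo < tol:
            return mid
        if (flo <= 0) == (fm <= 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def clopper_pearson_ci(successes: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    Bounds solve the binomial tail equations by bisection to 1e-10:
    lower: P(X >= successes | n, p) = alpha/2 (0 when successes = 0);
    upper: P(X <= successes | n, p) = alpha/2 (1 when successes = n).
    """
    if n <= 0 or not 0 <= successes <= n:
        raise ValidationError(f"invalid counts: {successes}/{n}")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must be in (0, 1)")
    alpha = 1.0 - level
    if successes == 0:
        lower = 0.0
    else:
        lower = _bisect_binom(
            lambda p: sps.binom.sf(successes - 1, n, p) - alpha / 2.0, 0.0, 1.0
        )
    if successes == n:
        upper = 1.0
    else:
        upper = _bisect_binom(
            lambda p: alpha / 2.0 - sps.binom.cdf(successes, n, p), 0.0, 1.0
        )
    return ProportionCI(successes=successes, n=n, level=level, lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# Cox regression (single covariate, Breslow ties, optional strata)

def _cox_terms(beta: float, times, events, z):
    """(loglik, gradient, information) of the Breslow partial likelihood."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    t_s, e_s, z_s = times[order], events[order], z[order]
    loglik = grad = info = 0.0
    s0 = s1 = s2 = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        for k in range(i, j):  # extend the risk set with this time's subjects
            w = math.exp(min(700.0, beta * z_s[k]))
            s0 += w
            s1 += w * z_s[k]
            s2 += w * z_s[k] ** 2
        d = int(e_s[i:j].sum())
        if d > 0:
            z_events = z_s[i:j][e_s[i:j] == 1].sum()
            loglik += beta * z_events - d * math.log(s0)
            mean = s1 / s0
            loglik_var = s2 / s0 - mean**2
            grad += z_events - d * mean
            info += d * loglik_var
        i = j
    return loglik, grad, info


def _newton_cox(groups, tol: float = 1e-8, max_iter: int = 50) -> tuple[float, float, bool]:
    """Maximize the summed partial likelihood over strata groups.

    The covariate is centered and scaled internally (the partial likelihood
    is invariant to location shifts and equivariant under scaling), which
    keeps exp() in range for covariates of any magnitude; the coefficient
    and information are returned on the original scale.  Monotone
    likelihoods are detected on the standardized scale (|beta| > 50).

    Returns (beta, information, converged).
    """
    pooled = np.concatenate([z for _, _, z in groups])
    center, scale = pooled.mean(), pooled.std()
    if scale == 0:
        raise ValidationError("no information for the covariate")
    groups = [(t, e, (z - center) / scale) for t, e, z in groups]
    beta = 0.0
    converged = False
    info = 0.0
    for _ in range(max_iter):
        grad = info = 0.0
        for times, events, z in groups:
            _, g, h = _cox_terms(beta, times, events, z)
            grad += g
            info += h
        if info <= 1e-12:
            if abs(beta) > 1e-6:
                # likelihood flattened out far from 0: monotone likelihood
                return beta / scale, info * scale**2, False
            raise ValidationError("no information for the covariate")
        step = grad / info
        # dampen wild steps far from the optimum
        step = max(-5.0, min(5.0, step))
        beta += step
        if abs(beta) > COX_DIVERGENCE_BOUND:
            return beta / scale, info * scale**2, False
        if abs(step) < tol:
            converged = True
            break
    return beta / scale, info * scale**2, converged


def _extract(patients: list[PatientRecord], covariate: str):
    times = np.array([p.time for p in patients], dtype=np.float64)
    events = np.array([p.event for p in patients], dtype=np.float64)
    z = np.array([p.value_of(covariate) for p in patients], dtype=np.float64)
    return times, events, z


def cox_univariate(patients: list[PatientRecord], covariate: str) -> CoxResult:
    """Single-covariate Cox proportional hazards fit (Breslow ties).

    Wald p-value; a coefficient running beyond +-50 marks a monotone
    likelihood and is returned with ``converged=False``.
    """
    times, events, z = _extract(patients, covariate)
    if events.sum() < 2:
        raise ValidationError("need at least 2 events")
    if np.unique(z).size == 1:
        raise ValidationError(f"covariate {covariate!r} is constant")
    beta, info, converged = _newton_cox([(times, events, z)])
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    p = min(1.0, 2.0 * sps.norm.sf(abs(beta) / se)) if converged else float("nan")
    return CoxResult(
        coefficient=float(beta), se=float(se), p_value=float(p),
        stratified=False, converged=converged,
    )


def cox_stratified(
    patients: list[PatientRecord], covariate: str, strata: str
) -> CoxResult:
    """Cox fit with the partial likelihood computed within strata."""
    times, events, z = _extract(patients, covariate)
    strata_vals = np.array([p.value_of(strata) for p in patients])
    groups = []
    informative = False
    for s in np.unique(strata_vals):
        sel = strata_vals == s
        if events[sel].sum() < 1:
            continue  # stratum without events contributes nothing
        groups.append((times[sel], events[sel], z[sel]))
        if np.unique(z[sel]).size > 1:
            informative = True
    if not groups:
        raise ValidationError("no stratum contains an event")
    if not informative:
        raise ValidationError(
            f"covariate {covariate!r} constant within every stratum"
        )
    beta, info, converged = _newton_cox(groups)
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    p = min(1.0, 2.0 * sps.norm.sf(abs(beta) / se)) if converged else float("nan")
    return CoxResult(
        coefficient=float(beta), se=float(se), p_value=float(p),
        stratified=True, converged=converged,
    )


# ---------------------------------------------------------------------------
# report tables

def cohort_report(
    patient_features: pd.DataFrame,
    patients: pd.DataFrame,
    grouping: str = "group",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group comparison and leukocyte correlation tables.

    ``patient_features``: one row per patient (medians); ``patients`` must
    carry the grouping column and ``leukocyte_count``, indexed or keyed by
    ``patient_id``.  Returns (comparison table, correlation table).
    """
    if "patient_id" in patients.columns:
        patients = patients.set_index("patient_id")
    merged = patient_features.join(patients[[grouping, "leukocyte_count"]], how="inner")
    if len(merged) != len(patient_features):
        missing = sorted(set(patient_features.index) - set(patients.index))
        raise ValidationError(f"patients table lacks ids: {missing}")
    levels = sorted(merged[grouping].unique())
    if len(levels) != 2:
        raise ValidationError(
            f"grouping {grouping!r} must have exactly 2 levels, got {levels}"
        )
    g1 = merged[merged[grouping] == levels[0]]
    g2 = merged[merged[grouping] == levels[1]]
    feature_cols = [c for c in patient_features.columns]
    comp_rows = []
    for col in feature_cols + ["leukocyte_count"]:
        a, b = g1[col].to_numpy(), g2[col].to_numpy()
        res = mann_whitney(a, b)
        comp_rows.append(
            {
                "feature": col,
                f"median_{levels[0]}": np.median(a),
                f"range_{levels[0]}": f"{a.min():.4g} - {a.max():.4g}",
                f"median_{levels[1]}": np.median(b),
                f"range_{levels[1]}": f"{b.min():.4g} - {b.max():.4g}",
                "p": res.p_value,
            }
        )
    corr_rows = []
    for col in feature_cols:
        res = spearman(merged[col].to_numpy(), merged["leukocyte_count"].to_numpy())
        corr_rows.append({"feature": col, "rho": res.statistic, "p": res.p_value})
    return pd.DataFrame(comp_rows), pd.DataFrame(corr_rows)
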