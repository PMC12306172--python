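"""Cluster-wise contingency comparisons and multivariate logistic regression.

The association analysis asks whether behavioural covariates differ between
the two enterotype clusters: level x cluster contingency tables are tested
by chi-square (no continuity correction) or Fisher's exact test, and a
binary logistic model (Segatella-dominated cluster = 1) with
treatment-coded behavioural covariates plus age and BMI yields adjusted
odds ratios with Wald 95% intervals.

The logistic fit is plain maximum likelihood by iteratively reweighted
least squares with an explicit complete-separation flag: a level that is
empty in one cluster sends its coefficient to infinity, and the fit reports
that rather than returning a silently diverged estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDOM_LEVELS, PARTNER_LEVELS, SEX_ROLE_LEVELS

Z_975 = stats.norm.ppf(0.975)  # 1.959964...

DEFAULT_REFERENCES = {
    "sex_role": "insertive_only",
    "partners": "<=1",
    "condom": "always",
}
CATEGORY_LEVELS = {
    "sex_role": SEX_ROLE_LEVELS,
    "partners": PARTNER_LEVELS,
    "condom": CONDOM_LEVELS,
}
DEFAULT_COVARIATES = (
    "sex_role", "partners", "condom",
    "commercial_sex", "group_sex", "std", "illicit_drug",
    "age", "bmi",
)


@dataclass
class ContingencyResult:
    variable: str
    counts: np.ndarray
    method: str          # "chi_square" or "fisher_exact"
    statistic: float
    p_value: float
    df: int | None = None


@dataclass
class LogisticFit:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    n_iterations: int
    separation: bool = False

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coefficients - Z_975 * self.standard_errors)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coefficients + Z_975 * self.standard_errors)

    @property
    def p_values(self) -> np.ndarray:
        z = self.coefficients / self.standard_errors
        return 2 * stats.norm.sf(np.abs(z))


def describe_cohort(metadata: pd.DataFrame,
                    variables: tuple[str, ...] = (
                        "sex_role", "partners", "condom", "commercial_sex",
                        "group_sex", "std", "illicit_drug"),
                    ) -> pd.DataFrame:
    """Cohort descriptives: per categorical level, count and percentage of
    the cohort (percentage rounded to 1 decimal)."""
    n = len(metadata)
    rows = []
    for var in variables:
        counts = metadata[var].value_counts()
        for level, c in counts.items():
            rows.append({
                "variable": var,
                "level": level,
                "count": int(c),
                "percent": round(100.0 * c / n, 1),
            })
    return pd.DataFrame(rows)


def _fisher_rx2_pvalue(counts: np.ndarray) -> float:
    """Exact conditional test for an r x 2 table by full enumeration of
    tables with the observed margins (point-probability ordering)."""
    from math import comb

    counts = np.asarray(counts, dtype=np.int64)
    row_sums = counts.sum(axis=1)
    col0 = int(counts[:, 0].sum())
    # P(table | margins) = prod_i C(row_i, a_i) / C(N, col0); two-sided p
    # sums the probability of every table no more probable than observed.
    denom = comb(int(row_sums.sum()), col0)
    obs_p = np.prod([comb(int(r), int(a)) for r, a in zip(row_sums, counts[:, 0])]) / denom

    ranges = [range(int(r) + 1) for r in row_sums]
    p = 0.0
    for combo in product(*ranges):
        if sum(combo) != col0:
            continue
        tp = np.prod([comb(int(r), int(a)) for r, a in zip(row_sums, combo)]) / denom
        if tp <= obs_p * (1 + 1e-9):
            p += tp
    return min(p, 1.0)


def contingency_test(counts, variable: str = "", method: str = "auto") -> ContingencyResult:
    """Test independence of a levels x clusters integer table.

    ``method='auto'`` uses chi-square without continuity correction unless
    some expected cell is below 5, in which case Fisher's exact test is
    used (2x2 hypergeometric; larger tables by exhaustive enumeration when
    the total is at most 30, else chi-square with a warning is kept).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal row or column")

    expected = stats.contingency.expected_freq(counts)
    use_fisher = method == "fisher" or (method == "auto" and (expected < 5).any())
    if use_fisher:
        if counts.shape == (2, 2):
            res = stats.fisher_exact(counts)
            return ContingencyResult(variable, counts, "fisher_exact",
                                     float(res[0]), float(res[1]))
        if counts.sum() <= 30:
            p = _fisher_rx2_pvalue(counts)
            return ContingencyResult(variable, counts, "fisher_exact",
                                     float("nan"), p)
        # exact test infeasible at this size; fall through to chi-square
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return ContingencyResult(variable, counts, "chi_square", float(chi2),
                             float(p), df=int(df))


def cluster_contingency(metadata: pd.DataFrame, labels: pd.Series,
                        variables: tuple[str, ...] = (
                            "sex_role", "partners", "condom", "commercial_sex",
                            "group_sex", "std", "illicit_drug"),
                        method: str = "auto") -> list[ContingencyResult]:
    """One contingency test per categorical variable against cluster label."""
    labels = pd.Series(labels).loc[metadata.index]
    out = []
    for var in variables:
        tab = pd.crosstab(metadata[var], labels)
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue  # variable (or labelling) degenerate in this cohort
        out.append(contingency_test(tab.to_numpy(), variable=var, method=method))
    return out


def build_design(metadata: pd.DataFrame,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                 references: dict[str, str] | None = None
                 ) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept.

    Categorical covariates are dummy-coded against their reference level
    (insertive_only, <=1 partners, always-condom by default); booleans
    become 0/1; age and BMI pass through unscaled. Constant columns are
    rejected as non-identifiable.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    cols: list[np.ndarray] = [np.ones(len(metadata))]
    names: list[str] = ["intercept"]
    for var in covariates:
        if metadata[var].isna().any():
            raise ValueError(f"missing values in covariate {var!r}")
        if var in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[var]
            ref = refs[var]
            if ref not in levels:
                raise ValueError(f"unknown reference level {ref!r} for {var!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((metadata[var] == lev).to_numpy(float))
                names.append(f"{var}[{lev}]")
        elif metadata[var].dtype == bool:
            cols.append(metadata[var].to_numpy(float))
            names.append(var)
        else:
            cols.append(metadata[var].to_numpy(float))
            names.append(var)
    X = np.column_stack(cols)
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate column {name!r} is constant (non-identifiable)")
    return X, names


def fit_logistic(y, X, terms: list[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood binary logistic regression by IRLS.

    Converges when the maximum absolute score (gradient) falls below
    ``tol``. Wald standard errors come from the inverse observed
    information. Complete or quasi-complete separation is detected from
    diverging coefficients and reported on the returned fit instead of
    being raised, so callers can surface the affected terms.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class")
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than samples")
    if terms is None:
        terms = [f"x{j}" for j in range(p)]

    beta = np.zeros(p)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        xtwx = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        # damp huge steps to keep the iteration stable near separation
        if np.max(np.abs(step)) > 50:
            step *= 50 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(beta)) > 15:  # odds ratio beyond e^15: separated
            separation = True
            break

    if converged and np.max(np.abs(beta)) > 15:
        separation = True  # score vanished only because the link saturated

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separation = True
    return LogisticFit(list(terms), beta, se, converged and not separation,
                       it, separation=separation)


def or_table(fit: LogisticFit, decimals: int = 3) -> pd.DataFrame:
    """Forest-plot-ready odds-ratio table for all non-intercept terms."""
    if not fit.converged:
        raise ValueError("fit did not converge" +
                         (" (separation detected)" if fit.separation else ""))
    rows = []
    for j, term in enumerate(fit.terms):
        if term == "intercept":
            continue
        rows.append({
            "term": term,
            "odds_ratio": round(float(fit.odds_ratios[j]), decimals),
            "ci_low": round(float(fit.ci_low[j]), decimals),
            "ci_high": round(float(fit.ci_high[j]), decimals),
            "p_value": round(float(fit.p_values[j]), decimals),
        })
    return pd.DataFrame(rows)
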