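"""The analysis battery: contingency tables with Pearson chi-square,
t-test / one-way ANOVA group comparison, binary and multinomial logistic
regression with odds ratios and Wald 95% CIs, and binned mean-FI blood
pressure profiles.

All operations take a tidy :class:`pandas.DataFrame` (one row per subject)
and use complete-case analysis — rows missing the variables involved are
dropped, with the n actually used reported in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

Z_95 = 1.96  # normal quantile used for the Wald 95% interval


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation in a logistic fit."""


class ConvergenceError(RuntimeError):
    """Maximum-likelihood fit did not converge."""


# ---------------------------------------------------------------------------
# contingency tables

def crosstab(df: pd.DataFrame, row_factor: str, col_factor: str) -> pd.DataFrame:
    """Exact integer counts of ``row_factor`` x ``col_factor``.

    Rows with either factor undefined are excluded; the count of excluded
    rows is stored in ``table.attrs['n_undefined']``.  Tables smaller than
    2x2 are rejected.
    """
    sub = df[[row_factor, col_factor]].dropna()
    table = pd.crosstab(sub[row_factor], sub[col_factor])
    if table.size == 0:
        raise ValueError("empty contingency table")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, "
                         f"got {table.shape[0]}x{table.shape[1]}")
    table.attrs["n_undefined"] = len(df) - len(sub)
    return table


def chi_square(table) -> tuple:
    """Pearson chi-square test of independence (no continuity correction).

    Returns ``(statistic, df, p)``; raises if any expected count is zero
    (collapse sparse categories first).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("negative counts")
    expected = sps.contingency.expected_freq(obs)
    if (expected <= 0).any():
        raise ValueError("zero expected count: collapse sparse categories")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# continuous group comparison

@dataclass
class GroupComparison:
    groups: list
    means: dict
    sds: dict
    ns: dict
    statistic: float
    p: float
    test: str  # "t" (pooled-variance) or "anova"


def group_compare_continuous(df: pd.DataFrame, value: str,
                             factor: str) -> GroupComparison:
    """Mean +/- SD per group; unpaired pooled-variance t-test for two
    groups, one-way ANOVA for three or more."""
    sub = df[[value, factor]].dropna()
    groups = sorted(sub[factor].unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [sub.loc[sub[factor] == g, value].to_numpy(dtype=float)
               for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    if len(groups) == 2:
        stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=True)
        test = "t"
    else:
        stat, p = sps.f_oneway(*samples)
        test = "anova"
    return GroupComparison(
        groups=list(groups),
        means={g: float(s.mean()) for g, s in zip(groups, samples)},
        sds={g: float(s.std(ddof=1)) for g, s in zip(groups, samples)},
        ns={g: int(len(s)) for g, s in zip(groups, samples)},
        statistic=float(stat), p=float(p), test=test,
    )


# ---------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticFit:
    table: pd.DataFrame  # term, coef, se, odds_ratio, ci_low, ci_high, p
    n: int
    log_likelihood: float
    outcome: str

    def term(self, name: str) -> pd.Series:
        rows = self.table[self.table["term"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


def _build_design(df: pd.DataFrame, terms, reference_levels=None):
    """Expand terms into a numeric design matrix.

    Boolean columns become 0/1; categorical/object columns are dummy-coded
    against the declared reference level (default: first level in sorted
    order), producing terms named ``factor[level]``.
    """
    reference_levels = reference_levels or {}
    cols = {}
    for term in terms:
        s = df[term]
        if s.dtype == bool:
            cols[term] = s.astype(float)
        elif s.dtype.kind in "ifu":
            cols[term] = s.astype(float)
        else:
            levels = sorted(s.dropna().unique(), key=str)
            ref = reference_levels.get(term, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in {term!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{term}[{lev}]"] = (s == lev).astype(float)
                cols[f"{term}[{lev}]"][s.isna()] = np.nan
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "intercept", 1.0)
    return X


def fit_logistic(df: pd.DataFrame, outcome: str, terms,
                 reference_levels: Optional[dict] = None,
                 maxiter: int = 100) -> LogisticFit:
    """Maximum-likelihood binary logistic regression.

    Returns a tidy table with the coefficient, its standard error, the odds
    ratio ``exp(coef)``, the Wald 95% CI ``exp(coef +/- 1.96 SE)`` and the
    Wald p-value per term.  Complete-case: rows with any missing variable
    are dropped.  Perfect separation and non-convergence raise explicit
    errors naming the culprit term / reporting the iteration budget.
    """
    X = _build_design(df, terms, reference_levels)
    y = df[outcome]
    if y.dtype == bool:
        y = y.astype(float)
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X[mask], y[mask].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    n = len(y)
    if n == 0 or y.min() == y.max():
        raise ValueError("outcome has no variation after complete-case filtering")

    model = sm.Logit(y.to_numpy(), X.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=maxiter)
        except (sm.tools.sm_exceptions.PerfectSeparationError, RuntimeWarning,
                np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"separation or singular fit for outcome {outcome!r}: {exc}"
            ) from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"logistic fit did not converge in {maxiter} iterations "
            f"(|grad| = {np.abs(res.model.score(res.params)).max():.3g})")
    coefs = np.asarray(res.params, dtype=float)
    ses = np.asarray(res.bse, dtype=float)
    if (np.abs(coefs) > 15).any() or (ses > 50).any():
        worst = X.columns[int(np.abs(coefs).argmax())]
        raise SeparationError(
            f"quasi-separation: term {worst!r} has coefficient "
            f"{coefs[np.abs(coefs).argmax()]:.2f}")
    table = pd.DataFrame({
        "term": list(X.columns),
        "coef": coefs,
        "se": ses,
        "odds_ratio": np.exp(coefs),
        "ci_low": np.exp(coefs - Z_95 * ses),
        "ci_high": np.exp(coefs + Z_95 * ses),
        "p": 2.0 * sps.norm.sf(np.abs(coefs / ses)),
    })
    return LogisticFit(table=table, n=n, log_likelihood=float(res.llf),
                       outcome=outcome)


def fit_multinomial(df: pd.DataFrame, outcome: str, terms,
                    outcome_reference: str,
                    reference_levels: Optional[dict] = None,
                    maxiter: int = 200) -> pd.DataFrame:
    """Multinomial logistic fit for a multi-level outcome (e.g. frailty
    status with robust as reference); tidy rows carry an ``outcome_level``
    column alongside the per-term OR and Wald CI."""
    X = _build_design(df, terms, reference_levels)
    y = df[outcome]
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X[mask], y[mask]
    levels = [outcome_reference] + sorted(set(y.unique()) - {outcome_reference},
                                          key=str)
    codes = y.map({lev: i for i, lev in enumerate(levels)}).to_numpy()
    model = sm.MNLogit(codes, X.to_numpy())
    res = model.fit(disp=0, maxiter=maxiter)
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"multinomial fit did not converge in {maxiter} "
                               f"iterations")
    rows = []
    for j, lev in enumerate(levels[1:]):
        coefs = np.asarray(res.params)[:, j]
        ses = np.asarray(res.bse)[:, j]
        for term, c, s in zip(X.columns, coefs, ses):
            rows.append({
                "outcome_level": lev, "term": term, "coef": c, "se": s,
                "odds_ratio": np.exp(c),
                "ci_low": np.exp(c - Z_95 * s),
                "ci_high": np.exp(c + Z_95 * s),
                "p": 2.0 * sps.norm.sf(abs(c / s)) if s > 0 else np.nan,
            })
    out = pd.DataFrame(rows)
    out.attrs["n"] = int(mask.sum())
    return out


# ---------------------------------------------------------------------------
# binned mean-FI blood-pressure profile

@dataclass
class UShapeProfile:
    bp_component: str
    edges: np.ndarray          # len = bins + 1, half-open [lo, hi)
    mean_fi: np.ndarray        # NaN for empty bins
    n: np.ndarray
    low_n_flag: np.ndarray     # True where n < min_n

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def argmin_bin(self) -> int:
        """Index of the reliable (unflagged) bin with the lowest mean FI."""
        vals = np.where(self.low_n_flag, np.nan, self.mean_fi)
        if np.isnan(vals).all():
            raise ValueError("no reliable bins")
        return int(np.nanargmin(vals))

    def is_interior_minimum(self) -> bool:
        """True when the minimum-FI reliable bin is not the first or last
        reliable bin — the signature of a U-shaped profile."""
        ok = np.flatnonzero(~self.low_n_flag & ~np.isnan(self.mean_fi))
        return ok[0] < self.argmin_bin() < ok[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.edges[:-1], "bin_high": self.edges[1:],
            "mean_fi": self.mean_fi, "n": self.n, "low_n": self.low_n_flag,
        })


def ushape_profile(df: pd.DataFrame, bp_component: str, bin_width: float,
                   fi_col: str = "fi", min_n: int = 20) -> UShapeProfile:
    """Per-bin mean frailty index over half-open BP bins of fixed width
    spanning the observed range; bins with n < ``min_n`` are flagged."""
    sub = df[[bp_component, fi_col]].dropna()
    if sub.empty:
        raise ValueError("no usable records for the profile")
    x = sub[bp_component].to_numpy(dtype=float)
    fi = sub[fi_col].to_numpy(dtype=float)
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.floor(x.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.minimum(((x - lo) / bin_width).astype(int), len(edges) - 2)
    n = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=fi, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        mean_fi = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return UShapeProfile(bp_component=bp_component, edges=edges,
                         mean_fi=mean_fi, n=n, low_n_flag=n < min_n)
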