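"""Regional inferential statistics.

Within each experimental group the three zones (wound, border, remote)
are compared with a one-way repeated-measures ANOVA (subject = sample,
within factor = zone), followed by post-hoc paired t-tests between
zones; fold-changes and systolic strains are additionally tested per
zone with a one-sample t-test against a hypothetical mean of zero.  All
tests are two-sided with significance declared at p < 0.05 (strict
inequality) and no multiplicity correction by default, with
Greenhouse-Geisser and Holm adjustments available as options.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError, ParameterError

ZONES = ("wound", "border", "remote")

_REL_TOL = 1e-12


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    flag: Optional[str] = None


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_effect: float
    df_error: float
    p: float
    flag: Optional[str] = None
    epsilon: Optional[float] = None


def _as_matrix(table: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        cols = [z for z in ZONES if z in table.columns]
        table = table[cols] if len(cols) >= 2 else table
        return table.to_numpy(float)
    return np.asarray(table, float)


def _gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the zone covariance."""
    k = X.shape[1]
    S = np.cov(X, rowvar=False, ddof=1)
    row = S.mean(axis=0)
    grand = S.mean()
    S_dc = S - row[:, None] - row[None, :] + grand
    num = np.trace(S_dc) ** 2
    den = (k - 1) * np.sum(S_dc**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), num / den)))


def rm_anova(
    table: Union[pd.DataFrame, np.ndarray], correction: Optional[str] = None
) -> AnovaResult:
    """One-way within-subject ANOVA across the zones.

    Rows are samples (subjects), columns the zones; rows containing
    missing values are dropped (listwise deletion).  A table with no
    zone-to-zone variation at all is flagged ``degenerate`` (the F ratio
    is 0/0); a table whose rows are each constant but differ from one
    another has zero effect sum of squares and returns F = 0, p = 1.
    ``correction='gg'`` applies the Greenhouse-Geisser adjustment.
    """
    X = _as_matrix(table)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("table must have at least two zone columns")
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if n < 2:
        raise AnalysisError("need at least two complete samples")
    scale = max(np.abs(X).max(), 1.0)
    grand = X.mean()
    ss_zone = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_zone - ss_subj
    tol = _REL_TOL * scale**2 * X.size
    if ss_total <= tol:  # every cell identical: F is 0/0
        return AnovaResult(np.nan, k - 1.0, (n - 1.0) * (k - 1.0), np.nan, "degenerate")
    if ss_zone <= tol:
        return AnovaResult(0.0, k - 1.0, (n - 1.0) * (k - 1.0), 1.0)
    if ss_err <= tol:
        return AnovaResult(
            np.inf, k - 1.0, (n - 1.0) * (k - 1.0), 0.0, "zero_residual"
        )

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "zone": np.tile(np.arange(k), n),
            "value": X.ravel(),
        }
    )
    res = AnovaRM(long, depvar="value", subject="subject", within=["zone"]).fit()
    row = res.anova_table.iloc[0]
    F = float(row["F Value"])
    df1 = float(row["Num DF"])
    df2 = float(row["Den DF"])
    p = float(row["Pr > F"])
    eps = None
    if correction == "gg":
        eps = _gg_epsilon(X)
        p = float(sps.f.sf(F, eps * df1, eps * df2))
    elif correction is not None:
        raise ParameterError(f"unknown correction {correction!r}")
    return AnovaResult(F, df1, df2, p, epsilon=eps)


def _clean_pair(a, b) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ParameterError("paired observations must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def paired_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on the differences a - b.

    Pairs with missing values are dropped (pairwise deletion); fewer
    than two remaining pairs raises, zero difference variance is flagged
    rather than raised.
    """
    a, b = _clean_pair(a, b)
    n = a.size
    if n < 2:
        raise ParameterError("paired t-test needs at least two pairs")
    return one_sample_t(a - b, 0.0)


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test against the hypothetical mean ``mu0``."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ParameterError("one-sample t-test needs at least two values")
    if np.ptp(v) == 0:
        # degenerate 0/0 or x/0 statistic: report the limiting convention
        # (no deviation -> t = 0, p = 1; constant deviation -> t = +-inf,
        # p = 0) and flag it so callers can exclude it from reports
        if v[0] == mu0:
            return TTestResult(0.0, n - 1.0, 1.0, flag="zero_variance")
        return TTestResult(
            float(np.sign(v[0] - mu0) * np.inf), n - 1.0, 0.0, flag="zero_variance"
        )
    res = sps.ttest_1samp(v, mu0)
    return TTestResult(float(res.statistic), float(n - 1), float(res.pvalue))


# ---------------------------------------------------------------------------
# report assembly

_MARKERS = {
    "vs_remote": "*",
    "vs_zero": "†",  # dagger
    "wound_vs_border": "*̅",  # starred bar
}


def regional_tests(
    table: pd.DataFrame, mu0: Optional[float] = 0.0
) -> pd.DataFrame:
    """The standard battery of regional comparisons for one group.

    ``table`` has zone columns (wound, border, remote) and one row per
    sample.  Produces paired t-tests wound-vs-remote, border-vs-remote
    and wound-vs-border, plus (when ``mu0`` is not None) a one-sample
    t-test of each zone against ``mu0``, and the repeated-measures
    ANOVA across the three zones.
    """
    rows = []
    an = rm_anova(table)
    rows.append(
        {
            "comparison": "rm_anova",
            "statistic": an.F,
            "df": f"{an.df_effect:g},{an.df_error:g}",
            "p": an.p,
            "flag": an.flag,
        }
    )
    pairs = [("wound", "remote"), ("border", "remote"), ("wound", "border")]
    for za, zb in pairs:
        kind = "wound_vs_border" if {za, zb} == {"wound", "border"} else "vs_remote"
        res = paired_t(table[za], table[zb])
        rows.append(
            {
                "comparison": f"{za}_vs_{zb}",
                "kind": kind,
                "statistic": res.t,
                "df": f"{res.df:g}",
                "p": res.p,
                "flag": res.flag,
            }
        )
    if mu0 is not None:
        for z in ZONES:
            if z not in table.columns:
                continue
            res = one_sample_t(table[z], mu0)
            rows.append(
                {
                    "comparison": f"{z}_vs_zero",
                    "kind": "vs_zero",
                    "statistic": res.t,
                    "df": f"{res.df:g}",
                    "p": res.p,
                    "flag": res.flag,
                }
            )
    return pd.DataFrame(rows)


def significance_report(
    tests: pd.DataFrame, alpha: float = 0.05, holm: bool = False
) -> pd.DataFrame:
    """Annotate a test table with significance flags and figure markers.

    Significance uses the strict inequality p < alpha.  ``holm=True``
    applies the Holm step-down adjustment across the table's p-values
    (off by default, matching the raw-threshold convention).
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    out = tests.copy()
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        out["marker"] = pd.Series(dtype=object)
        return out
    p = out["p"].to_numpy(float)
    if holm:
        finite = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if finite.any():
            adj[finite] = multipletests(p[finite], alpha=alpha, method="holm")[1]
        out["p_holm"] = adj
        p = adj
    out["significant"] = np.where(np.isfinite(p), p < alpha, False)
    kinds = out["kind"] if "kind" in out.columns else pd.Series(
        [None] * len(out), index=out.index
    )
    out["marker"] = [
        _MARKERS.get(k, "") if sig else ""
        for k, sig in zip(kinds, out["significant"])
    ]
    return out
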