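"""Percent-change and treatment-response statistics.

Per-visit morphometry and micro-FE records are assembled into a long
table keyed by (subject, group, visit in months).  Treatment response is
summarized as percent change from baseline (absolute change for the
biochemical turnover markers), and associations are characterized with
nonparametric Spearman correlations: changes of every index against the
response variables, and baseline values against the same responses.

A cohort simulator with planted group effects and planted change-change
correlations provides ground truth for recovery and type-I-error tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("PBO", "ALN")
#: response variables: absolute biomarker changes, percent biomechanics changes
DEFAULT_RESPONSES = ("d_bsap", "d_untx", "pct_k", "pct_ct_lf")

KEY_COLS = ("subject_id", "group", "visit")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in KEY_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"visit table lacks key columns {missing}")
    if table.duplicated(subset=list(KEY_COLS)).any():
        raise ValueError("visit table has duplicate (subject, group, visit) keys")


def percent_change(
    table: pd.DataFrame,
    variable: str,
    visit: int,
    absolute: bool = False,
) -> pd.Series:
    """Per-subject change from baseline at ``visit`` months.

    Percent change ``100*(x_v - x_0)/x_0`` by default; ``absolute=True``
    returns ``x_v - x_0`` (used for biomarkers).  Subjects with a zero or
    missing baseline get NaN.
    """
    _check_table(table)
    wide = table.pivot_table(index="subject_id", columns="visit", values=variable,
                             aggfunc="first")
    if 0 not in wide.columns or visit not in wide.columns:
        raise ValueError(f"need baseline and {visit}-month values for {variable}")
    x0, xv = wide[0], wide[visit]
    if absolute:
        return xv - x0
    out = 100.0 * (xv - x0) / x0.where(x0 != 0)
    return out


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value.

    Mid-ranks on ties; pairwise-complete deletion.  ``method="t"`` uses the
    t-approximation with n-2 degrees of freedom; ``method="exact"`` uses an
    exact permutation p-value (only for n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired complete observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan, np.nan  # constant input: undefined correlation
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only for n <= 10")
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def significance_stars(p: float) -> str:
    """Star notation: * p<.05, ** p<.01, *** p<.001, **** p<.0001."""
    if not np.isfinite(p):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""


@dataclass
class CorrelationTable:
    """Spearman rho and p-values, predictors as rows, responses as columns."""

    rho: pd.DataFrame
    p: pd.DataFrame
    group: str
    kind: str  # "change-vs-response" or "baseline-vs-response"

    def rendered(self) -> pd.DataFrame:
        """Table of 'rho stars' strings matching publication notation."""
        out = self.rho.copy().astype(object)
        for i in out.index:
            for c in out.columns:
                r, pv = self.rho.loc[i, c], self.p.loc[i, c]
                out.loc[i, c] = "" if not np.isfinite(r) else (
                    f"{r:.2f}{significance_stars(pv)}"
                )
        return out


def _corr_table(
    df: pd.DataFrame,
    predictors: Sequence[str],
    responses: Sequence[str],
    group: str,
    kind: str,
) -> CorrelationTable:
    rho = pd.DataFrame(index=list(predictors), columns=list(responses), dtype=float)
    p = rho.copy()
    for pred in predictors:
        for resp in responses:
            try:
                r, pv = spearman(df[pred], df[resp])
            except ValueError:
                r, pv = np.nan, np.nan
            rho.loc[pred, resp] = r
            p.loc[pred, resp] = pv
    return CorrelationTable(rho=rho, p=p, group=group, kind=kind)


def response_tables(
    table: pd.DataFrame,
    index_vars: Sequence[str],
    response_vars: Sequence[str] = DEFAULT_RESPONSES,
    absolute_vars: Sequence[str] = ("bsap", "untx"),
    visit: int = 24,
) -> dict[tuple[str, str], CorrelationTable]:
    """Build the treatment-response correlation tables.

    For each group: (a) the ``visit``-month change of every index versus
    the response variables; (b) baseline values of every index versus the
    same responses.  Response variables must already be columns computed
    per subject (e.g. via :func:`percent_change`), or named after index
    columns in which case they are derived here: ``d_<v>`` = absolute
    change of v, ``pct_<v>`` = percent change of v.
    """
    _check_table(table)
    out: dict[tuple[str, str], CorrelationTable] = {}
    for group in sorted(table["group"].unique()):
        sub = table[table["group"] == group]
        per_subject = pd.DataFrame(index=sub["subject_id"].unique())
        for v in index_vars:
            per_subject[f"chg_{v}"] = percent_change(
                sub, v, visit, absolute=v in absolute_vars
            )
            base = sub[sub["visit"] == 0].set_index("subject_id")[v]
            per_subject[f"base_{v}"] = base
        for rv in response_vars:
            if rv in sub.columns:
                base = sub[sub["visit"] == visit].set_index("subject_id")[rv]
                per_subject[rv] = base
            elif rv.startswith("d_"):
                per_subject[rv] = percent_change(sub, rv[2:], visit, absolute=True)
            elif rv.startswith("pct_"):
                per_subject[rv] = percent_change(sub, rv[4:], visit, absolute=False)
            else:
                raise ValueError(f"unknown response variable {rv!r}")
        out[(group, "change-vs-response")] = _corr_table(
            per_subject, [f"chg_{v}" for v in index_vars], list(response_vars),
            group, "change-vs-response",
        )
        out[(group, "baseline-vs-response")] = _corr_table(
            per_subject, [f"base_{v}" for v in index_vars], list(response_vars),
            group, "baseline-vs-response",
        )
    return out


@dataclass
class EffectSpec:
    """Planted cohort effects for the simulator.

    ``baseline_mean``/``baseline_sd`` give per-variable baseline
    distributions; ``change_mean_pct`` maps variable -> {group -> mean
    percent change at the follow-up visit}; ``change_sd_pct`` the SD of
    that percent change; ``change_corr`` plants correlations between the
    *changes* of variable pairs (Gaussian copula on the change noise).
    """

    baseline_mean: dict[str, float]
    baseline_sd: dict[str, float] = field(default_factory=dict)
    change_mean_pct: dict[str, dict[str, float]] = field(default_factory=dict)
    change_sd_pct: dict[str, float] = field(default_factory=dict)
    change_corr: dict[tuple[str, str], float] = field(default_factory=dict)


def simulate_cohort(
    effect: EffectSpec,
    n_per_group: int,
    seed: int,
    visits: Sequence[int] = (0, 24),
) -> pd.DataFrame:
    """Simulate a two-group cohort with planted effects.

    Returns a long visit table with known truth; percent changes at the
    follow-up visits are Gaussian with the specified group means, SDs and
    between-variable correlations.
    """
    rng = np.random.default_rng(seed)
    variables = list(effect.baseline_mean)
    k = len(variables)
    C = np.eye(k)
    for (a, b), r in effect.change_corr.items():
        ia, ib = variables.index(a), variables.index(b)
        C[ia, ib] = C[ib, ia] = r
    # validity check: correlation matrix must be positive semi-definite
    evals = np.linalg.eigvalsh(C)
    if evals.min() < -1e-10:
        raise ValueError("planted change correlations are not jointly consistent")
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(k))
    rows = []
    sid = 0
    for group in GROUPS:
        for _ in range(n_per_group):
            base = {
                v: rng.normal(
                    effect.baseline_mean[v], effect.baseline_sd.get(v, 0.0)
                )
                for v in variables
            }
            rows.append({"subject_id": f"S{sid:03d}", "group": group, "visit": 0,
                         **base})
            for visit in visits:
                if visit == 0:
                    continue
                z = chol @ rng.standard_normal(k)
                scale = visit / max(v for v in visits if v != 0)
                values = {}
                for i, v in enumerate(variables):
                    mu = effect.change_mean_pct.get(v, {}).get(group, 0.0) * scale
                    sd = effect.change_sd_pct.get(v, 0.0) * np.sqrt(scale)
                    pct = mu + sd * z[i]
                    values[v] = base[v] * (1.0 + pct / 100.0)
                rows.append({"subject_id": f"S{sid:03d}", "group": group,
                             "visit": visit, **values})
            sid += 1
    return pd.DataFrame(rows)
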