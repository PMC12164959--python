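"""Repeated-measures and individual-difference inference.

Random-intercept linear mixed models (REML via statsmodels) with
containment-style t tests and Holm-corrected follow-up simple slopes, the
step-down Holm-Bonferroni adjustment itself, and Zou's (2007) confidence
interval for the difference of two dependent overlapping correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm, t as t_dist

log = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Declaration of one (mixed) linear model.

    ``fixed`` is a formula right-hand side (e.g. ``"age * memory"``);
    ``covariates`` are appended additively; ``groups`` names the random-
    intercept grouping column.  ``contrasts`` requests follow-up simple
    slopes: each entry is ``{"focal": <column>, "by": <column>}`` and fits
    the focal slope within every level of ``by``, Holm-correcting the family.
    """

    outcome: str
    fixed: str
    groups: str = "participant_id"
    covariates: tuple = ()
    contrasts: tuple = ()

    def formula(self) -> str:
        rhs = self.fixed
        if self.covariates:
            rhs += " + " + " + ".join(self.covariates)
        return f"{self.outcome} ~ {rhs}"

    def check(self, data: pd.DataFrame) -> None:
        import re

        named = set(re.findall(r"[A-Za-z_]\w*", self.fixed))
        named |= set(self.covariates) | {self.outcome, self.groups}
        for c in self.contrasts:
            named |= {c["focal"], c["by"]}
        missing = [c for c in named if c not in data.columns and not c.startswith("C")]
        # formula operators like np/C are not columns; only complain about
        # plain identifiers absent from the table
        missing = [c for c in missing if c not in ("np", "C", "I", "Q", "center")]
        if missing:
            raise KeyError(f"model columns not in data: {missing}")


@dataclass
class FitResult:
    """Coefficient table plus Holm-adjusted follow-ups for one model."""

    params: pd.DataFrame          # term, estimate, se, t, df, p, partial_eta_sq
    followups: pd.DataFrame
    formula: str
    n_obs: int
    n_groups: int
    used_ols: bool
    random_intercept_var: float = np.nan


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment with monotonicity enforcement.

    NaN entries propagate as NaN and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return out
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = len(pv)
    order = np.argsort(pv, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pv[idx])
        adj[idx] = min(1.0, running)
    out[ok] = adj
    return out


def _column_is_between(col: np.ndarray, groups: np.ndarray) -> bool:
    df = pd.DataFrame({"v": col, "g": groups})
    return bool((df.groupby("g")["v"].nunique() == 1).all())


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit a random-intercept model by REML, or OLS in degenerate layouts.

    When every participant contributes exactly one row (or only one group is
    present) the model collapses to OLS and matches it exactly.  Fixed-effect
    t tests use containment degrees of freedom: between-participant terms are
    tested against ``G - p_between`` and within-participant terms against
    ``N - G - p_within``, which reproduces the paired t test on balanced
    two-condition designs.
    """
    spec.check(data)
    data = data.dropna(subset=[spec.outcome]).reset_index(drop=True)
    groups = data[spec.groups].to_numpy()
    n_groups = len(pd.unique(groups))
    sizes = pd.Series(groups).value_counts()
    degenerate = n_groups < 2 or (sizes == 1).all()

    if degenerate:
        if n_groups < 2:
            log.warning("singular grouping (%d group); falling back to OLS", n_groups)
        res = smf.ols(spec.formula(), data).fit()
        df_resid = float(res.df_resid)
        params = pd.DataFrame(
            {
                "term": res.params.index,
                "estimate": res.params.to_numpy(),
                "se": res.bse.to_numpy(),
                "t": res.tvalues.to_numpy(),
                "df": df_resid,
                "p": res.pvalues.to_numpy(),
            }
        )
        params["partial_eta_sq"] = params["t"] ** 2 / (params["t"] ** 2 + params["df"])
        followups = _fit_followups(spec, data)
        return FitResult(params, followups, spec.formula(), len(data), n_groups, True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(spec.formula(), data, groups=groups)
        res = md.fit(reml=True)
    exog = md.exog
    names = list(md.exog_names)
    between = {
        nm: _column_is_between(exog[:, j], groups) for j, nm in enumerate(names)
    }
    p_b = sum(between.values())
    p_w = len(names) - p_b
    N = len(data)
    df_map = {
        nm: (max(n_groups - p_b, 1) if b else max(N - n_groups - p_w, 1))
        for nm, b in between.items()
    }
    est = res.fe_params
    se = res.bse_fe
    rows = []
    for nm in names:
        tval = est[nm] / se[nm]
        df = df_map[nm]
        p = 2 * t_dist.sf(abs(tval), df)
        rows.append(
            {
                "term": nm, "estimate": est[nm], "se": se[nm], "t": tval,
                "df": df, "p": p,
                "partial_eta_sq": tval**2 / (tval**2 + df),
            }
        )
    params = pd.DataFrame(rows)
    followups = _fit_followups(spec, data)
    re_var = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else np.nan
    return FitResult(params, followups, spec.formula(), N, n_groups, False, re_var)


def _fit_followups(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Simple slopes of a focal predictor within each level of a moderator,
    Holm-corrected per requested family."""
    rows = []
    for c in spec.contrasts:
        focal, by = c["focal"], c["by"]
        family = []
        for level in pd.unique(data[by]):
            sub = data[data[by] == level]
            subspec = ModelSpec(
                spec.outcome, focal, spec.groups, spec.covariates, ()
            )
            try:
                fit = fit_lmm(subspec, sub)
            except Exception:  # pragma: no cover - follow-up robustness
                continue
            row = fit.params[fit.params["term"] == focal]
            if len(row) != 1:
                continue
            family.append(
                {
                    "focal": focal, "by": by, "level": level,
                    "estimate": float(row["estimate"].iloc[0]),
                    "se": float(row["se"].iloc[0]),
                    "p": float(row["p"].iloc[0]),
                }
            )
        if family:
            adj = holm_adjust([r["p"] for r in family])
            for r, a in zip(family, adj):
                r["p_holm"] = float(a)
            rows.extend(family)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dependent overlapping correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrComparison:
    """Difference of two correlations sharing one variable, with Zou 95% CI."""

    r1: float
    r2: float
    r12: float
    n: int
    delta: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


def compare_dependent_correlations(
    x, y1, y2, conf_level: float = 0.95
) -> CorrComparison:
    """Compare cor(x, y1) with cor(x, y2) on the same sample.

    Both correlations share ``x`` and are computed on the same n cases, so
    they are dependent with overlap; the confidence interval for
    ``r1 - r2`` uses Zou's (2007) asymptotic method built from the Fisher-z
    interval of each correlation and the correlation between the two
    correlation estimates.
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if not (len(x) == len(y1) == len(y2)):
        raise ValueError("input vectors must have equal length")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 cases")
    if not (np.isfinite(x).all() and np.isfinite(y1).all() and np.isfinite(y2).all()):
        raise ValueError("inputs must be finite")
    for name, v in (("x", x), ("y1", y1), ("y2", y2)):
        if np.std(v) == 0:
            raise ValueError(f"correlation undefined: {name} is constant")
    r1 = float(np.corrcoef(x, y1)[0, 1])
    r2 = float(np.corrcoef(x, y2)[0, 1])
    r12 = float(np.corrcoef(y1, y2)[0, 1])
    zcrit = norm.ppf(0.5 + conf_level / 2)
    se = 1.0 / np.sqrt(n - 3)

    def fisher_ci(r):
        z = np.arctanh(r)
        return np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)

    l1, u1 = fisher_ci(r1)
    l2, u2 = fisher_ci(r2)
    corr_num = (r12 - 0.5 * r1 * r2) * (1 - r1**2 - r2**2 - r12**2) + r12**3
    corr_den = (1 - r1**2) * (1 - r2**2)
    c = corr_num / corr_den
    delta = r1 - r2
    low = delta - np.sqrt(
        (r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2)
    )
    high = delta + np.sqrt(
        (u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2)
    )
    return CorrComparison(r1, r2, r12, n, delta, float(low), float(high), conf_level)
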