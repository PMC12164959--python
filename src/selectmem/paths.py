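"""Recursive path models: mediation, SEM-style systems, and R2 partitioning.

A declared path system is an ordered set of structural equations among
observed variables, e.g. the age -> {pTau181, DAN SME} -> selectivity ->
memory system

    M1 = k1 + a1*X + e1
    M3 =      a3*X + e3
    M2 = k2 + a2*X + d21*M1 + d23*M3 + e2
    Y  = k3 + c'*X + b1*M1 + b2*M2 + b3*M3 + e4

with sex and education appended to every equation as covariates.  Because
every variable is observed and the system is recursive, equation-wise OLS
gives the maximum-likelihood point estimates of the just-identified SEM, and
the total effect obeys c = c' + a1*d21*b2 + a1*b1 + a2*b2 + a3*b3 +
a3*d23*b2 as an exact algebraic identity of the fitted coefficients.

Indirect effects are products of path coefficients; their uncertainty comes
from a percentile bootstrap over participants (resample rows, refit the whole
system), implemented as batched linear algebra so thousands of resamples cost
a few matrix solves.  The completely standardized solution refits on z-scored
variables; bootstrap resamples standardize with their own SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Coef = tuple[str, str]  # (equation outcome, predictor)

MAX_FOCAL = 4
MAX_REDRAWS = 100


@dataclass
class PathSystem:
    """Ordered structural equations plus declared indirect-effect products."""

    equations: list          # [(outcome, [predictors...]), ...]
    products: dict = field(default_factory=dict)   # name -> tuple[Coef, ...]
    covariates: tuple = ()
    exposure: str | None = None
    final_outcome: str | None = None
    contrasts: dict = field(default_factory=dict)  # name -> (product_a, product_b)

    def __post_init__(self) -> None:
        outcomes = [eq[0] for eq in self.equations]
        if len(set(outcomes)) != len(outcomes):
            raise ValueError("duplicate equation outcomes")
        # recursive ordering: an outcome may only feed equations listed later
        for k, (outcome, preds) in enumerate(self.equations):
            clash = set(outcomes[k:]) & set(preds)
            if clash:
                raise ValueError(f"cyclic path system: {outcome!r} uses {sorted(clash)}")
        coef_set = {
            (outcome, p) for outcome, preds in self.equations for p in preds
        }
        for name, factors in self.products.items():
            for c in factors:
                if tuple(c) not in coef_set:
                    raise ValueError(f"product {name!r} references unknown path {c}")
        for name, (pa, pb) in self.contrasts.items():
            if pa not in self.products or pb not in self.products:
                raise ValueError(f"contrast {name!r} references unknown product")

    @property
    def variables(self) -> list:
        seen: list = []
        for outcome, preds in self.equations:
            for v in (outcome, *preds):
                if v not in seen:
                    seen.append(v)
        for v in self.covariates:
            if v not in seen:
                seen.append(v)
        return seen


@dataclass
class PathModelFit:
    """Point estimates, bootstrap CIs, and the standardized solution."""

    coefficients: pd.DataFrame   # outcome, predictor, estimate, std_estimate
    intercepts: dict
    residual_var: dict
    products: pd.DataFrame       # name, estimate, ci_low, ci_high, std_*
    contrasts: pd.DataFrame
    total_effect: float
    total_effect_std: float
    direct_effect: float
    n_used: int
    n_boot: int
    seed: int | None
    n_redrawn: int = 0

    def coef(self, outcome: str, predictor: str, standardized: bool = False) -> float:
        sel = self.coefficients[
            (self.coefficients["outcome"] == outcome)
            & (self.coefficients["predictor"] == predictor)
        ]
        col = "std_estimate" if standardized else "estimate"
        return float(sel[col].iloc[0])

    def identity_gap(self) -> float:
        """c - (c' + sum of declared indirect products), raw scale."""
        return float(
            self.total_effect
            - self.direct_effect
            - self.products["estimate"].sum()
        )


def _fit_equations(D: np.ndarray, eq_cols: list) -> list:
    """OLS coefficients for each equation on data matrix D (n, K).

    eq_cols: [(y_col, [x_cols...]), ...]; returns per-equation arrays of
    [intercept, betas...] plus residual variances.
    """
    out = []
    for y_col, x_cols, label in eq_cols:
        X = np.column_stack([np.ones(D.shape[0])] + [D[:, j] for j in x_cols])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear predictors in equation for {label!r}")
        beta, res, *_ = np.linalg.lstsq(X, D[:, y_col], rcond=None)
        resid = D[:, y_col] - X @ beta
        dof = max(D.shape[0] - X.shape[1], 1)
        out.append((beta, float(resid @ resid) / dof))
    return out


def _batched_fit(Db: np.ndarray, eq_cols: list) -> list:
    """Solve every equation's normal equations for a batch of resamples.

    Db: (B, n, K) resampled data.  Returns per-equation (B, p) coefficient
    arrays (intercept first).
    """
    B, n, _ = Db.shape
    ones = np.ones((B, n, 1))
    out = []
    for y_col, x_cols, _label in eq_cols:
        Xb = np.concatenate([ones, Db[:, :, x_cols]], axis=2)
        XtX = np.einsum("bnp,bnq->bpq", Xb, Xb)
        Xty = np.einsum("bnp,bn->bp", Xb, Db[:, :, y_col])
        out.append(np.linalg.solve(XtX, Xty[..., None])[..., 0])
    return out


def fit_path_system(
    system: PathSystem,
    data: pd.DataFrame,
    n_boot: int = 5000,
    seed: int | None = 0,
    conf_level: float = 0.95,
) -> PathModelFit:
    """Estimate a recursive path system by equation-wise OLS.

    Complete cases only (listwise deletion, logged via the returned
    ``n_used``); percentile bootstrap over participants for every declared
    product and contrast; completely standardized solution from refitting on
    z-scored variables.  ``n_boot = 0`` skips the bootstrap (CIs are NaN).
    """
    variables = system.variables
    frame = data[variables].dropna()
    n = len(frame)
    if n < 20:
        raise ValueError(f"only {n} complete cases; need >= 20")
    D = frame.to_numpy(dtype=float)
    col = {v: j for j, v in enumerate(variables)}
    eq_cols = [
        (col[outcome], [col[p] for p in (*preds, *system.covariates)], outcome)
        for outcome, preds in system.equations
    ]

    fits = _fit_equations(D, eq_cols)
    sd = D.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v in variables if sd[col[v]] == 0]
        raise ValueError(f"constant variables: {bad}")
    Dz = (D - D.mean(axis=0)) / sd
    fits_z = _fit_equations(Dz, eq_cols)

    coef_rows = []
    coef_index: dict[Coef, tuple[int, int]] = {}
    intercepts, resvar = {}, {}
    for k, (outcome, preds) in enumerate(system.equations):
        beta, rv = fits[k]
        beta_z, _ = fits_z[k]
        intercepts[outcome] = float(beta[0])
        resvar[outcome] = rv
        allpreds = (*preds, *system.covariates)
        for j, p in enumerate(allpreds, start=1):
            coef_rows.append(
                {
                    "outcome": outcome, "predictor": p,
                    "estimate": float(beta[j]), "std_estimate": float(beta_z[j]),
                }
            )
            coef_index[(outcome, p)] = (k, j)
    coefficients = pd.DataFrame(coef_rows)

    def products_from(fit_list) -> dict:
        vals = {}
        for name, factors in system.products.items():
            v = 1.0
            for c in factors:
                k, j = coef_index[tuple(c)]
                v *= fit_list[k][0][j]
            vals[name] = float(v)
        return vals

    prod_pt = products_from(fits)
    prod_pt_z = products_from(fits_z)

    # total and direct effects of the exposure on the final outcome
    total = total_z = direct = np.nan
    if system.exposure and system.final_outcome:
        tot_cols = [
            (col[system.final_outcome],
             [col[system.exposure]] + [col[c] for c in system.covariates],
             system.final_outcome)
        ]
        total = _fit_equations(D, tot_cols)[0][0][1]
        total_z = _fit_equations(Dz, tot_cols)[0][0][1]
        direct = float(
            coefficients.loc[
                (coefficients["outcome"] == system.final_outcome)
                & (coefficients["predictor"] == system.exposure),
                "estimate",
            ].iloc[0]
        )

    # ------------------------------------------------------------------ boot
    n_redrawn = 0
    q_lo, q_hi = 100 * (1 - conf_level) / 2, 100 * (1 + conf_level) / 2
    boot_cols = {name: (np.nan, np.nan) for name in system.products}
    boot_cols_z = dict(boot_cols)
    con_ci = {name: (np.nan, np.nan) for name in system.contrasts}
    con_pt = {
        name: prod_pt[pa] - prod_pt[pb] for name, (pa, pb) in system.contrasts.items()
    }
    used_cols = sorted({j for _, xs, _ in eq_cols for j in xs})
    if n_boot:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        for _ in range(MAX_REDRAWS):
            bad = (D[idx][:, :, used_cols].std(axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            n_redrawn += int(bad.sum())
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        else:
            raise RuntimeError("could not draw non-degenerate bootstrap resamples")
        Db = D[idx]
        coefs_b = _batched_fit(Db, eq_cols)
        mu = Db.mean(axis=1, keepdims=True)
        sdb = Db.std(axis=1, keepdims=True, ddof=1)
        coefs_bz = _batched_fit((Db - mu) / sdb, eq_cols)

        def boot_products(coef_batches) -> dict:
            vals = {}
            for name, factors in system.products.items():
                v = np.ones(n_boot)
                for c in factors:
                    k, j = coef_index[tuple(c)]
                    v = v * coef_batches[k][:, j]
                vals[name] = v
            return vals

        bp = boot_products(coefs_b)
        bpz = boot_products(coefs_bz)
        for name in system.products:
            boot_cols[name] = tuple(np.percentile(bp[name], [q_lo, q_hi]))
            boot_cols_z[name] = tuple(np.percentile(bpz[name], [q_lo, q_hi]))
        for name, (pa, pb) in system.contrasts.items():
            con_ci[name] = tuple(np.percentile(bp[pa] - bp[pb], [q_lo, q_hi]))

    products = pd.DataFrame(
        [
            {
                "name": name,
                "estimate": prod_pt[name],
                "ci_low": boot_cols[name][0],
                "ci_high": boot_cols[name][1],
                "std_estimate": prod_pt_z[name],
                "std_ci_low": boot_cols_z[name][0],
                "std_ci_high": boot_cols_z[name][1],
            }
            for name in system.products
        ]
    )
    contrasts = pd.DataFrame(
        [
            {"name": name, "estimate": con_pt[name],
             "ci_low": con_ci[name][0], "ci_high": con_ci[name][1]}
            for name in system.contrasts
        ]
    )
    return PathModelFit(
        coefficients, intercepts, resvar, products, contrasts,
        float(total), float(total_z), direct, n, n_boot, seed, n_redrawn,
    )


# ---------------------------------------------------------------------------
# Convenience constructors
# ---------------------------------------------------------------------------

def mediation_simple(
    data: pd.DataFrame, x: str, m: str, y: str,
    covariates=(), n_boot: int = 5000, seed: int | None = 0,
) -> PathModelFit:
    """Single-mediator model: M = k1 + a*X, Y = k2 + c'*X + b*M."""
    system = PathSystem(
        equations=[(m, [x]), (y, [x, m])],
        products={"ab": ((m, x), (y, m))},
        covariates=tuple(covariates),
        exposure=x,
        final_outcome=y,
    )
    return fit_path_system(system, data, n_boot=n_boot, seed=seed)


def mediation_multiple(
    data: pd.DataFrame, x: str, m1: str, m2: str, y: str,
    covariates=(), n_boot: int = 5000, seed: int | None = 0,
) -> PathModelFit:
    """Two parallel mediators with a bootstrap CI on a1*b1 - a2*b2."""
    system = PathSystem(
        equations=[(m1, [x]), (m2, [x]), (y, [x, m1, m2])],
        products={"a1b1": ((m1, x), (y, m1)), "a2b2": ((m2, x), (y, m2))},
        covariates=tuple(covariates),
        exposure=x,
        final_outcome=y,
        contrasts={"indirect_diff": ("a1b1", "a2b2")},
    )
    return fit_path_system(system, data, n_boot=n_boot, seed=seed)


def sem_system(
    x: str = "age_z", m1: str = "ptau181", m2: str = "selectivity",
    m3: str = "dan_sme", y: str = "memory", covariates=("sex", "education"),
) -> PathSystem:
    """The four-equation age / pTau / attention / selectivity / memory system
    with all five indirect products of the total-effect identity."""
    return PathSystem(
        equations=[(m1, [x]), (m3, [x]), (m2, [x, m1, m3]), (y, [x, m1, m2, m3])],
        products={
            "a1b1": ((m1, x), (y, m1)),
            "a2b2": ((m2, x), (y, m2)),
            "a3b3": ((m3, x), (y, m3)),
            "a1d21b2": ((m1, x), (m2, m1), (y, m2)),
            "a3d23b2": ((m3, x), (m2, m3), (y, m2)),
        },
        covariates=tuple(covariates),
        exposure=x,
        final_outcome=y,
    )


# ---------------------------------------------------------------------------
# Hierarchical R2 variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition:
    """Total, unique, and pairwise-shared R2 for a focal predictor set.

    unique_i = R2_full - R2(omit i); shared_ij = R2_full - R2(omit i and j)
    - unique_i - unique_j.  Subtraction schemes can go negative under
    suppression; values are stored as computed and flagged.
    """

    outcome: str
    focal: tuple
    covariates: tuple
    r2_total: float
    r2_covariates_only: float
    unique: dict
    shared: dict            # frozenset({i, j}) -> value
    negative_flags: list
    n_used: int


def _r2(y: np.ndarray, X_cols: list) -> float:
    X = np.column_stack([np.ones(len(y))] + X_cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss


def variance_partition(
    data: pd.DataFrame, outcome: str, focal, covariates=()
) -> VariancePartition:
    """Nested-model R2 decomposition over a set of focal predictors."""
    focal = tuple(focal)
    if len(focal) > MAX_FOCAL:
        raise ValueError(
            f"variance partition defined pairwise for at most {MAX_FOCAL} focal predictors"
        )
    cols = [outcome, *focal, *covariates]
    frame = data[cols].dropna()
    y = frame[outcome].to_numpy(dtype=float)

    def r2_of(predictors) -> float:
        return _r2(y, [frame[p].to_numpy(dtype=float) for p in predictors])

    full = list(focal) + list(covariates)
    r2_total = r2_of(full)
    r2_cov = r2_of(list(covariates)) if covariates else 0.0
    unique = {
        f: r2_total - r2_of([g for g in focal if g != f] + list(covariates))
        for f in focal
    }
    shared = {}
    for i, fi in enumerate(focal):
        for fj in focal[i + 1 :]:
            omit2 = r2_of([g for g in focal if g not in (fi, fj)] + list(covariates))
            shared[frozenset((fi, fj))] = (
                r2_total - omit2 - unique[fi] - unique[fj]
            )
    flags = [k for k, v in {**unique, **shared}.items() if v < -1e-12]
    return VariancePartition(
        outcome, focal, tuple(covariates), r2_total, r2_cov,
        unique, shared, flags, len(frame),
    )
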