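"""Path-system estimation: OLS mediation algebra, bootstrap behaviour,
standardized solutions, and the R2 variance partition against an
all-subsets oracle."""

import numpy as np
import pandas as pd
import pytest

from selectmem import paths, synthgen
from _oracles import all_subsets_r2


def _random_table(rng, n=200):
    x = rng.normal(size=n)
    sex = rng.integers(0, 2, n).astype(float)
    edu = rng.normal(16, 2, n)
    m = 0.5 * x + 0.2 * sex + rng.normal(size=n)
    y = 0.3 * x + 0.6 * m - 0.1 * edu + rng.normal(size=n)
    return pd.DataFrame({"x": x, "m": m, "y": y, "sex": sex, "edu": edu})


def test_simple_mediation_total_effect_identity(rng):
    """c from the Y~X regression equals c' + a*b exactly for any table."""
    for seed in range(5):
        df = _random_table(np.random.default_rng(seed))
        fit = paths.mediation_simple(df, "x", "m", "y", ("sex", "edu"), n_boot=0)
        ab = float(fit.products["estimate"].iloc[0])
        assert fit.total_effect == pytest.approx(fit.direct_effect + ab, abs=1e-10)
        assert fit.identity_gap() == pytest.approx(0.0, abs=1e-10)


def test_sem_total_effect_identity():
    """c = c' + a1d21b2 + a1b1 + a2b2 + a3b3 + a3d23b2 to 1e-8."""
    cfg = synthgen.GenerativeConfig(seed=17)
    df = synthgen.simulate_path_system(cfg, 300, np.random.default_rng(17))
    system = paths.sem_system(
        x="x", m1="m1", m2="m2", m3="m3", y="y", covariates=("sex", "education_z")
    )
    fit = paths.fit_path_system(system, df, n_boot=0)
    assert fit.identity_gap() == pytest.approx(0.0, abs=1e-8)
    # and in the standardized solution as well (all-variable z-scoring is an
    # affine map, preserving the OLS identity)
    prods = fit.products.set_index("name")
    total_std = fit.total_effect_std
    direct_std = fit.coefficients.query(
        "outcome == 'y' and predictor == 'x'"
    )["std_estimate"].iloc[0]
    assert total_std == pytest.approx(
        direct_std + prods["std_estimate"].sum(), abs=1e-8
    )


def test_known_product_recovery():
    """a1=0.4, d21=-0.3, b2=0.5 on a large sample recovers a1*d21*b2=-0.06."""
    p = dict(synthgen.NULL_TRUE_PATHS, a1=0.4, d21=-0.3, b2=0.5)
    cfg = synthgen.GenerativeConfig(true_paths=p, seed=23)
    df = synthgen.simulate_path_system(cfg, 5000, np.random.default_rng(23))
    system = paths.sem_system(
        x="x", m1="m1", m2="m2", m3="m3", y="y", covariates=("sex", "education_z")
    )
    fit = paths.fit_path_system(system, df, n_boot=0)
    got = fit.products.set_index("name").loc["a1d21b2", "estimate"]
    assert got == pytest.approx(-0.06, abs=0.02)


def test_full_mediation_bootstrap_inference(rng):
    """With c'=0 and a=b=0.5, the direct CI straddles 0 while the indirect
    CI excludes it."""
    n = 500
    x = rng.normal(size=n)
    m = 0.5 * x + rng.normal(size=n) * np.sqrt(0.75)
    y = 0.5 * m + rng.normal(size=n) * np.sqrt(0.75)
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    fit = paths.mediation_simple(df, "x", "m", "y", n_boot=1000, seed=4)
    row = fit.products.iloc[0]
    assert row["ci_low"] > 0
    # direct effect: bootstrap the Y~X+M coefficient via the same machinery
    assert fit.direct_effect == pytest.approx(0.0, abs=3 * 0.05)


def test_standardized_solution_affine_invariant(rng):
    df = _random_table(rng)
    fit1 = paths.mediation_simple(df, "x", "m", "y", ("sex", "edu"), n_boot=0)
    df2 = df.assign(x=5.0 + 13.0 * df["x"])
    fit2 = paths.mediation_simple(df2, "x", "m", "y", ("sex", "edu"), n_boot=0)
    pd.testing.assert_frame_equal(
        fit1.coefficients[["outcome", "predictor", "std_estimate"]],
        fit2.coefficients[["outcome", "predictor", "std_estimate"]],
        atol=1e-10,
    )


def test_standardized_equals_rescaled_raw(rng):
    """Standardized coefficients equal raw coefficients times SD ratios."""
    df = _random_table(rng)
    fit = paths.mediation_simple(df, "x", "m", "y", ("sex", "edu"), n_boot=0)
    sd = df.std(ddof=1)
    for _, row in fit.coefficients.iterrows():
        rescaled = row["estimate"] * sd[row["predictor"]] / sd[row["outcome"]]
        assert row["std_estimate"] == pytest.approx(rescaled, abs=1e-8)


def test_multiple_mediation_contrast(rng):
    n = 5000
    x = rng.normal(size=n)
    m1 = 0.4 * x + rng.normal(size=n)   # a1*b1 = 0.4*0.3 = 0.12
    m2 = 0.2 * x + rng.normal(size=n)   # a2*b2 = 0.2*0.2 = 0.04
    y = 0.3 * m1 + 0.2 * m2 + rng.normal(size=n)
    df = pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y})
    fit = paths.mediation_multiple(df, "x", "m1", "m2", "y", n_boot=500, seed=9)
    diff = fit.contrasts.set_index("name").loc["indirect_diff", "estimate"]
    assert diff == pytest.approx(0.08, abs=0.02)
    # swapping mediator labels negates the contrast exactly
    fit_sw = paths.mediation_multiple(df, "x", "m2", "m1", "y", n_boot=0, seed=9)
    diff_sw = fit_sw.contrasts.set_index("name").loc["indirect_diff", "estimate"]
    assert diff_sw == pytest.approx(-diff, abs=1e-12)


def test_symmetric_mediators_contrast_contains_zero(rng):
    n = 400
    x = rng.normal(size=n)
    m1 = 0.4 * x + rng.normal(size=n)
    m2 = 0.4 * x + rng.normal(size=n)
    y = 0.3 * m1 + 0.3 * m2 + rng.normal(size=n)
    df = pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y})
    fit = paths.mediation_multiple(df, "x", "m1", "m2", "y", n_boot=800, seed=1)
    row = fit.contrasts.iloc[0]
    assert row["ci_low"] <= 0 <= row["ci_high"]


def test_bootstrap_deterministic(rng):
    df = _random_table(rng)
    f1 = paths.mediation_simple(df, "x", "m", "y", n_boot=500, seed=42)
    f2 = paths.mediation_simple(df, "x", "m", "y", n_boot=500, seed=42)
    pd.testing.assert_frame_equal(f1.products, f2.products)
    f3 = paths.mediation_simple(df, "x", "m", "y", n_boot=500, seed=43)
    assert not np.allclose(f1.products["ci_low"], f3.products["ci_low"])


def test_system_validation():
    with pytest.raises(ValueError, match="cyclic"):
        paths.PathSystem(equations=[("a", ["b"]), ("b", ["a"])])
    with pytest.raises(ValueError, match="unknown path"):
        paths.PathSystem(
            equations=[("m", ["x"])], products={"bad": (("y", "x"),)}
        )


def test_collinear_predictors_error(rng):
    n = 50
    x = rng.normal(size=n)
    df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=n)})
    system = paths.PathSystem(equations=[("y", ["x", "x2"])])
    with pytest.raises(ValueError, match="collinear.*'y'"):
        paths.fit_path_system(system, df, n_boot=0)


def test_too_few_complete_cases(rng):
    df = _random_table(rng, n=30)
    df.loc[5:, "m"] = np.nan
    with pytest.raises(ValueError, match="complete cases"):
        paths.mediation_simple(df, "x", "m", "y", n_boot=0)


# ---------------------------------------------------------------------------
# Variance partition
# ---------------------------------------------------------------------------

def test_variance_partition_matches_all_subsets_oracle(rng):
    n = 120
    df = pd.DataFrame(
        rng.normal(size=(n, 5)), columns=["f1", "f2", "f3", "c1", "c2"]
    )
    df["y"] = (
        0.5 * df["f1"] + 0.3 * df["f2"] + 0.2 * df["f1"] * 0  # noqa: keep simple
        + 0.4 * df["c1"] + rng.normal(size=n)
    )
    vp = paths.variance_partition(df, "y", ("f1", "f2", "f3"), ("c1", "c2"))
    table = all_subsets_r2(
        df["y"].to_numpy(), {k: df[k].to_numpy() for k in ["f1", "f2", "f3", "c1", "c2"]}
    )
    full = frozenset({"f1", "f2", "f3", "c1", "c2"})
    assert vp.r2_total == pytest.approx(table[full], abs=1e-12)
    for f in ("f1", "f2", "f3"):
        expected = table[full] - table[full - {f}]
        assert vp.unique[f] == pytest.approx(expected, abs=1e-12)
    for (fi, fj) in (("f1", "f2"), ("f1", "f3"), ("f2", "f3")):
        expected = (
            table[full] - table[full - {fi, fj}]
            - vp.unique[fi] - vp.unique[fj]
        )
        assert vp.shared[frozenset((fi, fj))] == pytest.approx(expected, abs=1e-12)


def test_orthogonal_predictors_share_nothing(rng):
    n = 300
    raw = rng.normal(size=(n, 3))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    df = pd.DataFrame(q, columns=["f1", "f2", "f3"])
    df["y"] = 0.6 * df["f1"] + 0.3 * df["f2"] + rng.normal(0, 0.05, n)
    vp = paths.variance_partition(df, "y", ("f1", "f2", "f3"))
    for v in vp.shared.values():
        assert abs(v) < 1e-10
    assert sum(vp.unique.values()) == pytest.approx(vp.r2_total, abs=1e-10)


def test_duplicate_predictor_has_no_unique_variance(rng):
    n = 200
    f = rng.normal(size=n)
    df = pd.DataFrame({"f1": f, "f2": f + rng.normal(0, 1e-6, n)})
    df["y"] = 0.7 * f + rng.normal(size=n)
    vp = paths.variance_partition(df, "y", ("f1", "f2"))
    assert abs(vp.unique["f1"]) < 5e-3
    assert abs(vp.unique["f2"]) < 5e-3
    assert vp.shared[frozenset(("f1", "f2"))] == pytest.approx(
        vp.r2_total, abs=5e-3
    )


def test_focal_limit():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 6)),
                      columns=list("abcdef"))
    with pytest.raises(ValueError, match="at most"):
        paths.variance_partition(df, "a", ("b", "c", "d", "e", "f"))
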