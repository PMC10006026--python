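"""Stability indices: hand-checked fixture values, brute-force oracle
equivalence, and structural invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from conftest import random_table
from gxestab import GxETable, apply_unit_transform, compute_all
from gxestab import indices as idx

# exact hand-derived values for the T1 fixture ([[4,6,8],[0,6,6]])
T1_EXPECTED = {
    "environmental_variance": (4.0, 12.0),
    "coefficient_of_regression": (5 / 7, 9 / 7),
    "coefficient_of_determination": (25 / 28, 27 / 28),
    "deviation_mean_squares": (6 / 7, 6 / 7),
    "ecovalence": (2.0, 2.0),
    "ecovalence_modified": (2 / 3, 2 / 3),
    "genotypic_stability": (6 / 7, 38 / 7),
    "superiority_measure": (0.0, 10 / 3),
    "variance_of_rank": (0.25, 0.25),
}


@pytest.mark.parametrize("name,expected", sorted(T1_EXPECTED.items()))
def test_t1_hand_values(t1, name, expected):
    values = idx.compute_index(t1, name)
    np.testing.assert_allclose(values.to_numpy(), expected, atol=1e-12)


def test_t1_adjusted_cv_matches_oracle(t1):
    values = idx.adjusted_cv(t1)
    expected = oracle.adjusted_cv(t1.data.to_numpy().tolist())
    np.testing.assert_allclose(values.to_numpy(), [expected[0], expected[1]],
                               atol=1e-10)
    # two log-log points fit exactly, so both genotypes share one adjusted CV
    assert values.iloc[0] == pytest.approx(values.iloc[1], abs=1e-9)
    assert values.iloc[0] == pytest.approx(53.73, abs=0.05)


def test_t1_safety_first(t1):
    values = idx.safety_first_index(t1, lambda_=5.0)
    expected = oracle.safety_first_index(t1.data.to_numpy().tolist(), 5.0)
    np.testing.assert_allclose(values.to_numpy(), [expected[0], expected[1]],
                               atol=1e-12)
    # normal-CDF table values: Phi(-0.5), Phi(1/sqrt(12))
    np.testing.assert_allclose(values.to_numpy(), [0.3085, 0.6136], atol=1e-4)


def test_safety_first_limits(t1):
    assert idx.safety_first_index(t1, -1e9).max() < 1e-12
    # lambda at the genotype mean gives exactly 1/2
    assert idx.safety_first_index(t1, 6.0)["g1"] == pytest.approx(0.5)


@pytest.mark.parametrize("g,e", [(2, 3), (3, 3), (4, 5), (6, 6), (5, 4)])
def test_oracle_equivalence_random_tables(g, e):
    """Every index equals the definition-sum oracle on random tables."""
    rng = np.random.default_rng(1000 + 10 * g + e)
    for _ in range(10):
        t = random_table(rng, g, e)
        x = t.data.to_numpy().tolist()
        for name, fn in oracle.ORACLES.items():
            if name == "stability_variance" and g < 3:
                continue
            got = idx.compute_index(t, name).to_numpy()
            want = [fn(x)[i] for i in range(g)]
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-9,
                                       err_msg=f"{name} on {g}x{e}")
        got = idx.safety_first_index(t, 5.0).to_numpy()
        want = [oracle.safety_first_index(x, 5.0)[i] for i in range(g)]
        np.testing.assert_allclose(got, want, atol=1e-9)


def test_shukla_matches_anova_oracle():
    """Shukla's computational form agrees with the ANOVA-residual oracle
    and its genotype sum equals G*sum(W)/((G-1)(E-1))."""
    rng = np.random.default_rng(7)
    t = random_table(rng, 5, 8)
    got = idx.stability_variance(t)
    want = oracle.stability_variance(t.data.to_numpy().tolist())
    np.testing.assert_allclose(got.to_numpy(), [want[i] for i in range(5)],
                               atol=1e-9)
    g, e = 5, 8
    w_sum = idx.ecovalence(t).sum()
    assert got.sum() == pytest.approx(g * w_sum / ((g - 1) * (e - 1)), abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.integers(2, 6),
    st.integers(3, 6),
    st.integers(0, 2**31 - 1),
)
def test_structural_invariants(g, e, seed):
    """mean(b_i) = 1 and sum(W_i) = interaction SS on any complete table."""
    t = random_table(np.random.default_rng(seed), g, e)
    b = idx.coefficient_of_regression(t)
    assert b.mean() == pytest.approx(1.0, abs=1e-10)
    x = t.data.to_numpy()
    inter = x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + x.mean()
    assert idx.ecovalence(t).sum() == pytest.approx((inter**2).sum(), rel=1e-10)
    r2 = idx.coefficient_of_determination(t)
    assert ((r2 >= -1e-12) & (r2 <= 1 + 1e-12)).all()
    assert (idx.superiority_measure(t) >= 0).all()


def test_environment_shift_invariance():
    """Dynamic indices ignore a constant added to one environment column;
    the static environmental variance does not."""
    rng = np.random.default_rng(11)
    t = random_table(rng, 4, 5)
    shifted_data = t.data.copy()
    shifted_data.iloc[:, 0] += 5.0
    shifted = GxETable("yield", shifted_data)
    for name in ("ecovalence", "stability_variance", "superiority_measure",
                 "variance_of_rank"):
        np.testing.assert_allclose(
            idx.compute_index(t, name).to_numpy(),
            idx.compute_index(shifted, name).to_numpy(),
            atol=1e-9, err_msg=name,
        )
    assert not np.allclose(
        idx.environmental_variance(t), idx.environmental_variance(shifted)
    )


def test_superiority_zero_for_dominant_genotype(t1):
    """P_i = 0 iff the genotype attains the environment maximum everywhere."""
    p = idx.superiority_measure(t1)
    assert p["g1"] == 0.0 and p["g2"] > 0


def test_additive_table_degeneracies():
    """On x_ij = alpha_i + beta_j: W_i = 0, D2_i = 0, sigma2_i = 0, b_i = 1,
    and corrected values tie so the rank variance is 0."""
    alpha = np.array([1.0, 2.0, 4.0])
    beta = np.array([0.0, 1.0, 3.0, 5.0])
    t = GxETable("yield", pd.DataFrame(
        alpha[:, None] + beta[None, :],
        index=list("abc"), columns=list("wxyz"),
    ))
    np.testing.assert_allclose(idx.ecovalence(t), 0, atol=1e-12)
    np.testing.assert_allclose(idx.genotypic_stability(t), 0, atol=1e-12)
    np.testing.assert_allclose(idx.stability_variance(t), 0, atol=1e-12)
    np.testing.assert_allclose(idx.coefficient_of_regression(t), 1, atol=1e-12)
    np.testing.assert_allclose(idx.variance_of_rank(t), 0, atol=1e-12)
    np.testing.assert_allclose(idx.deviation_mean_squares(t), 0, atol=1e-12)
    np.testing.assert_allclose(idx.coefficient_of_determination(t), 1, atol=1e-12)


def test_adjusted_cv_reduces_to_cv_when_slope_two():
    """A table lying exactly on the slope-2 Taylor line gives the plain CV."""
    # construct two genotypes with sd proportional to mean => log-log slope 2
    base = np.array([-1.0, 0.0, 1.0])
    rows = {f"g{i}": m + m * 0.2 * base for i, m in enumerate([2.0, 4.0, 8.0])}
    t = GxETable("yield", pd.DataFrame(rows).T.set_axis(["e1", "e2", "e3"], axis=1))
    got = idx.adjusted_cv(t)
    plain = 100.0 * t.data.std(1, ddof=1) / t.genotype_means
    np.testing.assert_allclose(got, plain, rtol=1e-10)


def test_rank_variance_sign_reversal():
    rng = np.random.default_rng(3)
    t = random_table(rng, 4, 5)
    neg = GxETable("yield", -t.data)
    np.testing.assert_allclose(
        idx.variance_of_rank(t), idx.variance_of_rank(neg), atol=1e-12
    )


def test_duplicated_environments_scale_ecovalence(t1):
    """Duplicating the environment set doubles W_i but leaves W'_i fixed."""
    doubled = GxETable("yield", pd.concat(
        [t1.data, t1.data.set_axis(["e4", "e5", "e6"], axis=1)], axis=1
    ))
    np.testing.assert_allclose(
        idx.ecovalence(doubled), 2 * idx.ecovalence(t1), atol=1e-12
    )
    np.testing.assert_allclose(
        idx.ecovalence(doubled, modified=True),
        idx.ecovalence(t1, modified=True),
        atol=1e-12,
    )


def test_degrees_of_freedom_errors(t1):
    two_env = t1.subset(environments=["e1", "e2"])
    with pytest.raises(ValueError):
        idx.deviation_mean_squares(two_env)
    with pytest.raises(ValueError):
        idx.stability_variance(t1)  # G = 2
    flat = GxETable("yield", pd.DataFrame(
        [[1.0, 1.0], [2.0, 2.0]], index=["a", "b"], columns=["e1", "e2"]
    ))
    with pytest.raises(ValueError):
        idx.coefficient_of_regression(flat)  # all environment means equal
    with pytest.raises(ValueError):
        idx.adjusted_cv(GxETable("yield", t1.data - 4.0))  # nonpositive means


def test_single_genotype_slope_is_one():
    t = GxETable("yield", pd.DataFrame([[1.0, 2.0, 4.0]], index=["g"],
                                       columns=["e1", "e2", "e3"]))
    assert idx.coefficient_of_regression(t)["g"] == pytest.approx(1.0)
    # D2 of a lone genotype is its own regression residual SS
    assert idx.genotypic_stability(t)["g"] == pytest.approx(
        idx.deviation_mean_squares(t)["g"] * (3 - 2), abs=1e-12
    )


def test_constant_genotype_r2_missing():
    t = GxETable("yield", pd.DataFrame(
        [[3.0, 3.0, 3.0], [1.0, 2.0, 6.0]], index=["flat", "var"],
        columns=["e1", "e2", "e3"],
    ))
    with pytest.warns(UserWarning):
        r2 = idx.coefficient_of_determination(t)
    assert np.isnan(r2["flat"]) and np.isfinite(r2["var"])


# ---------------------------------------------------------------------------
# compute_all / unit transform
# ---------------------------------------------------------------------------


def test_compute_all_t1(t1):
    with pytest.warns(UserWarning):  # Shukla needs G >= 3
        res = compute_all(t1, lambda_=5.0, sqrt_squared_units=True)
    assert res.table.loc["g2", "superiority_measure"] == pytest.approx(
        np.sqrt(10 / 3), abs=1e-9
    )
    assert res.sqrt_applied["ecovalence"]
    assert res.table["stability_variance"].isna().all()
    assert "stability_variance" in res.flags
    # dimension-less slope untouched
    assert res.table.loc["g1", "coefficient_of_regression"] == pytest.approx(5 / 7)


def test_compute_all_requires_lambda(t1):
    with pytest.raises(ValueError, match="lambda"):
        compute_all(t1, indices=("safety_first_index",))


def test_unit_transform_preserves_ranking():
    rng = np.random.default_rng(5)
    t = random_table(rng, 6, 6)
    raw = compute_all(t, lambda_=5.0, sqrt_squared_units=False)
    cooked = apply_unit_transform(raw)
    for name in idx.SQUARED_UNIT_INDICES:
        r1 = raw.table[name].rank()
        r2 = cooked.table[name].rank()
        pd.testing.assert_series_equal(r1, r2, check_names=False)


def test_unit_transform_skips_negative_shukla():
    rng = np.random.default_rng(21)
    # heavy noise virtually guarantees some negative Shukla estimate
    for _ in range(20):
        t = random_table(rng, 6, 4)
        res = compute_all(t, sqrt_squared_units=False,
                          indices=("stability_variance",))
        if (res.table["stability_variance"] < 0).any():
            cooked = apply_unit_transform(res, extended=True)
            pd.testing.assert_series_equal(
                cooked.table["stability_variance"],
                res.table["stability_variance"],
            )
            assert "stability_variance" in cooked.flags
            return
    pytest.fail("no negative Shukla value encountered")


def test_multi_trait_same_machinery(small_pool):
    """Any trait column runs through the identical index machinery."""
    model = small_pool
    # build a protein table from the yield table's genotypes
    from gxestab import GenerativeModel, simulate_phenotypes

    ds = simulate_phenotypes(
        model.params, GenerativeModel(secondary_traits=("grain_protein",)),
        50, seed=4,
    )
    res = compute_all(ds.tables["grain_protein"], indices=("superiority_measure",))
    assert res.trait == "grain_protein"
    assert (res.table["superiority_measure"] >= 0).all()
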