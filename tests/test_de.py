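"""Moderated differential expression, BH adjustment, the leave-one-out
robustness procedure and the final signature filters."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rbnsig.de import (
    bh_adjust,
    final_gene_filter,
    fit_moderated_de,
    initial_gene_selection,
    lool,
    lool_pancancer_fraction,
)
from rbnsig.rb_status import DiscoveryGroups

from conftest import matrix_from


def pooled_t_oracle(xa, xb):
    """Independent ordinary pooled two-sample t (scipy)."""
    res = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    return res.statistic, res.pvalue


def test_disabled_prior_matches_pooled_t_oracle(rng):
    """With the variance prior disabled the moderated statistic is the
    ordinary pooled t, checked against scipy on a 50 x 12 fixture."""
    x = rng.standard_normal((50, 12))
    m = matrix_from(x)
    a, b = m.samples[:6], m.samples[6:]
    de = fit_moderated_de(m, a, b, prior_df=0)
    t_ref, p_ref = pooled_t_oracle(x[:, :6], x[:, 6:])
    np.testing.assert_allclose(de["t"].to_numpy(), t_ref, atol=1e-9)
    np.testing.assert_allclose(de["p"].to_numpy(), p_ref, atol=1e-9)


def test_equal_variance_limit_reduces_to_pooled_t(rng):
    """When every gene has the same sample variance, shrinkage collapses to
    that common value and moderated t equals ordinary pooled t."""
    base = rng.standard_normal(10)
    shifts = np.linspace(-2, 2, 30)
    x = np.vstack([base + s for s in shifts])  # identical within-row spread
    x[:, 5:] += np.linspace(0, 1, 30)[:, None]  # group-mean offsets only
    m = matrix_from(x)
    a, b = m.samples[:5], m.samples[5:]
    de = fit_moderated_de(m, a, b)  # prior estimated from data
    t_ref, _ = pooled_t_oracle(x[:, :5], x[:, 5:])
    np.testing.assert_allclose(de["t"].to_numpy(), t_ref, atol=1e-9)


def test_identical_groups_give_null_gene(rng):
    x = rng.standard_normal((5, 8))
    x[2, 4:] = x[2, :4]  # gene 3: group A values equal group B values
    m = matrix_from(x)
    de = fit_moderated_de(m, m.samples[:4], m.samples[4:])
    assert de.loc["g3", "log2fc"] == pytest.approx(0.0, abs=1e-12)
    assert de.loc["g3", "t"] == pytest.approx(0.0, abs=1e-12)
    assert de.loc["g3", "p"] == pytest.approx(1.0, abs=1e-12)


def test_group_validation(rng):
    m = matrix_from(rng.standard_normal((3, 6)))
    with pytest.raises(ValueError, match="overlap"):
        fit_moderated_de(m, ["s1", "s2"], ["s2", "s3"])
    with pytest.raises(KeyError):
        fit_moderated_de(m, ["s1", "s2"], ["s3", "zz"])
    with pytest.raises(ValueError, match="at least 2"):
        fit_moderated_de(m, ["s1"], ["s2", "s3"])


def test_bh_adjustment_closed_forms():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.5]), [0.5])
    np.testing.assert_allclose(bh_adjust([0.04, 0.01]), [0.04, 0.02])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@pytest.mark.parametrize(
    "log2fc,q,selected",
    [(0.60, 0.05, True), (0.58, 0.01, False), (2.0, 0.10, False), (-0.585, 0.099, True)],
)
def test_initial_selection_thresholds(log2fc, q, selected):
    de = pd.DataFrame({"log2fc": [log2fc], "q": [q]}, index=["g"])
    assert (["g"] == initial_gene_selection(de)) is selected


def _toy_groups(n, m):
    return DiscoveryGroups(
        defective=[f"s{i + 1}" for i in range(n)],
        proficient=[f"s{n + j + 1}" for j in range(m)],
        platform="tcga",
    )


def lool_oracle(matrix, groups, genes):
    """Naive enumeration: materialize every (defective, proficient) subset
    pair as a fresh matrix and rerun the public moderated fit."""
    counts = pd.Series(0, index=genes, dtype=int)
    for drop_d, drop_p in itertools.product(groups.defective, groups.proficient):
        a = [s for s in groups.defective if s != drop_d]
        b = [s for s in groups.proficient if s != drop_p]
        sub = matrix.subset_genes(genes).subset_samples(a + b)
        de = fit_moderated_de(sub, a, b)
        counts += ((de["log2fc"].abs() >= 1.0) & (de["q"] < 0.1)).astype(int)
    return counts / (groups.n * groups.m)


def test_lool_subset_count_and_planted_gene(rng):
    groups = _toy_groups(3, 3)
    x = rng.standard_normal((4, 6)) * 0.05
    x[0, :3] += 2.0  # planted gene with log2FC 2 and tiny noise
    m = matrix_from(x)
    res = lool(m, groups, m.genes)
    assert res.n_subsets == 9
    assert res.table.loc["g1", "robustness_fraction"] == 1.0
    assert res.table.loc["g1", "direction_consistency"] == 1.0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    # n, m >= 3 so every leave-one-out subset still has two samples per group
    n=st.integers(3, 6),
    m=st.integers(3, 6),
    n_genes=st.integers(2, 8),
    seed=st.integers(0, 10_000),
)
def test_lool_matches_naive_enumeration(n, m, n_genes, seed):
    """Robustness fractions are identical to brute-force enumeration of all
    n*m leave-one-out subsets on random instances."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_genes, n + m))
    x[: max(1, n_genes // 2), :n] += rng.uniform(0, 2)  # some genes shifted
    m_ = matrix_from(x)
    groups = _toy_groups(n, m)
    res = lool(m_, groups, m_.genes)
    expected = lool_oracle(m_, groups, m_.genes)
    np.testing.assert_allclose(
        res.table["robustness_fraction"].to_numpy(), expected.to_numpy(), atol=1e-12
    )


def test_lool_cap_and_minimum_sizes(rng):
    m = matrix_from(rng.standard_normal((2, 8)))
    with pytest.raises(ValueError, match="cap"):
        lool(m, _toy_groups(4, 4), m.genes, subset_cap=10)
    with pytest.raises(ValueError, match="at least 2"):
        lool(m, _toy_groups(1, 7), m.genes)


def test_final_filter_thresholds():
    table = pd.DataFrame(
        {
            "robustness_fraction": [0.25, 0.10, 0.30, 0.20],
            "mean_z_defective": [0.5, 0.5, 0.15, -0.6],
            "direction_consistency": [0.8, 0.9, 0.9, 0.61],
        },
        index=["keep_up", "weak_fraction", "weak_mean", "keep_down"],
    )
    from rbnsig.de import LoolResult

    sig = final_gene_filter(LoolResult(table=table, n_subsets=100))
    assert sig.genes == ["keep_up", "keep_down"]
    assert sig.directions == {"keep_up": 1, "keep_down": -1}
    assert sig.valid


def test_final_filter_empty_flags_invalid():
    from rbnsig.de import LoolResult

    table = pd.DataFrame(
        {"robustness_fraction": [0.05], "mean_z_defective": [0.1], "direction_consistency": [0.5]},
        index=["g"],
    )
    sig = final_gene_filter(LoolResult(table=table, n_subsets=10))
    assert not sig.valid and sig.genes == []


def test_raising_min_fraction_never_adds_genes(rng):
    from rbnsig.de import LoolResult

    table = pd.DataFrame(
        {
            "robustness_fraction": rng.uniform(0, 1, 50),
            "mean_z_defective": rng.uniform(-1, 1, 50),
            "direction_consistency": rng.uniform(0, 1, 50),
        },
        index=[f"g{i}" for i in range(50)],
    )
    res = LoolResult(table=table, n_subsets=10)
    previous = None
    for frac in np.linspace(0, 1, 11):
        genes = set(final_gene_filter(res, min_fraction=frac).genes)
        if previous is not None:
            assert genes <= previous
        previous = genes


@pytest.mark.parametrize("n,expected", [(30, 0.50), (21, 0.50), (20, 0.20), (10, 0.20), (0, 0.20)])
def test_pancancer_fraction_branch(n, expected):
    assert lool_pancancer_fraction(n) == expected
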