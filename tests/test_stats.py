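import itertools
import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from entropydiff import (
    PositivityError,
    adjust_pvalues,
    de_ttest_pvalue,
    dse_permutation_pvalue,
    fligner_killeen_pvalue,
)

from .conftest import oracle_entropy, oracle_fligner_two_sample

# ---------------------------------------------------------------- DSE perm


def exhaustive_dse_pvalue(a, b):
    """Exact permutation p over all (n1+n2)! arrangements, stdlib only."""
    obs = abs(oracle_entropy(a) - oracle_entropy(b))
    pool = list(a) + list(b)
    n1 = len(a)
    count = total = 0
    for perm in itertools.permutations(pool):
        d = abs(oracle_entropy(perm[:n1]) - oracle_entropy(perm[n1:]))
        count += d >= obs - 1e-12
        total += 1
    return count / total


def test_permutation_identical_lists_give_p_one():
    r = dse_permutation_pvalue([1, 2], [1, 2], seed=0)
    assert r.statistic == 0.0
    assert r.p_raw == 1.0


def test_permutation_deterministic_and_swap_symmetric():
    a, b = [1.0, 4.0, 2.5], [3.0, 9.0, 0.5, 7.0]
    r1 = dse_permutation_pvalue(a, b, n_permutations=500, seed=11)
    r2 = dse_permutation_pvalue(a, b, n_permutations=500, seed=11)
    r3 = dse_permutation_pvalue(b, a, n_permutations=500, seed=11)
    assert r1.p_raw == r2.p_raw
    assert r1.p_raw == r3.p_raw
    assert r1.statistic == r3.statistic


def test_permutation_matches_exhaustive_enumeration():
    a, b = [1.0, 1.0], [1.0, 9.0]
    exact = exhaustive_dse_pvalue(a, b)
    nperm = 4000
    r = dse_permutation_pvalue(a, b, n_permutations=nperm, seed=3)
    band = 3 * math.sqrt(exact * (1 - exact) / nperm)
    assert abs(r.p_raw - exact) <= band + 1e-12


def test_permutation_bias_corrected_estimator():
    a, b = [1.0, 2.0, 8.0], [4.0, 4.5, 5.0]
    nperm = 200
    plain = dse_permutation_pvalue(a, b, n_permutations=nperm, seed=5)
    corrected = dse_permutation_pvalue(
        a, b, n_permutations=nperm, seed=5, bias_corrected=True
    )
    count = round(plain.p_raw * nperm)
    assert corrected.p_raw == pytest.approx((count + 1) / (nperm + 1))
    assert corrected.p_raw > 0


def test_permutation_rejects_bad_input():
    with pytest.raises(PositivityError):
        dse_permutation_pvalue([1, 0.0], [1, 2], seed=0)
    with pytest.raises(ValueError):
        dse_permutation_pvalue([1, 2], [1, 2], n_permutations=0)
    with pytest.raises(ValueError):
        dse_permutation_pvalue([1], [1, 2])


@given(
    st.lists(st.floats(min_value=0.1, max_value=100), min_size=2, max_size=6),
    st.lists(st.floats(min_value=0.1, max_value=100), min_size=2, max_size=6),
)
@settings(max_examples=50, deadline=None)
def test_permutation_pvalue_in_unit_interval(a, b):
    r = dse_permutation_pvalue(a, b, n_permutations=50, seed=1)
    assert 0.0 <= r.p_raw <= 1.0
    assert 0.0 <= r.statistic <= 1.0


# ------------------------------------------------------------------ FK test


def test_fligner_identical_groups():
    r = fligner_killeen_pvalue([1, 2, 3, 4], [1, 2, 3, 4])
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_raw == pytest.approx(1.0, abs=1e-9)


def test_fligner_matches_independent_reference():
    # frozen external reference (R 4.3.3 fligner.test on the logs)
    a = [2.5, 3.1, 4.8, 5.2, 6.0, 7.3]
    b = [1.2, 1.9, 2.2, 8.8, 9.4, 10.1]
    r = fligner_killeen_pvalue(a, b)
    assert r.statistic == pytest.approx(7.58596071399451, rel=1e-12)
    assert r.p_raw == pytest.approx(0.00588246059938483, rel=1e-12)
    # hand-coded oracle on the same input
    stat, p = oracle_fligner_two_sample(np.log(a), np.log(b))
    assert r.statistic == pytest.approx(stat, rel=1e-9)
    assert r.p_raw == pytest.approx(p, rel=1e-9)


@given(
    st.lists(
        st.floats(min_value=0.5, max_value=50),
        min_size=3, max_size=12, unique=True,
    ),
    st.lists(
        st.floats(min_value=0.5, max_value=50),
        min_size=3, max_size=12, unique=True,
    ),
)
@settings(max_examples=60, deadline=None)
def test_fligner_agrees_with_hand_coded_oracle(a, b):
    r = fligner_killeen_pvalue(a, b)
    try:
        stat, p = oracle_fligner_two_sample(np.log(a), np.log(b))
    except ZeroDivisionError:  # all pooled deviations tied
        assume(False)
    assert r.statistic == pytest.approx(stat, rel=1e-7, abs=1e-9)
    assert r.p_raw == pytest.approx(p, rel=1e-7, abs=1e-12)
    assert 0.0 <= r.p_raw <= 1.0


def test_fligner_invariant_to_scale_and_log_base():
    # a common positive factor (equivalently, a different log base) shifts
    # (scales) every log equally, leaving the median-centered ranks alone
    from scipy.stats import fligner

    # odd group sizes: an even-sized group's two middle values are exactly
    # equidistant from its median, a structural tie whose floating-point
    # resolution is base-dependent
    rng = np.random.default_rng(2)
    for _ in range(30):
        a = rng.lognormal(1, 0.8, 2 * rng.integers(2, 8) + 1)
        b = rng.lognormal(1, 1.2, 2 * rng.integers(2, 8) + 1)
        r = fligner_killeen_pvalue(a, b)
        scaled = fligner_killeen_pvalue(3.7 * a, 3.7 * b)
        assert scaled.p_raw == pytest.approx(r.p_raw, rel=1e-9)
        _, p_base2 = fligner(np.log2(a), np.log2(b))
        assert p_base2 == pytest.approx(r.p_raw, rel=1e-9)


def test_fligner_degenerate_all_zero_deviations():
    with pytest.warns(RuntimeWarning, match="deviations are zero"):
        r = fligner_killeen_pvalue([5, 5, 5], [2, 2, 2])
    assert r.p_raw == 1.0


def test_fligner_requires_positive_values():
    with pytest.raises(PositivityError):
        fligner_killeen_pvalue([1, -2, 3], [1, 2, 3])


# ------------------------------------------------------------------ t-test


def test_ttest_identical_groups():
    r = de_ttest_pvalue([1, 2, 3], [1, 2, 3])
    assert r.statistic == 0.0
    assert r.p_raw == 1.0


def test_ttest_symmetric_and_welch():
    from scipy import stats as sps

    a, b = [1.0, 2.0, 8.0, 4.0], [4.0, 4.5, 5.0]
    r1, r2 = de_ttest_pvalue(a, b), de_ttest_pvalue(b, a)
    assert r1.p_raw == r2.p_raw
    assert r1.p_raw == sps.ttest_ind(a, b, equal_var=False).pvalue


def test_ttest_degenerate_constant_groups():
    with pytest.warns(RuntimeWarning, match="constant"):
        equal = de_ttest_pvalue([3, 3, 3], [3, 3])
    assert equal.p_raw == 1.0
    with pytest.warns(RuntimeWarning, match="constant"):
        unequal = de_ttest_pvalue([3, 3, 3], [4, 4])
    assert unequal.p_raw == 0.0


# -------------------------------------------------------------- adjustment


def holm_oracle(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adj[i] = running
    return adj


def hochberg_oracle(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i], reverse=True)
    adj = [0.0] * m
    running = 1.0
    for rank, i in enumerate(order):
        running = min(running, min(1.0, (rank + 1) * p[i]))
        adj[i] = running
    return adj


def bh_oracle(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i], reverse=True)
    adj = [0.0] * m
    running = 1.0
    for rank, i in enumerate(order):
        running = min(running, min(1.0, m / (m - rank) * p[i]))
        adj[i] = running
    return adj


@pytest.mark.parametrize(
    "method, expected",
    [
        ("bonferroni", [0.04, 0.08, 0.12, 0.16]),
        ("holm", [0.04, 0.06, 0.06, 0.06]),
        ("hochberg", [0.04, 0.04, 0.04, 0.04]),
        ("bh", [0.04, 0.04, 0.04, 0.04]),
        ("by", [1 / 12, 1 / 12, 1 / 12, 1 / 12]),
    ],
)
def test_adjust_known_values(method, expected):
    # hand-applied step rules on p = (0.01, 0.02, 0.03, 0.04); same numbers
    # as R's p.adjust
    got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], method)
    assert got == pytest.approx(expected, rel=1e-12)


def test_adjust_bonferroni_pair_and_singleton():
    assert adjust_pvalues([0.01, 0.04], "bonferroni") == pytest.approx(
        [0.02, 0.08]
    )
    for method in ["bonferroni", "holm", "hochberg", "bh", "by"]:
        assert adjust_pvalues([0.3], method) == pytest.approx([0.3])


@given(
    st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=25)
)
@settings(max_examples=150, deadline=None)
def test_adjust_properties(p):
    p_arr = np.asarray(p)
    for method, oracle in [
        ("holm", holm_oracle),
        ("hochberg", hochberg_oracle),
        ("bh", bh_oracle),
    ]:
        adj = adjust_pvalues(p, method)
        assert np.all(adj >= p_arr - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))
        assert adj == pytest.approx(oracle(list(p)), rel=1e-9, abs=1e-12)
    bonf = adjust_pvalues(p, "bonferroni")
    assert bonf == pytest.approx(np.minimum(p_arr * len(p), 1.0))
    by = adjust_pvalues(p, "by")
    assert np.all((by >= 0) & (by <= 1))
    # BH/BY adjusted sequences are monotone in the raw-p sorted order
    order = np.argsort(p_arr, kind="stable")
    for seq in (adjust_pvalues(p, "bh")[order], by[order]):
        assert np.all(np.diff(seq) >= -1e-12)


def test_adjust_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    mapping = {
        "bonferroni": "bonferroni",
        "holm": "holm",
        "hochberg": "simes-hochberg",
        "bh": "fdr_bh",
        "by": "fdr_by",
    }
    rng = np.random.default_rng(8)
    for _ in range(25):
        p = rng.random(rng.integers(2, 40))
        for ours, theirs in mapping.items():
            assert adjust_pvalues(p, ours) == pytest.approx(
                multipletests(p, method=theirs)[1], rel=1e-12
            )


def test_adjust_rejects_bad_input():
    with pytest.raises(ValueError, match="valid methods"):
        adjust_pvalues([0.1], "sidak")
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.5], "bh")
    with pytest.raises(ValueError):
        adjust_pvalues([], "bh")
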