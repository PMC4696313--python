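import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repeatable",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def demo_pair():
    from entropydiff import load_demo_pair

    return load_demo_pair()


@pytest.fixture(scope="session")
def demo_paths():
    """Filesystem paths of the packaged demo matrices."""
    from importlib import resources

    base = resources.files("entropydiff") / "data"
    return str(base / "demo_case.tsv"), str(base / "demo_control.tsv")


# ---------------------------------------------------------------------------
# Independent oracles, written with the stdlib only so they share no code
# with the implementation under test.


def oracle_entropy(values):
    """Normalized Shannon entropy via plain Python arithmetic."""
    values = [float(v) for v in values]
    total = math.fsum(values)
    h = -math.fsum((v / total) * math.log2(v / total) for v in values)
    return h / math.log2(len(values))


def oracle_cv(values):
    import statistics

    return statistics.stdev(values) / abs(statistics.mean(values))


def oracle_mean(values):
    return math.fsum(values) / len(values)


def oracle_fligner_two_sample(a, b):
    """Median-centered Fligner-Killeen chi-square statistic and p-value,
    coded from the textbook definition (mid-ranks for ties)."""
    import statistics

    from scipy.stats import chi2, norm, rankdata

    a = [float(v) for v in a]
    b = [float(v) for v in b]
    dev = [abs(v - statistics.median(a)) for v in a] + [
        abs(v - statistics.median(b)) for v in b
    ]
    n_total = len(dev)
    ranks = rankdata(dev)
    scores = [norm.ppf(0.5 + r / (2.0 * (n_total + 1))) for r in ranks]
    grand = math.fsum(scores) / n_total
    var = math.fsum((s - grand) ** 2 for s in scores) / (n_total - 1)
    mean_a = math.fsum(scores[: len(a)]) / len(a)
    mean_b = math.fsum(scores[len(a):]) / len(b)
    stat = (
        len(a) * (mean_a - grand) ** 2 + len(b) * (mean_b - grand) ** 2
    ) / var
    return stat, float(chi2.sf(stat, df=1))


@pytest.fixture(scope="session")
def oracles():
    return {
        "dse": oracle_entropy,
        "dcv": oracle_cv,
        "de": oracle_mean,
        "fligner": oracle_fligner_two_sample,
    }


def make_pair(rows, case_cols=("c1", "c2", "c3"), ctrl_cols=("k1", "k2", "k3")):
    """Build a row-matched DataFrame pair from {label: (case, control)}."""
    case = pd.DataFrame(
        {lab: vals[0] for lab, vals in rows.items()}, index=list(case_cols)
    ).T
    ctrl = pd.DataFrame(
        {lab: vals[1] for lab, vals in rows.items()}, index=list(ctrl_cols)
    ).T
    case.index.name = ctrl.index.name = "feature"
    return case, ctrl
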