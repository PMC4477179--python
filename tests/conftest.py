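"""Shared fixtures: deterministic RNGs and session-scoped simulation studies.

The acceptance-level checks compare Monte-Carlo rejection rates against
published reference values, so several tests share one 5000-replicate
study per scenario; those studies are computed once per session here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import triadppi as tp
from triadppi.parent import parent_lrt
from triadppi.tdt import comb_tdt, paren_tdt, tdt
from triadppi.transmission import transmission_lrt
from triadppi.joint import ppi_ct_from_tests

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: master seed for every stochastic fixture in the suite
MASTER_SEED = 1


def mc_study(spec, reps, seed, single_intercept=False):
    """Simulate ``reps`` studies and collect per-replicate statistics.

    Returns a dict of per-test p-value arrays plus the signed-root z
    components and relative-risk estimates needed by the composite-test
    and estimation checks.
    """
    rng = np.random.default_rng(seed)
    expected = tp.expected_cell_frequencies(spec)
    probs = expected.counts.ravel() / expected.total
    draws = rng.multinomial(spec.n, probs, size=reps)
    shape = expected.counts.shape

    keys = ["offspring", "parent", "ppi_ct", "tdt", "parentdt", "combtdt"]
    if single_intercept:
        keys.append("parent_single")
    out = {k: np.full(reps, np.nan) for k in keys}
    out["rr_offspring"] = np.full(reps, np.nan)
    out["rr_parent"] = np.full(reps, np.nan)
    out["z_t"] = np.full(reps, np.nan)
    out["z_p"] = np.full(reps, np.nan)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(reps):
            table = tp.CellCountTable(
                draws[i].reshape(shape).astype(float), expected.design
            )
            t = transmission_lrt(table)
            p = parent_lrt(table)
            out["offspring"][i] = t.pvalue
            out["parent"][i] = p.pvalue
            out["rr_offspring"][i] = t.estimate
            if p.estimate is not None:
                out["rr_parent"][i] = p.estimate
            if not (t.is_na or p.is_na):
                out["z_t"][i] = t.sign * np.sqrt(t.statistic)
                out["z_p"][i] = p.sign * np.sqrt(p.statistic)
                out["ppi_ct"][i] = ppi_ct_from_tests(t, p).pvalue
            out["tdt"][i] = tdt(table).pvalue
            out["parentdt"][i] = paren_tdt(table).pvalue
            out["combtdt"][i] = comb_tdt(table).pvalue
            if single_intercept:
                out["parent_single"][i] = parent_lrt(
                    table, mating_intercepts=False
                ).pvalue
    return out


def rejection_rate(pvals, alpha=0.05):
    ok = np.isfinite(pvals)
    return float((pvals[ok] < alpha).mean())


@pytest.fixture(scope="session")
def null300_study():
    """5000 null studies of 300 triads, homogeneous population
    (allele frequency 0.3, MBR 0.2, all relative risks 1)."""
    return mc_study(tp.ScenarioSpec.homogeneous(n=300), reps=5000, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def maternal300_study():
    """5000 studies of 300 triads under the maternally-mediated-only
    scenario (R = 1, S1 = 1.4, apparent Rm1 = 1.2)."""
    return mc_study(
        tp.ScenarioSpec.homogeneous(n=300, s1=1.4), reps=5000, seed=MASTER_SEED + 1
    )


@pytest.fixture(scope="session")
def maternal1200_study():
    """As ``maternal300_study`` with 1200 triads per study."""
    return mc_study(
        tp.ScenarioSpec.homogeneous(n=1200, s1=1.4), reps=5000, seed=MASTER_SEED + 2
    )


def stratified_spec(mbr1, mbr2, f1, f2, ratio, n):
    """Two equal-sized subpopulations; ``ratio`` is the subpopulation-1 vs
    subpopulation-2 child baseline-risk ratio."""
    return tp.ScenarioSpec(
        subpops=[
            tp.Subpopulation(0.5, f1, mbr1, child_risk=ratio),
            tp.Subpopulation(0.5, f2, mbr2, child_risk=1.0),
        ],
        n=n,
    )
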