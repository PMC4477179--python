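"""Log-binomial parent-phenotype model: recovery, robustness, oracles."""

import numpy as np
import pytest
from scipy import optimize

import triadppi as tp
from triadppi.data import CELL_F, CELL_M, CELL_MT
from triadppi.parent import ParentPhenotypeModel, parent_lrt


def test_null_scenario_recovers_mbr_and_unit_rr():
    counts = tp.expected_cell_frequencies(tp.ScenarioSpec.homogeneous(mbr=0.2))
    fit = tp.fit_parent_phenotype(counts)
    assert np.exp(fit.beta[0]) == pytest.approx(1.0, abs=1e-6)
    alpha = fit.alpha(0)
    assert np.exp(alpha) == pytest.approx(np.full(6, 0.2), abs=1e-6)


@pytest.mark.parametrize("coding,rm1,rm2", [
    ("log_additive", 1.4, None),
    ("codominant", 1.4, 1.96),
    ("dominant", 1.5, 1.5),
])
def test_parameter_recovery_on_expected_counts(coding, rm1, rm2):
    spec = tp.ScenarioSpec.homogeneous(rm1=rm1, rm2=rm2)
    fit = tp.fit_parent_phenotype(
        tp.expected_cell_frequencies(spec), coding=coding
    )
    assert np.exp(fit.beta[0]) == pytest.approx(rm1, rel=1e-5)


def test_stratification_robustness_and_single_intercept_bias():
    # admixed null with differing allele frequencies and mother baseline
    # risks: mating-type intercepts absorb the confounding ...
    spec = tp.ScenarioSpec(
        subpops=[
            tp.Subpopulation(0.5, 0.1, 0.1, child_risk=3.0),
            tp.Subpopulation(0.5, 0.3, 0.2, child_risk=1.0),
        ]
    )
    counts = tp.expected_cell_frequencies(spec)
    robust = tp.fit_parent_phenotype(counts)
    assert robust.beta[0] == pytest.approx(0.0, abs=1e-6)
    # ... while the single-intercept ablation is biased away from zero
    biased = tp.fit_parent_phenotype(counts, mating_intercepts=False)
    assert abs(biased.beta[0]) > 0.05


def test_parent_lrt_degenerate_without_affected_mothers():
    counts = tp.expected_cell_frequencies(tp.ScenarioSpec.homogeneous(n=300))
    arr = counts.counts.copy()
    arr[:, 0] += arr[:, 1]
    arr[:, 1] = 0.0
    res = parent_lrt(tp.CellCountTable(arr))
    assert res.is_na


def test_parent_lrt_degenerate_without_discordant_parents():
    # all mass on genotype-concordant mating types: no information on beta
    arr = np.zeros((15, 2))
    for i, mt in enumerate(CELL_MT):
        if CELL_M[i] == CELL_F[i]:
            arr[i] = [8.0, 2.0]
    res = parent_lrt(tp.CellCountTable(arr))
    assert res.is_na
    assert "discordant" in res.message


def _generic_bernoulli_mle(counts, coding="log_additive"):
    """Independent oracle: SLSQP on the explicitly written Bernoulli
    log-likelihood over 6 intercepts + slope, with eta <= 0."""
    pair = 3 * CELL_M + CELL_F
    tot = counts.mother_strata().sum(axis=1)
    aff = counts.mother_strata()[:, 1]
    rows = []
    for p in range(9):
        mask = pair == p
        if tot[mask].sum() > 0:
            rows.append((CELL_MT[mask][0], CELL_M[mask][0],
                         aff[mask].sum(), tot[mask].sum()))
    mt = np.array([r[0] for r in rows])
    m = np.array([r[1] for r in rows], dtype=float)
    y = np.array([r[2] for r in rows])
    n = np.array([r[3] for r in rows])
    # mating types with no affected mother sit at the alpha -> -inf
    # boundary where their contribution vanishes; a bounded numerical
    # optimizer cannot reach that supremum, so resolve it analytically
    keep = np.array([y[mt == t].sum() > 0 for t in mt])
    mt, m, y, n = mt[keep], m[keep], y[keep], n[keep]
    X = np.column_stack([np.eye(6)[mt], m])

    def negll(theta):
        eta = X @ theta
        with np.errstate(over="ignore", invalid="ignore"):
            one_m = -np.expm1(np.minimum(eta, -1e-12))
            return -float(y @ eta + (n - y) @ np.log(one_m))

    cons = {"type": "ineq", "fun": lambda th: -1e-9 - X @ th}
    x0 = np.r_[np.full(6, np.log(max(y.sum() / n.sum(), 1e-3))), 0.0]
    res = optimize.minimize(negll, x0, method="SLSQP", constraints=[cons],
                            options={"maxiter": 500, "ftol": 1e-14})
    # polish with an interior-point pass; keep the better of the two
    res2 = optimize.minimize(
        negll, res.x, method="trust-constr",
        constraints=[optimize.LinearConstraint(X, -np.inf, -1e-9)],
        options={"xtol": 1e-14, "gtol": 1e-12, "maxiter": 3000},
    )
    return max(-res.fun, -res2.fun)


@pytest.mark.parametrize("seed", range(10))
def test_oracle_equivalence_generic_maximization(seed):
    rng = np.random.default_rng(300 + seed)
    spec = tp.ScenarioSpec.homogeneous(
        allele_freq=rng.uniform(0.2, 0.5), mbr=rng.uniform(0.15, 0.35),
        rm1=rng.uniform(0.8, 1.5), n=400,
    )
    table = tp.simulate_counts(spec, rng)
    fit = tp.fit_parent_phenotype(table)
    if not np.all(np.isfinite(fit.params)):
        pytest.skip("degenerate draw")
    oracle = _generic_bernoulli_mle(table)
    assert fit.llf == pytest.approx(oracle, abs=1e-6)


def test_oracle_equivalence_statsmodels_log_binomial():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(42)
    table = tp.simulate_counts(tp.ScenarioSpec.homogeneous(rm1=1.3, n=600), rng)
    pair = 3 * CELL_M + CELL_F
    tot = table.mother_strata().sum(axis=1)
    aff = table.mother_strata()[:, 1]
    mt, m, y, n = [], [], [], []
    for p in range(9):
        mask = pair == p
        if tot[mask].sum() > 0:
            mt.append(CELL_MT[mask][0]); m.append(CELL_M[mask][0])
            y.append(aff[mask].sum()); n.append(tot[mask].sum())
    mt, m, y, n = map(np.array, (mt, m, y, n))
    X = np.column_stack([np.eye(6)[mt][:, sorted(set(mt))], m.astype(float)])
    fam = sm.families.Binomial(link=sm.families.links.Log())
    glm = sm.GLM(np.column_stack([y, n - y]), X, family=fam).fit(maxiter=200)
    mine = tp.fit_parent_phenotype(table)
    assert mine.beta[0] == pytest.approx(glm.params[-1], abs=1e-5)
    # GLM reports expected-information SEs, we use observed information;
    # they agree closely but not exactly for this non-canonical link
    assert mine.bse[0] == pytest.approx(glm.bse[-1], rel=0.02)


# ---------------------------------------------------------------------------
# two-sex design
# ---------------------------------------------------------------------------

def two_sex_counts(rm1=1.4, rf1=1.4, **kw):
    spec = tp.ScenarioSpec.homogeneous(fbr=0.1, rm1=rm1, rf1=rf1, **kw)
    return tp.expected_cell_frequencies(spec)


def test_two_sex_pooled_recovers_common_rr():
    fit = tp.fit_parent_phenotype(two_sex_counts())
    assert np.exp(fit.beta[0]) == pytest.approx(1.4, rel=1e-5)


def test_two_sex_free_fit_recovers_each_sex():
    fit = tp.fit_parent_phenotype(two_sex_counts(rm1=1.4, rf1=1.1), pooled=False)
    assert np.exp(fit.beta[0]) == pytest.approx(1.4, rel=1e-4)
    assert np.exp(fit.theta[0]) == pytest.approx(1.1, rel=1e-4)


def test_sex_equality_test_null_and_alternative():
    eq0 = tp.sex_equality_test(two_sex_counts())
    assert eq0.statistic == pytest.approx(0.0, abs=1e-7)
    eq1 = tp.sex_equality_test(two_sex_counts(rm1=1.4, rf1=1.0))
    assert eq1.statistic > 0.1
    # the equality-test statistic is an NCP: linear in the study size
    big = two_sex_counts(rm1=1.4, rf1=1.0, n=600)
    eq2 = tp.sex_equality_test(big)
    assert eq2.statistic == pytest.approx(2 * eq1.statistic, rel=1e-6)


def test_one_sex_fit_is_two_sex_restricted_to_mothers():
    counts = two_sex_counts(rm1=1.4, rf1=1.1)
    mothers_only = tp.CellCountTable(counts.mother_strata())
    one = tp.fit_parent_phenotype(mothers_only)
    free = tp.fit_parent_phenotype(counts, pooled=False)
    assert one.beta[0] == pytest.approx(free.beta[0], abs=1e-6)


def test_pooled_equals_either_sex_under_equality():
    counts = two_sex_counts(rm1=1.4, rf1=1.4)
    pooled = tp.fit_parent_phenotype(counts, pooled=True)
    mothers = tp.fit_parent_phenotype(tp.CellCountTable(counts.mother_strata()))
    assert pooled.beta[0] == pytest.approx(mothers.beta[0], abs=1e-6)
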