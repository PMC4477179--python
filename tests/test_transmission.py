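"""Log-linear transmission model: recovery, LRT, oracles, robustness."""

import numpy as np
import pytest
from scipy import optimize

import triadppi as tp
from triadppi.data import CELL_C, CELL_LOGW, CELL_M, CELL_MT
from triadppi.transmission import TransmissionModel, transmission_lrt


def null_counts(n=300, p=0.3):
    return tp.expected_cell_frequencies(tp.ScenarioSpec.homogeneous(n=n, allele_freq=p))


def test_null_expected_counts_give_zero_statistic_and_unit_rr():
    res = transmission_lrt(null_counts())
    assert res.statistic == pytest.approx(0.0, abs=1e-8)
    assert res.estimate == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("coding,r1,r2", [
    ("log_additive", 1.4, None),
    ("codominant", 1.4, 1.96),
    ("codominant", 1.3, 2.5),
])
def test_parameter_recovery_on_expected_counts(coding, r1, r2):
    # the generator and the model share the same family, so the MLE on
    # expected counts recovers the generating relative risks exactly
    spec = tp.ScenarioSpec.homogeneous(r1=r1, r2=r2)
    fit = tp.fit_transmission(tp.expected_cell_frequencies(spec), coding=coding)
    rr = np.exp(fit.gamma)
    assert rr[0] == pytest.approx(r1, rel=1e-5)
    if coding == "codominant":
        assert rr[1] == pytest.approx(r2 if r2 is not None else r1**2, rel=1e-5)


def test_maternal_effect_recovery_and_adjusted_gamma_test():
    spec = tp.ScenarioSpec.homogeneous(s1=1.4, s2=1.96)
    counts = tp.expected_cell_frequencies(spec)
    mat = tp.maternal_effect_test(counts)
    assert mat.estimate == pytest.approx(1.4, rel=1e-5)
    # no child effect: the maternally-adjusted transmission LRT is null
    adj = transmission_lrt(counts, maternal=True)
    assert adj.statistic == pytest.approx(0.0, abs=1e-7)
    # and with a child effect but no maternal effect, rho recovers 1
    spec2 = tp.ScenarioSpec.homogeneous(r1=1.4)
    mat2 = tp.maternal_effect_test(tp.expected_cell_frequencies(spec2))
    assert mat2.estimate == pytest.approx(1.0, abs=1e-5)


def test_fitted_cell_expectations_conserve_mating_type_totals():
    rng = np.random.default_rng(3)
    spec = tp.ScenarioSpec.homogeneous(r1=1.3)
    table = tp.simulate_counts(spec, rng)
    fit = tp.fit_transmission(table)
    fitted = fit.fitted_cell_counts()
    observed = table.genotype_margin()
    for mt in range(6):
        mask = CELL_MT == mt
        assert fitted[mask].sum() == pytest.approx(observed[mask].sum(), abs=1e-8)


def test_stratification_robustness_on_admixed_expected_counts():
    # equal relative risks in both strata: gamma-hat is unbiased on the
    # admixed expected counts, and invariant to scaling baseline risks
    spec = tp.ScenarioSpec(
        subpops=[
            tp.Subpopulation(0.5, 0.1, 0.1, child_risk=3.0),
            tp.Subpopulation(0.5, 0.3, 0.2, child_risk=1.0),
        ],
        r1=1.4,
    )
    fit = tp.fit_transmission(tp.expected_cell_frequencies(spec))
    assert np.exp(fit.gamma[0]) == pytest.approx(1.4, rel=1e-6)


def _generic_multinomial_mle(counts, coding="log_additive"):
    """Independent oracle: maximize the full multinomial log-likelihood
    (explicit mu parameters, softmax over all 15 cells) generically."""
    n = counts.genotype_margin() if hasattr(counts, "genotype_margin") else counts
    x_gamma = CELL_C.astype(float)[:, None] if coding == "log_additive" else \
        np.column_stack([(CELL_C == 1), (CELL_C == 2)]).astype(float)

    def negll(theta):
        mu = np.zeros(6)
        mu[1:] = theta[: 5]
        gamma = theta[5:]
        eta = mu[CELL_MT] + CELL_LOGW + x_gamma @ gamma
        logz = np.log(np.exp(eta - eta.max()).sum()) + eta.max()
        return -(n @ (eta - logz))

    k = x_gamma.shape[1]
    res = optimize.minimize(negll, np.zeros(5 + k), method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-10})
    # polish with a second-order pass from the BFGS solution
    res2 = optimize.minimize(negll, res.x, method="trust-ncg",
                             jac=lambda t: _num_grad(negll, t),
                             hess=lambda t: _num_hess(negll, t),
                             options={"gtol": 1e-12})
    return max(-res.fun, -res2.fun)


def _num_grad(f, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x); e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _num_hess(f, x, h=1e-4):
    k = len(x)
    out = np.zeros((k, k))
    for i in range(k):
        e = np.zeros_like(x); e[i] = h
        out[i] = (_num_grad(f, x + e) - _num_grad(f, x - e)) / (2 * h)
    return 0.5 * (out + out.T)


@pytest.mark.parametrize("seed", range(10))
def test_oracle_equivalence_generic_maximization(seed):
    rng = np.random.default_rng(100 + seed)
    spec = tp.ScenarioSpec.homogeneous(
        allele_freq=rng.uniform(0.15, 0.6), r1=rng.uniform(0.7, 1.6)
    )
    table = tp.simulate_counts(spec, rng)
    fit = tp.fit_transmission(table)
    assert fit.converged
    oracle_ll = _generic_multinomial_mle(table)
    assert fit.llf == pytest.approx(oracle_ll, abs=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_oracle_equivalence_statsmodels_poisson_trick(seed):
    """The multinomial fit via a Poisson log-linear regression with
    mating-type indicators and the ln(2) offset gives the same gamma-hat
    and the same LRT statistic."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(200 + seed)
    table = tp.simulate_counts(tp.ScenarioSpec.homogeneous(r1=1.3), rng)
    n = table.genotype_margin()
    X = np.column_stack([np.eye(6)[CELL_MT], CELL_C.astype(float)])
    X0 = np.eye(6)[CELL_MT]
    full = sm.GLM(n, X, family=sm.families.Poisson(), offset=CELL_LOGW).fit()
    nullf = sm.GLM(n, X0, family=sm.families.Poisson(), offset=CELL_LOGW).fit()
    mine = transmission_lrt(table)
    assert np.log(mine.estimate) == pytest.approx(full.params[-1], abs=1e-6)
    assert mine.statistic == pytest.approx(2 * (full.llf - nullf.llf), abs=1e-6)
    assert mine.sigma == pytest.approx(full.bse[-1], rel=1e-4)


def test_zero_count_mating_types_warn_and_fit():
    n = null_counts().genotype_margin()
    n[CELL_MT == 5] = 0.0  # remove the (2,2) class
    with pytest.warns(UserWarning, match="zero total"):
        model = TransmissionModel(n)
    fit = model.fit()
    assert np.isfinite(fit.llf)


def test_empty_table_rejected():
    with pytest.raises(ValueError, match="empty"):
        TransmissionModel(np.zeros(15))
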