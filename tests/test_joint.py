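"""Joint two-generation model, EM, and the composite test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import triadppi as tp
from triadppi.joint import (
    CompositeInputs,
    JointTriadModel,
    build_groups,
    groups_from_counts,
    ppi_ct_from_tests,
    zc_statistic,
)
from triadppi.parent import parent_lrt
from triadppi.transmission import transmission_lrt


def alt_counts(r1=1.4, rm1=1.4, n=300):
    return tp.expected_cell_frequencies(
        tp.ScenarioSpec.homogeneous(r1=r1, rm1=rm1, n=n)
    )


# ---------------------------------------------------------------------------
# complete data
# ---------------------------------------------------------------------------

def test_complete_data_joint_loglik_is_sum_of_separate_fits():
    counts = alt_counts()
    free = JointTriadModel(counts, constraint="free").fit()
    tr = tp.fit_transmission(counts)
    pr = tp.fit_parent_phenotype(counts)
    assert free.llf == pytest.approx(tr.llf + pr.llf, abs=1e-8)
    assert free.em_iterations == 1


def test_ppi_lrt_null_expected_counts():
    counts = tp.expected_cell_frequencies(tp.ScenarioSpec.homogeneous())
    res = tp.ppi_lrt(counts)
    assert res.statistic == pytest.approx(0.0, abs=1e-7)


def test_ppi_lrt_shared_recovery_and_deviance_additivity():
    counts = alt_counts()
    shared = JointTriadModel(counts, constraint="shared").fit()
    assert np.exp(shared.shared_coef[0]) == pytest.approx(1.4, rel=1e-5)
    # nested-model identity: equality + shared-vs-null = free-vs-null
    free = JointTriadModel(counts, constraint="free").fit()
    null = JointTriadModel(counts, constraint="null").fit()
    eq_stat = 2 * (free.llf - shared.llf)
    shared_stat = 2 * (shared.llf - null.llf)
    full_stat = 2 * (free.llf - null.llf)
    assert eq_stat + shared_stat == pytest.approx(full_stat, abs=1e-8)


def test_generation_equality_test_null_and_alternative():
    assert tp.generation_equality_test(alt_counts()).statistic == pytest.approx(
        0.0, abs=1e-7
    )
    uneq = alt_counts(r1=1.4, rm1=1.0)
    assert tp.generation_equality_test(uneq).statistic > 0.3


# ---------------------------------------------------------------------------
# EM with missing parental genotypes
# ---------------------------------------------------------------------------

def test_em_identity_on_complete_records():
    recs = tp.simulate_study(tp.ScenarioSpec.homogeneous(n=200, r1=1.4), 3)
    table = tp.tabulate(recs)
    direct = JointTriadModel(table, constraint="shared").fit()
    via_records = JointTriadModel(recs, constraint="shared").fit()
    assert via_records.em_iterations == 1
    assert via_records.llf == pytest.approx(direct.llf, abs=1e-9)


def test_em_recovers_rr_from_expected_pseudo_data_with_missing_fathers():
    counts = alt_counts()
    for rate in (0.2, 1.0):
        groups = groups_from_counts(counts, missing_father_rate=rate)
        fit = JointTriadModel(groups, constraint="shared").fit()
        assert fit.converged
        assert np.exp(fit.shared_coef[0]) == pytest.approx(1.4, abs=1e-3)


def test_em_loglik_monotone_on_random_incomplete_datasets():
    # many small random datasets with heavy missingness; the fit itself
    # raises if the observed log-likelihood ever decreases
    rng = np.random.default_rng(7)
    n_checked = 0
    for i in range(60):
        spec = tp.ScenarioSpec.homogeneous(
            allele_freq=float(rng.uniform(0.1, 0.7)),
            mbr=float(rng.uniform(0.1, 0.3)),
            r1=float(rng.uniform(0.7, 1.6)),
            rm1=float(rng.uniform(0.7, 1.5)),
            n=60,
            missing_father_rate=float(rng.uniform(0.1, 0.8)),
            missing_mother_rate=float(rng.uniform(0.0, 0.3)),
        )
        recs = tp.simulate_study(spec, rng)
        model = JointTriadModel(recs, constraint="shared")
        if model.complete:
            continue
        fit = model.fit()
        trace = np.asarray(fit.em_trace)
        assert np.all(np.diff(trace) >= -1e-7 * (1 + np.abs(trace[1:])))
        n_checked += 1
    assert n_checked > 40


def test_ppi_lrt_with_all_fathers_missing_retains_information():
    counts = alt_counts()
    res_full = tp.ppi_lrt(counts)
    res_missing = tp.ppi_lrt(groups_from_counts(counts, missing_father_rate=1.0))
    assert 0 < res_missing.statistic < res_full.statistic
    # while the TDT-based combination has nothing left
    comb = tp.ncp_from_expected_counts(
        tp.ScenarioSpec.homogeneous(r1=1.4, rm1=1.4, missing_father_rate=1.0),
        "combtdt",
    )
    assert comb.ncp == 0.0


def test_build_groups_rejects_inconsistent_observed_genotypes():
    with pytest.raises(ValueError, match="inconsistent"):
        build_groups([tp.TriadRecord("x", 0, 0, 2, 0)])
    # missing parent with inconsistent remainder
    with pytest.raises(ValueError, match="inconsistent"):
        build_groups([tp.TriadRecord("y", 0, None, 2, 0)])


# ---------------------------------------------------------------------------
# composite test
# ---------------------------------------------------------------------------

def test_zc_degenerate_weight_reduces_to_single_component():
    z = zc_statistic(CompositeInputs(4.0, 0.0, 1, 1, 0.5, np.inf))
    assert z == pytest.approx(2.0)


def test_zc_equal_sigmas_is_symmetric_average():
    z = zc_statistic(CompositeInputs(4.0, 9.0, 1, 1, 0.3, 0.3))
    assert z == pytest.approx((2.0 + 3.0) / np.sqrt(2))


@given(
    x_t=st.floats(0, 30), x_p=st.floats(0, 30),
    s_t=st.sampled_from([-1, 1]), s_p=st.sampled_from([-1, 1]),
    sig_t=st.floats(0.05, 5), sig_p=st.floats(0.05, 5),
    scale=st.floats(0.1, 10),
)
def test_zc_invariances(x_t, x_p, s_t, s_p, sig_t, sig_p, scale):
    z = zc_statistic(CompositeInputs(x_t, x_p, s_t, s_p, sig_t, sig_p))
    # scaling both standard errors leaves the statistic unchanged
    z2 = zc_statistic(
        CompositeInputs(x_t, x_p, s_t, s_p, scale * sig_t, scale * sig_p)
    )
    assert z == pytest.approx(z2, rel=1e-9, abs=1e-9)
    # the combination is bounded by the largest component magnitude * sqrt(2)
    assert abs(z) <= np.sqrt(2) * max(np.sqrt(x_t), np.sqrt(x_p)) + 1e-9


def test_zc_unit_variance_under_null_for_any_weights():
    # with independent standard-normal components, the normalized linear
    # combination has variance 1 for arbitrary positive weights
    rng = np.random.default_rng(2)
    zt, zp = rng.standard_normal((2, 200_000))
    for st_, sp_ in ((0.1, 0.3), (1.0, 1.0), (2.0, 0.2)):
        w_t, w_p = 1 / st_, 1 / sp_
        z = (w_t * zt + w_p * zp) / np.sqrt(w_t**2 + w_p**2)
        assert np.var(z) == pytest.approx(1.0, abs=0.02)


def test_ppi_ct_from_tests_matches_formula_and_flags_degenerate():
    counts = alt_counts()
    t = transmission_lrt(counts)
    p = parent_lrt(counts)
    res = ppi_ct_from_tests(t, p)
    manual = zc_statistic(
        CompositeInputs(t.statistic, p.statistic, t.sign, p.sign, t.sigma, p.sigma)
    )
    assert res.statistic == pytest.approx(manual**2)
    # degenerate parent component -> NA result pointing at the LRT
    from triadppi.results import TestResult
    na = TestResult("parent", np.nan, 1, np.nan)
    out = ppi_ct_from_tests(t, na)
    assert out.is_na and "ppi_lrt" in out.message


def test_ppi_ct_ncp_matches_ppi_lrt_ncp_under_shared_alternative():
    for p in (0.1, 0.3, 0.5, 0.7, 0.9):
        spec = tp.ScenarioSpec.homogeneous(allele_freq=p, r1=1.4, rm1=1.4)
        ct = tp.ncp_from_expected_counts(spec, "ppi_ct")
        lrt = tp.ncp_from_expected_counts(spec, "ppi_lrt")
        assert ct.ncp == pytest.approx(lrt.ncp, rel=2e-3)
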