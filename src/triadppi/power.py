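"""Noncentrality-parameter power engine and Monte-Carlo study driver.

Asymptotic power for every test in the package is computed by the
expected-counts ("pseudo-data") device: the scenario's expected cell
table is treated as data, the likelihood-ratio statistic (or the TDT-type
statistic) evaluated on it is the noncentrality parameter (NCP) of the
test's chi-square distribution under that alternative, and power is the
upper tail of the corresponding noncentral chi-square beyond the central
critical value.  NCPs are proportional to the sample size, so a result
computed at one study size rescales exactly to any other.

``type_i_error_study`` is the companion Monte-Carlo driver: it simulates
replicate studies from a scenario and reports per-test rejection rates
(Type I error under a null scenario, power under an alternative) together
with mean relative-risk estimates and Monte-Carlo confidence intervals
for those means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data import CellCountTable
from .joint import groups_from_counts, ppi_ct_from_tests, ppi_lrt
from .parent import parent_lrt
from .results import TestResult, n_risk_params
from .simulate import ScenarioSpec, expected_cell_frequencies
from .tdt import comb_tdt, paren_tdt, tdt
from .transmission import transmission_lrt

TESTS = ("offspring", "parent", "ppi_ct", "ppi_lrt", "tdt", "parentdt", "combtdt")


@dataclass
class PowerResult:
    """NCP-based power for one test under one scenario."""

    ncp: float
    df: int
    alpha: float
    power: float
    test: str
    n_ref: int

    def __str__(self) -> str:
        return (
            f"{self.test}: NCP = {self.ncp:.4f} (df {self.df}, n = {self.n_ref}), "
            f"power at alpha={self.alpha:g}: {self.power:.4f}"
        )


def power_from_ncp(ncp: float, df: int = 1, alpha: float = 0.05) -> float:
    """P(noncentral chi2(df, ncp) exceeds the central critical value)."""
    if ncp < 0:
        raise ValueError("ncp must be nonnegative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.isf(alpha, df)
    if ncp == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, ncp))


def _statistic_on_counts(
    spec: ScenarioSpec, counts: CellCountTable, test: str, coding: str
) -> tuple[float, int]:
    rf, rm = spec.missing_father_rate, spec.missing_mother_rate
    keep = (1 - rf) * (1 - rm)
    k = n_risk_params(coding)
    if test == "offspring":
        return transmission_lrt(counts, coding).statistic * keep, k
    if test == "parent":
        return parent_lrt(counts, coding).statistic * keep, k
    if test == "ppi_ct":
        # complete-data composite (missingness handled by the PPI-LRT)
        t = transmission_lrt(counts, coding)
        p = parent_lrt(counts, coding)
        return ppi_ct_from_tests(t, p).statistic * keep, 1
    if test == "ppi_lrt":
        if rf > 0 or rm > 0:
            groups = groups_from_counts(counts, rf, rm)
            return ppi_lrt(groups, coding).statistic, k
        return ppi_lrt(counts, coding).statistic, k
    if test == "tdt":
        res = tdt(counts)
    elif test == "parentdt":
        res = paren_tdt(counts)
    elif test == "combtdt":
        res = comb_tdt(counts)
    else:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    stat = 0.0 if res.is_na else res.statistic
    return stat * keep, 1


def ncp_from_expected_counts(
    spec: ScenarioSpec,
    test: str,
    coding: str = "log_additive",
    alpha: float = 0.05,
) -> PowerResult:
    """NCP and asymptotic power for ``test`` under the scenario.

    The scenario's expected cell table is used as pseudo-data; for the
    likelihood ratio tests the NCP is the change in deviance between the
    null and alternative fits, for the TDT family it is the statistic
    itself evaluated on the expected counts.  Families with missing
    genotypes are discarded by the TDT-type tests and the separate-model
    tests (scaling their NCPs by the completeness fraction) and retained
    by the EM-based PPI-LRT.
    """
    counts = expected_cell_frequencies(spec)
    stat, df = _statistic_on_counts(spec, counts, test, coding)
    stat = max(float(stat), 0.0)
    if stat < 1e-9:
        stat = 0.0  # numerical zero on null pseudo-data
    return PowerResult(stat, df, alpha, power_from_ncp(stat, df, alpha), test, spec.n)


def scale_ncp(result: PowerResult, n_new: int) -> PowerResult:
    """Rescale an NCP to a new study size (NCPs are linear in n)."""
    if n_new <= 0:
        raise ValueError("n_new must be positive")
    ncp = result.ncp * n_new / result.n_ref
    return replace(
        result, ncp=ncp, n_ref=n_new,
        power=power_from_ncp(ncp, result.df, result.alpha),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo rejection-rate studies
# ---------------------------------------------------------------------------

def _run_tests_on_table(
    table: CellCountTable, tests: Sequence[str], coding: str
) -> dict[str, TestResult]:
    out: dict[str, TestResult] = {}
    need_ct = "ppi_ct" in tests
    t_res = p_res = None
    if "offspring" in tests or need_ct:
        t_res = transmission_lrt(table, coding)
    if "parent" in tests or need_ct:
        p_res = parent_lrt(table, coding)
    if "offspring" in tests:
        out["offspring"] = t_res
    if "parent" in tests:
        out["parent"] = p_res
    if need_ct:
        out["ppi_ct"] = ppi_ct_from_tests(t_res, p_res)
    if "ppi_lrt" in tests:
        out["ppi_lrt"] = ppi_lrt(table, coding)
    if "tdt" in tests:
        out["tdt"] = tdt(table)
    if "parentdt" in tests:
        out["parentdt"] = paren_tdt(table)
    if "combtdt" in tests:
        out["combtdt"] = comb_tdt(table)
    return out


def type_i_error_study(
    spec: ScenarioSpec,
    reps: int = 5000,
    alpha: float = 0.05,
    seed: Union[int, np.random.SeedSequence, None] = None,
    tests: Sequence[str] = ("offspring", "parent", "ppi_ct", "tdt", "parentdt", "combtdt"),
    coding: str = "log_additive",
    max_failure_fraction: float = 0.01,
    return_details: bool = False,
):
    """Monte-Carlo rejection rates (and RR estimate means) per test.

    Simulates ``reps`` studies of ``spec.n`` triads and reports, per test,
    the fraction of replicates with p < ``alpha`` alongside its binomial
    Monte-Carlo standard error.  For the model-based tests the mean
    relative-risk estimate across replicates is reported with a normal
    Monte-Carlo 95% interval for that mean.  Degenerate replicates
    (convergence failure or uninformative tables) are excluded per test;
    if they exceed ``max_failure_fraction`` the study is flagged invalid.
    """
    spec.validate()
    if spec.missing_father_rate > 0 or spec.missing_mother_rate > 0:
        raise ValueError(
            "rejection-rate studies operate on complete-data scenarios; "
            "set the missingness rates to 0 (the PPI-LRT NCP engine handles "
            "missingness deterministically)"
        )
    rng = np.random.default_rng(seed)
    expected = expected_cell_frequencies(spec)
    probs = expected.counts.ravel() / expected.total
    shape = expected.counts.shape
    draws = rng.multinomial(spec.n, probs, size=reps)

    pvals = {t: np.full(reps, np.nan) for t in tests}
    rrs = {t: np.full(reps, np.nan) for t in tests}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(reps):
            table = CellCountTable(draws[i].reshape(shape).astype(float),
                                   expected.design)
            for name, res in _run_tests_on_table(table, tests, coding).items():
                pvals[name][i] = res.pvalue
                if res.estimate is not None:
                    rrs[name][i] = res.estimate

    rows = []
    for t in tests:
        p = pvals[t]
        ok = np.isfinite(p)
        n_ok = int(ok.sum())
        frac_failed = 1 - n_ok / reps
        if frac_failed > max_failure_fraction:
            warnings.warn(
                f"{t}: {frac_failed:.1%} of replicates degenerate; "
                "study flagged invalid for this test"
            )
        rate = float((p[ok] < alpha).mean()) if n_ok else np.nan
        se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan
        r = rrs[t]
        r_ok = r[np.isfinite(r)]
        if r_ok.size:
            mean_rr = float(r_ok.mean())
            half = 1.96 * r_ok.std(ddof=1) / np.sqrt(r_ok.size)
            ci = (mean_rr - half, mean_rr + half)
        else:
            mean_rr, ci = np.nan, (np.nan, np.nan)
        rows.append(
            dict(test=t, rejection_rate=rate, mc_se=se, n_valid=n_ok,
                 n_failed=reps - n_ok, mean_rr=mean_rr,
                 rr_ci_low=ci[0], rr_ci_high=ci[1])
        )
    summary = pd.DataFrame(rows).set_index("test")
    if return_details:
        return summary, pd.DataFrame(pvals), pd.DataFrame(rrs)
    return summary
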