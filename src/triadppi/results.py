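"""Common result containers: hypothesis-test results and risk codings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

#: Supported modes of inheritance for the risk terms.  ``codominant`` uses
#: two indicator terms (1 copy, 2 copies); the others use one term.
CODINGS = ("codominant", "log_additive", "dominant", "recessive")


def risk_design(g: np.ndarray, coding: str) -> tuple[np.ndarray, list[str]]:
    """Design columns for the genetic risk term of a genotype vector."""
    g = np.asarray(g)
    if coding == "codominant":
        x = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        return x, ["1copy", "2copies"]
    if coding == "log_additive":
        return g.astype(float)[:, None], ["per_allele"]
    if coding == "dominant":
        return (g >= 1).astype(float)[:, None], ["carrier"]
    if coding == "recessive":
        return (g == 2).astype(float)[:, None], ["homozygous"]
    raise ValueError(f"unknown coding {coding!r}; choose from {CODINGS}")


def n_risk_params(coding: str) -> int:
    return 2 if coding == "codominant" else 1


@dataclass
class TestResult:
    """Outcome of one association test.

    ``estimate`` is a relative risk (``exp`` of the tested coefficient)
    where the test provides one; ``sign`` and ``sigma`` are the sign and
    Wald standard error of the log-additive coefficient, carried for the
    composite test.  ``statistic`` is ``nan`` for degenerate inputs.
    """

    test: str
    statistic: float
    df: int
    pvalue: float
    estimate: Optional[float] = None
    conf_int: Optional[tuple[float, float]] = None
    sign: Optional[int] = None
    sigma: Optional[float] = None
    n_used: Optional[float] = None
    message: str = ""

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.statistic)

    def __str__(self) -> str:
        bits = [f"{self.test}: chi2({self.df}) = {self.statistic:.6g}, p = {self.pvalue:.4g}"]
        if self.estimate is not None and np.isfinite(self.estimate):
            ci = ""
            if self.conf_int is not None:
                ci = f" (95% CI {self.conf_int[0]:.4g}, {self.conf_int[1]:.4g})"
            bits.append(f"RR = {self.estimate:.4g}{ci}")
        if self.message:
            bits.append(self.message)
        return "; ".join(bits)


def chi2_test(name: str, statistic: float, df: int, **kw) -> TestResult:
    if not np.isfinite(statistic):
        return TestResult(name, np.nan, df, np.nan, **kw)
    statistic = max(statistic, 0.0)
    return TestResult(name, statistic, df, float(stats.chi2.sf(statistic, df)), **kw)


def wald_rr_ci(coef: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    z = stats.norm.isf(alpha / 2)
    return (float(np.exp(coef - z * se)), float(np.exp(coef + z * se)))
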