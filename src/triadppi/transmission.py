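"""The log-linear transmission model for case-parent triads.

The model describes the joint distribution of the triad genotypes
``(M, F, C)`` conditional on the child being affected:

    ln Pr(M, F, C | affected child)
        = mu_(M,F) + gamma_1 I(C=1) + gamma_2 I(C=2) + ln(2) I(M=1,F=1,C=1)

with six mating-type parameters ``mu`` indexed by the unordered parental
genotype pair (mating symmetry), and ``exp(gamma_j)`` the relative risk
for a child carrying ``j`` copies of the variant.  Conditioning on the
mating type makes inference about ``gamma`` depend only on transmission
distortion, which confers robustness to population stratification.  The
maternal-effects extension adds ``rho_1 I(M=1) + rho_2 I(M=2)``, with
``exp(rho_j)`` the relative risk attributable to the mother's own
genotype irrespective of transmission.

Fitting maximizes the multinomial likelihood of the 15 Mendelian cells.
Because ``mu`` enters as a free intercept per mating type, it can be
profiled out exactly: given the risk coefficients the fitted mating-type
totals equal the observed ones, leaving a product of within-mating-type
conditional multinomials whose cell weights are the Mendelian offsets
times ``exp`` of the risk terms.  The fitter below is a Newton iteration
on that profile likelihood; the equivalent Poisson log-linear regression
is used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._optim import maximize_newton
from .data import (
    CELL_C,
    CELL_LOGW,
    CELL_M,
    CELL_MT,
    CellCountTable,
    N_GENO_CELLS,
)
from .results import TestResult, chi2_test, n_risk_params, risk_design, wald_rr_ci

# contiguous mating-type segments of the sorted cell list
_SEG_STARTS = np.flatnonzero(np.r_[1, np.diff(CELL_MT)])
_N_MT = 6


def _segment_logsumexp(eta: np.ndarray) -> np.ndarray:
    """log(sum(exp(eta))) within each mating-type segment (length 6)."""
    out = np.empty(_N_MT)
    for k in range(_N_MT):
        lo = _SEG_STARTS[k]
        hi = _SEG_STARTS[k + 1] if k + 1 < _N_MT else len(eta)
        seg = eta[lo:hi]
        m = seg.max()
        out[k] = m + np.log(np.exp(seg - m).sum())
    return out


class TransmissionModel:
    """Log-linear model for triad genotype counts.

    Parameters
    ----------
    counts : CellCountTable or array of length 15
        Triad counts per genotype cell; phenotype strata are collapsed.
    coding : str
        Mode of inheritance for the child risk term.
    maternal : bool
        Include the maternally-mediated risk terms (``rho``).
    maternal_only : bool
        Drop the child term and keep only ``rho`` (used as the null model
        of the transmission test when adjusting for maternal effects).
    """

    def __init__(
        self,
        counts: Union[CellCountTable, np.ndarray],
        coding: str = "log_additive",
        maternal: bool = False,
        maternal_only: bool = False,
    ):
        if isinstance(counts, CellCountTable):
            n = counts.genotype_margin()
        else:
            n = np.asarray(counts, dtype=float)
        if n.shape != (N_GENO_CELLS,):
            raise ValueError(f"expected {N_GENO_CELLS} genotype-cell counts")
        if np.any(n < 0):
            raise ValueError("negative counts")
        self.n = n
        self.coding = coding
        self.maternal = maternal or maternal_only

        cols, names = [], []
        if not maternal_only:
            xc, nc = risk_design(CELL_C, coding)
            cols.append(xc)
            names += [f"gamma_{s}" for s in nc]
        if self.maternal:
            xm, nm = risk_design(CELL_M, coding)
            cols.append(xm)
            names += [f"rho_{s}" for s in nm]
        self.exog = np.hstack(cols) if cols else np.zeros((N_GENO_CELLS, 0))
        self.param_names = names
        self.k_gamma = 0 if maternal_only else n_risk_params(coding)

        self.n_mt = np.array(
            [n[CELL_MT == k].sum() for k in range(_N_MT)]
        )
        self.total = float(n.sum())
        if self.total <= 0:
            raise ValueError("empty count table")
        if np.any(self.n_mt == 0):
            warnings.warn(
                "some mating types have zero total count; they carry no "
                "information and are effectively dropped"
            )
        self._n_mt_cell = self.n_mt[CELL_MT]
        # constant part of the full multinomial loglik: mating-type margin
        pos = self.n_mt > 0
        self._ll_margin = float(
            (self.n_mt[pos] * np.log(self.n_mt[pos] / self.total)).sum()
        )

    # -- likelihood ---------------------------------------------------------
    def _cond_probs(self, params: np.ndarray) -> np.ndarray:
        eta = CELL_LOGW + self.exog @ params
        lz = _segment_logsumexp(eta)
        return np.exp(eta - lz[CELL_MT])

    def loglike(self, params: np.ndarray) -> float:
        """Full multinomial log-likelihood with ``mu`` profiled out."""
        eta = CELL_LOGW + self.exog @ params
        lz = _segment_logsumexp(eta)
        return self._ll_margin + float(self.n @ (eta - lz[CELL_MT]))

    def _fgh(self, params: np.ndarray):
        eta = CELL_LOGW + self.exog @ params
        lz = _segment_logsumexp(eta)
        p = np.exp(eta - lz[CELL_MT])
        ll = self._ll_margin + float(self.n @ (eta - lz[CELL_MT]))
        w = self._n_mt_cell * p
        grad = self.exog.T @ (self.n - w)
        # -hess = sum_mt n_mt Cov_mt(x)
        xw = self.exog * w[:, None]
        h = -(self.exog.T @ xw)
        for k in range(_N_MT):
            if self.n_mt[k] <= 0:
                continue
            mask = CELL_MT == k
            xbar = (self.exog[mask] * p[mask, None]).sum(axis=0)
            h += self.n_mt[k] * np.outer(xbar, xbar)
        return ll, grad, h

    def fit(self, start: Optional[np.ndarray] = None) -> "TransmissionResults":
        k = self.exog.shape[1]
        if k == 0:
            ll = self.loglike(np.zeros(0))
            return TransmissionResults(self, np.zeros(0), ll, np.zeros((0, 0)), True)
        x0 = np.zeros(k) if start is None else np.asarray(start, float)
        res = maximize_newton(self._fgh, x0, ridge=1e-9)
        if not res.converged:
            warnings.warn(f"transmission fit did not converge: {res.message}")
        neg_h = -res.hess
        try:
            cov = np.linalg.inv(neg_h)
        except np.linalg.LinAlgError:
            cov = np.full((k, k), np.nan)
        return TransmissionResults(self, res.x, res.loglik, cov, res.converged)


@dataclass
class TransmissionResults:
    """Fitted transmission model: estimates, covariance, log-likelihood."""

    model: TransmissionModel
    params: np.ndarray
    llf: float
    cov_params: np.ndarray
    converged: bool

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0, None))

    @property
    def gamma(self) -> np.ndarray:
        return self.params[: self.model.k_gamma]

    @property
    def rho(self) -> np.ndarray:
        return self.params[self.model.k_gamma:]

    @property
    def relative_risks(self) -> dict[str, float]:
        return {nm: float(np.exp(v)) for nm, v in zip(self.param_names, self.params)}

    @property
    def mu(self) -> np.ndarray:
        """Recovered mating-type parameters (``-inf`` for empty types)."""
        eta = CELL_LOGW + self.model.exog @ self.params
        lz = _segment_logsumexp(eta)
        with np.errstate(divide="ignore"):
            return np.log(self.model.n_mt / self.model.total) - lz

    def fitted_cell_counts(self) -> np.ndarray:
        """Expected genotype-cell counts under the fit (length 15)."""
        p = self.model._cond_probs(self.params)
        return self.model._n_mt_cell * p

    def conf_int(self, alpha: float = 0.05) -> list[tuple[float, float]]:
        return [wald_rr_ci(c, s, alpha) for c, s in zip(self.params, self.bse)]

    def summary(self) -> str:
        lines = [
            "Transmission log-linear model",
            f"  coding: {self.model.coding}   maternal terms: {self.model.maternal}",
            f"  families: {self.model.total:.6g}   loglik: {self.llf:.6f}"
            f"   converged: {self.converged}",
            f"  {'term':<18}{'coef':>10}{'se':>10}{'RR':>8}{'95% CI':>20}",
        ]
        for nm, c, s, ci in zip(self.param_names, self.params, self.bse, self.conf_int()):
            lines.append(
                f"  {nm:<18}{c:>10.4f}{s:>10.4f}{np.exp(c):>8.3f}"
                f"   ({ci[0]:.3f}, {ci[1]:.3f})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Tests built on the model
# ---------------------------------------------------------------------------

def fit_transmission(
    counts, coding: str = "log_additive", maternal: bool = False
) -> TransmissionResults:
    """Convenience wrapper: build and fit a :class:`TransmissionModel`."""
    return TransmissionModel(counts, coding=coding, maternal=maternal).fit()


def transmission_lrt(
    counts, coding: str = "log_additive", maternal: bool = False
) -> TestResult:
    """Likelihood ratio test of no child genotype effect (gamma = 0).

    With ``maternal=True`` the maternal terms ``rho`` are kept in both the
    null and alternative model, so the test remains a test of the child
    (transmission) effect adjusted for maternally-mediated effects.
    """
    full = TransmissionModel(counts, coding=coding, maternal=maternal).fit()
    if maternal:
        ll0 = TransmissionModel(counts, coding=coding, maternal_only=True).fit().llf
    else:
        # gamma = 0 is the null; mu profiles out at any gamma
        ll0 = full.model.loglike(np.zeros(full.model.exog.shape[1]))
    stat = 2.0 * (full.llf - ll0)
    df = full.model.k_gamma
    kw = {}
    if df == 1:
        coef = float(full.gamma[0])
        kw = dict(
            estimate=float(np.exp(coef)),
            conf_int=full.conf_int()[0],
            sign=1 if coef >= 0 else -1,
            sigma=float(full.bse[0]),
        )
    return chi2_test(
        "transmission", stat, df, n_used=full.model.total, **kw
    )


def maternal_effect_test(counts, coding: str = "log_additive") -> TestResult:
    """LRT of no maternally-mediated effect (rho = 0), adjusting for gamma."""
    full = TransmissionModel(counts, coding=coding, maternal=True).fit()
    reduced = TransmissionModel(counts, coding=coding, maternal=False).fit()
    stat = 2.0 * (full.llf - reduced.llf)
    df = n_risk_params(coding)
    kw = {}
    if df == 1:
        coef = float(full.rho[0])
        i = full.model.k_gamma
        kw = dict(
            estimate=float(np.exp(coef)),
            conf_int=full.conf_int()[i],
            sign=1 if coef >= 0 else -1,
            sigma=float(full.bse[i]),
        )
    return chi2_test("maternal_effect", stat, df, n_used=full.model.total, **kw)
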