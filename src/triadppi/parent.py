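"""Log-binomial model for disease in the parents of cases.

For a one-sex disease the mother of each affected child contributes a
Bernoulli outcome with

    ln Pr(D_M = 1 | M, F, affected child) = alpha_(M,F) + beta_1 I(M=1) + beta_2 I(M=2)

where the six ``alpha`` intercepts are indexed by the unordered parental
mating type and ``exp(beta_j)`` is the relative risk for mothers carrying
``j`` copies of the variant.  The mating-type intercepts act as a proxy
adjustment for subpopulation membership: only parents whose genotypes
differ within a mating type inform ``beta``, which is what makes the test
robust to population stratification.  Setting ``mating_intercepts=False``
fits a single-intercept ablation that forfeits that robustness.

For diseases affecting both sexes each family contributes two independent
Bernoulli outcomes; fathers get their own per-mating-type intercept
offsets and either their own risk coefficients ``theta`` or, when
``pooled=True``, the mother's coefficients.

Numerically, the log link requires every fitted linear predictor to stay
negative.  Mating types whose parents are genotype-concordant (or whose
outcomes are saturated by the intercept) are profiled out exactly; the
remaining parameters are maximized by damped Newton constrained to the
feasible region, with a sequential-quadratic fallback.  The model's
likelihood accepts fractional counts, as produced by expected-count
pseudo-data and by the EM algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import optimize

from ._optim import maximize_newton
from .data import CELL_F, CELL_M, CELL_MT, CellCountTable
from .results import TestResult, chi2_test, n_risk_params, risk_design, wald_rr_ci

_ETA_CAP = -1e-9  # linear predictors must satisfy eta <= this (prob <= 1)


def _binom_ll(y: np.ndarray, n: np.ndarray) -> float:
    """Saturated Bernoulli log-likelihood sum y*ln(y/n)+(n-y)*ln(1-y/n)."""
    y = np.atleast_1d(np.asarray(y, float))
    n = np.atleast_1d(np.asarray(n, float))
    out = 0.0
    for yi, ni in zip(y, n):
        if ni <= 0:
            continue
        p = yi / ni
        if yi > 0:
            out += yi * np.log(p)
        if ni - yi > 0:
            out += (ni - yi) * np.log(1 - p)
    return out


class _BernoulliCells:
    """Grouped Bernoulli log-likelihood with log link.

    ``eta = X_slope @ slope + alpha[group]``; parameter vector is
    ``[slope (K), alpha (J)]`` so a caller can share the slope with
    another likelihood component.
    """

    def __init__(self, n, y, x_slope, group, n_groups):
        self.n = np.asarray(n, float)
        self.y = np.asarray(y, float)
        self.x_slope = np.asarray(x_slope, float)
        self.group = np.asarray(group, int)
        self.k = self.x_slope.shape[1]
        self.j = n_groups
        # full design for Newton algebra
        g_ind = np.zeros((len(self.n), self.j))
        g_ind[np.arange(len(self.n)), self.group] = 1.0
        self.X = np.hstack([self.x_slope, g_ind])

    def eta(self, params):
        return self.X @ params

    def feasible(self, params) -> bool:
        return bool(np.all(self.eta(params) <= _ETA_CAP + 1e-15))

    def fgh(self, params):
        eta = self.eta(params)
        mu = np.exp(eta)
        one_minus = -np.expm1(eta)  # 1 - mu, accurately near the boundary
        nm = self.n - self.y
        ll = float(self.y @ eta + nm @ np.log(np.maximum(one_minus, 1e-300)))
        ratio = mu / np.maximum(one_minus, 1e-300)
        g_row = self.y - nm * ratio
        w_row = nm * mu / np.maximum(one_minus, 1e-300) ** 2
        grad = self.X.T @ g_row
        hess = -(self.X.T * w_row) @ self.X
        return ll, grad, hess

    def start(self):
        params = np.zeros(self.k + self.j)
        for j in range(self.j):
            mask = self.group == j
            p_hat = self.y[mask].sum() / self.n[mask].sum()
            params[self.k + j] = np.log(np.clip(p_hat, 1e-6, 1 - 1e-4))
        # with slope 0 the start is feasible by construction
        return params

    def make_feasible(self, params):
        """Shift group intercepts down so every eta <= the cap."""
        params = np.asarray(params, float).copy()
        eta = self.eta(params)
        for j in range(self.j):
            excess = eta[self.group == j].max() - _ETA_CAP
            if excess > 0:
                params[self.k + j] -= excess + 1e-12
        return params

    def maximize(self, start=None):
        x0 = self.start() if start is None else self.make_feasible(start)
        res = maximize_newton(self.fgh, x0, feasible=self.feasible, ridge=1e-9)
        if not res.converged:
            alt = self._fallback(res.x)
            if alt.loglik >= res.loglik:
                res = alt
        return res

    def _fallback(self, x0):
        cons = {
            "type": "ineq",
            "fun": lambda p: _ETA_CAP - self.eta(p),
            "jac": lambda p: -self.X,
        }
        opt = optimize.minimize(
            lambda p: -self.fgh(p)[0],
            x0,
            jac=lambda p: -self.fgh(p)[1],
            constraints=[cons],
            method="SLSQP",
            options={"maxiter": 300, "ftol": 1e-12},
        )
        from ._optim import NewtonResult

        ll, g, h = self.fgh(opt.x)
        return NewtonResult(opt.x, ll, g, h, bool(opt.success), opt.nit, opt.message)


@dataclass
class _RowSet:
    sex: np.ndarray      # 0 mother, 1 father
    mt: np.ndarray       # 0-based mating type
    gpar: np.ndarray     # the modeled parent's genotype
    n: np.ndarray
    y: np.ndarray


def _build_rows(table: CellCountTable) -> _RowSet:
    pair = 3 * CELL_M + CELL_F  # 9 ordered (m, f) combos
    sexes, mts, gs, ns, ys = [], [], [], [], []
    strata = [(0, CELL_M, table.mother_strata())]
    if table.design == "two_sex":
        strata.append((1, CELL_F, table.father_strata()))
    for sex, gvec, cnt in strata:
        tot = cnt.sum(axis=1)
        aff = cnt[:, 1]
        for p in range(9):
            mask = pair == p
            if not mask.any():
                continue
            n_p = tot[mask].sum()
            if n_p <= 0:
                continue
            sexes.append(sex)
            mts.append(CELL_MT[mask][0])
            gs.append(int(gvec[mask][0]))
            ns.append(n_p)
            ys.append(aff[mask].sum())
    return _RowSet(*(np.array(a) for a in (sexes, mts, gs, ns, ys)))


class ParentPhenotypeModel:
    """Log-binomial relative-risk model for parental disease status."""

    def __init__(
        self,
        counts: CellCountTable,
        coding: str = "log_additive",
        mating_intercepts: bool = True,
        pooled: bool = True,
    ):
        if not isinstance(counts, CellCountTable):
            raise TypeError("ParentPhenotypeModel requires a CellCountTable")
        self.counts = counts
        self.design = counts.design
        self.coding = coding
        self.mating_intercepts = mating_intercepts
        self.pooled = pooled if self.design == "two_sex" else True
        self.rows = _build_rows(counts)
        k1 = n_risk_params(coding)
        if self.design == "two_sex" and not self.pooled:
            self.slope_names = [f"beta_{s}" for s in risk_design(np.zeros(1), coding)[1]]
            self.slope_names += [f"theta_{s}" for s in risk_design(np.zeros(1), coding)[1]]
            self.k_slope = 2 * k1
        else:
            self.slope_names = [f"beta_{s}" for s in risk_design(np.zeros(1), coding)[1]]
            self.k_slope = k1

    # -- structural analysis -------------------------------------------------
    def _slope_covariates(self, rows: _RowSet) -> np.ndarray:
        x, _ = risk_design(rows.gpar, self.coding)
        if self.design == "two_sex" and not self.pooled:
            k1 = x.shape[1]
            out = np.zeros((len(rows.n), 2 * k1))
            mother = rows.sex == 0
            out[mother, :k1] = x[mother]
            out[~mother, k1:] = x[~mother]
            return out
        return x

    def _group_keys(self, rows: _RowSet) -> list[tuple]:
        if self.mating_intercepts:
            return [(s, m) for s, m in zip(rows.sex, rows.mt)]
        return [(s,) for s in rows.sex]

    def fit(self, start=None) -> "ParentResults":
        """Fit the model.  ``start`` optionally warm-starts the optimizer
        as ``(slope_vector, {sex: alpha_array6})``; infeasible or
        non-finite entries fall back to the default starting values."""
        rows = self.rows
        if len(rows.n) == 0 or rows.y.sum() <= 0:
            return ParentResults(
                self, np.full(self.k_slope, np.nan), np.nan,
                np.full((self.k_slope, self.k_slope), np.nan), False, {},
                message="no affected parents: model degenerate",
            )
        x_slope = self._slope_covariates(rows)
        keys = self._group_keys(rows)
        uniq = sorted(set(keys))
        alpha: dict[tuple, float] = {}
        profiled_llf = 0.0
        opt_idx: list[int] = []
        opt_group: list[int] = []
        opt_keys: list[tuple] = []
        profiled: dict[tuple, tuple] = {}

        for key in uniq:
            idx = [i for i, k in enumerate(keys) if k == key]
            y_g = rows.y[idx].sum()
            n_g = rows.n[idx].sum()
            if y_g <= 0:
                # boundary MLE: risk -> 0 in this stratum, contributes 0
                alpha[key] = -np.inf
                continue
            same_cov = self.mating_intercepts and all(
                np.array_equal(x_slope[i], x_slope[idx[0]]) for i in idx
            )
            if same_cov:
                # saturated by its intercept: profile out exactly
                profiled_llf += _binom_ll(y_g, n_g)
                profiled[key] = (float(np.log(y_g / n_g)), x_slope[idx[0]].copy())
                continue
            gi = len(opt_keys)
            opt_keys.append(key)
            for i in idx:
                opt_idx.append(i)
                opt_group.append(gi)

        if not opt_keys:
            # no stratum carries information about the slope
            return ParentResults(
                self, np.full(self.k_slope, np.nan), profiled_llf,
                np.full((self.k_slope, self.k_slope), np.nan), True, alpha,
                profiled=profiled,
                message="no genotype-discordant informative strata",
            )

        lik = _BernoulliCells(
            rows.n[opt_idx], rows.y[opt_idx], x_slope[opt_idx],
            opt_group, len(opt_keys),
        )
        x0 = None
        if start is not None:
            slope0, alpha0 = start
            x0 = lik.start()
            if np.all(np.isfinite(slope0)) and len(slope0) == self.k_slope:
                x0[: self.k_slope] = slope0
            for gi, key in enumerate(opt_keys):
                sex = key[0]
                a = alpha0.get(sex) if isinstance(alpha0, dict) else None
                if a is not None and self.mating_intercepts:
                    val = a[key[1]]
                    if np.isfinite(val):
                        x0[self.k_slope + gi] = val
        res = lik.maximize(start=x0)
        if not res.converged:
            warnings.warn(f"log-binomial fit did not converge: {res.message}")
        slope = res.x[: self.k_slope]
        for gi, key in enumerate(opt_keys):
            alpha[key] = float(res.x[self.k_slope + gi])
        neg_h = -res.hess
        try:
            cov = np.linalg.inv(neg_h)[: self.k_slope, : self.k_slope]
        except np.linalg.LinAlgError:
            cov = np.full((self.k_slope, self.k_slope), np.nan)
        return ParentResults(
            self, slope, res.loglik + profiled_llf, cov, res.converged,
            alpha, profiled=profiled,
        )

    def null_llf(self) -> float:
        """Maximized log-likelihood with all risk coefficients fixed at 0.

        Every intercept stratum is then saturated, so the null fit is the
        pooled binomial within each stratum, in closed form.
        """
        rows = self.rows
        keys = self._group_keys(rows)
        out = 0.0
        for key in sorted(set(keys)):
            idx = [i for i, k in enumerate(keys) if k == key]
            out += _binom_ll(rows.y[idx].sum(), rows.n[idx].sum())
        return out


@dataclass
class ParentResults:
    """Fitted parent-phenotype model."""

    model: ParentPhenotypeModel
    params: np.ndarray          # risk coefficients (beta [, theta])
    llf: float
    cov_params: np.ndarray
    converged: bool
    _alpha_opt: dict
    profiled: dict = field(default_factory=dict)
    message: str = ""

    @property
    def param_names(self) -> list[str]:
        return self.model.slope_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0, None))

    @property
    def beta(self) -> np.ndarray:
        k1 = n_risk_params(self.model.coding)
        return self.params[:k1]

    @property
    def theta(self) -> Optional[np.ndarray]:
        if self.model.design == "two_sex" and not self.model.pooled:
            k1 = n_risk_params(self.model.coding)
            return self.params[k1:]
        return None

    def alpha(self, sex: int = 0) -> np.ndarray:
        """Per-mating-type intercepts for one parental sex (length 6).

        Profiled strata are recovered as ``ln(p_hat) - x*slope``; empty or
        all-unaffected strata are ``-inf``.
        """
        out = np.full(6, -np.inf)
        for key, val in self._alpha_opt.items():
            if not self.model.mating_intercepts:
                if key == (sex,):
                    out[:] = val
            elif key[0] == sex:
                out[key[1]] = val
        for key, (eta_hat, x_row) in self.profiled.items():
            if key[0] == sex and np.all(np.isfinite(self.params)):
                out[key[1]] = eta_hat - float(x_row @ self.params)
        return out

    @property
    def relative_risks(self) -> dict[str, float]:
        return {nm: float(np.exp(v)) for nm, v in zip(self.param_names, self.params)}

    def conf_int(self, alpha: float = 0.05) -> list[tuple[float, float]]:
        return [wald_rr_ci(c, s, alpha) for c, s in zip(self.params, self.bse)]

    def summary(self) -> str:
        m = self.model
        lines = [
            "Parent-phenotype log-binomial model",
            f"  design: {m.design}   coding: {m.coding}   "
            f"mating intercepts: {m.mating_intercepts}   pooled: {m.pooled}",
            f"  families: {m.counts.total:.6g}   loglik: {self.llf:.6f}"
            f"   converged: {self.converged}",
        ]
        if self.message:
            lines.append(f"  note: {self.message}")
        if np.all(np.isfinite(self.params)):
            lines.append(f"  {'term':<18}{'coef':>10}{'se':>10}{'RR':>8}{'95% CI':>20}")
            for nm, c, s, ci in zip(self.param_names, self.params, self.bse, self.conf_int()):
                lines.append(
                    f"  {nm:<18}{c:>10.4f}{s:>10.4f}{np.exp(c):>8.3f}"
                    f"   ({ci[0]:.3f}, {ci[1]:.3f})"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Tests built on the model
# ---------------------------------------------------------------------------

def fit_parent_phenotype(
    counts, coding: str = "log_additive", mating_intercepts: bool = True,
    pooled: bool = True,
) -> ParentResults:
    return ParentPhenotypeModel(
        counts, coding=coding, mating_intercepts=mating_intercepts, pooled=pooled
    ).fit()


def parent_lrt(
    counts, coding: str = "log_additive", mating_intercepts: bool = True,
    pooled: bool = True,
) -> TestResult:
    """LRT of no parental-genotype effect on parental disease risk."""
    model = ParentPhenotypeModel(
        counts, coding=coding, mating_intercepts=mating_intercepts, pooled=pooled
    )
    full = model.fit()
    if not np.all(np.isfinite(full.params)):
        return TestResult(
            "parent", np.nan, model.k_slope, np.nan,
            message=full.message or "degenerate fit",
        )
    stat = 2.0 * (full.llf - model.null_llf())
    kw = {}
    if model.k_slope == 1:
        coef = float(full.params[0])
        kw = dict(
            estimate=float(np.exp(coef)),
            conf_int=full.conf_int()[0],
            sign=1 if coef >= 0 else -1,
            sigma=float(full.bse[0]),
        )
    return chi2_test("parent", stat, model.k_slope, n_used=counts.total, **kw)


def sex_equality_test(counts, coding: str = "log_additive") -> TestResult:
    """LRT of equal relative risks in mothers and fathers (two-sex designs)."""
    if counts.design != "two_sex":
        raise ValueError("sex_equality_test requires a two-sex table")
    free = ParentPhenotypeModel(counts, coding=coding, pooled=False).fit()
    pooled = ParentPhenotypeModel(counts, coding=coding, pooled=True).fit()
    if not (np.all(np.isfinite(free.params)) and np.all(np.isfinite(pooled.params))):
        return TestResult("sex_equality", np.nan, n_risk_params(coding), np.nan,
                          message="degenerate fit")
    stat = 2.0 * (free.llf - pooled.llf)
    return chi2_test("sex_equality", stat, n_risk_params(coding), n_used=counts.total)
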