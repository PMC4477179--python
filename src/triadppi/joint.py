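"""Joint two-generation likelihood, EM for missing parents, and the
composite test.

The joint likelihood factors family-wise as

    Pr(D_M, M, F, C | affected child)
        = Pr(M, F, C | affected child) * Pr(D_M | M, F, affected child)

with the first factor the log-linear transmission model and the second
the log-binomial parent-phenotype model.  With complete data and separate
risk parameters the two factors can be maximized independently; the joint
model earns its keep when the offspring and maternal relative risks are
constrained equal (``R = R_m``, giving the parent-phenotype informed LRT,
*PPI-LRT*) or when parental genotypes are missing, in which case the
likelihood is maximized by EM: the E-step distributes each incomplete
family over its Mendelian-compatible genotype completions in proportion
to the current fitted cell probabilities times the parental-phenotype
likelihood, and the M-step refits on the fractional counts.

The *PPI-CT* composite statistic instead combines the two separately
fitted one-parameter tests:

    Z_C = (w_t S_t sqrt(X_t) + w_p S_p sqrt(X_p)) / sqrt(w_t^2 + w_p^2)

with inverse-standard-error weights ``w = 1/sigma``.  Under the null each
signed root is standard normal and the two are independent (complete
data), so the normalization gives ``Z_C`` unit variance and ``Z_C^2`` a
1-df chi-square reference distribution.  Under a shared-relative-risk
alternative the component drifts are proportional to ``1/sigma``, so
these weights are also the asymptotically optimal combination — the
composite noncentrality then coincides with that of the joint PPI-LRT.

The joint model is defined for one-sex designs (mother's phenotype); for
two-sex designs use the composite test with the two-sex parent model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
from scipy import optimize

from ._optim import NewtonResult, maximize_newton
from .data import (
    CELL_M,
    CELL_MEND,
    CELL_MT,
    CellCountTable,
    GENO_CELLS,
    N_GENO_CELLS,
    TriadRecord,
)
from .parent import ParentPhenotypeModel, _BernoulliCells, _build_rows, _binom_ll
from .results import TestResult, chi2_test, n_risk_params, risk_design, wald_rr_ci
from .transmission import TransmissionModel

# ---------------------------------------------------------------------------
# Observation groups: sufficient data for (possibly incomplete) families
# ---------------------------------------------------------------------------

GroupKey = tuple  # (M or None, F or None, C, D_M)


def _completion_indices() -> dict:
    out = {}
    m_opts = (0, 1, 2, None)
    for m in m_opts:
        for f in m_opts:
            for c in (0, 1, 2):
                idx = [
                    i
                    for i, (_, cm, cf, cc) in enumerate(GENO_CELLS)
                    if cc == c
                    and (m is None or cm == m)
                    and (f is None or cf == f)
                ]
                if idx:
                    out[(m, f, c)] = np.array(idx)
    return out


_COMPLETIONS = _completion_indices()


def build_groups(records: Iterable[TriadRecord]) -> dict[GroupKey, float]:
    """Aggregate records into weighted observation groups.

    Records with inconsistent observed genotypes raise; the child genotype
    must be present.
    """
    groups: dict[GroupKey, float] = {}
    for rec in records:
        if (rec.M, rec.F, rec.C) not in _COMPLETIONS:
            raise ValueError(
                f"family {rec.family_id}: observed genotypes are "
                "Mendelian-inconsistent"
            )
        key = (rec.M, rec.F, rec.C, rec.D_M)
        groups[key] = groups.get(key, 0.0) + 1.0
    return groups


def groups_from_counts(
    table: CellCountTable,
    missing_father_rate: float = 0.0,
    missing_mother_rate: float = 0.0,
) -> dict[GroupKey, float]:
    """Expected observation groups from a (one-sex) cell table with
    independent parental-genotype missingness at the given rates."""
    if table.design != "one_sex":
        raise ValueError("the joint model is defined for one-sex designs")
    rf, rm = missing_father_rate, missing_mother_rate
    groups: dict[GroupKey, float] = {}

    def add(key, w):
        if w > 0:
            groups[key] = groups.get(key, 0.0) + w

    for i, (_, m, f, c) in enumerate(GENO_CELLS):
        for d in (0, 1):
            w = table.counts[i, d]
            if w <= 0:
                continue
            add((m, f, c, d), w * (1 - rf) * (1 - rm))
            add((m, None, c, d), w * rf * (1 - rm))
            add((None, f, c, d), w * (1 - rf) * rm)
            add((None, None, c, d), w * rf * rm)
    return groups


def _groups_complete(groups: dict) -> bool:
    return all(k[0] is not None and k[1] is not None for k in groups)


def _table_from_groups(groups: dict) -> CellCountTable:
    table = CellCountTable.zeros("one_sex")
    for (m, f, c, d), w in groups.items():
        table.add(m, f, c, d, weight=w)
    return table


# ---------------------------------------------------------------------------
# Complete-data fits (fractional counts allowed)
# ---------------------------------------------------------------------------

@dataclass
class _CompleteFit:
    llf: float
    gamma: np.ndarray           # child risk coefficients (== beta if shared)
    beta: np.ndarray            # maternal risk coefficients
    alpha: np.ndarray           # 6 mother intercepts (may contain -inf)
    cond_probs: np.ndarray      # P(cell | mating type) at the fit, length 15
    cov_slope: Optional[np.ndarray]
    converged: bool


def _q_cells(alpha: np.ndarray, beta: np.ndarray, coding: str) -> np.ndarray:
    """Pr(mother affected) per genotype cell from intercepts + coefficients."""
    x, _ = risk_design(CELL_M, coding)
    eta = alpha[CELL_MT] + (x @ beta if len(beta) else 0.0)
    with np.errstate(over="ignore"):
        return np.clip(np.exp(eta), 0.0, 1.0)


def _fit_complete(
    table: CellCountTable, coding: str, constraint: str,
    start: Optional[_CompleteFit] = None,
) -> _CompleteFit:
    """Maximize the joint likelihood on a complete-data table.

    ``free``: the likelihood factors, fit the two models separately.
    ``shared``: one risk vector for both generations, joint Newton.
    ``null``: risk coefficients fixed at zero; both factors then have
    closed-form profile maxima.
    """
    k = n_risk_params(coding)
    tm = TransmissionModel(table, coding=coding)
    if constraint == "null":
        zero = np.zeros(k)
        ll_t = tm.loglike(zero)
        pm = ParentPhenotypeModel(table, coding=coding)
        ll_p = pm.null_llf()
        rows = pm.rows
        alpha = np.full(6, -np.inf)
        for mt in range(6):
            mask = rows.mt == mt
            if mask.any() and rows.y[mask].sum() > 0:
                alpha[mt] = np.log(rows.y[mask].sum() / rows.n[mask].sum())
        return _CompleteFit(
            ll_t + ll_p, zero, zero, alpha, tm._cond_probs(zero), None, True
        )
    if constraint == "free":
        tr = tm.fit(start=None if start is None else start.gamma)
        pr = ParentPhenotypeModel(table, coding=coding).fit(
            start=None if start is None else (start.beta, {0: start.alpha})
        )
        beta = pr.params if np.all(np.isfinite(pr.params)) else np.zeros(k)
        llf = tr.llf + (pr.llf if np.isfinite(pr.llf) else 0.0)
        return _CompleteFit(
            llf, tr.gamma, beta, pr.alpha(0), tm._cond_probs(tr.params),
            pr.cov_params, tr.converged and pr.converged,
        )
    if constraint != "shared":
        raise ValueError(f"unknown constraint {constraint!r}")

    # shared: parameters [t (k), parent intercepts (J)]
    pm = ParentPhenotypeModel(table, coding=coding)
    rows = pm.rows
    x_slope, _ = risk_design(rows.gpar, coding)
    alpha = np.full(6, -np.inf)
    profiled_llf = 0.0
    profiled = {}
    opt_rows, opt_group, opt_keys = [], [], []
    for mt in sorted(set(rows.mt)):
        idx = np.flatnonzero(rows.mt == mt)
        y_g, n_g = rows.y[idx].sum(), rows.n[idx].sum()
        if y_g <= 0:
            continue  # alpha -> -inf, contributes 0 for any slope
        if all(np.array_equal(x_slope[i], x_slope[idx[0]]) for i in idx):
            profiled_llf += _binom_ll(y_g, n_g)
            profiled[mt] = (float(np.log(y_g / n_g)), x_slope[idx[0]].copy())
            continue
        gi = len(opt_keys)
        opt_keys.append(mt)
        opt_rows.extend(idx.tolist())
        opt_group.extend([gi] * len(idx))

    if opt_keys:
        lik = _BernoulliCells(
            rows.n[opt_rows], rows.y[opt_rows], x_slope[opt_rows],
            opt_group, len(opt_keys),
        )
    else:
        lik = None

    def fgh(params):
        t = params[:k]
        ll, g, h = tm._fgh(t)
        grad = np.zeros_like(params)
        hess = np.zeros((len(params), len(params)))
        grad[:k] = g
        hess[:k, :k] = h
        if lik is not None:
            llp, gp, hp = lik.fgh(params)
            ll += llp
            grad += gp
            hess += hp
        return ll, grad, hess

    x0 = np.zeros(k + (len(opt_keys) if lik is not None else 0))
    if lik is not None:
        x0[k:] = lik.start()[lik.k:]
        feasible = lik.feasible
    else:
        feasible = None
    if start is not None and np.all(np.isfinite(start.gamma)):
        x0[:k] = start.gamma
        if lik is not None:
            for gi, mt in enumerate(opt_keys):
                if np.isfinite(start.alpha[mt]):
                    x0[k + gi] = start.alpha[mt]
            x0 = lik.make_feasible(x0)
    res = maximize_newton(fgh, x0, feasible=feasible, ridge=1e-9)
    if not res.converged and lik is not None:
        cons = {
            "type": "ineq",
            "fun": lambda p: -1e-9 - lik.eta(p),
            "jac": lambda p: -lik.X,
        }
        opt = optimize.minimize(
            lambda p: -fgh(p)[0], res.x, jac=lambda p: -fgh(p)[1],
            constraints=[cons], method="SLSQP",
            options={"maxiter": 300, "ftol": 1e-12},
        )
        ll2, g2, h2 = fgh(opt.x)
        if ll2 >= res.loglik:
            res = NewtonResult(opt.x, ll2, g2, h2, bool(opt.success), opt.nit)
    t_hat = res.x[:k]
    for gi, mt in enumerate(opt_keys):
        alpha[mt] = res.x[k + gi]
    for mt, (eta_hat, x_row) in profiled.items():
        alpha[mt] = eta_hat - float(x_row @ t_hat)
    try:
        cov = np.linalg.inv(-res.hess)[:k, :k]
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return _CompleteFit(
        res.loglik + profiled_llf, t_hat, t_hat, alpha,
        tm._cond_probs(t_hat), cov, res.converged,
    )


# ---------------------------------------------------------------------------
# The joint model with EM
# ---------------------------------------------------------------------------

class JointTriadModel:
    """Two-generation likelihood for one-sex triad data.

    ``data`` may be triad records, weighted observation groups, or a
    complete-data :class:`CellCountTable`.  ``constraint`` is ``shared``
    (one risk vector for both generations), ``free`` (separate), or
    ``null`` (risk fixed at zero).  ``use_parent=False`` drops the
    parental-phenotype factor, leaving the transmission model alone with
    EM over missing parents.
    """

    def __init__(
        self,
        data,
        coding: str = "log_additive",
        constraint: str = "shared",
        use_parent: bool = True,
    ):
        if isinstance(data, CellCountTable):
            self.groups = groups_from_counts(data)
        elif isinstance(data, dict):
            self.groups = dict(data)
        else:
            self.groups = build_groups(data)
        self.coding = coding
        self.constraint = constraint
        self.use_parent = use_parent
        self.total = sum(self.groups.values())
        if self.total <= 0:
            raise ValueError("no data")
        self.complete = _groups_complete(self.groups)

    # -- EM machinery -------------------------------------------------------
    def _cell_probs(self, fit: _CompleteFit, table: CellCountTable) -> np.ndarray:
        """P(M,F,C | affected child) per cell: mating-type margin from the
        fractional table times fitted within-type conditionals."""
        margin = table.genotype_margin()
        mt_tot = np.array([margin[CELL_MT == t].sum() for t in range(6)])
        pi_mt = mt_tot / mt_tot.sum()
        return pi_mt[CELL_MT] * fit.cond_probs

    def _e_step(
        self, pi_cell: np.ndarray, q_cell: Optional[np.ndarray]
    ) -> tuple[CellCountTable, float]:
        counts = np.zeros((N_GENO_CELLS, 2))
        ll = 0.0
        for (m, f, c, d), w in self.groups.items():
            idx = _COMPLETIONS[(m, f, c)]
            lik = pi_cell[idx].copy()
            if q_cell is not None:
                lik *= q_cell[idx] if d == 1 else (1.0 - q_cell[idx])
            tot = lik.sum()
            ll += w * np.log(max(tot, 1e-300))
            if tot <= 0:
                # no mass: spread by Mendelian weights to keep EM alive
                lik = CELL_MEND[idx].copy()
                tot = lik.sum()
            counts[idx, d] += w * lik / tot
        return CellCountTable(counts), ll

    def _m_step(
        self, table: CellCountTable, warm: Optional[_CompleteFit] = None
    ) -> _CompleteFit:
        if not self.use_parent:
            tm = TransmissionModel(table, coding=self.coding)
            k = n_risk_params(self.coding)
            if self.constraint == "null":
                zero = np.zeros(k)
                return _CompleteFit(
                    tm.loglike(zero), zero, zero, np.full(6, -np.inf),
                    tm._cond_probs(zero), None, True,
                )
            tr = tm.fit(start=None if warm is None else warm.gamma)
            return _CompleteFit(
                tr.llf, tr.gamma, tr.gamma, np.full(6, -np.inf),
                tm._cond_probs(tr.params), tr.cov_params, tr.converged,
            )
        return _fit_complete(table, self.coding, self.constraint, start=warm)

    def fit(self, tol: float = 1e-8, max_iter: int = 500) -> "JointResults":
        if self.complete:
            table = _table_from_groups(self.groups)
            fit = self._m_step(table)
            return JointResults(
                self, fit, llf=fit.llf, em_iterations=1, em_trace=[fit.llf],
                converged=fit.converged, expected_counts=table,
            )
        # initial E-step: Mendelian completion weights only
        pi0 = np.ones(N_GENO_CELLS)
        table, _ = self._e_step(pi0 * CELL_MEND, None)
        trace: list[float] = []
        fit = None
        converged = False
        for it in range(1, max_iter + 1):
            # warm-starting each M-step at the previous parameters makes
            # this a generalized EM: the M-step never loses likelihood,
            # so the observed-data trace is guaranteed nondecreasing
            fit = self._m_step(table, warm=fit)
            pi_cell = self._cell_probs(fit, table)
            q_cell = (
                _q_cells(fit.alpha, fit.beta, self.coding)
                if self.use_parent
                else None
            )
            table, ll_obs = self._e_step(pi_cell, q_cell)
            if trace and ll_obs < trace[-1] - 1e-6 * (1 + abs(ll_obs)):
                raise RuntimeError(
                    f"EM observed log-likelihood decreased at iteration {it}: "
                    f"{trace[-1]:.10g} -> {ll_obs:.10g}"
                )
            done = bool(trace) and abs(ll_obs - trace[-1]) < tol * (1 + abs(ll_obs))
            trace.append(float(ll_obs))
            if done:
                converged = True
                break
        if not converged:
            warnings.warn(f"EM did not converge in {max_iter} iterations")
        return JointResults(
            self, fit, llf=trace[-1], em_iterations=len(trace),
            em_trace=trace, converged=converged and fit.converged,
            expected_counts=table,
        )


@dataclass
class JointResults:
    """Fitted joint model (complete-data or EM)."""

    model: JointTriadModel
    _fit: _CompleteFit
    llf: float                      # observed-data log-likelihood
    em_iterations: int
    em_trace: list
    converged: bool
    expected_counts: CellCountTable

    @property
    def constraint(self) -> str:
        return self.model.constraint

    @property
    def gamma(self) -> np.ndarray:
        return self._fit.gamma

    @property
    def beta(self) -> np.ndarray:
        return self._fit.beta

    @property
    def shared_coef(self) -> np.ndarray:
        if self.constraint != "shared":
            raise ValueError("shared coefficient defined only under 'shared'")
        return self._fit.gamma

    @property
    def alpha(self) -> np.ndarray:
        return self._fit.alpha

    @property
    def bse_risk(self) -> Optional[np.ndarray]:
        """Wald SEs of the risk coefficients.

        With missing data these come from the final M-step (complete-data)
        information and slightly understate the true uncertainty.
        """
        if self._fit.cov_slope is None:
            return None
        return np.sqrt(np.clip(np.diag(self._fit.cov_slope), 0, None))

    def summary(self) -> str:
        k = len(self.gamma)
        lines = [
            "Joint two-generation model",
            f"  coding: {self.model.coding}   constraint: {self.constraint}",
            f"  families: {self.model.total:.6g}   observed loglik: {self.llf:.6f}",
            f"  EM iterations: {self.em_iterations}   converged: {self.converged}",
        ]
        if self.constraint == "shared" and k:
            rr = np.exp(self.shared_coef)
            lines.append(f"  shared RR estimate: {np.array2string(rr, precision=4)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def em_fit(
    data,
    model: str = "joint",
    coding: str = "log_additive",
    constraint: str = "shared",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> JointResults:
    """Maximum likelihood with EM over missing parental genotypes.

    ``model='transmission'`` drops the parental-phenotype factor;
    ``model='parent'`` fits the joint model with free risk parameters
    (the genotype factor is needed to complete missing parents) and the
    parent coefficients are read from the result.
    """
    if model == "transmission":
        return JointTriadModel(
            data, coding=coding, constraint="free", use_parent=False
        ).fit(tol=tol, max_iter=max_iter)
    if model == "parent":
        constraint = "free"
    return JointTriadModel(data, coding=coding, constraint=constraint).fit(
        tol=tol, max_iter=max_iter
    )


def ppi_lrt(data, coding: str = "log_additive", tol: float = 1e-8,
            max_iter: int = 500) -> TestResult:
    """Parent-phenotype informed LRT: shared risk vector vs null.

    Handles missing parental genotypes through EM in both fits.
    """
    shared = JointTriadModel(data, coding=coding, constraint="shared").fit(
        tol=tol, max_iter=max_iter
    )
    null = JointTriadModel(data, coding=coding, constraint="null").fit(
        tol=tol, max_iter=max_iter
    )
    k = n_risk_params(coding)
    stat = 2.0 * (shared.llf - null.llf)
    kw = {}
    if k == 1:
        coef = float(shared.shared_coef[0])
        se = shared.bse_risk
        kw = dict(
            estimate=float(np.exp(coef)),
            sign=1 if coef >= 0 else -1,
        )
        if se is not None and np.isfinite(se[0]):
            kw["sigma"] = float(se[0])
            kw["conf_int"] = wald_rr_ci(coef, float(se[0]))
    res = chi2_test("ppi_lrt", stat, k, n_used=shared.model.total, **kw)
    if not (shared.converged and null.converged):
        res.message = "EM convergence flagged"
    return res


def generation_equality_test(
    data, coding: str = "log_additive", tol: float = 1e-8, max_iter: int = 500
) -> TestResult:
    """LRT of equal offspring and maternal relative risks (shared vs free)."""
    free = JointTriadModel(data, coding=coding, constraint="free").fit(
        tol=tol, max_iter=max_iter
    )
    shared = JointTriadModel(data, coding=coding, constraint="shared").fit(
        tol=tol, max_iter=max_iter
    )
    stat = 2.0 * (free.llf - shared.llf)
    return chi2_test(
        "generation_equality", stat, n_risk_params(coding),
        n_used=free.model.total,
    )


# ---------------------------------------------------------------------------
# Composite test
# ---------------------------------------------------------------------------

@dataclass
class CompositeInputs:
    """Components of the composite statistic Z_C."""

    x_t: float       # 1-df transmission LRT chi-square
    x_p: float       # 1-df parent-phenotype LRT chi-square
    s_t: int         # sign of the transmission coefficient
    s_p: int         # sign of the parent coefficient
    sigma_t: float   # Wald SE of the transmission coefficient
    sigma_p: float   # Wald SE of the parent coefficient

    def __post_init__(self):
        if self.x_t < 0 or self.x_p < 0:
            raise ValueError("chi-square components must be nonnegative")
        if self.sigma_t <= 0 or self.sigma_p <= 0:
            raise ValueError("standard errors must be positive")
        self.s_t = 1 if self.s_t >= 0 else -1
        self.s_p = 1 if self.s_p >= 0 else -1


def zc_statistic(inputs: CompositeInputs) -> float:
    """The signed composite statistic ``Z_C`` (standard normal under H0)."""
    w_t = 0.0 if np.isinf(inputs.sigma_t) else 1.0 / inputs.sigma_t
    w_p = 0.0 if np.isinf(inputs.sigma_p) else 1.0 / inputs.sigma_p
    denom = np.sqrt(w_t**2 + w_p**2)
    if denom == 0:
        return np.nan
    num = w_t * inputs.s_t * np.sqrt(inputs.x_t) + w_p * inputs.s_p * np.sqrt(inputs.x_p)
    return float(num / denom)


def ppi_ct(inputs: CompositeInputs) -> TestResult:
    """Composite test: ``Z_C^2`` against chi-square(1), two-sided."""
    z = zc_statistic(inputs)
    return chi2_test("ppi_ct", z * z, 1, sign=1 if z >= 0 else -1)


def ppi_ct_from_tests(
    transmission: TestResult, parent: TestResult
) -> TestResult:
    """Build the composite test from the two fitted 1-df component tests.

    Requires complete data (the two components must be independent); the
    component tests themselves refuse incomplete records upstream.  If the
    parent test is degenerate, returns a degenerate result directing the
    caller to the PPI-LRT.
    """
    if transmission.df != 1 or parent.df != 1:
        raise ValueError("composite test needs 1-df component tests")
    if parent.is_na or transmission.is_na or not (
        transmission.sigma and parent.sigma
    ):
        return TestResult(
            "ppi_ct", np.nan, 1, np.nan,
            message="degenerate component test; consider ppi_lrt",
        )
    return ppi_ct(
        CompositeInputs(
            x_t=transmission.statistic, x_p=parent.statistic,
            s_t=transmission.sign, s_p=parent.sign,
            sigma_t=transmission.sigma, sigma_p=parent.sigma,
        )
    )
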