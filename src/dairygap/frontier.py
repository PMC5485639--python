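"""Stochastic frontier analysis of multi-output farms.

Estimates a Cobb-Douglas stochastic output distance function by maximum
likelihood under the classical composed-error assumptions: i.i.d. normal
noise v and i.i.d. half-normal inefficiency u ≥ 0. Linear homogeneity in
outputs is imposed by normalising with one output, giving the regression

    -ln y_M = α0 + Σ_k β_k ln x_k + Σ_{m≠M} γ_m ln(y_m / y_M) + v + u .

Because the regressand is -ln of the normalising output, inefficiency (which
depresses output) *adds* to the composed error: ε = v + u, with marginal
density f(ε) = (2/σ) φ(ε/σ) Φ(λ ε/σ), σ² = σv² + σu², λ = σu/σv. The
variance decomposition is carried in the (σ², γ) parameterisation with
γ = σu²/σ² ∈ [0, 1), as in the FRONTIER estimation tradition.

Per-farm technical efficiency is the conditional-expectation (Battese–Coelli)
point estimator TE_i = E[exp(-u_i) | ε_i]; a z-test on γ̂ tests the null of
no inefficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .survey import SurveyTable

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceFunctionSpec",
    "FrontierDesign",
    "FrontierFit",
    "EfficiencyScore",
    "InefficiencyTest",
    "build_design",
    "neg_log_likelihood",
    "fit_frontier",
    "technical_efficiency_scores",
    "inefficiency_z_test",
    "gap_from_efficiency",
]

_GAMMA_EPS = 1e-8  # internal open-interval guard for γ on the logit scale
_PHI_FLOOR = 1e-300  # floor on Φ ratios in the TE estimator


class UnderIdentifiedError(ValueError):
    """Fewer usable farms than parameters + 2."""


class NonConvergenceError(RuntimeError):
    """All optimiser starts failed; carries the best point found."""

    def __init__(self, msg: str, best: "FrontierFit | None" = None):
        super().__init__(msg)
        self.best = best


@dataclass(frozen=True)
class DistanceFunctionSpec:
    """Which outputs/inputs enter the distance function and which output normalises."""

    output_names: tuple[str, ...]
    input_names: tuple[str, ...]
    normalizing_output: str

    def __post_init__(self) -> None:
        if self.normalizing_output not in self.output_names:
            raise ValueError(f"normalizing output {self.normalizing_output!r} not among outputs")
        if not self.output_names or not self.input_names:
            raise ValueError("need at least one output and one input")


@dataclass
class FrontierDesign:
    """Materialised regression design: r = -ln y_M against X = [1, ln x, ln(y/y_M)]."""

    r: np.ndarray  # (n,)
    X: np.ndarray  # (n, 1 + K + M - 1), first column constant
    farm_ids: list[str]
    spec: DistanceFunctionSpec
    dropped: int = 0

    @property
    def n(self) -> int:
        return self.r.size


@dataclass
class FrontierFit:
    """ML estimates of the distance-function frontier."""

    alpha0: float
    beta: np.ndarray
    gamma_out: np.ndarray
    sigma_sq: float
    gamma: float  # σu²/σ²
    loglik: float
    std_errors: dict[str, float]
    converged: bool
    n: int
    design: FrontierDesign | None = field(default=None, repr=False)

    @property
    def coefs(self) -> np.ndarray:
        return np.concatenate(([self.alpha0], self.beta, self.gamma_out))

    @property
    def residuals(self) -> np.ndarray:
        if self.design is None:
            raise ValueError("fit carries no design")
        return self.design.r - self.design.X @ self.coefs


@dataclass(frozen=True)
class EfficiencyScore:
    farm_id: str
    te: float


@dataclass(frozen=True)
class InefficiencyTest:
    z_value: float
    p_value: float
    significant_at: float | None  # coarsest of 0.001/0.01/0.05/0.1 exceeded, else None


def build_design(table: SurveyTable, spec: DistanceFunctionSpec) -> FrontierDesign:
    """Build the normalised log-log design, dropping farms with any zero quantity.

    Zeros are outside the log domain; affected farms are dropped (and counted)
    rather than shifted by an arbitrary constant.
    """
    rows, rs, ids = [], [], []
    dropped = 0
    y_m_names = [o for o in spec.output_names if o != spec.normalizing_output]
    for rec in table.records:
        vals_out = {o: rec.outputs[o] for o in spec.output_names}
        vals_in = {i: rec.inputs[i] for i in spec.input_names}
        if any(v <= 0 for v in vals_out.values()) or any(v <= 0 for v in vals_in.values()):
            dropped += 1
            continue
        yM = vals_out[spec.normalizing_output]
        row = [1.0]
        row += [np.log(vals_in[k]) for k in spec.input_names]
        row += [np.log(vals_out[m] / yM) for m in y_m_names]
        rows.append(row)
        rs.append(-np.log(yM))
        ids.append(rec.farm_id)
    if dropped:
        logger.info("build_design: dropped %d farms with zero quantities", dropped)
    X = np.asarray(rows, dtype=float)
    r = np.asarray(rs, dtype=float)
    p = 1 + len(spec.input_names) + len(y_m_names)
    if r.size < p + 2:
        raise UnderIdentifiedError(f"{r.size} farms for {p} parameters")
    return FrontierDesign(r=r, X=X, farm_ids=ids, spec=spec, dropped=dropped)


def _composed_loglik(eps: np.ndarray, sigma_sq: float, gamma: float) -> np.ndarray:
    """Pointwise log-density of ε = v + u (v normal, u half-normal)."""
    sigma = np.sqrt(sigma_sq)
    z = eps / sigma
    if gamma <= 0.0:
        return stats.norm.logpdf(eps, scale=sigma)
    lam = np.sqrt(gamma / (1.0 - gamma))
    return np.log(2.0) - np.log(sigma) + stats.norm.logpdf(z) + stats.norm.logcdf(lam * z)


def neg_log_likelihood(
    params: Sequence[float] | tuple,
    design: FrontierDesign,
) -> float:
    """Negative log-likelihood at natural parameters (coefs..., σ², γ).

    params is the flat vector (α0, β..., γ_out..., sigma_sq, gamma).
    At γ = 0 this is exactly the Gaussian regression NLL with variance σ².
    """
    params = np.asarray(params, dtype=float)
    coefs, sigma_sq, gamma = params[:-2], params[-2], params[-1]
    if sigma_sq <= 0 or not (0.0 <= gamma < 1.0):
        raise ValueError(f"require sigma_sq > 0 and 0 <= gamma < 1, got {sigma_sq}, {gamma}")
    eps = design.r - design.X @ coefs
    ll = _composed_loglik(eps, sigma_sq, gamma)
    if not np.all(np.isfinite(ll)):
        bad = int(np.argmin(np.isfinite(ll)))
        raise FloatingPointError(f"non-finite log-likelihood at row {bad} (farm {design.farm_ids[bad]})")
    return float(-np.sum(ll))


def _logit(p: float) -> float:
    p = min(max(p, _GAMMA_EPS), 1 - _GAMMA_EPS)
    return float(np.log(p / (1 - p)))


def _expit(t: float) -> float:
    return float(1.0 / (1.0 + np.exp(-t)))


def _nll_transformed(theta: np.ndarray, design: FrontierDesign) -> float:
    """NLL over unconstrained params: (coefs, log σ², logit γ)."""
    coefs = theta[:-2]
    sigma_sq = float(np.exp(theta[-2]))
    gamma = _expit(theta[-1])
    gamma = min(gamma, 1 - _GAMMA_EPS)
    eps = design.r - design.X @ coefs
    ll = _composed_loglik(eps, sigma_sq, gamma)
    if not np.all(np.isfinite(ll)):
        return 1e30
    return float(-np.sum(ll))


def _cols_start(design: FrontierDesign) -> tuple[np.ndarray, float, float]:
    """Corrected-OLS start: OLS slopes, moment-corrected (σ², γ) from residual skew.

    For ε = v + u with half-normal u the third central moment is
    m3 = σu³ √(2/π) (4/π − 1) > 0; invert it for σu, then σv² = m2 − (1−2/π)σu²
    and shift the intercept by E[u] = σu √(2/π).
    """
    b, *_ = np.linalg.lstsq(design.X, design.r, rcond=None)
    resid = design.r - design.X @ b
    m2 = float(np.mean(resid**2))
    m3 = float(np.mean(resid**3))
    c3 = np.sqrt(2 / np.pi) * (4 / np.pi - 1)
    if m3 > 0:
        sigma_u_sq = (m3 / c3) ** (2 / 3)
    else:
        sigma_u_sq = 0.0
    sigma_v_sq = max(m2 - (1 - 2 / np.pi) * sigma_u_sq, 1e-6)
    sigma_sq = sigma_v_sq + sigma_u_sq
    gamma = max(sigma_u_sq / sigma_sq, 0.05)  # γ floor keeps the start off the boundary
    gamma = min(gamma, 0.95)
    coefs = b.copy()
    coefs[0] -= np.sqrt(2 / np.pi) * np.sqrt(gamma * sigma_sq)  # remove E[u] from intercept
    return coefs, sigma_sq, gamma


def fit_frontier(
    table: SurveyTable | None,
    spec: DistanceFunctionSpec | None = None,
    design: FrontierDesign | None = None,
) -> FrontierFit:
    """Maximum-likelihood fit of the half-normal stochastic frontier.

    Starts from the corrected-OLS solution plus restarts at γ ∈ {0.3, 0.7};
    the best log-likelihood is kept. Standard errors come from the inverse
    observed information in the natural (coefs, σ², γ) parameterisation.
    """
    if design is None:
        if table is None or spec is None:
            raise ValueError("provide either a design or (table, spec)")
        design = build_design(table, spec)
    spec = design.spec

    coefs0, s2_0, g0 = _cols_start(design)
    starts = [(coefs0, s2_0, g0)]
    for g_alt in (0.3, 0.7):
        starts.append((coefs0, s2_0, g_alt))

    best = None
    for coefs, s2, g in starts:
        theta0 = np.concatenate([coefs, [np.log(s2), _logit(g)]])
        res = optimize.minimize(
            _nll_transformed,
            theta0,
            args=(design,),
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    theta = best.x
    coefs = theta[:-2]
    sigma_sq = float(np.exp(theta[-2]))
    gamma = _expit(theta[-1])
    loglik = -float(best.fun)
    # BFGS sometimes stops with a precision-loss status at a genuine optimum;
    # a near-zero gradient is the honest convergence check
    grad_ok = best.jac is not None and float(np.max(np.abs(best.jac))) < 1e-3 * max(1.0, abs(best.fun))
    converged = (bool(best.success) or grad_ok) and np.isfinite(loglik)

    # observed information in natural parameters (γ kept off the boundary)
    names = (
        ["alpha0"]
        + [f"beta_{k}" for k in spec.input_names]
        + [f"gamma_out_{m}" for m in spec.output_names if m != spec.normalizing_output]
        + ["sigma_sq", "gamma"]
    )
    natural = np.concatenate([coefs, [sigma_sq, max(gamma, 1e-6)]])
    std_errors: dict[str, float] = {}
    try:
        H = approx_hess(natural, lambda p: neg_log_likelihood(p, design))
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        std_errors = dict(zip(names, ses.tolist()))
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        logger.warning("fit_frontier: information matrix not invertible; no std errors")

    K = len(spec.input_names)
    fit = FrontierFit(
        alpha0=float(coefs[0]),
        beta=coefs[1 : 1 + K].copy(),
        gamma_out=coefs[1 + K :].copy(),
        sigma_sq=sigma_sq,
        gamma=float(gamma),
        loglik=loglik,
        std_errors=std_errors,
        converged=converged,
        n=design.n,
        design=design,
    )
    if not converged and not np.isfinite(loglik):
        raise NonConvergenceError("all optimiser starts failed", best=fit)
    return fit


def technical_efficiency_scores(
    fit: FrontierFit,
    design: FrontierDesign | None = None,
    estimator: str = "bc",
) -> list[EfficiencyScore]:
    """Per-farm technical efficiency from the composed-error decomposition.

    The conditional distribution of u given ε is N(μ*, σ*²) truncated at zero
    with μ* = γ ε and σ*² = γ(1−γ)σ². ``estimator="bc"`` returns the
    conditional expectation of exp(−u) (the default of the classic frontier
    packages); ``estimator="jlms"`` returns exp(−E[u|ε]).
    """
    design = design or fit.design
    if design is None:
        raise ValueError("no design available")
    eps = design.r - design.X @ fit.coefs
    s2, g = fit.sigma_sq, fit.gamma
    if g <= 0:
        return [EfficiencyScore(fid, 1.0) for fid in design.farm_ids]
    mu_star = g * eps
    sig_star = np.sqrt(g * (1 - g) * s2)
    a = mu_star / sig_star
    if estimator == "bc":
        num = stats.norm.cdf(a - sig_star)
        den = stats.norm.cdf(a)
        ratio = np.maximum(num, _PHI_FLOOR) / np.maximum(den, _PHI_FLOOR)
        te = np.exp(-mu_star + 0.5 * sig_star**2) * ratio
    elif estimator == "jlms":
        # E[u|ε] for the truncated normal
        pdf, cdf = stats.norm.pdf(a), np.maximum(stats.norm.cdf(a), _PHI_FLOOR)
        e_u = mu_star + sig_star * pdf / cdf
        te = np.exp(-e_u)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    te = np.clip(te, np.finfo(float).tiny, 1.0)
    return [EfficiencyScore(fid, float(t)) for fid, t in zip(design.farm_ids, te)]


def mean_te(scores: Sequence[EfficiencyScore]) -> float:
    """Average of the individual farm technical-efficiency scores."""
    return float(np.mean([s.te for s in scores]))


_BANDS = (0.001, 0.01, 0.05, 0.1)


def inefficiency_z_test(fit: FrontierFit) -> InefficiencyTest:
    """z-test of the no-inefficiency null: z = γ̂ / SE(γ̂), one-sided normal tail."""
    se = fit.std_errors.get("gamma")
    if se is None or se == 0 or not np.isfinite(se):
        raise ZeroDivisionError("degenerate information: no usable SE for gamma")
    z = fit.gamma / se
    p = float(stats.norm.sf(z))
    sig = None
    for band in _BANDS:  # coarsest band the p-value clears
        if p < band:
            sig = band
            break
    return InefficiencyTest(z_value=float(z), p_value=p, significant_at=sig)


def band_for_z(z: float) -> float | None:
    """Significance band for a reported z statistic under the one-sided normal reference."""
    p = float(stats.norm.sf(z))
    for band in _BANDS:
        if p < band:
            return band
    return None


def gap_from_efficiency(mean_te_value: float) -> float:
    """Convert mean technical efficiency to a yield gap (% increase to the frontier)."""
    if not (0.0 < mean_te_value <= 1.0):
        raise ValueError("mean TE must be in (0, 1]")
    return (1.0 / mean_te_value - 1.0) * 100.0
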