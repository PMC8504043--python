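"""Beta-distributed GLMM with a patient random intercept.

The multivariable model for prescription fulfilment scores: the outcome
``y_ij`` (the boundary-transformed prescription-Fscore of prescription *j*
in patient *i*) follows a beta distribution in mean–precision form,

    y_ij | b_i  ~  Beta(mu_ij * phi, (1 - mu_ij) * phi),
    logit(mu_ij) = x_ij' beta + b_i,        b_i ~ N(0, sigma_b^2),

with a single precision parameter ``phi`` (no dispersion covariates).  Fixed
effects are the time point (post- vs pre-implementation), the prescription
category (reference: standard peroral), the discrete number of
comedications, and the ward indicator in *weighted* effect coding, so ward
coefficients are deviations from the prescription-weighted grand mean and
the reference ward's coefficient is recoverable as the negative weighted sum
of the others.

Estimation maximises the exact marginal likelihood

    L = prod_i  ∫ prod_j Beta(y_ij; mu_ij(b), phi) · N(b; 0, sigma_b^2) db

by adaptive Gauss–Hermite quadrature: the integrand of each patient is
re-centred at its mode and re-scaled by its curvature before applying the
Gauss–Hermite rule, so a moderate number of nodes (default 15) suffices;
one node is the Laplace approximation.  Optimisation is quasi-Newton over
(beta, log sigma_b, log phi) from a deterministic start, and the covariance
of the estimates comes from the inverse numerical Hessian.

Exponentiated coefficients are odds ratios for improving the ratio between
the fulfilment score and its distance to perfect scoring.  The E-value for
unmeasured confounding is provided for sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special

from .prescriptions import PrescriptionCategory, TimePoint

__all__ = [
    "ModelSpec",
    "Design",
    "BetaGLMMFit",
    "EffectEstimate",
    "build_design",
    "marginal_loglikelihood",
    "beta_logpdf_mean_precision",
    "fit",
    "odds_ratios",
    "predict_adjusted",
    "net_interventional_effect",
    "evalue",
]

_CATEGORY_ORDER = [
    PrescriptionCategory.RISKY_ROUTE,
    PrescriptionCategory.AS_NEEDED,
    PrescriptionCategory.OTHER,
]

REQUIRED_COLUMNS = ("patient_id", "time_point", "category", "n_comedications", "ward_id")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the fixed and random structure.

    Parameters
    ----------
    reference_ward:
        Ward whose effect-coded column is omitted and later derived.  ``None``
        selects the ward with the most prescriptions (most precise derived
        coefficient).
    n_quadrature_nodes:
        Gauss–Hermite nodes for the adaptive quadrature; 1 = Laplace.
    gradient_tol, max_iter:
        Quasi-Newton stopping controls.
    """

    reference_ward: int | None = None
    n_quadrature_nodes: int = 15
    gradient_tol: float = 1e-6
    max_iter: int = 500

    def to_dict(self) -> dict:
        return {
            "reference_ward": self.reference_ward,
            "n_quadrature_nodes": self.n_quadrature_nodes,
            "gradient_tol": self.gradient_tol,
            "max_iter": self.max_iter,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(**{k: d[k] for k in
                      ("reference_ward", "n_quadrature_nodes", "gradient_tol", "max_iter")
                      if k in d})


@dataclass
class Design:
    """Fixed-effect design matrix plus the clustering index.

    ``ward_weights`` maps ward id to its share of prescriptions; the weights
    are treated as fixed constants of the observed design thereafter (in
    particular when deriving the reference-ward coefficient).
    """

    X: np.ndarray
    columns: list[str]
    patient_codes: np.ndarray
    patient_ids: list[str]
    ward_weights: dict[int, float]
    reference_ward: int
    ward_levels: list[int]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def _as_category(value) -> PrescriptionCategory:
    return value if isinstance(value, PrescriptionCategory) else PrescriptionCategory(value)


def _as_timepoint(value) -> TimePoint:
    return value if isinstance(value, TimePoint) else TimePoint(value)


def build_design(
    obs: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    ward_weights: Mapping[int, float] | None = None,
) -> Design:
    """Build the fixed-effect matrix with weighted effect-coded wards.

    *obs* needs one row per prescription with columns ``patient_id``,
    ``time_point``, ``category``, ``n_comedications`` and ``ward_id``.
    An observation in ward ``k`` (k ≠ reference) scores 1 in column ``k``;
    a reference-ward observation scores ``−w_k/w_ref`` in every ward column,
    which makes each column's prescription-weighted mean zero.

    Pre-computed *ward_weights* (from the training design) may be supplied
    when rebuilding the matrix for prediction.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table lacks columns {missing}")
    if obs[list(REQUIRED_COLUMNS)].isna().any().any():
        bad = obs[list(REQUIRED_COLUMNS)].isna().any()
        raise ValueError(f"missing covariate values in {list(bad[bad].index)}")

    n = len(obs)
    wards = obs["ward_id"].astype(int).to_numpy()
    if ward_weights is None:
        counts = pd.Series(wards).value_counts()
        if (counts == 0).any():
            raise ValueError("every ward level must carry at least one prescription")
        ward_weights = (counts / n).to_dict()
    ward_levels = sorted(ward_weights)
    unseen = set(np.unique(wards)) - set(ward_levels)
    if unseen:
        raise ValueError(f"wards {sorted(unseen)} not in the training design")

    ref = spec.reference_ward
    if ref is None:
        ref = max(ward_levels, key=lambda k: (ward_weights[k], k))
    if ref not in ward_levels:
        raise ValueError(f"reference ward {ref} has no prescriptions")

    tp = np.array([_as_timepoint(t) is TimePoint.POST for t in obs["time_point"]], float)
    cats = [_as_category(c) for c in obs["category"]]

    cols: list[np.ndarray] = [np.ones(n), tp]
    names = ["intercept", "time_post"]
    for cat in _CATEGORY_ORDER:
        cols.append(np.array([c is cat for c in cats], float))
        names.append(f"category_{cat.value}")
    cols.append(obs["n_comedications"].to_numpy(float))
    names.append("n_comedications")
    is_ref = wards == ref
    for k in ward_levels:
        if k == ref:
            continue
        col = np.where(wards == k, 1.0, 0.0)
        col[is_ref] = -ward_weights[k] / ward_weights[ref]
        cols.append(col)
        names.append(f"ward_{k}")

    pat_ids, codes = np.unique(obs["patient_id"].to_numpy(), return_inverse=True)
    return Design(
        X=np.column_stack(cols),
        columns=names,
        patient_codes=codes.astype(np.intp),
        patient_ids=list(pat_ids),
        ward_weights={int(k): float(v) for k, v in ward_weights.items()},
        reference_ward=int(ref),
        ward_levels=[int(k) for k in ward_levels],
    )


# ---------------------------------------------------------------------------
# marginal likelihood


def beta_logpdf_mean_precision(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Log density of Beta(mu*phi, (1-mu)*phi) at y, elementwise."""
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


class _LikelihoodWorkspace:
    """Pre-computed pieces reused across likelihood evaluations.

    Keeps the logit of the outcome, the per-patient observation index and a
    warm start for the per-patient mode search, which shrinks the Newton
    iteration count during optimisation to one or two steps.
    """

    def __init__(self, y: np.ndarray, design: Design, n_nodes: int):
        y = np.asarray(y, float)
        if np.any((y <= 0.0) | (y >= 1.0)):
            raise ValueError("outcomes must lie strictly inside (0,1); transform first")
        self.y = y
        self.logit_y = np.log(y) - np.log1p(-y)
        self.log_y = np.log(y)
        self.log1m_y = np.log1p(-y)
        self.codes = design.patient_codes
        self.n_pat = design.n_patients
        z, w = hermgauss(n_nodes)
        self.z = z
        self.logw_plus_z2 = np.log(w) + z**2
        self.b_warm = np.zeros(self.n_pat)

    def per_patient(self, arr: np.ndarray) -> np.ndarray:
        return np.bincount(self.codes, weights=arr, minlength=self.n_pat)


def _obs_loglik_and_derivs(ws, eta, phi, order=2):
    """Per-observation beta log density and its first/second η-derivatives."""
    mu = special.expit(eta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (
        special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
        + (a - 1.0) * ws.log_y + (b - 1.0) * ws.log1m_y
    )
    if order == 0:
        return ll, None, None
    mustar = ws.logit_y - special.psi(a) + special.psi(b)
    dmu = mu * (1.0 - mu)
    g = dmu * phi * mustar
    if order == 1:
        return ll, g, None
    dT = -phi * (special.polygamma(1, a) + special.polygamma(1, b))
    h = (1.0 - 2.0 * mu) * g + dmu * phi * dmu * dT
    return ll, g, h


def _obs_dloglik_dphi(ws, eta, phi):
    """Per-observation derivative of the beta log density wrt phi."""
    mu = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
    return (
        special.psi(phi)
        - mu * special.psi(mu * phi)
        - (1.0 - mu) * special.psi((1.0 - mu) * phi)
        + mu * ws.log_y
        + (1.0 - mu) * ws.log1m_y
    )


def _find_modes(ws, eta0, sigma, phi, tol=1e-9, max_iter=50):
    """Per-patient posterior mode of b and curvature, by safeguarded Newton."""
    b = ws.b_warm.copy()
    inv_s2 = 1.0 / (sigma * sigma)

    def objective(b_vec):
        eta = eta0 + b_vec[ws.codes]
        ll, g, h = _obs_loglik_and_derivs(ws, eta, phi)
        f = ws.per_patient(ll) - 0.5 * b_vec**2 * inv_s2
        grad = ws.per_patient(g) - b_vec * inv_s2
        hess = ws.per_patient(h) - inv_s2
        return f, grad, hess

    f, grad, hess = objective(b)
    for _ in range(max_iter):
        hess_safe = np.minimum(hess, -inv_s2 * 1e-8)
        step = -grad / hess_safe
        step = np.clip(step, -5.0, 5.0)
        scale = np.ones_like(b)
        for _ in range(25):
            b_new = b + scale * step
            f_new, grad_new, hess_new = objective(b_new)
            worse = ~np.isfinite(f_new) | (f_new < f - 1e-12)
            if not worse.any():
                break
            scale[worse] *= 0.5
        b, f, grad, hess = b_new, f_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol:
            break
    ws.b_warm = b.copy()
    curv = -np.minimum(hess, -inv_s2 * 1e-10)
    return b, curv


def _marginal_loglik(ws, X, beta, sigma, phi, want_grad=False):
    """AGQ marginal log-likelihood; optionally its gradient in
    (beta, log sigma, log phi).

    The gradient differentiates the quadrature sum holding each patient's
    node locations fixed; the neglected mode-shift term is of the order of
    the quadrature error itself.
    """
    eta0 = X @ beta
    if sigma <= 1e-8:
        ll, g, _ = _obs_loglik_and_derivs(ws, eta0, phi,
                                          order=1 if want_grad else 0)
        if not want_grad:
            return float(ll.sum())
        grad_beta = X.T @ g
        dphi = _obs_dloglik_dphi(ws, eta0, phi).sum() * phi
        return float(ll.sum()), np.concatenate([grad_beta, [0.0], [dphi]])
    bhat, curv = _find_modes(ws, eta0, sigma, phi)
    tau = 1.0 / np.sqrt(curv)
    # log ∫ e^{h(b)} db ≈ log[√2 τ Σ_k w_k e^{z_k²} e^{h(b̂+√2 τ z_k)}]
    nodes_b = bhat[None, :] + math.sqrt(2.0) * tau[None, :] * ws.z[:, None]
    log_norm = -0.5 * math.log(2 * math.pi) - math.log(sigma)
    n_nodes = len(ws.z)
    contrib = np.empty((n_nodes, ws.n_pat))
    g_obs = np.empty((n_nodes, len(ws.y))) if want_grad else None
    dphi_obs = np.empty((n_nodes, len(ws.y))) if want_grad else None
    for k in range(n_nodes):
        bk = nodes_b[k]
        eta = eta0 + bk[ws.codes]
        ll, g, _ = _obs_loglik_and_derivs(ws, eta, phi,
                                          order=1 if want_grad else 0)
        contrib[k] = (
            ws.per_patient(ll)
            + log_norm
            - 0.5 * bk**2 / (sigma * sigma)
            + ws.logw_plus_z2[k]
        )
        if want_grad:
            g_obs[k] = g
            dphi_obs[k] = _obs_dloglik_dphi(ws, eta, phi)
    per_pat = special.logsumexp(contrib, axis=0) + 0.5 * math.log(2.0) + np.log(tau)
    total = float(per_pat.sum())
    if not want_grad:
        return total
    # posterior node weights p_ik, then per-observation mixture weights
    p_ik = np.exp(contrib - special.logsumexp(contrib, axis=0, keepdims=True))
    p_obs = p_ik[:, ws.codes]
    omega = (p_obs * g_obs).sum(axis=0)
    grad_beta = X.T @ omega
    dlogsigma = float((p_ik * (nodes_b**2 / (sigma * sigma) - 1.0)).sum())
    dlogphi = float((p_obs * dphi_obs).sum() * phi)
    return total, np.concatenate([grad_beta, [dlogsigma], [dlogphi]])


def marginal_loglikelihood(
    beta: Sequence[float],
    sigma_b: float,
    phi: float,
    y: Sequence[float],
    design: Design,
    n_nodes: int = 15,
) -> float:
    """Marginal log-likelihood of the beta GLMM at the given parameters.

    ``sigma_b = 0`` degenerates exactly to the fixed-effects beta-regression
    log-likelihood.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if sigma_b < 0:
        raise ValueError("sigma_b must be nonnegative")
    ws = _LikelihoodWorkspace(np.asarray(y, float), design, n_nodes)
    return _marginal_loglik(ws, design.X, np.asarray(beta, float), sigma_b, phi)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class BetaGLMMFit:
    """Maximum-marginal-likelihood fit artifact.

    ``vcov`` is the covariance of (beta, log sigma_b, log phi) in that order;
    ``param_names`` labels its rows.  ``sigma_b_ci`` is a 95% Wald interval
    on the SD scale obtained by exponentiating the log-scale interval.
    """

    beta: np.ndarray
    sigma_b: float
    phi: float
    vcov: np.ndarray
    loglik: float
    converged: bool
    design: Design
    spec: ModelSpec
    param_names: list[str] = field(default_factory=list)
    n_obs: int = 0
    fixed_sigma_zero: bool = False
    y_train: np.ndarray | None = None

    @property
    def beta_se(self) -> np.ndarray:
        k = len(self.beta)
        return np.sqrt(np.diag(self.vcov)[:k])

    @property
    def sigma_b_ci(self) -> tuple[float, float]:
        if self.fixed_sigma_zero:
            return (0.0, 0.0)
        k = len(self.beta)
        se = math.sqrt(self.vcov[k, k])
        log_s = math.log(self.sigma_b)
        return (math.exp(log_s - 1.96 * se), math.exp(log_s + 1.96 * se))

    def coef_table(self) -> pd.DataFrame:
        se = self.beta_se
        z = self.beta / se
        p = 2.0 * special.ndtr(-np.abs(z))
        return pd.DataFrame(
            {"coef": self.beta, "se": se, "z": z, "p": p},
            index=self.design.columns,
        )


def _start_values(y, X):
    """Deterministic start: OLS on the logit outcome for beta."""
    logit_y = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(X, logit_y, rcond=None)
    return beta0


def _hessian_from_grad(grad, x0, step=1e-5):
    """Numerical Hessian from central differences of the gradient."""
    p = len(x0)
    H = np.empty((p, p))
    steps = step * np.maximum(1.0, np.abs(x0))
    for i in range(p):
        e = np.zeros(p)
        e[i] = steps[i]
        H[i] = (grad(x0 + e) - grad(x0 - e)) / (2.0 * steps[i])
    return 0.5 * (H + H.T)


def _numerical_hessian(f, x0, step=1e-4):
    p = len(x0)
    H = np.empty((p, p))
    steps = step * np.maximum(1.0, np.abs(x0))
    f0 = f(x0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            if i == j:
                fpp = f(x0 + ei); fmm = f(x0 - ei)
                H[i, i] = (fpp - 2.0 * f0 + fmm) / steps[i] ** 2
            else:
                fpp = f(x0 + ei + ej); fpm = f(x0 + ei - ej)
                fmp = f(x0 - ei + ej); fmm = f(x0 - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def fit(
    obs: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    outcome: str = "y",
    fix_sigma_zero: bool = False,
    compute_vcov: bool = True,
) -> BetaGLMMFit:
    """Fit the beta GLMM by adaptive Gauss–Hermite marginal likelihood.

    *obs* needs the covariate columns of :func:`build_design` plus the
    transformed outcome in column *outcome* (strictly inside (0,1)).

    The optimisation runs over ``(beta, log sigma_b, log phi)`` from a fixed
    start (beta from an ordinary least-squares fit on the logit outcome,
    sigma_b = 0.1, phi = 10), so refitting the same data always reproduces
    the same estimates bitwise.  With ``fix_sigma_zero=True`` the random
    intercept is removed and the model reduces to fixed-effects beta
    regression.
    """
    design = build_design(obs, spec)
    y = obs[outcome].to_numpy(float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("outcome must be strictly inside (0,1); transform first")
    if design.n_patients < 2:
        raise ValueError("need at least 2 patients")
    rank = np.linalg.matrix_rank(design.X)
    if rank < design.X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {design.X.shape[1]})"
        )
    ws = _LikelihoodWorkspace(y, design, spec.n_quadrature_nodes)
    X = design.X
    p = X.shape[1]
    beta0 = _start_values(y, X)

    if fix_sigma_zero:
        x0 = np.concatenate([beta0, [math.log(10.0)]])

        def nll(theta):
            val, grad = _marginal_loglik(ws, X, theta[:p], 0.0,
                                         math.exp(theta[p]), want_grad=True)
            if not np.isfinite(val):
                return 1e12, np.zeros_like(theta)
            return -val, -np.delete(grad, p)  # drop the sigma slot
    else:
        x0 = np.concatenate([beta0, [math.log(0.1)], [math.log(10.0)]])

        def nll(theta):
            val, grad = _marginal_loglik(ws, X, theta[:p], math.exp(theta[p]),
                                         math.exp(theta[p + 1]), want_grad=True)
            if not np.isfinite(val):
                return 1e12, np.zeros_like(theta)
            return -val, -grad

    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", jac=True,
        options={"maxiter": spec.max_iter, "ftol": 1e-11,
                 "gtol": spec.gradient_tol},
    )
    theta = res.x
    if not res.success:
        warnings.warn(f"beta GLMM optimisation did not converge: {res.message}")

    if compute_vcov:
        H = _hessian_from_grad(lambda x: nll(x)[1], theta)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
        vcov = 0.5 * (vcov + vcov.T)
    else:
        vcov = np.full((len(theta), len(theta)), np.nan)

    if fix_sigma_zero:
        sigma_b, phi = 0.0, math.exp(theta[p])
        names = design.columns + ["log_phi"]
    else:
        sigma_b, phi = math.exp(theta[p]), math.exp(theta[p + 1])
        names = design.columns + ["log_sigma_b", "log_phi"]
    return BetaGLMMFit(
        beta=theta[:p].copy(),
        sigma_b=sigma_b,
        phi=phi,
        vcov=vcov,
        loglik=-res.fun,
        converged=bool(res.success),
        design=design,
        spec=replace(spec, reference_ward=design.reference_ward),
        param_names=names,
        n_obs=len(y),
        fixed_sigma_zero=fix_sigma_zero,
        y_train=y.copy(),
    )


# ---------------------------------------------------------------------------
# reporting


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float


def odds_ratios(fit_result: BetaGLMMFit) -> list[EffectEstimate]:
    """Wald odds ratios for every fixed effect, all wards included.

    The omitted reference ward's coefficient is derived from the weighted
    effect-coding identity ``sum_k w_k beta_k = 0`` as
    ``beta_ref = −Σ_{k≠ref} (w_k/w_ref) beta_k``, with its standard error by
    the delta method (ward weights treated as fixed).
    """
    if not np.all(np.isfinite(fit_result.vcov)):
        raise ValueError("fit lacks a covariance matrix")
    d = fit_result.design
    out: list[EffectEstimate] = []

    def wald(term, coef, se):
        z = coef / se if se > 0 else math.inf
        p = 2.0 * float(special.ndtr(-abs(z)))
        return EffectEstimate(
            term=term,
            odds_ratio=math.exp(coef),
            ci_low=math.exp(coef - 1.96 * se),
            ci_high=math.exp(coef + 1.96 * se),
            p=p,
            coef=coef,
            se=se,
        )

    se_all = fit_result.beta_se
    ward_positions = {}
    for i, (name, coef) in enumerate(zip(d.columns, fit_result.beta)):
        if name.startswith("ward_"):
            ward_positions[int(name.split("_")[1])] = i
            continue
        out.append(wald(name, float(coef), float(se_all[i])))

    # wards in id order, reference derived in place
    w = d.ward_weights
    ref = d.reference_ward
    idx = [ward_positions[k] for k in sorted(ward_positions)]
    a = np.zeros(len(fit_result.beta))
    for k, i in ward_positions.items():
        a[i] = -w[k] / w[ref]
    vcov_beta = fit_result.vcov[: len(fit_result.beta), : len(fit_result.beta)]
    coef_ref = float(a @ fit_result.beta)
    se_ref = float(math.sqrt(a @ vcov_beta @ a))
    for k in d.ward_levels:
        if k == ref:
            out.append(wald(f"ward_{k}", coef_ref, se_ref))
        else:
            i = ward_positions[k]
            out.append(wald(f"ward_{k}", float(fit_result.beta[i]), float(se_all[i])))
    return out


def predict_adjusted(
    fit_result: BetaGLMMFit, obs: pd.DataFrame, conditional: bool = False
) -> np.ndarray:
    """Covariate-adjusted predicted fulfilment score per observation.

    Population-level by default (random intercept at zero).  With
    ``conditional=True`` the empirical-Bayes patient intercepts from the
    training data are added for patients seen at fit time.
    """
    design = build_design(
        obs,
        replace(fit_result.spec, reference_ward=fit_result.design.reference_ward),
        ward_weights=fit_result.design.ward_weights,
    )
    eta = design.X @ fit_result.beta
    if conditional and not fit_result.fixed_sigma_zero:
        train = fit_result.design
        if fit_result.y_train is None:
            raise ValueError("fit carries no training outcomes")
        ws = _LikelihoodWorkspace(fit_result.y_train, train, 1)
        bhat, _ = _find_modes(
            ws, train.X @ fit_result.beta, fit_result.sigma_b, fit_result.phi
        )
        eb = dict(zip(train.patient_ids, bhat))
        eta = eta + np.array([eb.get(pid, 0.0) for pid in obs["patient_id"]])
    return special.expit(eta)


def net_interventional_effect(
    fit_result: BetaGLMMFit, obs: pd.DataFrame
) -> dict[str, float]:
    """Difference of predicted group means, post − pre, per category.

    Returned in percentage points.  A category observed at only one time
    point is omitted with a warning.
    """
    pred = predict_adjusted(fit_result, obs)
    tps = np.array([_as_timepoint(t) is TimePoint.POST for t in obs["time_point"]])
    cats = np.array([_as_category(c).value for c in obs["category"]])
    out: dict[str, float] = {}
    for cat in [PrescriptionCategory.STANDARD_PERORAL, *_CATEGORY_ORDER]:
        mask = cats == cat.value
        post = pred[mask & tps]
        pre = pred[mask & ~tps]
        if post.size == 0 or pre.size == 0:
            warnings.warn(f"category {cat.value!r} absent at one time point; omitted")
            continue
        out[cat.value] = float((post.mean() - pre.mean()) * 100.0)
    return out


def evalue(odds_ratio: float) -> float:
    """E-value for unmeasured confounding, applied directly to the odds ratio.

    For OR ≥ 1: ``E = OR + sqrt(OR·(OR−1))``; an OR below 1 is inverted
    first.  The E-value is the minimum strength of association (risk-ratio
    scale) an unmeasured confounder would need with both intervention and
    outcome to explain the estimate away.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    r = odds_ratio if odds_ratio >= 1.0 else 1.0 / odds_ratio
    return r + math.sqrt(r * (r - 1.0))
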