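"""Variational Laplace: free-energy maximisation under Gaussian beliefs.

Model inversion fits a parameter vector θ with Gaussian prior to data y
under additive Gaussian observation noise with unknown precision exp(λ).
Beliefs q(θ) are Gaussian; the (negative) variational free energy

    F = accuracy − complexity
      = E_q[ln p(y|θ, λ)] − KL(q(θ) ‖ p(θ))          (− KL over λ when free)

is a lower bound on the log evidence ln p(y|m) and is ascended by a
regularised (Levenberg–Marquardt) Gauss–Newton scheme: candidate steps that
would decrease F are rejected and the regulariser increased, so the trace of
F over accepted iterations is non-decreasing by construction.  The noise
log-precision λ is updated by interleaved Newton steps (coordinate ascent).
For a linear forward map all these quantities are exact and the optimum
reproduces the conjugate closed-form posterior and log marginal likelihood.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .network import DEFAULT_FREE, ModelParameters, NetworkSpec, parameter_names
from .simulate import SensorData, TimeGrid, predict_sensor_batch

__all__ = [
    "GaussianBelief",
    "InversionResult",
    "free_energy",
    "invert",
    "invert_erp",
    "sensitivity",
    "default_priors",
    "PRIOR_VARIANCES",
]

logger = logging.getLogger(__name__)

#: Prior variances per parameter class: mild shrinkage (1/16) around the
#: template for extrinsic/intrinsic/modulatory log-scalings, tight (1/128)
#: for rate-constant scalings, unit variance for input and lead gains.
PRIOR_VARIANCES = {
    "a_fwd": 1.0 / 16, "a_bwd": 1.0 / 16, "b": 1.0 / 16, "g": 1.0 / 16,
    "c": 1.0, "kappa": 1.0 / 128, "lead": 1.0,
}

_PSD_FLOOR = 1e-12


@dataclass
class GaussianBelief:
    """A Gaussian belief (prior or posterior) over a named parameter vector."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        d = len(self.names)
        if self.mean.shape != (d,) or self.cov.shape != (d, d):
            raise ValueError("names, mean and covariance dimensions must align")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh((self.cov + self.cov.T) / 2).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")

    @property
    def dim(self) -> int:
        return len(self.names)

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def precision(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular covariance; cannot form precision") from err

    def index(self, name: str) -> int:
        return self.names.index(name)

    def credible_interval(self, level: float = 0.90) -> np.ndarray:
        """Central credible intervals per parameter; (dim, 2) array."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        s = self.sd()
        return np.stack([self.mean - z * s, self.mean + z * s], axis=1)

    def copy(self) -> "GaussianBelief":
        return GaussianBelief(self.names, self.mean.copy(), self.cov.copy())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"names": list(self.names), "mean": self.mean.tolist(),
                       "cov": self.cov.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GaussianBelief":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["names"]), np.array(d["mean"]), np.array(d["cov"]))


@dataclass
class InversionResult:
    posterior: GaussianBelief
    free_energy: float
    trace: np.ndarray  # free energy per accepted iteration
    converged: bool
    n_iter: int
    residual_variance: np.ndarray  # per channel (or single entry if unshaped)
    noise_log_precision: float
    noise_log_precision_var: float
    prior: GaussianBelief | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "names": list(self.posterior.names),
                    "mean": self.posterior.mean.tolist(),
                    "free_energy": self.free_energy,
                    "trace": np.asarray(self.trace).tolist(),
                    "converged": bool(self.converged),
                    "n_iter": int(self.n_iter),
                    "residual_variance": np.asarray(self.residual_variance).tolist(),
                    "noise_log_precision": self.noise_log_precision,
                    "noise_log_precision_var": self.noise_log_precision_var,
                },
                fh, indent=1)


def default_priors(spec: NetworkSpec, free: Sequence[str] = DEFAULT_FREE,
                   variances: dict | None = None) -> GaussianBelief:
    """Zero-mean Gaussian priors over the free log-scaling parameters."""
    variances = {**PRIOR_VARIANCES, **(variances or {})}
    names = parameter_names(spec, free)
    var = []
    for nm in names:
        block = nm.split("[")[0] if "[" in nm else "lead"
        var.append(variances[block])
    return GaussianBelief(tuple(names), np.zeros(len(names)), np.diag(var))


def _symmetrize_psd(S: np.ndarray) -> np.ndarray:
    """Project to symmetric PSD with a relative eigenvalue floor."""
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    floor = max(w.max(), 1.0) * _PSD_FLOOR
    if w.min() < floor:
        logger.debug("posterior covariance eigenvalue floored at %.3g", floor)
        w = np.clip(w, floor, None)
        S = (V * w) @ V.T
        S = (S + S.T) / 2.0
    return S


def sensitivity(forward: Callable[[np.ndarray], np.ndarray], theta: np.ndarray,
                epsilon: float = 1e-3) -> np.ndarray:
    """Central finite-difference Jacobian of a batched forward map.

    ``forward`` maps (B, P) parameter vectors to (B, N) predictions; the
    Jacobian is returned as (N, P).  One batched call evaluates all 2P
    perturbed trajectories.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    theta = np.asarray(theta, dtype=float)
    P = theta.size
    steps = epsilon * np.eye(P)
    batch = np.vstack([theta + steps, theta - steps])
    Y = forward(batch)
    return ((Y[:P] - Y[P:]) / (2.0 * epsilon)).T


def _gaussian_kl(m_q, S_q, m_p, S_p_inv, logdet_Sp) -> float:
    d = m_q.size
    diff = m_q - m_p
    sign, logdet_Sq = np.linalg.slogdet(S_q)
    if sign <= 0:
        raise ValueError("posterior covariance not positive definite")
    return 0.5 * (np.trace(S_p_inv @ S_q) + diff @ S_p_inv @ diff - d
                  + logdet_Sp - logdet_Sq)


def free_energy(y: np.ndarray, belief: GaussianBelief, prior: GaussianBelief,
                forward: Callable[[np.ndarray], np.ndarray],
                log_precision: float, jacobian: np.ndarray | None = None) -> float:
    """Variational free energy of a belief: accuracy minus complexity.

    Accuracy is the expected Gaussian log-likelihood of the residuals under
    the belief, evaluated by local linearisation of the forward map at the
    belief mean (the trace term); complexity is KL(belief ‖ prior).
    """
    if belief.names != prior.names:
        raise ValueError("belief and prior must share parameter names")
    y = np.asarray(y, dtype=float).ravel()
    resid = y - forward(belief.mean[None, :])[0]
    J = jacobian if jacobian is not None else sensitivity(forward, belief.mean)
    N = y.size
    pi = np.exp(log_precision)
    trace_term = float(np.sum((J @ belief.cov) * J))
    accuracy = (-0.5 * pi * (resid @ resid + trace_term)
                + 0.5 * N * log_precision - 0.5 * N * np.log(2.0 * np.pi))
    P0 = prior.precision()
    sign, logdet_Sp = np.linalg.slogdet(prior.cov)
    if sign <= 0:
        raise ValueError("singular prior covariance")
    complexity = _gaussian_kl(belief.mean, belief.cov, prior.mean, P0, logdet_Sp)
    return float(accuracy - complexity)


def _update_noise(lam: float, S: float, N: int, lam0: float, v_lam: float,
                  n_newton: int = 8) -> tuple[float, float]:
    """Newton ascent on F in the noise log-precision; returns (mean, var)."""
    for _ in range(n_newton):
        grad = -0.5 * np.exp(lam) * S + 0.5 * N - (lam - lam0) / v_lam
        hess = -0.5 * np.exp(lam) * S - 1.0 / v_lam
        step = -grad / hess
        lam = lam + np.clip(step, -4.0, 4.0)
    return float(lam), float(-1.0 / hess)


def invert(y: np.ndarray, forward: Callable[[np.ndarray], np.ndarray],
           prior: GaussianBelief, *,
           noise_prior: tuple[float, float] = (4.0, 16.0),
           fix_noise: bool = False,
           max_iter: int = 128, tol: float = 0.01, tol_hits: int = 4,
           fd_eps: float = 1e-3, max_rejects: int = 6) -> InversionResult:
    """Fit a Gaussian posterior by regularised Gauss–Newton free-energy ascent.

    ``forward`` is a batched map (B, P) -> (B, N).  ``noise_prior`` is the
    Gaussian prior (mean, variance) on the noise log-precision λ; with
    ``fix_noise`` λ stays at its prior mean and contributes no complexity,
    in which case F is exactly the conjugate log evidence for linear maps.
    Convergence: free-energy gain below ``tol`` nats on ``tol_hits``
    successive accepted steps, or ``max_iter`` iterations.
    """
    y = np.asarray(y, dtype=float).ravel()
    N = y.size
    m0 = prior.mean
    P0 = prior.precision()
    sign, logdet_Sp = np.linalg.slogdet(prior.cov)
    if sign <= 0:
        raise ValueError("singular prior covariance")
    lam0, v_lam = noise_prior
    lam, lam_var = float(lam0), (0.0 if fix_noise else float(v_lam))

    def predict(th):
        out = forward(th[None, :])[0]
        return out

    def total_F(m, Sigma, resid, J, lam, lam_var) -> float:
        pi = np.exp(lam)
        trace_term = float(np.sum((J @ Sigma) * J))
        acc = (-0.5 * pi * (resid @ resid + trace_term)
               + 0.5 * N * lam - 0.5 * N * np.log(2.0 * np.pi))
        comp = _gaussian_kl(m, Sigma, m0, P0, logdet_Sp)
        if not fix_noise:
            comp += 0.5 * ((lam - lam0) ** 2 / v_lam - 1.0
                           + np.log(v_lam / lam_var))
        return float(acc - comp)

    m = m0.copy()
    try:
        resid = y - predict(m)
    except FloatingPointError as err:
        raise ValueError(
            "forward model failed at the prior mean; inspect priors and "
            "parameter scales") from err
    if not np.all(np.isfinite(resid)):
        raise ValueError(
            "non-finite prediction at the prior mean; inspect priors and "
            "parameter scales")

    J = sensitivity(forward, m, fd_eps)
    if not fix_noise:
        S0 = float(resid @ resid) + 0.0
        lam, lam_var = _update_noise(lam, S0, N, lam0, v_lam)
    H = np.exp(lam) * (J.T @ J) + P0
    Sigma = _symmetrize_psd(np.linalg.inv(H))
    F = total_F(m, Sigma, resid, J, lam, lam_var)
    if not np.isfinite(F):
        raise ValueError(
            "free energy non-finite at the prior mean; inspect priors and "
            "the scale of data and noise")
    trace = [F]
    if max_iter == 0:
        prior_post = GaussianBelief(prior.names, m0.copy(), prior.cov.copy())
        F0 = total_F(m0, prior.cov, resid, J, lam, lam_var)
        rv = _residual_variance(resid)
        return InversionResult(prior_post, F0, np.array([F0]), False, 0, rv,
                               lam, lam_var, prior=prior)

    nu = 0.0  # LM regulariser; 0 = pure Gauss-Newton trial step
    small_gain = 0
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        accepted = False
        for _ in range(max_rejects):
            pi = np.exp(lam)
            H = pi * (J.T @ J) + P0
            reg = H + nu * np.diag(np.diag(H))
            grad = pi * (J.T @ resid) - P0 @ (m - m0)
            try:
                dm = np.linalg.solve(reg, grad)
            except np.linalg.LinAlgError:
                nu = max(4.0 * (nu + 1e-8), 1e-4)
                continue
            m_new = m + dm
            try:
                resid_new = y - predict(m_new)
            except FloatingPointError:
                nu = max(8.0 * (nu + 1e-8), 1e-3)
                continue
            if not np.all(np.isfinite(resid_new)):
                nu = max(8.0 * (nu + 1e-8), 1e-3)
                continue
            J_new = sensitivity(forward, m_new, fd_eps)
            lam_new, lam_var_new = (lam, lam_var)
            H_new = np.exp(lam_new) * (J_new.T @ J_new) + P0
            Sigma_new = _symmetrize_psd(np.linalg.inv(H_new))
            if not fix_noise:
                S = float(resid_new @ resid_new) + float(
                    np.sum((J_new @ Sigma_new) * J_new))
                lam_new, lam_var_new = _update_noise(lam, S, N, lam0, v_lam)
                H_new = np.exp(lam_new) * (J_new.T @ J_new) + P0
                Sigma_new = _symmetrize_psd(np.linalg.inv(H_new))
            F_new = total_F(m_new, Sigma_new, resid_new, J_new, lam_new,
                            lam_var_new)
            if np.isfinite(F_new) and F_new >= F - 1e-9:
                # ties (|dF| below numerical tolerance) are accepted and
                # count toward convergence
                dF = F_new - F
                m, resid, J, lam, lam_var, F = (m_new, resid_new, J_new,
                                                lam_new, lam_var_new, F_new)
                trace.append(F)
                nu = nu / 2.0 if nu > 1e-8 else 0.0
                accepted = True
                small_gain = small_gain + 1 if dF < tol else 0
                break
            nu = max(8.0 * (nu + 1e-8), 1e-3)
        if not accepted:
            logger.debug("no acceptable step at iteration %d; stopping", it)
            break
        if small_gain >= tol_hits:
            converged = True
            break

    H = np.exp(lam) * (J.T @ J) + P0
    Sigma = _symmetrize_psd(np.linalg.inv(H))
    posterior = GaussianBelief(prior.names, m, Sigma)
    rv = _residual_variance(resid)
    return InversionResult(posterior, F, np.array(trace), converged, it, rv,
                           lam, lam_var, prior=prior)


def _residual_variance(resid: np.ndarray) -> np.ndarray:
    return np.atleast_1d(float(np.mean(resid**2)))


def invert_erp(data: SensorData, spec: NetworkSpec, base: ModelParameters,
               prior: GaussianBelief | None = None,
               free: Sequence[str] = DEFAULT_FREE,
               substeps: int = 2, **options) -> InversionResult:
    """Invert the CMC forward model given sensor-level evoked responses.

    ``base`` supplies everything held fixed (lead field, input timing);
    ``prior`` defaults to the standard zero-mean log-scaling priors.  The
    data grid must match the model's sampling grid exactly.
    """
    if data.n_channels != base.lead_gain.shape[0]:
        raise ValueError("data channel count does not match lead field")
    if tuple(data.design) != tuple(spec.design):
        spec = spec.with_design(data.design, data.condition_labels)
    prior = prior or default_priors(spec, free)
    grid = data.grid

    def forward(thetas: np.ndarray) -> np.ndarray:
        return predict_sensor_batch(spec, base, thetas, free, grid,
                                    substeps=substeps)

    res = invert(data.ravel(), forward, prior, **options)
    # per-channel residual variance
    pred = forward(res.posterior.mean[None, :])[0].reshape(data.data.shape)
    res.residual_variance = np.mean((data.data - pred) ** 2, axis=(0, 2))
    return res
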