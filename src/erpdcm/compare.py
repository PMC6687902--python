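"""Bayesian model reduction, model posteriors, and model averaging.

Reduced models differ from the full model only in their priors (here:
condition-specific modulation effects switched off by a near-delta prior at
zero).  Their evidence and posteriors follow analytically from the full
model's prior and posterior, so one inversion scores the whole model space.

For Gaussian beliefs the change in log evidence of swapping prior
(m0, Σ0) for a reduced prior (m̃0, Σ̃0), given posterior (m, Σ), is

    ΔF = ½[ln|P| + ln|P̃0| − ln|P0| − ln|P̃|]
       + ½[m̃ᵀP̃m̃ − mᵀPm − m̃0ᵀP̃0m̃0 + m0ᵀP0m0]

with precisions P = Σ⁻¹ etc., reduced posterior precision
P̃ = P + P̃0 − P0 and mean m̃ = P̃⁻¹(Pm + P̃0m̃0 − P0m0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .laplace import GaussianBelief, _symmetrize_psd

__all__ = [
    "ModelSpace",
    "ComparisonResult",
    "enumerate_reduced_models",
    "reduce",
    "model_posterior",
    "bma",
    "parametric_design",
    "coupling_trajectory",
    "reduced_prior_for_pattern",
    "compare_modulations",
    "SWITCHED_OFF_VARIANCE",
]

#: prior variance representing an effect switched off a priori (a numerically
#: stable stand-in for the zero-variance limit)
SWITCHED_OFF_VARIANCE = 1e-8

MAX_EFFECTS = 20


@dataclass(frozen=True)
class ModelSpace:
    """Exhaustive keep/remove model space over switchable effects.

    Patterns are ordered by binary counting with effect 1 as the least
    significant bit: index 0 removes every effect, the last index keeps all
    (the full model).
    """

    effects: tuple[str, ...]
    patterns: tuple[tuple[int, ...], ...]

    @property
    def n_models(self) -> int:
        return len(self.patterns)

    @property
    def full_model_index(self) -> int:
        return self.n_models - 1

    def describe(self, i: int) -> str:
        kept = [e for e, k in zip(self.effects, self.patterns[i]) if k]
        return "+".join(kept) if kept else "(none)"


def enumerate_reduced_models(effects: Sequence[str]) -> ModelSpace:
    """All 2^k keep/remove combinations of k switchable effects."""
    k = len(effects)
    if not 1 <= k <= MAX_EFFECTS:
        raise ValueError(f"number of effects must be in 1..{MAX_EFFECTS}, got {k}")
    patterns = tuple(
        tuple((i >> bit) & 1 for bit in range(k)) for i in range(2**k)
    )
    return ModelSpace(effects=tuple(effects), patterns=patterns)


def reduce(full_posterior: GaussianBelief, full_prior: GaussianBelief,
           reduced_prior: GaussianBelief) -> tuple[float, GaussianBelief]:
    """Analytic evidence change and posterior under a swapped (reduced) prior."""
    if not (full_posterior.names == full_prior.names == reduced_prior.names):
        raise ValueError("beliefs must share parameter names")
    if (np.array_equal(reduced_prior.mean, full_prior.mean)
            and np.array_equal(reduced_prior.cov, full_prior.cov)):
        # identity reduction: evidence change is exactly zero
        return 0.0, full_posterior.copy()
    Pq = full_posterior.precision()
    P0 = full_prior.precision()
    Pr0 = reduced_prior.precision()
    Pr = Pq + Pr0 - P0
    w = np.linalg.eigvalsh((Pr + Pr.T) / 2.0)
    if w.min() <= 0:
        raise ValueError(
            "reduced posterior precision is not positive definite for this "
            "model; the reduction is ill-posed")
    m, m0, r0 = full_posterior.mean, full_prior.mean, reduced_prior.mean
    mr = np.linalg.solve(Pr, Pq @ m + Pr0 @ r0 - P0 @ m0)
    logdets = [np.linalg.slogdet(A) for A in (Pq, Pr0, P0, Pr)]
    if any(s <= 0 for s, _ in logdets):
        raise ValueError("non-positive-definite precision in reduction")
    (_, ld_q), (_, ld_r0), (_, ld_p0), (_, ld_r) = logdets
    dF = 0.5 * (ld_q + ld_r0 - ld_p0 - ld_r) + 0.5 * (
        mr @ Pr @ mr - m @ Pq @ m - r0 @ Pr0 @ r0 + m0 @ P0 @ m0)
    Sr = _symmetrize_psd(np.linalg.inv(Pr))
    return float(dF), GaussianBelief(full_posterior.names, mr, Sr)


def model_posterior(free_energies: Sequence[float],
                    prior_model_probs: Sequence[float] | None = None) -> np.ndarray:
    """Posterior model probabilities: overflow-safe softmax of free energies."""
    F = np.asarray(free_energies, dtype=float)
    if F.size == 0:
        raise ValueError("need at least one model")
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    logp = F.copy()
    if prior_model_probs is not None:
        logp = logp + np.log(np.asarray(prior_model_probs, dtype=float))
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def bma(posteriors: Sequence[GaussianBelief], probs: Sequence[float]) -> GaussianBelief:
    """Moment-matched Gaussian of the model-averaged posterior mixture."""
    probs = np.asarray(probs, dtype=float)
    if len(posteriors) != probs.size:
        raise ValueError("posteriors and probabilities must align")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a probability vector")
    names = posteriors[0].names
    mean = sum(p * q.mean for p, q in zip(probs, posteriors))
    second = sum(p * (q.cov + np.outer(q.mean, q.mean))
                 for p, q in zip(probs, posteriors))
    cov = second - np.outer(mean, mean)
    return GaussianBelief(names, mean, _symmetrize_psd(cov))


def parametric_design(n_events: int) -> np.ndarray:
    """Linear per-event covariates [0, 1, ..., n_events-1] (first event = baseline)."""
    if n_events < 2:
        raise ValueError("a parametric design needs at least 2 events")
    return np.arange(n_events, dtype=float)


def coupling_trajectory(b_effect: float, event_index) -> np.ndarray:
    """Connection strength at event k as percent of its initial value.

    A linear parametric effect on a log-scaling parameter is a
    monoexponential change in coupling: 100·exp(k·b), starting from
    exp(0) = 100% at the first event.
    """
    k = np.asarray(event_index, dtype=float)
    if np.any(k < 0):
        raise ValueError("event index must be non-negative")
    return 100.0 * np.exp(k * b_effect)


def reduced_prior_for_pattern(prior: GaussianBelief, effect_names: Sequence[str],
                              pattern: Sequence[int]) -> GaussianBelief:
    """Full prior with removed effects pinned at zero (variance 1e-8)."""
    rp = prior.copy()
    for name, keep in zip(effect_names, pattern):
        if not keep:
            i = rp.index(name)
            rp.mean[i] = 0.0
            rp.cov[i, :] = 0.0
            rp.cov[:, i] = 0.0
            rp.cov[i, i] = SWITCHED_OFF_VARIANCE
    return rp


@dataclass
class ComparisonResult:
    """Scores and averages over an exhaustive reduced-model space."""

    space: ModelSpace
    delta_F: np.ndarray               # per model, relative to the full model
    probabilities: np.ndarray
    reduced_posteriors: list[GaussianBelief]
    bma_posterior: GaussianBelief
    effect_names: tuple[str, ...]

    @property
    def winner(self) -> int:
        return int(np.argmax(self.probabilities))

    @property
    def winning_pattern(self) -> tuple[int, ...]:
        return self.space.patterns[self.winner]

    def table(self) -> pd.DataFrame:
        rows = []
        for i, pat in enumerate(self.space.patterns):
            rows.append({
                "model": i + 1,
                "kept_effects": self.space.describe(i),
                "delta_F": self.delta_F[i],
                "probability": self.probabilities[i],
            })
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "effects": list(self.space.effects),
                "patterns": [list(p) for p in self.space.patterns],
                "delta_F": self.delta_F.tolist(),
                "probabilities": self.probabilities.tolist(),
                "winner": self.winner,
                "bma_mean": self.bma_posterior.mean.tolist(),
                "bma_cov": self.bma_posterior.cov.tolist(),
                "names": list(self.bma_posterior.names),
            }, fh, indent=1)

    def plot(self, ax=None):
        """Bar chart of posterior model probabilities (optional extra)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(np.arange(1, self.space.n_models + 1), self.probabilities)
        ax.set_xlabel("model")
        ax.set_ylabel("posterior probability")
        return ax


def compare_modulations(full_posterior: GaussianBelief, full_prior: GaussianBelief,
                        effect_names: Sequence[str],
                        prior_model_probs: Sequence[float] | None = None) -> ComparisonResult:
    """Score every keep/remove combination of the named effects by BMR.

    Returns per-model evidence changes (relative to the full model), the
    posterior over models (uniform model prior unless given) and the Bayesian
    model average over all reduced posteriors.
    """
    space = enumerate_reduced_models(effect_names)
    dFs = np.empty(space.n_models)
    posts: list[GaussianBelief] = []
    for i, pat in enumerate(space.patterns):
        rp = reduced_prior_for_pattern(full_prior, effect_names, pat)
        dF, post = reduce(full_posterior, full_prior, rp)
        dFs[i] = dF
        posts.append(post)
    probs = model_posterior(dFs, prior_model_probs)
    avg = bma(posts, probs)
    return ComparisonResult(space=space, delta_F=dFs, probabilities=probs,
                            reduced_posteriors=posts, bma_posterior=avg,
                            effect_names=tuple(effect_names))
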