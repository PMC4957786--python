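"""The uncertainty-relevance model of social preference shift (PS model).

An agent is uncertain about its own taste-for-patience ``k_s`` and summarises
its evidence as a Gaussian likelihood ``N(k_s; m_s, u_s)``.  It assumes that
its own taste and the taste ``k_o`` of an observed Other are both drawn, with
independent Gaussian noise of variance ``sigma_r**2``, from a latent reference
population mean ``k_r`` that carries a flat prior and is integrated out.
Under these assumptions the Other's choices bear on the agent's own taste:
the posterior over ``k_s`` is the product of the self-likelihood with the
other-likelihood widened by ``2 * sigma_r**2``,

    p(k_s | d_s, d_o)  ∝  N(k_s; m_s, u_s) * N(k_s; k_o_hat, 2*sigma_r**2 + u_o_hat)

and symmetrically for the belief about the Other.  Small ``sigma_r`` means the
Other is highly relevant (strong shift); ``sigma_r -> inf`` decouples the two.

The other-likelihood ``N(k_o_hat, u_o_hat)`` is obtained by *filtering*: at
trial ``t`` it summarises the Other's observed choices ``1..t-1``, evaluated on
a grid over ``k`` under a unit-temperature softmax generative model and
moment-matched to a Gaussian.

The full behavioural model has five parameters (``PSParams``): the
self-likelihood mode ``m_s`` and variance ``u_s``, the reference dispersion
``sigma_r``, a relaxation temperature ``tau_o`` applied to unincentivised
choices made on behalf of the Other, and a lapse rate ``xi`` on self-choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import logsumexp

from .data import ROLE_OTHER, ROLE_SELF, ParticipantDataset
from .models import (
    OptionPair,
    apply_lapse,
    bernoulli_loglik,
    kt_policy_arrays,
    ku_policy_arrays,
    relax_policy_arrays,
)

__all__ = [
    "K_GRID",
    "GaussianBelief",
    "PSParams",
    "posterior_self",
    "posterior_other",
    "OtherBeliefFilter",
    "other_likelihood_filter",
    "ps_trial_policy",
    "ps_trial_probabilities",
    "ps_loglik",
]

#: Default grid over k = ln(K) used wherever a distribution over tastes is
#: represented numerically: 601 nodes spanning [-12, 2].
K_GRID = (-12.0, 2.0, 601)

# Variance floor used when inverting fitted variances; keeps the u_s -> 0
# limit well defined without special-casing step policies during fitting.
_VAR_FLOOR = 1e-12


def k_grid_nodes(grid: tuple[float, float, int] = K_GRID) -> np.ndarray:
    lo, hi, n = grid
    if not (hi > lo and int(n) >= 3):
        raise ValueError(f"degenerate k grid {grid}")
    return np.linspace(lo, hi, int(n))


@dataclass(frozen=True)
class GaussianBelief:
    """Gaussian belief over ``k``; ``var = inf`` encodes the flat belief."""

    mean: float
    var: float

    def __post_init__(self) -> None:
        if not (self.var >= 0):
            raise ValueError(f"belief variance must be >= 0, got {self.var}")

    @property
    def precision(self) -> float:
        if math.isinf(self.var):
            return 0.0
        return 1.0 / max(self.var, _VAR_FLOOR)

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.var)

    @classmethod
    def flat(cls) -> "GaussianBelief":
        return cls(0.0, math.inf)


@dataclass(frozen=True)
class PSParams:
    """The five parameters of the preference-shift model."""

    m_s: float
    u_s: float
    sigma_r: float
    tau_o: float
    xi: float

    def __post_init__(self) -> None:
        if not (self.u_s >= 0):
            raise ValueError("u_s must be >= 0")
        if not (self.sigma_r > 0):
            raise ValueError("sigma_r must be > 0")
        if not (self.tau_o > 0):
            raise ValueError("tau_o must be > 0")
        if not (0 <= self.xi <= 1):
            raise ValueError("xi must lie in [0, 1]")

    @property
    def self_belief(self) -> GaussianBelief:
        return GaussianBelief(self.m_s, self.u_s)


def _combine(primary: GaussianBelief, secondary: GaussianBelief, sigma_r: float) -> GaussianBelief:
    """Precision-weighted product of ``primary``'s own likelihood with
    ``secondary``'s likelihood widened by ``2 * sigma_r**2``."""
    if not (sigma_r > 0):
        raise ValueError("sigma_r must be > 0")
    if primary.var == 0.0:
        return GaussianBelief(primary.mean, 0.0)
    widened = 2.0 * sigma_r**2 + secondary.var  # inf-safe
    prec_p = primary.precision
    prec_s = 0.0 if math.isinf(widened) else 1.0 / widened
    total = prec_p + prec_s
    if total <= 0.0:
        raise ValueError("posterior improper: both belief components are flat")
    mean = (prec_p * primary.mean + prec_s * secondary.mean) / total
    return GaussianBelief(mean, 1.0 / total)


def posterior_self(
    self_b: GaussianBelief, other_b: GaussianBelief, sigma_r: float
) -> GaussianBelief:
    """Posterior belief about one's own taste after observing the Other.

    The mean lies strictly between the two likelihood modes whenever they
    differ (the shift never overtakes the Other) and the variance never
    exceeds the self-likelihood variance.
    """
    return _combine(self_b, other_b, sigma_r)


def posterior_other(
    self_b: GaussianBelief, other_b: GaussianBelief, sigma_r: float
) -> GaussianBelief:
    """Posterior belief about the Other's taste; the mirror image of
    :func:`posterior_self`.  With no data about the Other yet this reduces to
    the self-likelihood widened by ``2 * sigma_r**2``."""
    return _combine(other_b, self_b, sigma_r)


class OtherBeliefFilter:
    """Running grid likelihood over the Other's taste ``k_o``.

    Each observed Other choice multiplies in a unit-temperature softmax
    Bernoulli likelihood term evaluated on the ``k`` grid; the current belief
    is the moment-matched Gaussian of the normalised product.  With zero
    observations the belief is flat.  The finite grid acts as a uniform prior
    over its span, which keeps the moment match proper even when all observed
    choices are one-sided.
    """

    def __init__(
        self,
        grid: tuple[float, float, int] = K_GRID,
        assumed_T: float = 1.0,
    ) -> None:
        if not (assumed_T > 0):
            raise ValueError("assumed_T must be > 0")
        self.nodes = k_grid_nodes(grid)
        self.assumed_T = assumed_T
        self._cum_loglik = np.zeros_like(self.nodes)
        self._n_obs = 0

    def update(self, pair: OptionPair, other_choice: int) -> None:
        pi = kt_policy_arrays(pair.R0, pair.RD, pair.D, self.nodes, self.assumed_T)
        pi = np.clip(pi, 1e-300, 1.0 - 1e-16)
        self._cum_loglik += np.log(pi) if other_choice == 1 else np.log1p(-pi)
        self._n_obs += 1

    def belief(self) -> GaussianBelief:
        if self._n_obs == 0:
            return GaussianBelief.flat()
        w = np.exp(self._cum_loglik - logsumexp(self._cum_loglik))
        w /= w.sum()
        mean = float(w @ self.nodes)
        var = float(w @ (self.nodes - mean) ** 2)
        return GaussianBelief(mean, max(var, _VAR_FLOOR))

    @property
    def n_obs(self) -> int:
        return self._n_obs


def other_likelihood_filter(
    observed_other_choices: Iterable[tuple[OptionPair, int]],
    assumed_T: float = 1.0,
    grid: tuple[float, float, int] = K_GRID,
) -> GaussianBelief:
    """Gaussian summary of the Other's taste from their observed choices."""
    f = OtherBeliefFilter(grid=grid, assumed_T=assumed_T)
    for pair, choice in observed_other_choices:
        f.update(pair, choice)
    return f.belief()


def ps_trial_policy(
    trial: OptionPair,
    role: str,
    params: PSParams,
    other_b: GaussianBelief,
) -> float:
    """Choice probability for one trial under the preference-shift model.

    ``role='self'``: random-preference policy under the posterior self-belief,
    followed by the lapse mixture.  ``role='other'``: random-preference policy
    under the posterior other-belief, relaxed by ``tau_o``.
    ``other_b`` must be the filtered belief from Other choices observed
    *before* this trial (flat during phase 1).
    """
    theta = trial.indifference_k
    if role == ROLE_SELF:
        post = posterior_self(params.self_belief, other_b, params.sigma_r)
        pi = float(ku_policy_arrays(theta, post.mean, post.var))
        return float(apply_lapse(pi, params.xi))
    if role == ROLE_OTHER:
        post = posterior_other(params.self_belief, other_b, params.sigma_r)
        pi = float(ku_policy_arrays(theta, post.mean, post.var))
        return float(relax_policy_arrays(pi, params.tau_o))
    raise ValueError(f"role must be 'self' or 'other', got {role!r}")


# ---------------------------------------------------------------------------
# Whole-dataset likelihood
# ---------------------------------------------------------------------------

class _PSDesign:
    """Parameter-independent per-dataset arrays for the PS likelihood.

    The filtered other-belief sequence depends only on the Other's observed
    choices (through veridical feedback) and the assumed unit-temperature
    generative model, never on the fitted parameters, so it is computed once
    per dataset and cached.
    """

    __slots__ = (
        "theta_self", "choice_self", "obel_mean_self", "obel_var_self",
        "theta_other", "choice_other", "obel_mean_other", "obel_var_other",
        "n_trials",
    )

    def __init__(self, data: ParticipantDataset, grid, assumed_T: float) -> None:
        if not data.trials:
            raise ValueError("empty dataset")
        filt = OtherBeliefFilter(grid=grid, assumed_T=assumed_T)
        rows_s: list[tuple[float, int, float, float]] = []
        rows_o: list[tuple[float, int, float, float]] = []
        for t in data.trials:
            b = filt.belief()
            if t.role == ROLE_SELF:
                rows_s.append((t.pair.indifference_k, t.choice, b.mean, b.var))
            else:
                if t.phase == 2 and (t.other_choice is None or t.feedback is None):
                    raise ValueError(
                        f"{data.participant_id}: phase-2 trial {t.index} lacks "
                        "feedback/other_choice; cannot filter the other-belief"
                    )
                rows_o.append((t.pair.indifference_k, t.choice, b.mean, b.var))
                if t.other_choice is not None:
                    filt.update(t.pair, t.other_choice)
        def cols(rows):
            if not rows:
                return (np.empty(0),) * 4
            a = np.array(rows, dtype=float)
            return a[:, 0], a[:, 1], a[:, 2], a[:, 3]
        self.theta_self, self.choice_self, self.obel_mean_self, self.obel_var_self = cols(rows_s)
        self.theta_other, self.choice_other, self.obel_mean_other, self.obel_var_other = cols(rows_o)
        self.n_trials = len(rows_s) + len(rows_o)


_DESIGN_ATTR = "_ps_design_cache"


def ps_design(
    data: ParticipantDataset,
    grid: tuple[float, float, int] = K_GRID,
    assumed_T: float = 1.0,
) -> _PSDesign:
    key = (grid, assumed_T)
    cache = getattr(data, _DESIGN_ATTR, None)
    if cache is None:
        cache = {}
        object.__setattr__(data, _DESIGN_ATTR, cache) if hasattr(data, "__slots__") else setattr(data, _DESIGN_ATTR, cache)
    if key not in cache:
        cache[key] = _PSDesign(data, grid, assumed_T)
    return cache[key]


def ps_trial_probabilities(
    params: PSParams,
    data: ParticipantDataset,
    grid: tuple[float, float, int] = K_GRID,
    assumed_T: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial choice probabilities under the PS model.

    Returns ``(pi_self, choices_self, pi_other, choices_other)`` in dataset
    order within each role.
    """
    d = ps_design(data, grid, assumed_T)
    u_s = max(params.u_s, _VAR_FLOOR)
    two_sr2 = 2.0 * params.sigma_r**2

    with np.errstate(divide="ignore", invalid="ignore"):
        # self trials: posterior over own taste
        prec_s = 1.0 / u_s
        prec_rel = 1.0 / (two_sr2 + d.obel_var_self)  # 0 where belief flat
        prec_rel = np.where(np.isfinite(prec_rel), prec_rel, 0.0)
        post_var = 1.0 / (prec_s + prec_rel)
        post_mean = (prec_s * params.m_s + prec_rel * d.obel_mean_self) / (prec_s + prec_rel)
        pi_self = ku_policy_arrays(d.theta_self, post_mean, post_var)
        pi_self = apply_lapse(pi_self, params.xi)

        # other trials: posterior over the Other's taste
        prec_o = 1.0 / d.obel_var_other
        prec_o = np.where(np.isfinite(prec_o), prec_o, 0.0)
        prec_rel2 = 1.0 / (two_sr2 + u_s)
        if not np.isfinite(prec_rel2):
            prec_rel2 = 0.0
        tot = prec_o + prec_rel2
        post_var_o = np.where(tot > 0, 1.0 / np.where(tot > 0, tot, 1.0), np.inf)
        post_mean_o = np.where(
            tot > 0,
            (prec_o * d.obel_mean_other + prec_rel2 * params.m_s) / np.where(tot > 0, tot, 1.0),
            0.0,
        )
        pi_other = ku_policy_arrays(d.theta_other, post_mean_o, post_var_o)
        pi_other = relax_policy_arrays(pi_other, params.tau_o)

    return pi_self, d.choice_self, pi_other, d.choice_other


def ps_loglik(
    params: PSParams,
    data: ParticipantDataset,
    grid: tuple[float, float, int] = K_GRID,
    assumed_T: float = 1.0,
) -> float:
    """Log-likelihood of all self- and other-choices in a dataset under the
    five-parameter preference-shift model."""
    pi_s, c_s, pi_o, c_o = ps_trial_probabilities(params, data, grid, assumed_T)
    ll = 0.0
    if pi_s.size:
        ll += bernoulli_loglik(pi_s, c_s)
    if pi_o.size:
        ll += bernoulli_loglik(pi_o, c_o)
    if pi_s.size == 0 and pi_o.size == 0:
        raise ValueError("empty dataset")
    return ll
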