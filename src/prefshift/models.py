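"""Choice models for hyperbolic temporal discounting.

An intertemporal choice problem offers an immediate reward ``R0`` against a
larger-but-later reward ``RD`` delivered after ``D`` days.  Under hyperbolic
discounting the delayed option is worth ``RD / (1 + K * D)`` where ``K`` is the
discount rate; we work throughout with ``k = ln K``.

Two accounts of choice variability are implemented:

* **KT (preference-temperature)** — deterministic hyperbolic valuation plus
  softmax ("trembling hand") response noise with temperature ``T``.  Noise is
  independent of the taste parameter.
* **KU (preference-uncertainty / random preference)** — the agent samples its
  taste ``k`` from ``N(m, u)`` on every trial and then chooses
  deterministically; choice variability *is* taste uncertainty.  The resulting
  policy is a probit in the option pair's indifference point
  ``theta = ln[(RD/R0 - 1) / D]``, i.e. a Fechnerian comparison of log
  attribute to criterion.

Two auxiliary response transforms used by the social preference-shift model
also live here: a power relaxation with temperature ``tau_o`` applied to
unincentivised choices made on behalf of another person, and a symmetric
lapse mixture with rate ``xi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "PI_CLIP",
    "OptionPair",
    "KTParams",
    "KUParams",
    "discounted_value",
    "kt_policy",
    "kt_policy_arrays",
    "ku_policy",
    "ku_policy_arrays",
    "relax_policy",
    "relax_policy_arrays",
    "apply_lapse",
    "bernoulli_loglik",
    "dataset_loglik",
]

#: Policy probabilities are clipped to ``[PI_CLIP, 1 - PI_CLIP]`` inside
#: log-likelihoods so that a single deterministic miss cannot produce ``-inf``.
PI_CLIP = 1e-12


@dataclass(frozen=True)
class OptionPair:
    """One intertemporal choice problem.

    Parameters
    ----------
    R0 : float
        Immediate reward, in currency units; must be positive.
    RD : float
        Delayed reward, in the same units.
    D : float
        Delay of the late option, in days; must be positive.
    """

    R0: float
    RD: float
    D: float

    def __post_init__(self) -> None:
        if not (self.R0 > 0):
            raise ValueError(f"R0 must be positive, got {self.R0}")
        if not (self.D > 0):
            raise ValueError(f"D must be positive, got {self.D}")
        if not np.isfinite([self.R0, self.RD, self.D]).all():
            raise ValueError("OptionPair fields must be finite")

    @property
    def indifference_k(self) -> float:
        """``ln[(RD/R0 - 1) / D]`` — the value of ``k`` at which a
        deterministic hyperbolic discounter is indifferent.  Defined only for
        genuine larger-later offers (``RD > R0``)."""
        if self.RD <= self.R0:
            raise ValueError(
                f"indifference point undefined: RD={self.RD} <= R0={self.R0}"
            )
        return math.log((self.RD / self.R0 - 1.0) / self.D)


@dataclass(frozen=True)
class KTParams:
    """Softmax model parameters: log discount rate ``k`` and temperature ``T > 0``."""

    k: float
    T: float

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError(f"softmax temperature must be positive, got {self.T}")


@dataclass(frozen=True)
class KUParams:
    """Random-preference parameters: belief mean ``m`` and variance ``u >= 0`` over ``k``."""

    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.u >= 0):
            raise ValueError(f"taste-uncertainty variance must be >= 0, got {self.u}")


def discounted_value(RD, D, K):
    """Hyperbolic present value ``RD / (1 + K * D)``.

    Accepts scalars or broadcastable arrays.  ``D`` and ``K`` must be
    non-negative.
    """
    RD = np.asarray(RD, dtype=float)
    D = np.asarray(D, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(D < 0):
        raise ValueError("delay D must be non-negative")
    if np.any(K < 0):
        raise ValueError("discount rate K must be non-negative")
    out = RD / (1.0 + K * D)
    return float(out) if out.ndim == 0 else out


def kt_policy_arrays(R0, RD, D, k, T):
    """Vectorised softmax probability of the delayed option.

    ``pi_D = 1 / (1 + exp((Q0 - QD) / T))`` with ``Q0 = R0`` and
    ``QD = RD / (1 + e^k * D)``.
    """
    QD = np.asarray(RD, float) / (1.0 + np.exp(np.asarray(k, float)) * np.asarray(D, float))
    return expit((QD - np.asarray(R0, float)) / np.asarray(T, float))

def kt_policy(opt: OptionPair, p: KTParams) -> float:
    """Probability of choosing the delayed option under the KT model."""
    return float(kt_policy_arrays(opt.R0, opt.RD, opt.D, p.k, p.T))


def ku_policy_arrays(theta, m, u):
    """Vectorised random-preference probability of the delayed option.

    ``pi_D = Phi((theta - m) / sqrt(u))``; the ``u = 0`` limit is the step
    function of a deterministic discounter (0.5 at exact indifference).
    """
    theta = np.asarray(theta, float)
    m = np.asarray(m, float)
    u = np.asarray(u, float)
    diff = theta - m
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / np.sqrt(u)
    out = ndtr(z)
    # u == 0: deterministic threshold rule
    step = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    out = np.where(u == 0, step, out)
    return out

def ku_policy(opt: OptionPair, p: KUParams) -> float:
    """Probability of choosing the delayed option under the KU model.

    Requires ``RD > R0`` (otherwise the indifference point is undefined and
    the trial is rejected)."""
    return float(ku_policy_arrays(opt.indifference_k, p.m, p.u))


def relax_policy_arrays(piD, tau_o):
    """Power relaxation ``p^(1/tau) / (p^(1/tau) + (1-p)^(1/tau))``."""
    tau_o = np.asarray(tau_o, float)
    if np.any(tau_o <= 0):
        raise ValueError("tau_o must be positive")
    p = np.asarray(piD, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("piD must lie in [0, 1]")
    # work in logs for stability; 0 and 1 are fixed points
    with np.errstate(divide="ignore"):
        a = np.log(p) / tau_o
        b = np.log1p(-p) / tau_o
    out = expit(a - b)
    out = np.where(p == 0.0, 0.0, np.where(p == 1.0, 1.0, out))
    return out

def relax_policy(piD: float, tau_o: float) -> float:
    """Relax a choice probability toward 0.5 (``tau_o > 1``) or sharpen it
    (``tau_o < 1``); ``tau_o = 1`` is the identity and 0, 0.5, 1 are fixed
    points."""
    return float(relax_policy_arrays(piD, tau_o))


def apply_lapse(piD, xi):
    """Lapse mixture ``pi * (1 - xi) + xi / 2``; result lies in ``[xi/2, 1 - xi/2]``."""
    xi = np.asarray(xi, float)
    if np.any((xi < 0) | (xi > 1)):
        raise ValueError("lapse rate xi must lie in [0, 1]")
    p = np.asarray(piD, float)
    out = p * (1.0 - xi) + xi / 2.0
    return float(out) if out.ndim == 0 else out


def bernoulli_loglik(piD, choices) -> float:
    """Sum of Bernoulli log-likelihoods, choices coded 1 = delayed, 0 = immediate.

    Probabilities are clipped to ``[PI_CLIP, 1 - PI_CLIP]``.
    """
    p = np.clip(np.asarray(piD, float), PI_CLIP, 1.0 - PI_CLIP)
    c = np.asarray(choices, float)
    if p.size == 0:
        raise ValueError("empty trial list")
    if not np.all((c == 0) | (c == 1)):
        raise ValueError("choices must be coded 0/1")
    return float(np.sum(c * np.log(p) + (1.0 - c) * np.log1p(-p)))


def dataset_loglik(
    trials: Iterable[tuple[OptionPair, int]],
    policy: Callable[[OptionPair], float],
) -> float:
    """Log-likelihood of a sequence of ``(OptionPair, choice)`` records under a
    per-trial policy function mapping an option pair to ``pi_D``."""
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial list")
    pis = [policy(opt) for opt, _ in trials]
    choices = [c for _, c in trials]
    return bernoulli_loglik(pis, choices)
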