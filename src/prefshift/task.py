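"""Simulator of the three-phase delegated interpersonal discounting task.

The simulator is the package's stand-in for raw behavioural data.  It
reproduces the task protocol:

* **Phase 1** — 60 self-choices: 30 pairs from a standard set whose
  indifference points tile a wide range of ``k``, interleaved with 30 pairs
  chosen adaptively to minimise the expected entropy of a grid posterior over
  the participant's discount rate (maintained under a unit-temperature
  softmax observation model).
* **Other selection** — the phase-1 posterior mode ``k_b`` determines the
  partner's taste: ``k_o = k_b ± 2.3`` (one population SD), shifted toward
  the population mean −4.5 with probability 2/3 and away with 1/3.
* **Phase 2** — the participant guesses the Other's choices and receives
  veridical feedback (the Other's actual choice is simulated with a
  unit-temperature softmax at ``k_o``); trials continue until 8 of the last
  10 guesses are correct or 60 trials elapse.
* **Phase 3** — interleaved mini-blocks of 10 self-choices and 10
  other-choices (with feedback), 3 blocks per role by default.

Synthetic agents behave according to the preference-shift model
(:mod:`prefshift.social`); a pure random-preference (KU) agent is the special
case ``sigma_r = inf, tau_o = 1`` whose self-choices are unaffected by the
Other.  The default population has ``ln K ~ N(-4.5, 2.3**2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .data import ROLE_OTHER, ROLE_SELF, ParticipantDataset, Trial
from .models import KTParams, KUParams, OptionPair, apply_lapse, kt_policy_arrays, ku_policy_arrays
from .social import (
    K_GRID,
    OtherBeliefFilter,
    PSParams,
    k_grid_nodes,
    ps_trial_policy,
)

__all__ = [
    "TaskConfig",
    "PopulationSpec",
    "GridPosterior",
    "standard_option_set",
    "random_option_pair",
    "grid_update",
    "adaptive_select",
    "choose_other_k",
    "phase2_should_stop",
    "simulate_phase1",
    "simulate_participant",
    "simulate_population",
]


@dataclass(frozen=True)
class TaskConfig:
    """Task protocol and stimulus-generation settings.

    Reward magnitudes and delay menus are configurable; defaults use
    immediate rewards of 1–10 currency units, delayed/immediate reward
    ratios in (1, 5] and delays of 1–365 days, with standard-set
    indifference points evenly log-spaced over ``[-9, 0]``.
    """

    pop_mean_k: float = -4.5
    pop_sd_k: float = 2.3
    other_shift: float = 2.3          # one population SD
    p_toward: float = 2.0 / 3.0       # probability the Other sits toward -4.5
    n_standard: int = 30
    n_adaptive: int = 30
    phase2_max: int = 60
    phase2_window: int = 10
    phase2_needed: int = 8
    phase3_blocks: int = 3            # mini-blocks per role
    phase3_block_size: int = 10
    standard_k_lo: float = -9.0
    standard_k_hi: float = 0.0
    r0_lo: float = 1.0
    r0_hi: float = 10.0
    ratio_lo: float = 1.5
    ratio_hi: float = 5.0
    d_lo: float = 1.0
    d_hi: float = 365.0
    n_candidates: int = 200           # adaptive candidate pool per trial
    grid: tuple[float, float, int] = K_GRID
    assumed_T: float = 1.0            # in-task observation model temperature

    def __post_init__(self) -> None:
        if not (0 <= self.p_toward <= 1):
            raise ValueError("p_toward must lie in [0, 1]")
        for name in ("n_standard", "n_adaptive", "phase2_max", "phase3_blocks",
                     "phase3_block_size", "n_candidates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling distributions for synthetic-agent parameters.

    ``kind='ps'`` draws full preference-shift agents; ``kind='ku'`` fixes
    ``sigma_r = inf`` and ``tau_o = 1`` (no social coupling, uncorrelated
    ``m`` and ``u``); ``kind='kt'`` draws softmax agents for phase-1-only
    studies.  Log-scale spreads are chosen to mimic the dispersion of fitted
    parameters in community samples: ``m ~ N(-4.5, 2.3^2)``,
    ``ln u ~ N(-0.1, 0.8^2)`` (mean taste-uncertainty near 1.2),
    ``ln sigma_r ~ N(0, 0.6^2)`` (mean reference dispersion near 1.2),
    ``ln tau_o ~ N(0, 0.3^2)`` and ``xi ~ Beta(2, 100)`` (median lapse
    around 0.017).
    """

    kind: str = "ps"                  # 'ps' | 'ku' | 'kt'
    mean_m: float = -4.5
    sd_m: float = 2.3
    mu_ln_u: float = -0.1
    sd_ln_u: float = 0.8
    mu_ln_sigma_r: float = 0.0
    sd_ln_sigma_r: float = 0.6
    mu_ln_tau_o: float = 0.0
    sd_ln_tau_o: float = 0.3
    xi_a: float = 2.0
    xi_b: float = 100.0
    mu_ln_T: float = 0.2              # kt only; mean T near 1.4
    sd_ln_T: float = 0.6

    def draw(self, rng: np.random.Generator) -> Union[PSParams, KTParams]:
        if self.kind == "kt":
            return KTParams(
                k=rng.normal(self.mean_m, self.sd_m),
                T=float(np.exp(rng.normal(self.mu_ln_T, self.sd_ln_T))),
            )
        m = rng.normal(self.mean_m, self.sd_m)
        u = float(np.exp(rng.normal(self.mu_ln_u, self.sd_ln_u)))
        xi = float(rng.beta(self.xi_a, self.xi_b))
        if self.kind == "ku":
            return PSParams(m_s=m, u_s=u, sigma_r=math.inf, tau_o=1.0, xi=xi)
        if self.kind != "ps":
            raise ValueError(f"unknown population kind {self.kind!r}")
        return PSParams(
            m_s=m,
            u_s=u,
            sigma_r=float(np.exp(rng.normal(self.mu_ln_sigma_r, self.sd_ln_sigma_r))),
            tau_o=float(np.exp(rng.normal(self.mu_ln_tau_o, self.sd_ln_tau_o))),
            xi=xi,
        )


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

def _pair_from_indifference(k_target: float, R0: float, ratio: float, cfg: TaskConfig) -> OptionPair:
    """Build a pair whose indifference point is ``k_target`` where the delay
    bounds allow it; clipping the delay into ``[d_lo, d_hi]`` moves the
    realised reward ratio instead."""
    D = float(np.clip((ratio - 1.0) * math.exp(-k_target), cfg.d_lo, cfg.d_hi))
    RD = R0 * (1.0 + D * math.exp(k_target))
    return OptionPair(R0=R0, RD=RD, D=D)


def standard_option_set(cfg: TaskConfig = TaskConfig()) -> list[OptionPair]:
    """The deterministic 30-pair standard set.

    Target indifference points are evenly spaced over
    ``[standard_k_lo, standard_k_hi]``; immediate rewards cycle over 1..10.
    Note that for very patient targets the delay cap forces reward ratios
    close to 1, a structural feature of any bounded-delay menu.
    """
    targets = np.linspace(cfg.standard_k_lo, cfg.standard_k_hi, cfg.n_standard)
    pairs = []
    for i, kt in enumerate(targets):
        R0 = cfg.r0_lo + (i % 10) * (cfg.r0_hi - cfg.r0_lo) / 9.0
        pairs.append(_pair_from_indifference(float(kt), R0, 3.0, cfg))
    return pairs


def random_option_pair(cfg: TaskConfig, rng: np.random.Generator) -> OptionPair:
    """Random pair with indifference point uniform over the standard span and
    reward ratio uniform over ``[ratio_lo, ratio_hi]``."""
    k_t = rng.uniform(cfg.standard_k_lo, cfg.standard_k_hi)
    ratio = rng.uniform(cfg.ratio_lo, cfg.ratio_hi)
    R0 = rng.uniform(cfg.r0_lo, cfg.r0_hi)
    return _pair_from_indifference(float(k_t), float(R0), float(ratio), cfg)


# ---------------------------------------------------------------------------
# Adaptive design
# ---------------------------------------------------------------------------

@dataclass
class GridPosterior:
    """Discrete posterior over ``k`` on a fixed grid."""

    nodes: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float)
        self.mass = np.asarray(self.mass, float)
        if self.nodes.shape != self.mass.shape or self.nodes.size < 2:
            raise ValueError("degenerate grid posterior")
        if np.any(self.mass < 0) or not math.isclose(float(self.mass.sum()), 1.0, rel_tol=1e-6):
            raise ValueError("posterior masses must be non-negative and sum to 1")

    @classmethod
    def flat(cls, grid: tuple[float, float, int] = K_GRID) -> "GridPosterior":
        nodes = k_grid_nodes(grid)
        return cls(nodes, np.full(nodes.size, 1.0 / nodes.size))

    def entropy(self) -> float:
        m = self.mass[self.mass > 0]
        return float(-(m * np.log(m)).sum())

    def mode(self) -> float:
        return float(self.nodes[int(np.argmax(self.mass))])

    def mean(self) -> float:
        return float(self.mass @ self.nodes)


def _pair_likelihood(post: GridPosterior, opt: OptionPair, assumed_T: float) -> np.ndarray:
    return kt_policy_arrays(opt.R0, opt.RD, opt.D, post.nodes, assumed_T)


def grid_update(
    post: GridPosterior, opt: OptionPair, choice: int, assumed_T: float = 1.0
) -> GridPosterior:
    """Bayes update of the grid posterior with one observed choice under the
    unit-temperature softmax observation model."""
    pi = _pair_likelihood(post, opt, assumed_T)
    like = pi if choice == 1 else 1.0 - pi
    new = post.mass * like
    s = float(new.sum())
    if not (s > 0) or not np.isfinite(s):
        raise ValueError("posterior vanished after update")
    return GridPosterior(post.nodes, new / s)


def adaptive_select(
    post: GridPosterior,
    candidates: Sequence[OptionPair],
    assumed_T: float = 1.0,
) -> OptionPair:
    """Pick the candidate pair minimising expected posterior entropy.

    The expectation is over the two predicted choices under the current
    posterior; ties break toward the lowest candidate index.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    R0 = np.array([c.R0 for c in candidates])
    RD = np.array([c.RD for c in candidates])
    D = np.array([c.D for c in candidates])
    # (n_candidates, n_nodes) delayed-choice probabilities
    pi = kt_policy_arrays(R0[:, None], RD[:, None], D[:, None], post.nodes[None, :], assumed_T)
    m = post.mass[None, :]
    p_delay = (m * pi).sum(axis=1)

    def _entropies(w: np.ndarray) -> np.ndarray:
        s = w.sum(axis=1, keepdims=True)
        s = np.where(s > 0, s, 1.0)
        w = w / s
        with np.errstate(divide="ignore", invalid="ignore"):
            lw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), 0.0)
        return -(w * lw).sum(axis=1)

    h1 = _entropies(m * pi)
    h0 = _entropies(m * (1.0 - pi))
    expected = p_delay * h1 + (1.0 - p_delay) * h0
    return candidates[int(np.argmin(expected))]


# ---------------------------------------------------------------------------
# Protocol pieces
# ---------------------------------------------------------------------------

def choose_other_k(k_b: float, cfg: TaskConfig, rng: np.random.Generator) -> float:
    """Partner taste: one ``other_shift`` from ``k_b``, toward the population
    mean with probability ``p_toward`` and away with the complement."""
    if not math.isfinite(k_b):
        raise ValueError("k_b must be finite")
    toward = math.copysign(1.0, cfg.pop_mean_k - k_b) if k_b != cfg.pop_mean_k else (
        1.0 if rng.random() < 0.5 else -1.0
    )
    direction = toward if rng.random() < cfg.p_toward else -toward
    return k_b + direction * cfg.other_shift


def phase2_should_stop(
    history: Sequence[bool], window: int = 10, needed: int = 8, max_trials: int = 60
) -> bool:
    """Learning-criterion stop rule: ``needed`` correct in the last full
    ``window`` trials, or the trial cap.  The window must be full before the
    criterion can fire."""
    n = len(history)
    if n >= max_trials:
        return True
    if n < window:
        return False
    return sum(history[-window:]) >= needed


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _adaptive_pair_fast(
    post: GridPosterior, cfg: TaskConfig, rng: np.random.Generator
) -> OptionPair:
    """Vectorised candidate pool + expected-entropy selection (equivalent to
    :func:`adaptive_select` over ``n_candidates`` draws from
    :func:`random_option_pair`, without constructing intermediate objects)."""
    n = cfg.n_candidates
    k_t = rng.uniform(cfg.standard_k_lo, cfg.standard_k_hi, size=n)
    ratio = rng.uniform(cfg.ratio_lo, cfg.ratio_hi, size=n)
    R0 = rng.uniform(cfg.r0_lo, cfg.r0_hi, size=n)
    D = np.clip((ratio - 1.0) * np.exp(-k_t), cfg.d_lo, cfg.d_hi)
    RD = R0 * (1.0 + D * np.exp(k_t))
    pi = kt_policy_arrays(R0[:, None], RD[:, None], D[:, None],
                          post.nodes[None, :], cfg.assumed_T)
    m = post.mass[None, :]
    p_delay = (m * pi).sum(axis=1)

    def ent(w):
        s = w.sum(axis=1, keepdims=True)
        s = np.where(s > 0, s, 1.0)
        w = w / s
        with np.errstate(divide="ignore", invalid="ignore"):
            lw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), 0.0)
        return -(w * lw).sum(axis=1)

    expected = p_delay * ent(m * pi) + (1.0 - p_delay) * ent(m * (1.0 - pi))
    i = int(np.argmin(expected))
    return OptionPair(R0=float(R0[i]), RD=float(RD[i]), D=float(D[i]))


AgentSpec = Union[PSParams, KTParams]


def _phase1_choice_prob(agent: AgentSpec, pair: OptionPair) -> float:
    if isinstance(agent, KTParams):
        return float(kt_policy_arrays(pair.R0, pair.RD, pair.D, agent.k, agent.T))
    pi = float(ku_policy_arrays(pair.indifference_k, agent.m_s, agent.u_s))
    return float(apply_lapse(pi, agent.xi))


def simulate_phase1(
    agent: AgentSpec,
    cfg: TaskConfig,
    rng: np.random.Generator,
    start_index: int = 0,
) -> tuple[list[Trial], GridPosterior]:
    """Run phase 1: standard and adaptive pairs interleaved, with the
    experimenter's grid posterior updated after every choice."""
    standard = standard_option_set(cfg)
    post = GridPosterior.flat(cfg.grid)
    trials: list[Trial] = []
    n_total = cfg.n_standard + cfg.n_adaptive
    si = 0
    for i in range(n_total):
        if i % 2 == 0 and si < len(standard):
            pair = standard[si]
            si += 1
        else:
            pair = _adaptive_pair_fast(post, cfg, rng)
        pi = _phase1_choice_prob(agent, pair)
        choice = int(rng.random() < pi)
        trials.append(Trial(phase=1, index=start_index + i, role=ROLE_SELF, pair=pair, choice=choice))
        post = grid_update(post, pair, choice, cfg.assumed_T)
    return trials, post


def simulate_participant(
    agent: PSParams,
    cfg: TaskConfig = TaskConfig(),
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "p0",
    age: Optional[float] = None,
    gender: Optional[str] = None,
) -> ParticipantDataset:
    """Simulate one participant through all three phases.

    The agent itself runs the preference-shift model: it filters a belief
    about the Other from the feedback it receives, guesses the Other's
    choices through the relaxed other-posterior policy, and makes phase-3
    self-choices from the (possibly shifted) self-posterior.
    """
    if rng is None:
        rng = np.random.default_rng()
    trials, post = simulate_phase1(agent, cfg, rng)
    k_b = post.mode()
    k_o = choose_other_k(k_b, cfg, rng)
    K_o = math.exp(k_o)

    filt = OtherBeliefFilter(grid=cfg.grid, assumed_T=cfg.assumed_T)
    idx = len(trials)
    correct_history: list[bool] = []

    def other_trial(phase: int, i: int) -> Trial:
        pair = random_option_pair(cfg, rng)
        pi_guess = ps_trial_policy(pair, ROLE_OTHER, agent, filt.belief())
        guess = int(rng.random() < pi_guess)
        pi_actual = float(kt_policy_arrays(pair.R0, pair.RD, pair.D, k_o, 1.0))
        actual = int(rng.random() < pi_actual)
        fb = "correct" if guess == actual else "incorrect"
        filt.update(pair, actual)
        return Trial(
            phase=phase, index=i, role=ROLE_OTHER, pair=pair,
            choice=guess, other_choice=actual, feedback=fb,
        )

    # phase 2: learn the Other until criterion or cap
    while True:
        t = other_trial(2, idx)
        trials.append(t)
        idx += 1
        correct_history.append(t.feedback == "correct")
        if phase2_should_stop(
            correct_history, cfg.phase2_window, cfg.phase2_needed, cfg.phase2_max
        ):
            break

    # phase 3: interleaved self/other mini-blocks
    for _ in range(cfg.phase3_blocks):
        for _ in range(cfg.phase3_block_size):
            pair = random_option_pair(cfg, rng)
            pi = ps_trial_policy(pair, ROLE_SELF, agent, filt.belief())
            choice = int(rng.random() < pi)
            trials.append(Trial(phase=3, index=idx, role=ROLE_SELF, pair=pair, choice=choice))
            idx += 1
        for _ in range(cfg.phase3_block_size):
            trials.append(other_trial(3, idx))
            idx += 1

    truth = {
        "kind": "ku" if math.isinf(agent.sigma_r) else "ps",
        "m_s": agent.m_s, "u_s": agent.u_s, "sigma_r": agent.sigma_r,
        "tau_o": agent.tau_o, "xi": agent.xi,
        "k_b": k_b, "k_o": k_o,
    }
    ds = ParticipantDataset(
        participant_id=participant_id, trials=trials, age=age, gender=gender, truth=truth
    )
    ds.validate()
    return ds


def simulate_population(
    N: int,
    pop: PopulationSpec = PopulationSpec(),
    cfg: TaskConfig = TaskConfig(),
    seed: int = 0,
    phase1_only: bool = False,
) -> list[ParticipantDataset]:
    """Simulate ``N`` participants with parameters drawn from ``pop``.

    Fully reproducible: a single ``seed`` spawns one independent stream per
    participant.  ``phase1_only`` skips phases 2–3 (useful for studies of the
    pre-exposure fits); it is implied for ``kind='kt'`` agents, whose social
    behaviour is not modelled.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    streams = np.random.SeedSequence(seed).spawn(N)
    out: list[ParticipantDataset] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        agent = pop.draw(rng)
        age = float(rng.integers(14, 25))
        gender = "f" if i % 2 == 0 else "m"
        pid = f"p{i:04d}"
        if phase1_only or isinstance(agent, KTParams):
            trials, post = simulate_phase1(agent, cfg, rng)
            if isinstance(agent, KTParams):
                truth = {"kind": "kt", "k": agent.k, "T": agent.T, "k_b": post.mode()}
            else:
                truth = {
                    "kind": "ku" if math.isinf(agent.sigma_r) else "ps",
                    "m_s": agent.m_s, "u_s": agent.u_s, "sigma_r": agent.sigma_r,
                    "tau_o": agent.tau_o, "xi": agent.xi, "k_b": post.mode(),
                }
            ds = ParticipantDataset(
                participant_id=pid, trials=trials, age=age, gender=gender, truth=truth
            )
            ds.validate()
        else:
            ds = simulate_participant(
                agent, cfg, rng, participant_id=pid, age=age, gender=gender
            )
        out.append(ds)
    return out
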