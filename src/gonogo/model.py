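"""Rescorla-Wagner / Q-learning hybrid model of Go/NoGo choice with a Pavlovian bias.

The agent carries two value systems for each card (stimulus):

* an action-free stimulus value ``V(s)`` updated by a delta rule on every
  trial, and
* instrumental action values ``Q(a|s)`` updated by the same delta rule but
  only for the action actually taken.

Choice is a softmax over action weights in which the Go weight is augmented
by a constant Go-bias ``b_go`` and by ``pi * V(s)`` — the Pavlovian bias
term that pushes toward action for positively valued cards and toward
inaction for negatively valued ones.  The temperature ``beta`` *divides*
the weights, so larger ``beta`` means more random choice.

The same recursion serves as a generative agent (:func:`simulate_agent`)
and as a Bernoulli likelihood for observed choice sequences
(:func:`negative_log_likelihood`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .task import CARD_INDEX, CARDS, Card

__all__ = [
    "AgentParams",
    "LearnerState",
    "action_weights",
    "p_go",
    "update_stimulus_value",
    "update_action_value",
    "simulate_agent",
    "negative_log_likelihood",
    "fit_ml",
    "ML_BOUNDS",
]

#: default points-to-model-units factor: feedback of +/-10 points enters the
#: delta rules as +/-1 (Go-cost outcomes become 0.9, -0.1, -1.1).
DEFAULT_REWARD_SCALE = 0.1


@dataclass(frozen=True)
class AgentParams:
    """Per subject-block model parameters.

    alpha : learning rate, strictly inside (0, 1)
    beta  : softmax temperature, > 0 (weights are divided by it)
    pi    : Pavlovian bias weight on V(s), unconstrained in sign
    b_go  : additive Go-bias, unconstrained
    """

    alpha: float
    beta: float
    pi: float
    b_go: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if not self.beta > 0.0:
            raise ValueError(f"beta must be strictly positive, got {self.beta}")

    def to_linked(self) -> np.ndarray:
        """(logit alpha, log beta, pi, b_go) — the unconstrained scale."""
        return np.array([logit(self.alpha), np.log(self.beta), self.pi, self.b_go])

    @classmethod
    def from_linked(cls, eta: np.ndarray) -> "AgentParams":
        return cls(alpha=float(expit(eta[0])), beta=float(np.exp(eta[1])),
                   pi=float(eta[2]), b_go=float(eta[3]))


@dataclass
class LearnerState:
    """Running stimulus values V(s) and action values Q(a|s).

    Values start at zero for every card at the beginning of each block
    (each block introduces four new cards, so no knowledge carries over).
    With rewards bounded in [r_min, r_max] and alpha in (0, 1], every V and
    Q stays within [min(0, r_min), max(0, r_max)].
    """

    V: dict = field(default_factory=lambda: {c: 0.0 for c in CARDS})
    Q: dict = field(default_factory=lambda: {(c, a): 0.0 for c in CARDS for a in ("go", "nogo")})
    reward_scale: float = DEFAULT_REWARD_SCALE

    @classmethod
    def fresh(cls, reward_scale: float = DEFAULT_REWARD_SCALE) -> "LearnerState":
        return cls(reward_scale=reward_scale)


def action_weights(state: LearnerState, card, params: AgentParams) -> tuple[float, float]:
    """Action weights (W_go, W_nogo) for one card.

    W_go = Q(Go|s) + b_go + pi * V(s);  W_nogo = Q(NoGo|s).
    """
    card = Card(card)
    if card not in state.V:
        raise ValueError(f"unknown card {card!r}")
    w_go = state.Q[(card, "go")] + params.b_go + params.pi * state.V[card]
    w_nogo = state.Q[(card, "nogo")]
    return w_go, w_nogo


def p_go(w_go: float, w_nogo: float, beta: float) -> float:
    """Softmax probability of Go: logistic of (W_go - W_nogo) / beta.

    Computed in log-space (overflow-safe) and algebraically identical to the
    two-option softmax with weights divided by the temperature.
    """
    if not beta > 0.0:
        raise ValueError(f"beta must be strictly positive, got {beta}")
    return float(expit((w_go - w_nogo) / beta))


def update_stimulus_value(state: LearnerState, card, reward: float, alpha: float) -> LearnerState:
    """Delta-rule update of V(s); runs on every trial regardless of action."""
    card = Card(card)
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    state.V[card] += alpha * (reward - state.V[card])
    return state


def update_action_value(state: LearnerState, card, action: str, reward: float,
                        alpha: float) -> LearnerState:
    """Delta-rule update of Q(a|s) for the chosen action only."""
    card = Card(card)
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    key = (card, action)
    state.Q[key] += alpha * (reward - state.Q[key])
    return state


def simulate_agent(params_by_block, schedules, rng_seed: int, *,
                   subject_id: str = "sim", control: str = "high", tdcs: str = "sham",
                   yoked_streams=None,
                   reward_scale: float = DEFAULT_REWARD_SCALE) -> pd.DataFrame:
    """Generative use of the model: run one agent through a full session.

    Thin wrapper over :func:`gonogo.task.run_session`; see there for the
    session mechanics (outcome resolution, Go-cost, yoked replay).
    """
    from .task import run_session

    return run_session(subject_id=subject_id, control=control, tdcs=tdcs,
                       params_by_block=params_by_block, schedules=schedules,
                       rng_seed=rng_seed, yoked_streams=yoked_streams,
                       reward_scale=reward_scale)


def _block_arrays(records: pd.DataFrame):
    """(cards, go, delivered, new_block) arrays in replay order.

    ``new_block[t]`` marks trials at which the learner state resets (the
    first trial overall and every block boundary).
    """
    rec = records.sort_values(["block", "trial"]) if "block" in records else \
        records.sort_values("trial")
    cards = rec["card"].map(CARD_INDEX).to_numpy(dtype=np.int64)
    go = (rec["response"].to_numpy() == "go").astype(np.int64)
    delivered = rec["delivered_points"].to_numpy(dtype=np.float64)
    if "block" in rec:
        blocks = rec["block"].to_numpy()
        new_block = np.r_[True, blocks[1:] != blocks[:-1]]
    else:
        new_block = np.r_[True, np.zeros(len(rec) - 1, dtype=bool)]
    return cards, go, delivered, new_block


def negative_log_likelihood(params: AgentParams, records: pd.DataFrame,
                            reward_scale: float = DEFAULT_REWARD_SCALE) -> float:
    """-log p(choices | params) for one subject-block, by replaying the recursion.

    The learner state is reconstructed trial by trial from the recorded
    sequence: weights and P(Go) are computed from the current V/Q, the
    recorded choice contributes -log P(choice), and the recorded (scaled)
    feedback drives the V and Q updates.  If the records span several
    blocks, V and Q reset to zero at each block boundary (new cards).  An
    empty record list yields 0.
    """
    if len(records) == 0:
        return 0.0
    cards, go, delivered, new_block = _block_arrays(records)
    eta = params.to_linked()
    return float(_nll_arrays(eta, cards, go, delivered * reward_scale, new_block))


def _nll_arrays(eta: np.ndarray, cards: np.ndarray, go: np.ndarray,
                rewards: np.ndarray, new_block: np.ndarray) -> float:
    """Fast sequence NLL on pre-extracted arrays (linked-scale params)."""
    alpha = expit(eta[0])
    beta = np.exp(np.clip(eta[1], -20.0, 20.0))
    pi, b_go = eta[2], eta[3]
    V = np.zeros(4)
    Q = np.zeros((4, 2))  # action axis: 0 = nogo, 1 = go
    nll = 0.0
    for t, (c, a, r) in enumerate(zip(cards, go, rewards)):
        if new_block[t]:
            V[:] = 0.0
            Q[:] = 0.0
        x = (Q[c, 1] + b_go + pi * V[c] - Q[c, 0]) / beta
        sign = 1.0 if a == 1 else -1.0
        nll += np.logaddexp(0.0, -sign * x)
        V[c] += alpha * (r - V[c])
        Q[c, a] += alpha * (r - Q[c, a])
    return float(nll)


#: box constraints on the linked scale used for maximum-likelihood fits
ML_BOUNDS = ((-6.0, 6.0), (-3.0, 3.0), (-10.0, 10.0), (-10.0, 10.0))


def fit_ml(records: pd.DataFrame, reward_scale: float = DEFAULT_REWARD_SCALE,
           groupby=("subject_id", "block"), ridge: float = 0.05) -> pd.DataFrame:
    """Independent maximum-likelihood estimates per subject-block (default)
    or per subject (``groupby=("subject_id",)``, both blocks with a state
    reset at the boundary).

    Minimizes the sequence NLL on the linked scale (logit alpha, log beta,
    pi, b_go) with L-BFGS-B from several fixed starting points.  A light
    ridge penalty ``ridge * ||eta||^2`` stabilises the flat likelihood
    ridges this model is known for (a subject with little detectable
    learning leaves beta unidentified); it is far too weak to move an
    informative estimate but pins unidentified directions near zero
    instead of the box bounds.  Set ``ridge=0`` for the bare ML solution.
    The reported ``nll`` is the unpenalised value at the optimum.
    """
    starts = (np.array([0.0, 0.0, 0.0, 0.0]),
              np.array([-1.0, 1.0, 0.5, 0.5]),
              np.array([-1.0, -0.5, 0.0, -0.5]))
    rows = []
    for key, grp in records.groupby(list(groupby), sort=True):
        cards, go, delivered, new_block = _block_arrays(grp)
        rewards = delivered * reward_scale

        def objective(eta):
            return _nll_arrays(eta, cards, go, rewards, new_block) + ridge * eta @ eta

        best = None
        for x0 in starts:
            res = minimize(objective, x0, method="L-BFGS-B", bounds=ML_BOUNDS)
            if best is None or res.fun < best.fun:
                best = res
        eta = best.x
        row = dict(zip(groupby, key if isinstance(key, tuple) else (key,)))
        row.update(eta_alpha=eta[0], eta_beta=eta[1], eta_pi=eta[2], eta_b_go=eta[3],
                   alpha=float(expit(eta[0])), beta=float(np.exp(eta[1])),
                   pi=float(eta[2]), b_go=float(eta[3]),
                   nll=float(best.fun - ridge * eta @ eta),
                   n_trials=len(grp))
        rows.append(row)
    return pd.DataFrame(rows)
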