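"""Orthogonalized Go/NoGo task: schedules, outcomes, Go-cost and yoked replay.

Four cards cross outcome valence (Win vs Avoid) with the instrumentally
correct action (Go vs NoGo).  Win cards pay +10 or 0 points, Avoid cards
pay 0 or -10; any outcome that follows an active (Go) response is reduced
by a fixed 1-point Go-cost (so 9 / -1 / -11 on Go trials).  Correct
responses earn the favorable outcome with a fixed 70/30 probabilistic
contingency.

The low-controllability manipulation is a yoked design: each LowControl
subject receives, card label by card label, a shuffled replay of the base
outcomes (Go-cost removed) that a paired HighControl subject earned in
block 1, severing the response-outcome contingency while matching
reward/loss frequency between groups.  The Go-cost is still applied to the
replayed outcomes according to the LowControl subject's own responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Card",
    "CARDS",
    "CARD_INDEX",
    "GO_COST",
    "ScheduledTrial",
    "make_block_schedule",
    "resolve_outcome",
    "apply_go_cost",
    "build_yoked_streams",
    "run_session",
    "TRIAL_COLUMNS",
]

#: fixed penalty on any outcome preceded by a Go response, in points
GO_COST = 1


class Card(str, Enum):
    """One of the four card types (valence x required action)."""

    GO_WIN = "go_win"
    NOGO_WIN = "nogo_win"
    GO_AVOID = "go_avoid"
    NOGO_AVOID = "nogo_avoid"

    @property
    def valence(self) -> str:
        return "win" if self in (Card.GO_WIN, Card.NOGO_WIN) else "avoid"

    @property
    def required_action(self) -> str:
        return "go" if self in (Card.GO_WIN, Card.GO_AVOID) else "nogo"

    @property
    def congruent(self) -> bool:
        """Pavlovian-congruent iff the correct action matches the Pavlovian pull."""
        return (self.valence == "win") == (self.required_action == "go")


CARDS: tuple[Card, ...] = (Card.GO_WIN, Card.NOGO_WIN, Card.GO_AVOID, Card.NOGO_AVOID)
CARD_INDEX: dict[str, int] = {c.value: i for i, c in enumerate(CARDS)}

#: CSV dialect for trial tables, one row per trial
TRIAL_COLUMNS = ("subject_id", "control", "tdcs", "block", "trial", "card",
                 "response", "base_points", "delivered_points", "correct")


@dataclass(frozen=True)
class ScheduledTrial:
    block: int
    trial_index: int
    card: Card
    #: True = the correct response yields the good outcome on this trial
    favorable: bool


def make_block_schedule(n_reps: int, contingency: float, rng_seed: int, *,
                        block: int = 1, mode: str = "fixed") -> list[ScheduledTrial]:
    """Uniformly shuffled block of ``4 * n_reps`` trials.

    In ``mode="fixed"`` (the default) each card carries exactly
    ``round(contingency * n_reps)`` favorable flags, so a 0.7 contingency
    with 40 repetitions gives exactly 28 contingency-respecting trials per
    card.  ``mode="bernoulli"`` draws the flag i.i.d. per trial instead.
    Deterministic given the seed.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be a positive integer, got {n_reps}")
    if not 0.0 <= contingency <= 1.0:
        raise ValueError(f"contingency must lie in [0, 1], got {contingency}")
    if mode not in ("fixed", "bernoulli"):
        raise ValueError(f"unknown contingency mode {mode!r}")
    rng = np.random.default_rng(rng_seed)
    pairs: list[tuple[Card, bool]] = []
    for card in CARDS:
        if mode == "fixed":
            n_fav = int(round(contingency * n_reps))
            flags = np.zeros(n_reps, dtype=bool)
            flags[:n_fav] = True
        else:
            flags = rng.random(n_reps) < contingency
        pairs.extend((card, bool(f)) for f in flags)
    order = rng.permutation(len(pairs))
    return [ScheduledTrial(block=block, trial_index=t, card=pairs[k][0],
                           favorable=pairs[k][1])
            for t, k in enumerate(order)]


def resolve_outcome(card: Card, response: str, favorable: bool) -> int:
    """Base outcome in points, before the Go-cost.

    The good outcome (Win: +10, Avoid: 0) is delivered iff response
    correctness matches the trial's favorable flag; otherwise the bad
    outcome (Win: 0, Avoid: -10).
    """
    card = Card(card)
    correct = response == card.required_action
    good = correct == favorable
    if card.valence == "win":
        return 10 if good else 0
    return 0 if good else -10


def apply_go_cost(base_points: int, response: str) -> int:
    """Delivered points: base minus 1 after a Go response, unchanged after NoGo."""
    return base_points - GO_COST if response == "go" else base_points


def build_yoked_streams(source_block1: pd.DataFrame, rng_seed: int) -> dict[Card, list[int]]:
    """Card-specific outcome streams replayed to a yoked LowControl subject.

    Takes a HighControl source subject's complete block-1 records and
    returns, per card label, the source's base outcomes (Go-cost removed)
    in a fresh random order.  The per-card multiset of outcomes is exactly
    the source's, which is what matches reward/loss frequency between the
    yoked pair.
    """
    rng = np.random.default_rng(rng_seed)
    counts = source_block1["card"].value_counts()
    n_reps = counts.iloc[0] if len(counts) else 0
    if len(counts) != 4 or counts.nunique() != 1:
        raise ValueError("source block 1 is incomplete: need equal counts for all four cards, "
                         f"got {counts.to_dict()}")
    streams: dict[Card, list[int]] = {}
    for card in CARDS:
        rows = source_block1[source_block1["card"] == card.value]
        base = rows["base_points"].to_numpy(dtype=np.int64)
        # equivalent to delivered + GO_COST on Go-preceded trials
        streams[card] = [int(b) for b in rng.permutation(base)]
    assert all(len(s) == n_reps for s in streams.values())
    return streams


def run_session(subject_id: str, control: str, tdcs: str, params_by_block: dict,
                schedules: dict[int, list[ScheduledTrial]], rng_seed: int, *,
                yoked_streams: dict[Card, list[int]] | None = None,
                reward_scale: float | None = None) -> pd.DataFrame:
    """Simulate one subject through all blocks; returns a trial table.

    HighControl sessions resolve outcomes from the schedule's contingency
    flags in both blocks.  LowControl sessions replay the yoked stream in
    block 1 — the base outcome is the next stream item for the shown card
    regardless of the response; only the Go-cost depends on it — and
    revert to contingency-driven outcomes in block 2.

    Learner state (V and Q) starts from zero at each block boundary, since
    each block introduces four new cards.
    """
    from .model import (DEFAULT_REWARD_SCALE, LearnerState, action_weights, p_go,
                        update_action_value, update_stimulus_value)

    if control not in ("high", "low"):
        raise ValueError(f"control must be 'high' or 'low', got {control!r}")
    if tdcs not in ("stim", "sham"):
        raise ValueError(f"tdcs must be 'stim' or 'sham', got {tdcs!r}")
    if control == "low" and yoked_streams is None:
        raise ValueError("LowControl sessions require yoked_streams for block 1")
    if reward_scale is None:
        reward_scale = DEFAULT_REWARD_SCALE

    rng = np.random.default_rng(rng_seed)
    if yoked_streams is not None:
        cursors = {card: 0 for card in yoked_streams}
    rows = []
    for block in sorted(schedules):
        params = params_by_block[block]
        state = LearnerState.fresh(reward_scale)
        for trial in schedules[block]:
            card = trial.card
            w_go, w_nogo = action_weights(state, card, params)
            response = "go" if rng.random() < p_go(w_go, w_nogo, params.beta) else "nogo"
            if control == "low" and block == 1:
                k = cursors[card]
                if k >= len(yoked_streams[card]):
                    raise RuntimeError(f"yoked stream exhausted for card {card.value}")
                base = yoked_streams[card][k]
                cursors[card] = k + 1
            else:
                base = resolve_outcome(card, response, trial.favorable)
            delivered = apply_go_cost(base, response)
            r = delivered * reward_scale
            update_stimulus_value(state, card, r, params.alpha)
            update_action_value(state, card, response, r, params.alpha)
            rows.append((subject_id, control, tdcs, block, trial.trial_index,
                         card.value, response, base, delivered,
                         int(response == card.required_action)))
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
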