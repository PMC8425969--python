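import pandas as pd
import pytest

from gonogo.cohort import CohortConfig, generate_cohort
from gonogo.model import AgentParams
from gonogo.task import make_block_schedule, run_session


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects per group, full two-block structure with yoking."""
    cfg = CohortConfig(seed=20, n_per_group={("high", "sham"): 4, ("high", "stim"): 4,
                                             ("low", "sham"): 4, ("low", "stim"): 4})
    table, truth = generate_cohort(cfg)
    return table, truth


@pytest.fixture(scope="session")
def one_session():
    """One HighControl subject, 2 x 160 trials, moderate parameters."""
    p = AgentParams(alpha=0.25, beta=1.0, pi=0.6, b_go=0.3)
    sch = {1: make_block_schedule(40, 0.7, 101, block=1),
           2: make_block_schedule(40, 0.7, 102, block=2)}
    return run_session("s0", "high", "sham", {1: p, 2: p}, sch, rng_seed=7)


def forced_session(response: str, n_reps: int = 40, seed: int = 5) -> pd.DataFrame:
    """A balanced block answered with one fixed response throughout."""
    from gonogo.task import apply_go_cost, resolve_outcome

    rows = []
    for t, trial in enumerate(make_block_schedule(n_reps, 0.7, seed)):
        base = resolve_outcome(trial.card, response, trial.favorable)
        rows.append(("f0", "high", "sham", 1, t, trial.card.value, response, base,
                     apply_go_cost(base, response),
                     int(response == trial.card.required_action)))
    from gonogo.task import TRIAL_COLUMNS

    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def pavlovian_session(n_reps: int = 40, seed: int = 5) -> pd.DataFrame:
    """A purely Pavlovian responder: Go on Win cards, NoGo on Avoid cards."""
    from gonogo.task import TRIAL_COLUMNS, apply_go_cost, resolve_outcome

    rows = []
    for t, trial in enumerate(make_block_schedule(n_reps, 0.7, seed)):
        response = "go" if trial.card.valence == "win" else "nogo"
        base = resolve_outcome(trial.card, response, trial.favorable)
        rows.append(("p0", "high", "sham", 1, t, trial.card.value, response, base,
                     apply_go_cost(base, response),
                     int(response == trial.card.required_action)))
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
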