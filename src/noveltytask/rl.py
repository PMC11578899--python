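"""Rescorla-Wagner learning core.

The behavioral model has two free parameters: a learning rate alpha and a
softmax inverse temperature beta. On each trial the reward prediction error
(RPE) is the difference between the feedback F and the expected value EV of
the chosen stimulus,

    RPE_t = F_t - EV_t(chosen),

and only the chosen stimulus's value is updated,

    EV_{t+1}(chosen) = EV_t(chosen) + alpha * RPE_t.

Choice follows an exponential softmax over the on-screen EVs with inverse
temperature beta. EVs are in dollars (feedback ranges $0.00-$0.30), so
discriminating values that differ by a few cents requires beta of order 10;
the default generative beta is 15. Novel stimuli enter with an initial EV
of $0.216, the population indifference value recovered by the logistic
calibration in :mod:`noveltytask.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .task import Session

__all__ = [
    "FIXED_ALPHA",
    "NOVEL_EV_INIT",
    "AgentParams",
    "ValueState",
    "SoftmaxAgent",
    "rw_update",
    "softmax_probs",
    "compute_trajectories",
    "replay_values",
]

#: Population learning rate used for trajectory replay (fit on 290 sessions).
FIXED_ALPHA = 0.692

#: Initial expected value assigned to novel stimuli (dollars).
NOVEL_EV_INIT = 0.216


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the Rescorla-Wagner / softmax agent.

    ``ev_init_start`` is the initial EV of the three stimuli present on
    trial 0; the original task description does not pin it down, so it
    defaults to the same value as novel stimuli.
    """

    alpha: float = FIXED_ALPHA
    beta: float = 15.0
    ev_init_novel: float = NOVEL_EV_INIT
    ev_init_start: float = NOVEL_EV_INIT

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.beta >= 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.ev_init_novel <= 0.30:
            raise ValueError("ev_init_novel must be in [0, 0.30] dollars")
        if not 0.0 <= self.ev_init_start <= 0.30:
            raise ValueError("ev_init_start must be in [0, 0.30] dollars")


class ValueState:
    """Map stimulus id -> current expected value (dollars)."""

    def __init__(self) -> None:
        self._ev: dict[int, float] = {}

    def initialize(self, stim_id: int, ev: float) -> None:
        self._ev[stim_id] = float(ev)

    def __getitem__(self, stim_id: int) -> float:
        try:
            return self._ev[stim_id]
        except KeyError:
            raise KeyError(f"unknown stimulus id {stim_id}") from None

    def __setitem__(self, stim_id: int, ev: float) -> None:
        if stim_id not in self._ev:
            raise KeyError(f"stimulus {stim_id} was never initialized")
        self._ev[stim_id] = float(ev)

    def __contains__(self, stim_id: int) -> bool:
        return stim_id in self._ev

    def as_dict(self) -> dict[int, float]:
        return dict(self._ev)


def rw_update(ev: float, feedback: float, alpha: float) -> tuple[float, float]:
    """One Rescorla-Wagner step for the chosen stimulus.

    Returns ``(new_ev, rpe)`` with ``rpe = feedback - ev`` and
    ``new_ev = ev + alpha * rpe``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    rpe = feedback - ev
    return ev + alpha * rpe, rpe


def softmax_probs(evs: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities p_i = exp(beta*EV_i) / sum_j exp(beta*EV_j).

    Computed with the max subtracted, so it is stable for arbitrarily large
    beta * EV.
    """
    evs = np.asarray(evs, dtype=float)
    if evs.size == 0:
        raise ValueError("softmax needs at least one option")
    if not np.isfinite(beta) or beta < 0:
        raise ValueError(f"beta must be finite and >= 0, got {beta}")
    z = beta * evs
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


class SoftmaxAgent:
    """A Rescorla-Wagner learner choosing by softmax over on-screen EVs.

    Implements the :class:`noveltytask.task.Agent` protocol. ``greedy=True``
    makes the agent deterministic argmax (the beta -> infinity limit), with
    uniform tie-breaking via the session rng.
    """

    def __init__(self, params: AgentParams | None = None, greedy: bool = False) -> None:
        self.params = params or AgentParams()
        self.greedy = greedy
        self.values = ValueState()

    def register_stimulus(self, stim_id: int, is_initial: bool) -> None:
        init = self.params.ev_init_start if is_initial else self.params.ev_init_novel
        self.values.initialize(stim_id, init)

    def choose(self, stim_ids: Sequence[int], rng: np.random.Generator) -> int:
        evs = np.array([self.values[s] for s in stim_ids])
        if self.greedy:
            best = np.flatnonzero(evs == evs.max())
            return stim_ids[int(rng.choice(best))]
        probs = softmax_probs(evs, self.params.beta)
        return stim_ids[int(rng.choice(len(stim_ids), p=probs))]

    def observe(self, stim_id: int, feedback: float) -> None:
        new_ev, _ = rw_update(self.values[stim_id], feedback, self.params.alpha)
        self.values[stim_id] = new_ev


def _session_arrays(
    events: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (offered ids (n,3), chosen position (n,), feedback (n,))."""
    offered = events[["stim_left", "stim_middle", "stim_right"]].to_numpy(dtype=int)
    chosen = events["chosen"].to_numpy(dtype=int)
    pos = np.argmax(offered == chosen[:, None], axis=1)
    bad = offered[np.arange(len(events)), pos] != chosen
    if bad.any():
        t = int(np.flatnonzero(bad)[0])
        raise ValueError(f"trial {t}: chosen stimulus {chosen[t]} not among offered")
    feedback = events["feedback"].to_numpy(dtype=float)
    return offered, pos, feedback


def replay_values(
    offered: np.ndarray,
    chosen_pos: np.ndarray,
    feedback: np.ndarray,
    alpha: float,
    ev_init_novel: float = NOVEL_EV_INIT,
    ev_init_start: float | None = None,
    initial_ids: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replay the RW recurrence over a fixed choice/feedback sequence.

    Stimuli offered on trial 0 (or listed in ``initial_ids``) are initialized
    at ``ev_init_start``; all others at ``ev_init_novel``. Returns the
    pre-choice EVs of the offered stimuli, shape (n_trials, 3), and the
    per-trial RPE of the chosen stimulus.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    n = len(feedback)
    ev_offered = np.empty((n, 3), dtype=float)
    rpe = np.empty(n, dtype=float)
    if n == 0:
        return ev_offered, rpe
    if ev_init_start is None:
        ev_init_start = ev_init_novel
    if initial_ids is None:
        initial_ids = offered[0]
    initial = set(int(s) for s in initial_ids)
    values: dict[int, float] = {}
    for t in range(n):
        row = offered[t]
        for j in range(3):
            sid = int(row[j])
            if sid not in values:
                values[sid] = ev_init_start if sid in initial else ev_init_novel
            ev_offered[t, j] = values[sid]
        c = int(row[chosen_pos[t]])
        r = feedback[t] - values[c]
        values[c] += alpha * r
        rpe[t] = r
    return ev_offered, rpe


def compute_trajectories(
    session: Session | pd.DataFrame,
    params: AgentParams | None = None,
) -> pd.DataFrame:
    """Deterministically replay EV/RPE trajectories over an observed session.

    Given the fixed choice/feedback sequence of a session and agent
    parameters (by default the fixed population learning rate and the novel
    initial EV), returns a DataFrame aligned with the events table carrying
    the pre-choice EV of each offered stimulus (``ev_left``, ``ev_middle``,
    ``ev_right``), the chosen stimulus's EV (``ev_chosen``) and the trial
    RPE (``rpe``). The replay is pure: identical inputs give identical
    output.
    """
    params = params or AgentParams()
    events = session.events if isinstance(session, Session) else session
    cols = ["ev_left", "ev_middle", "ev_right", "ev_chosen", "rpe"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)
    offered, pos, feedback = _session_arrays(events)
    initial_ids = None
    if isinstance(session, Session):
        initial_ids = [s.stim_id for s in session.schedule if not s.is_novel]
    ev_offered, rpe = replay_values(
        offered,
        pos,
        feedback,
        alpha=params.alpha,
        ev_init_novel=params.ev_init_novel,
        ev_init_start=params.ev_init_start,
        initial_ids=initial_ids,
    )
    out = pd.DataFrame(ev_offered, columns=["ev_left", "ev_middle", "ev_right"])
    out["ev_chosen"] = ev_offered[np.arange(len(events)), pos]
    out["rpe"] = rpe
    out.index = events.index
    return out
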