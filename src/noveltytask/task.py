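"""Novelty Task simulator.

The Novelty Task is a three-armed bandit in which each arm (stimulus) is
presented for 5-9 consecutive trials and then replaced by a novel stimulus,
so the participant must repeatedly decide between exploiting familiar arms
with partially learned values and exploring novel arms of unknown value.
Every stimulus carries its own win probability and win magnitude (a whole
number of cents between $0.00 and $0.30); the participant is paid 10% of
total winnings at the end of the session.

This module owns the task structure: stimulus schedules, reward draws,
on-screen position randomization, and session execution against any agent
implementing the small :class:`Agent` protocol. Learning-model bookkeeping
(expected values, prediction errors) lives in :mod:`noveltytask.rl`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "MAX_MAGNITUDE",
    "RewardSpec",
    "StimulusSpec",
    "SessionConfig",
    "Session",
    "Agent",
    "generate_schedule",
    "session_length",
    "draw_feedback",
    "randomize_positions",
    "run_session",
    "payout",
]

#: Largest win magnitude in dollars ($0.30 per trial).
MAX_MAGNITUDE = 0.30

#: The task always shows three stimuli per trial (left, middle, right).
N_SLOTS = 3

POSITIONS = ("left", "middle", "right")


def _is_whole_cents(x: float) -> bool:
    return abs(x * 100.0 - round(x * 100.0)) < 1e-9


@dataclass(frozen=True)
class RewardSpec:
    """Reward contingency of one bandit arm.

    Parameters
    ----------
    win_prob : float
        Probability in [0, 1] that choosing the arm pays out.
    magnitude : float
        Payout in dollars; a whole number of cents in [0.00, 0.30].
    """

    win_prob: float
    magnitude: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.win_prob <= 1.0:
            raise ValueError(f"win_prob must be in [0, 1], got {self.win_prob}")
        if not 0.0 <= self.magnitude <= MAX_MAGNITUDE:
            raise ValueError(
                f"magnitude must be in [0.00, {MAX_MAGNITUDE}], got {self.magnitude}"
            )
        if not _is_whole_cents(self.magnitude):
            raise ValueError(f"magnitude must be a whole number of cents, got {self.magnitude}")


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus in a session: its reward contingency and its on-screen tenure."""

    stim_id: int
    reward: RewardSpec
    intro_trial: int
    lifetime: int

    def __post_init__(self) -> None:
        if self.intro_trial < 0:
            raise ValueError("intro_trial must be >= 0")
        if self.lifetime < 1:
            raise ValueError("lifetime must be >= 1")

    @property
    def is_novel(self) -> bool:
        """True for replacement stimuli (not among the three initial stimuli)."""
        return self.intro_trial > 0


@dataclass
class SessionConfig:
    """Structural parameters of one Novelty Task session.

    Defaults reproduce the published task design: three on-screen slots,
    40 replacement (novel) stimuli, lifetimes uniform on {5,...,9} trials,
    win magnitudes a whole number of cents drawn from {5,...,30}, win
    probabilities uniform on [0.2, 0.9]. Timing fields only affect the
    event onsets written to the events table (used by the GLM stage).
    """

    n_novel: int = 40
    lifetime_min: int = 5
    lifetime_max: int = 9
    win_prob_range: tuple[float, float] = (0.2, 0.9)
    magnitude_cents_range: tuple[int, int] = (5, 30)
    n_slots: int = N_SLOTS
    trial_duration: float = 3.0
    iti: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_slots != N_SLOTS:
            raise ValueError("the Novelty Task presents exactly 3 stimuli per trial")
        if self.n_novel < 0:
            raise ValueError("n_novel must be >= 0")
        if not 1 <= self.lifetime_min <= self.lifetime_max:
            raise ValueError("need 1 <= lifetime_min <= lifetime_max")
        lo, hi = self.magnitude_cents_range
        if not 0 <= lo <= hi <= round(MAX_MAGNITUDE * 100):
            raise ValueError("magnitude range must lie within [0, 30] cents")


@runtime_checkable
class Agent(Protocol):
    """Minimal interface a decision maker must expose to :func:`run_session`."""

    def register_stimulus(self, stim_id: int, is_initial: bool) -> None:
        """Called once when a stimulus first appears on screen."""

    def choose(self, stim_ids: Sequence[int], rng: np.random.Generator) -> int:
        """Return the chosen stimulus id; must be one of ``stim_ids``."""

    def observe(self, stim_id: int, feedback: float) -> None:
        """Receive the feedback for the chosen stimulus."""


def _draw_unique_reward(
    config: SessionConfig, rng: np.random.Generator, used: set[tuple[float, int]]
) -> RewardSpec:
    lo_p, hi_p = config.win_prob_range
    lo_c, hi_c = config.magnitude_cents_range
    for _ in range(10_000):
        p = float(rng.uniform(lo_p, hi_p))
        cents = int(rng.integers(lo_c, hi_c + 1))
        key = (round(p, 12), cents)
        if key not in used:
            used.add(key)
            return RewardSpec(win_prob=p, magnitude=cents / 100.0)
    raise RuntimeError("could not draw a unique reward spec; range too narrow")


def generate_schedule(
    config: SessionConfig, rng: np.random.Generator
) -> list[StimulusSpec]:
    """Generate the stimulus schedule for one session.

    Three initial stimuli start at trial 0; each time a slot's stimulus
    reaches the end of its lifetime it is replaced by a novel stimulus
    (next replacement always goes to the slot that expires earliest), until
    ``config.n_novel`` replacements have been introduced. Reward
    contingencies are unique per session at the (win_prob, magnitude) level.

    Returns the stimuli in introduction order; the three initial stimuli
    occupy slots 0-2 in list order.
    """
    used: set[tuple[float, int]] = set()
    schedule: list[StimulusSpec] = []
    slot_end = np.empty(config.n_slots, dtype=int)
    for slot in range(config.n_slots):
        lifetime = int(rng.integers(config.lifetime_min, config.lifetime_max + 1))
        schedule.append(
            StimulusSpec(
                stim_id=slot,
                reward=_draw_unique_reward(config, rng, used),
                intro_trial=0,
                lifetime=lifetime,
            )
        )
        slot_end[slot] = lifetime
    for k in range(config.n_novel):
        slot = int(np.argmin(slot_end))  # earliest-expiring slot gets the novel stimulus
        lifetime = int(rng.integers(config.lifetime_min, config.lifetime_max + 1))
        schedule.append(
            StimulusSpec(
                stim_id=config.n_slots + k,
                reward=_draw_unique_reward(config, rng, used),
                intro_trial=int(slot_end[slot]),
                lifetime=lifetime,
            )
        )
        slot_end[slot] += lifetime
    return schedule


def session_length(schedule: Sequence[StimulusSpec]) -> int:
    """Number of trials in the session: the last scheduled lifetime end."""
    return max(s.intro_trial + s.lifetime for s in schedule)


def _slot_timelines(
    schedule: Sequence[StimulusSpec], n_slots: int = N_SLOTS
) -> list[list[StimulusSpec]]:
    """Reconstruct per-slot stimulus sequences from introduction trials."""
    slots: list[list[StimulusSpec]] = [[] for _ in range(n_slots)]
    slot_end = [0] * n_slots
    for stim in sorted(schedule, key=lambda s: (s.intro_trial, s.stim_id)):
        if stim.intro_trial == 0:
            slot = slot_end.index(0)
        else:
            candidates = [i for i in range(n_slots) if slot_end[i] == stim.intro_trial]
            if not candidates:
                raise ValueError(
                    f"stimulus {stim.stim_id} introduced at trial {stim.intro_trial} "
                    "does not continue any slot"
                )
            slot = candidates[0]
        slots[slot].append(stim)
        slot_end[slot] = stim.intro_trial + stim.lifetime
    return slots


def draw_feedback(stim: StimulusSpec, rng: np.random.Generator) -> float:
    """Draw the trial feedback: ``magnitude`` with probability ``win_prob``, else $0."""
    return stim.reward.magnitude if rng.random() < stim.reward.win_prob else 0.0


def randomize_positions(
    offered: Sequence[int], rng: np.random.Generator
) -> tuple[int, int, int]:
    """Uniformly permute the three offered stimuli over (left, middle, right)."""
    if len(offered) != N_SLOTS:
        raise ValueError(f"exactly {N_SLOTS} stimuli must be offered, got {len(offered)}")
    order = rng.permutation(N_SLOTS)
    return tuple(offered[i] for i in order)  # type: ignore[return-value]


@dataclass
class Session:
    """A completed session: the trial-level events table plus bookkeeping.

    ``events`` is a BIDS-events-like DataFrame with one row per trial:
    onset, duration, trial_index, stim_left/middle/right, pres_left/middle/
    right (how many times each on-screen stimulus has been presented,
    including this trial), chosen, feedback. Model columns (ev_chosen, rpe,
    explore) are appended by :mod:`noveltytask.inference`.
    """

    events: pd.DataFrame
    schedule: list[StimulusSpec]
    config: SessionConfig
    total_winnings: float

    @property
    def n_trials(self) -> int:
        return len(self.events)

    @property
    def novel_ids(self) -> frozenset[int]:
        return frozenset(s.stim_id for s in self.schedule if s.is_novel)

    def payout(self) -> float:
        return payout(self.total_winnings)


def run_session(
    agent: Agent,
    config: SessionConfig,
    rng: np.random.Generator,
    schedule: Sequence[StimulusSpec] | None = None,
) -> Session:
    """Run one full session of the Novelty Task with the given agent.

    The agent is registered with each stimulus when it first appears, asked
    to choose among the three on-screen stimulus ids each trial, and shown
    the feedback for its choice. An agent returning a stimulus that is not
    on screen is a hard error.
    """
    if schedule is None:
        schedule = generate_schedule(config, rng)
    schedule = list(schedule)
    by_id = {s.stim_id: s for s in schedule}
    slots = _slot_timelines(schedule, config.n_slots)
    n_trials = session_length(schedule)

    # Per-slot pointer into its stimulus sequence; the final stimulus on a
    # slot stays on screen through the end of the session.
    pointers = [0] * config.n_slots
    pres_count: dict[int, int] = {}
    registered: set[int] = set()
    rows = []
    total = 0.0
    for t in range(n_trials):
        offered: list[int] = []
        for slot in range(config.n_slots):
            seq = slots[slot]
            while (
                pointers[slot] + 1 < len(seq)
                and seq[pointers[slot] + 1].intro_trial <= t
            ):
                pointers[slot] += 1
            offered.append(seq[pointers[slot]].stim_id)
        for sid in offered:
            if sid not in registered:
                agent.register_stimulus(sid, is_initial=not by_id[sid].is_novel)
                registered.add(sid)
            pres_count[sid] = pres_count.get(sid, 0) + 1
        left, middle, right = randomize_positions(offered, rng)
        chosen = agent.choose((left, middle, right), rng)
        if chosen not in offered:
            raise RuntimeError(
                f"agent chose stimulus {chosen}, not among offered {offered} on trial {t}"
            )
        feedback = draw_feedback(by_id[chosen], rng)
        agent.observe(chosen, feedback)
        total += feedback
        rows.append(
            {
                "onset": t * (config.trial_duration + config.iti),
                "duration": config.trial_duration,
                "trial_index": t,
                "stim_left": left,
                "stim_middle": middle,
                "stim_right": right,
                "pres_left": pres_count[left],
                "pres_middle": pres_count[middle],
                "pres_right": pres_count[right],
                "chosen": chosen,
                "feedback": feedback,
            }
        )
    events = pd.DataFrame(rows)
    return Session(
        events=events, schedule=schedule, config=config, total_winnings=round(total, 10)
    )


def payout(total_winnings: float) -> float:
    """Participant payment: 10% of total winnings, rounded half-up to cents."""
    if total_winnings < 0:
        raise ValueError("total winnings cannot be negative")
    amount = Decimal(str(total_winnings)) * Decimal("0.10")
    return float(amount.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
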