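"""Synthetic cohort generator.

The study population is adolescents grouped by early-life-stress exposure
from Childhood Trauma Questionnaire (CTQ) subscale scores against the
published clinical cutoffs: abuse is "high" if any of emotional abuse > 8,
physical abuse > 7, sexual abuse > 5; neglect is "high" if emotional
neglect > 9 or physical neglect > 7. Crossing the two indicators yields
four groups (abuse+neglect, abuse only, neglect only, control); a subject
below every cutoff but carrying a psychopathology diagnosis matches no
group (the healthy-control definition excludes them) and is marked
EXCLUDED.

Because no participant data are deposited, this module fabricates cohorts
with the statistical structure the downstream analysis assumes: CTQ
profiles consistent with each group, Rescorla-Wagner agents with
subject-level (alpha, beta) variation, full simulated task sessions, a
novelty-propensity covariate computed exactly as for real data, and
per-condition RPE-coupling values in which a Neglect-by-Explore effect of
chosen standardized size d is injected (coupling on Explore trials reduced
by d standard deviations for neglect-exposed subjects, Non-Explore coupling
identical across groups).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glm as neuro_glm
from .inference import novelty_indifference, novelty_propensity
from .rl import AgentParams, SoftmaxAgent, compute_trajectories
from .task import Session, SessionConfig, run_session

__all__ = [
    "ABUSE_CUTOFFS",
    "NEGLECT_CUTOFFS",
    "CTQProfile",
    "Group",
    "CouplingConfig",
    "SubjectRecord",
    "assign_group",
    "sample_ctq",
    "sample_couplings",
    "generate_cohort",
    "cohort_frame",
]

#: CTQ manual cutoffs: a subscale score strictly above its cutoff counts as exposure.
ABUSE_CUTOFFS = {"emotional_abuse": 8, "physical_abuse": 7, "sexual_abuse": 5}
NEGLECT_CUTOFFS = {"emotional_neglect": 9, "physical_neglect": 7}

_SCORE_MIN, _SCORE_MAX = 5, 25


@dataclass(frozen=True)
class CTQProfile:
    """Five CTQ subscale scores, each an integer in [5, 25]."""

    emotional_abuse: int
    physical_abuse: int
    sexual_abuse: int
    emotional_neglect: int
    physical_neglect: int

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (_SCORE_MIN <= value <= _SCORE_MAX):
                raise ValueError(f"{name} = {value} outside the CTQ range [5, 25]")
            if value != int(value):
                raise ValueError(f"{name} must be an integer score")

    def as_dict(self) -> dict[str, int]:
        return {
            "emotional_abuse": self.emotional_abuse,
            "physical_abuse": self.physical_abuse,
            "sexual_abuse": self.sexual_abuse,
            "emotional_neglect": self.emotional_neglect,
            "physical_neglect": self.physical_neglect,
        }

    @property
    def abuse_high(self) -> bool:
        return any(self.as_dict()[k] > c for k, c in ABUSE_CUTOFFS.items())

    @property
    def neglect_high(self) -> bool:
        return any(self.as_dict()[k] > c for k, c in NEGLECT_CUTOFFS.items())


class Group(enum.Enum):
    ABUSE_AND_NEGLECT = "abuse_and_neglect"
    ABUSE_ONLY = "abuse_only"
    NEGLECT_ONLY = "neglect_only"
    CONTROL = "control"
    #: below every cutoff but with psychopathology: matches no study group
    EXCLUDED = "excluded"

    @property
    def abuse(self) -> bool:
        return self in (Group.ABUSE_AND_NEGLECT, Group.ABUSE_ONLY)

    @property
    def neglect(self) -> bool:
        return self in (Group.ABUSE_AND_NEGLECT, Group.NEGLECT_ONLY)


def assign_group(ctq: CTQProfile, has_psychopathology: bool = False) -> Group:
    """Four-group assignment from CTQ cutoffs.

    Healthy controls must be below every abuse and neglect cutoff *and*
    free of psychopathology; a below-cutoff subject with psychopathology is
    EXCLUDED rather than assigned to a group.
    """
    abuse, neglect = ctq.abuse_high, ctq.neglect_high
    if abuse and neglect:
        return Group.ABUSE_AND_NEGLECT
    if abuse:
        return Group.ABUSE_ONLY
    if neglect:
        return Group.NEGLECT_ONLY
    return Group.EXCLUDED if has_psychopathology else Group.CONTROL


# Proposal means per (group-relevance): scales that must exceed their cutoff
# are proposed near cutoff + 4; scales that must stay below near the floor.
_LOW_MEAN, _LOW_SD = 6.0, 1.5
_HIGH_OFFSET, _HIGH_SD = 4.0, 3.0


def sample_ctq(group: Group, rng: np.random.Generator, max_tries: int = 10_000) -> CTQProfile:
    """Rejection-sample an integer CTQ profile consistent with ``group``.

    Subscales are proposed independently from discretized truncated normals
    whose means depend on whether the group requires exposure on that
    dimension, then rejected until :func:`assign_group` returns ``group``.
    """
    if group is Group.EXCLUDED:
        raise ValueError("EXCLUDED is a sentinel, not a samplable group")
    cutoffs = {**ABUSE_CUTOFFS, **NEGLECT_CUTOFFS}
    abuse_scales = list(ABUSE_CUTOFFS)
    neglect_scales = list(NEGLECT_CUTOFFS)
    for _ in range(max_tries):
        scores = {}
        for name, cutoff in cutoffs.items():
            high_dim = group.abuse if name in abuse_scales else group.neglect
            mean = cutoff + _HIGH_OFFSET if high_dim else _LOW_MEAN
            sd = _HIGH_SD if high_dim else _LOW_SD
            scores[name] = int(np.clip(round(rng.normal(mean, sd)), _SCORE_MIN, _SCORE_MAX))
        profile = CTQProfile(**scores)
        if assign_group(profile, has_psychopathology=False) is group:
            return profile
    raise RuntimeError(f"could not sample a CTQ profile for {group} in {max_tries} tries")


@dataclass
class CouplingConfig:
    """Generative model of per-subject RPE-coupling values (signal per dollar).

    True couplings are Gaussian around condition means; the Neglect-by-
    Explore effect of standardized size ``d_neglect_explore`` subtracts
    ``d * sd`` from the Explore coupling of neglect-exposed subjects, while
    Non-Explore coupling is identical across groups. Estimated couplings
    add Gaussian estimation noise of ``noise_sd`` (the simplest stand-in
    for per-subject GLM error) unless the full GLM route is used.
    Defaults give the Explore condition the larger baseline coupling,
    mirroring RPE augmentation for novel stimuli in healthy subjects.
    """

    mean_explore: float = 1.2
    mean_nonexplore: float = 0.8
    sd: float = 1.0
    noise_sd: float = 0.5
    d_neglect_explore: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.noise_sd < 0:
            raise ValueError("sd must be > 0 and noise_sd >= 0")
        if not np.isfinite(self.d_neglect_explore):
            raise ValueError("effect size must be finite")


@dataclass
class SubjectRecord:
    """One synthetic participant."""

    subject_id: int
    ctq: CTQProfile
    group: Group
    has_psychopathology: bool
    params: AgentParams
    session: Session | None = None
    np_score: float = np.nan
    indifference_ev: float = np.nan
    b_explore_true: float = np.nan
    b_nonexplore_true: float = np.nan
    b_explore_est: float = np.nan
    b_nonexplore_est: float = np.nan


#: Named preset reproducing the study's total sample of 178 adolescents.
PRESET_178 = {
    Group.ABUSE_AND_NEGLECT: 45,
    Group.ABUSE_ONLY: 45,
    Group.NEGLECT_ONLY: 44,
    Group.CONTROL: 44,
}

_STUDY_GROUPS = [Group.ABUSE_AND_NEGLECT, Group.ABUSE_ONLY, Group.NEGLECT_ONLY, Group.CONTROL]


def _draw_couplings(
    neglect: np.ndarray, coupling: CouplingConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = len(neglect)
    shift = coupling.d_neglect_explore * coupling.sd * neglect.astype(float)
    b_explore = rng.normal(coupling.mean_explore - shift, coupling.sd, size=n)
    b_nonexplore = rng.normal(coupling.mean_nonexplore, coupling.sd, size=n)
    return b_explore, b_nonexplore


def sample_couplings(
    n_per_cell: int,
    coupling: CouplingConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fast cohort of per-subject couplings only (no sessions).

    Returns one row per subject with abuse/neglect indicators balanced
    across the four cells, a standard-normal NP covariate, true couplings
    and noisy estimates. Used for calibration and power studies of the
    group analysis where simulating full sessions adds nothing.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    abuse = np.repeat([True, True, False, False], n_per_cell)
    neglect = np.repeat([True, False, True, False], n_per_cell)
    n = len(abuse)
    b_explore, b_nonexplore = _draw_couplings(neglect, coupling, rng)
    noise = coupling.noise_sd
    return pd.DataFrame(
        {
            "abuse": abuse,
            "neglect": neglect,
            "np": rng.normal(size=n),
            "b_explore_true": b_explore,
            "b_nonexplore_true": b_nonexplore,
            "b_explore": b_explore + rng.normal(0, noise, n),
            "b_nonexplore": b_nonexplore + rng.normal(0, noise, n),
        }
    )


def _sample_agent_params(rng: np.random.Generator) -> AgentParams:
    # alpha ~ Beta centered on the population learning rate 0.692
    # (concentration 30), beta ~ logNormal around the generative 15.
    kappa = 30.0
    alpha = float(np.clip(rng.beta(0.692 * kappa, (1 - 0.692) * kappa), 0.02, 0.98))
    beta = float(rng.lognormal(np.log(15.0), 0.25))
    return AgentParams(alpha=alpha, beta=beta)


def generate_cohort(
    n_per_group: int | None = None,
    group_sizes: dict[Group, int] | None = None,
    coupling: CouplingConfig | None = None,
    session_config: SessionConfig | None = None,
    rng: np.random.Generator | None = None,
    estimate_via: str = "noise",
    glm_config: "neuro_glm.GlmConfig | None" = None,
) -> list[SubjectRecord]:
    """Generate a full synthetic cohort.

    Each subject receives a CTQ profile and group, agent parameters, a full
    simulated Novelty Task session, a novelty-propensity (NP) score computed
    from that session by the same calibration applied to real data, and
    true/estimated RPE couplings. ``estimate_via`` selects how estimated
    couplings are produced: ``"noise"`` adds Gaussian estimation error to
    the true couplings; ``"glm"`` simulates a BOLD-like time series from the
    subject's own RPE trajectory and estimates couplings by OLS
    (:mod:`noveltytask.glm`).

    With no size arguments the named 178-subject preset (45/45/44/44) is
    used; ``n_per_group`` gives equal cells.
    """
    if rng is None:
        rng = np.random.default_rng()
    if coupling is None:
        coupling = CouplingConfig()
    if session_config is None:
        session_config = SessionConfig()
    if estimate_via not in ("noise", "glm"):
        raise ValueError("estimate_via must be 'noise' or 'glm'")
    if group_sizes is None:
        if n_per_group is not None:
            group_sizes = {g: n_per_group for g in _STUDY_GROUPS}
        else:
            group_sizes = dict(PRESET_178)
    subjects: list[SubjectRecord] = []
    sid = 0
    for group in _STUDY_GROUPS:
        for _ in range(group_sizes.get(group, 0)):
            ctq = sample_ctq(group, rng)
            params = _sample_agent_params(rng)
            agent = SoftmaxAgent(params)
            session = run_session(agent, session_config, rng)
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    ctq=ctq,
                    group=group,
                    has_psychopathology=bool(
                        group is not Group.CONTROL and rng.random() < 0.5
                    ),
                    params=params,
                    session=session,
                )
            )
            sid += 1

    # novelty propensity: per-subject indifference EV, z-scored across the cohort
    import warnings as _warnings

    indiff = []
    for s in subjects:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            cal = novelty_indifference(s.session)
        s.indifference_ev = cal.indifference_ev
        indiff.append(cal.indifference_ev)
    nps = novelty_propensity(indiff)
    for s, z in zip(subjects, nps):
        s.np_score = float(z)

    neglect = np.array([s.group.neglect for s in subjects])
    b_explore, b_nonexplore = _draw_couplings(neglect, coupling, rng)
    for s, be, bn in zip(subjects, b_explore, b_nonexplore):
        s.b_explore_true = float(be)
        s.b_nonexplore_true = float(bn)
        if estimate_via == "noise":
            s.b_explore_est = float(be + rng.normal(0, coupling.noise_sd))
            s.b_nonexplore_est = float(bn + rng.normal(0, coupling.noise_sd))
        else:
            est = neuro_glm.estimate_couplings(
                s.session,
                b_explore=float(be),
                b_nonexplore=float(bn),
                rng=rng,
                config=glm_config,
                params=s.params,
            )
            s.b_explore_est = est.b_explore
            s.b_nonexplore_est = est.b_nonexplore
    return subjects


def cohort_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject: CTQ scores, group, NP, agent params, couplings."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        row.update({f"ctq_{k}": v for k, v in s.ctq.as_dict().items()})
        row.update(
            {
                "group": s.group.value,
                "abuse": s.group.abuse,
                "neglect": s.group.neglect,
                "has_psychopathology": s.has_psychopathology,
                "alpha": s.params.alpha,
                "beta": s.params.beta,
                "indifference_ev": s.indifference_ev,
                "np": s.np_score,
                "b_explore_true": s.b_explore_true,
                "b_nonexplore_true": s.b_nonexplore_true,
                "b_explore": s.b_explore_est,
                "b_nonexplore": s.b_nonexplore_est,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
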