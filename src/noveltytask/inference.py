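"""Fitting the learning model to choice data.

Three subject-level quantities are estimated from a session:

* **Rescorla-Wagner parameters.** :class:`RescorlaWagnerModel` is built from
  an events table and fitted by maximum likelihood over the learning rate
  alpha in [0.01, 0.99] and inverse temperature beta in [0, 50]. Because
  the EV trajectories depend on alpha only, the negative log-likelihood is
  profiled: for each alpha the replayed EVs are reused while beta is
  optimized in one dimension, and alpha itself is optimized by bounded
  scalar minimization seeded from a fixed start grid. The procedure is
  fully deterministic given the data.

* **Explore labels.** A trial is an Explore trial iff the chosen stimulus
  is a novel (replacement) stimulus on its second presentation; every other
  trial — including choosing a novel stimulus on its first or third
  presentation — is Non-Explore.

* **Novelty calibration / novelty propensity (NP).** Over trials where a
  novel stimulus is at its second presentation, the indicator
  "chose the novel stimulus" is regressed (logistic) on the EV of the best
  non-novel alternative on screen. The indifference value is the EV at
  which the fitted probability is 0.5, i.e. -intercept/slope, clamped to
  the feedback range [0, 0.30]. NP is the cohort z-score of the
  indifference value: higher NP means the subject demands a better known
  alternative before forgoing the novel option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .rl import NOVEL_EV_INIT, AgentParams, compute_trajectories, replay_values, _session_arrays
from .task import Session

__all__ = [
    "FitResult",
    "NoveltyCalibration",
    "RescorlaWagnerModel",
    "RescorlaWagnerResults",
    "negative_log_likelihood",
    "fit_mle",
    "label_explore",
    "fit_indifference",
    "novelty_indifference",
    "novelty_propensity",
    "augment_events",
]

ALPHA_BOUNDS = (0.01, 0.99)
BETA_BOUNDS = (0.0, 50.0)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimates for one subject's session."""

    alpha_hat: float
    beta_hat: float
    neg_log_likelihood: float
    converged: bool
    n_trials: int

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_hat < 1.0:
            raise ValueError("alpha_hat must lie in (0, 1)")
        if self.beta_hat < 0:
            raise ValueError("beta_hat must be >= 0")
        if self.neg_log_likelihood < -1e-9:
            raise ValueError("negative log-likelihood must be >= 0")


@dataclass(frozen=True)
class NoveltyCalibration:
    """Logistic calibration of the novel-stimulus value for one subject."""

    intercept: float
    slope: float
    indifference_ev: float
    n_second_appearance_trials: int
    quality_flag: str = "ok"  # "ok", "separation", "degenerate_slope"


class RescorlaWagnerModel:
    """Rescorla-Wagner / softmax choice model for one session's choice data.

    Parameters
    ----------
    events : DataFrame or Session
        Trial-level events with columns stim_left/middle/right, chosen,
        feedback (the layout written by :func:`noveltytask.task.run_session`).
    ev_init_novel, ev_init_start : float
        Initial EVs for replacement and trial-0 stimuli (dollars).
    initial_ids : sequence of int, optional
        Explicit ids of the trial-0 stimuli; default: stimuli offered on
        the first trial.

    Examples
    --------
    >>> res = RescorlaWagnerModel(session.events).fit()
    >>> res.alpha, res.beta, res.nll  # doctest: +SKIP
    """

    def __init__(
        self,
        events: pd.DataFrame | Session,
        ev_init_novel: float = NOVEL_EV_INIT,
        ev_init_start: float | None = None,
        initial_ids=None,
    ) -> None:
        if isinstance(events, Session):
            if initial_ids is None:
                initial_ids = [s.stim_id for s in events.schedule if not s.is_novel]
            events = events.events
        self.events = events
        self.ev_init_novel = ev_init_novel
        self.ev_init_start = ev_init_novel if ev_init_start is None else ev_init_start
        self._offered, self._pos, self._feedback = _session_arrays(events)
        self._initial_ids = initial_ids
        self.n_trials = len(events)

    # -- likelihood ---------------------------------------------------------

    def _ev_offered(self, alpha: float) -> np.ndarray:
        ev, _ = replay_values(
            self._offered,
            self._pos,
            self._feedback,
            alpha=alpha,
            ev_init_novel=self.ev_init_novel,
            ev_init_start=self.ev_init_start,
            initial_ids=self._initial_ids,
        )
        return ev

    @staticmethod
    def _nll_beta(ev_offered: np.ndarray, pos: np.ndarray, beta: float) -> float:
        z = beta * ev_offered
        lse = special.logsumexp(z, axis=1)
        ll = z[np.arange(len(pos)), pos] - lse
        return float(-ll.sum())

    def nloglike(self, alpha: float, beta: float) -> float:
        """Negative log-likelihood of the observed choices under (alpha, beta)."""
        if not np.isfinite(alpha) or not np.isfinite(beta):
            raise ValueError("alpha and beta must be finite")
        if not 0.0 < alpha <= 1.0 or beta < 0:
            raise ValueError("alpha must be in (0, 1] and beta >= 0")
        return self._nll_beta(self._ev_offered(alpha), self._pos, beta)

    def loglike(self, alpha: float, beta: float) -> float:
        return -self.nloglike(alpha, beta)

    # -- fitting ------------------------------------------------------------

    def _profile_beta(self, ev_offered: np.ndarray, n_starts: int = 7) -> tuple[float, float]:
        """Optimal beta (and its NLL) for fixed EV trajectories."""
        grid = np.linspace(BETA_BOUNDS[0], BETA_BOUNDS[1], n_starts)
        vals = [self._nll_beta(ev_offered, self._pos, b) for b in grid]
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, n_starts - 1)]
        if lo == hi:  # degenerate grid
            return float(grid[k]), float(vals[k])
        res = optimize.minimize_scalar(
            lambda b: self._nll_beta(ev_offered, self._pos, b),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if res.fun <= vals[k]:
            return float(res.x), float(res.fun)
        return float(grid[k]), float(vals[k])

    def fit(self, fix_alpha: float | None = None, min_trials_warn: int = 30) -> "RescorlaWagnerResults":
        """Maximum-likelihood fit over alpha in [0.01, 0.99], beta in [0, 50].

        ``fix_alpha`` pins the learning rate (e.g. at the population value
        0.692) and estimates beta alone. Fewer than ``min_trials_warn``
        trials triggers a warning: two-parameter fits on short sessions are
        poorly identified.
        """
        if self.n_trials < min_trials_warn:
            warnings.warn(
                f"fitting on {self.n_trials} trials; estimates are unreliable below "
                f"{min_trials_warn} trials",
                stacklevel=2,
            )
        converged = True
        if fix_alpha is not None:
            if not ALPHA_BOUNDS[0] <= fix_alpha <= ALPHA_BOUNDS[1]:
                raise ValueError(f"fix_alpha must be within {ALPHA_BOUNDS}")
            beta_hat, nll = self._profile_beta(self._ev_offered(fix_alpha))
            alpha_hat = float(fix_alpha)
        else:

            def profiled(alpha: float) -> float:
                return self._profile_beta(self._ev_offered(alpha))[1]

            agrid = np.linspace(ALPHA_BOUNDS[0], ALPHA_BOUNDS[1], 9)
            avals = [profiled(a) for a in agrid]
            k = int(np.argmin(avals))
            lo, hi = agrid[max(k - 1, 0)], agrid[min(k + 1, len(agrid) - 1)]
            res = optimize.minimize_scalar(
                profiled, bounds=(lo, hi), method="bounded", options={"xatol": 1e-5}
            )
            if res.fun <= avals[k]:
                alpha_hat = float(res.x)
                converged = bool(res.success)
            else:  # scalar refinement failed to beat the grid; keep best grid point
                alpha_hat = float(agrid[k])
                converged = False
            beta_hat, nll = self._profile_beta(self._ev_offered(alpha_hat))
        result = FitResult(
            alpha_hat=min(max(alpha_hat, 1e-9), 1 - 1e-9),
            beta_hat=beta_hat,
            neg_log_likelihood=max(nll, 0.0),
            converged=converged,
            n_trials=self.n_trials,
        )
        return RescorlaWagnerResults(self, result, alpha_fixed=fix_alpha is not None)


class RescorlaWagnerResults:
    """MLE results for a :class:`RescorlaWagnerModel`.

    Exposes point estimates, standard errors from the numerical Hessian of
    the negative log-likelihood at the optimum (delta method; not available
    when a parameter sits on a bound), and a text ``summary()``.
    """

    def __init__(self, model: RescorlaWagnerModel, result: FitResult, alpha_fixed: bool) -> None:
        self.model = model
        self.result = result
        self.alpha_fixed = alpha_fixed
        self._bse: tuple[float, float] | None = None

    @property
    def alpha(self) -> float:
        return self.result.alpha_hat

    @property
    def beta(self) -> float:
        return self.result.beta_hat

    @property
    def nll(self) -> float:
        return self.result.neg_log_likelihood

    @property
    def converged(self) -> bool:
        return self.result.converged

    def _hessian(self, h_a: float = 1e-4, h_b: float = 1e-3) -> np.ndarray:
        f = self.model.nloglike
        a, b = self.alpha, self.beta
        a = min(max(a, ALPHA_BOUNDS[0] + 2 * h_a), ALPHA_BOUNDS[1] - 2 * h_a)
        b = max(b, 2 * h_b)
        faa = (f(a + h_a, b) - 2 * f(a, b) + f(a - h_a, b)) / h_a**2
        fbb = (f(a, b + h_b) - 2 * f(a, b) + f(a, b - h_b)) / h_b**2
        fab = (
            f(a + h_a, b + h_b) - f(a + h_a, b - h_b) - f(a - h_a, b + h_b) + f(a - h_a, b - h_b)
        ) / (4 * h_a * h_b)
        return np.array([[faa, fab], [fab, fbb]])

    @property
    def bse(self) -> dict[str, float]:
        """Asymptotic standard errors of (alpha, beta) from the observed information."""
        if self._bse is None:
            try:
                cov = np.linalg.inv(self._hessian())
                var = np.clip(np.diag(cov), 0, np.inf)
                self._bse = (float(np.sqrt(var[0])), float(np.sqrt(var[1])))
            except np.linalg.LinAlgError:
                self._bse = (float("nan"), float("nan"))
        return {"alpha": self._bse[0], "beta": self._bse[1]}

    def summary(self) -> str:
        bse = self.bse
        lines = [
            "Rescorla-Wagner model fit (maximum likelihood)",
            "=" * 48,
            f"n trials            {self.result.n_trials:>10d}",
            f"neg. log-likelihood {self.nll:>10.3f}",
            f"converged           {str(self.converged):>10s}",
            "-" * 48,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
            f"{'alpha':<8}{self.alpha:>12.4f}"
            + (f"{'(fixed)':>12}" if self.alpha_fixed else f"{bse['alpha']:>12.4f}"),
            f"{'beta':<8}{self.beta:>12.4f}{bse['beta']:>12.4f}",
        ]
        return "\n".join(lines)

    def trajectories(self) -> pd.DataFrame:
        """EV/RPE trajectories replayed at the fitted parameters."""
        params = AgentParams(
            alpha=self.alpha,
            beta=max(self.beta, 0.0),
            ev_init_novel=self.model.ev_init_novel,
            ev_init_start=self.model.ev_init_start,
        )
        return compute_trajectories(self.model.events, params)

    def plot_learning_curve(self, ax=None):
        """Plot EV of the chosen stimulus and RPE across trials."""
        import matplotlib.pyplot as plt

        traj = self.trajectories()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(traj.index, traj["ev_chosen"], label="EV (chosen)")
        ax.plot(traj.index, traj["rpe"], label="RPE", alpha=0.7)
        ax.set_xlabel("trial")
        ax.set_ylabel("dollars")
        ax.legend()
        return ax


def negative_log_likelihood(
    events: pd.DataFrame | Session,
    alpha: float,
    beta: float,
    ev_init_novel: float = NOVEL_EV_INIT,
) -> float:
    """Choice NLL under (alpha, beta); convenience wrapper around the model."""
    return RescorlaWagnerModel(events, ev_init_novel=ev_init_novel).nloglike(alpha, beta)


def fit_mle(
    events: pd.DataFrame | Session,
    fix_alpha: float | None = None,
    ev_init_novel: float = NOVEL_EV_INIT,
) -> FitResult:
    """Fit (alpha, beta) by MLE; returns the plain :class:`FitResult`."""
    return RescorlaWagnerModel(events, ev_init_novel=ev_init_novel).fit(fix_alpha=fix_alpha).result


# -- explore labels ----------------------------------------------------------


def _novel_ids(events: pd.DataFrame, novel_ids=None) -> frozenset[int]:
    if novel_ids is not None:
        return frozenset(int(s) for s in novel_ids)
    first = events.iloc[0]
    initial = {int(first["stim_left"]), int(first["stim_middle"]), int(first["stim_right"])}
    all_ids = set(
        np.unique(events[["stim_left", "stim_middle", "stim_right"]].to_numpy())
    )
    return frozenset(int(s) for s in all_ids - initial)


def label_explore(events: pd.DataFrame, novel_ids=None) -> pd.DataFrame:
    """Attach the ``explore`` column.

    A trial is Explore iff the chosen stimulus is a novel (replacement)
    stimulus at its second presentation; all other trials are Non-Explore.
    ``novel_ids`` defaults to every stimulus not on screen on the first
    trial. Returns a copy; the input is not modified.
    """
    events = events.copy()
    if len(events) == 0:
        events["explore"] = pd.Series(dtype=bool)
        return events
    novel = _novel_ids(events, novel_ids)
    offered = events[["stim_left", "stim_middle", "stim_right"]].to_numpy(dtype=int)
    pres = events[["pres_left", "pres_middle", "pres_right"]].to_numpy(dtype=int)
    chosen = events["chosen"].to_numpy(dtype=int)
    pos = np.argmax(offered == chosen[:, None], axis=1)
    pres_chosen = pres[np.arange(len(events)), pos]
    events["explore"] = (pres_chosen == 2) & np.isin(chosen, list(novel))
    return events


# -- novelty calibration -----------------------------------------------------


def fit_indifference(
    ev_best: np.ndarray, chose_novel: np.ndarray, clamp: tuple[float, float] = (0.0, 0.30)
) -> NoveltyCalibration:
    """Logistic regression of choose-novel on the best-alternative EV.

    Fits P(choose novel) = sigmoid(intercept + slope * EV_best) and returns
    the indifference point -intercept/slope (fitted probability 0.5),
    clamped to ``clamp``. Complete separation or a non-negative slope
    yields a clamped boundary value and a quality flag.
    """
    ev_best = np.asarray(ev_best, dtype=float)
    y = np.asarray(chose_novel, dtype=float)
    n = len(y)
    if n == 0 or len(ev_best) != n:
        raise ValueError("ev_best and chose_novel must be equal-length and non-empty")
    if y.min() == y.max():  # one outcome only: separation by definition
        value = clamp[1] if y[0] == 1.0 else clamp[0]
        return NoveltyCalibration(np.nan, np.nan, value, n, quality_flag="separation")
    import statsmodels.api as sm

    X = sm.add_constant(ev_best)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        separated = not np.isfinite(fit.llf) or np.abs(fit.params).max() > 1e4
    except Exception:
        separated = True
        intercept = slope = float("nan")
    if separated:
        # deterministic choosers: indifference at the empirical switch point
        boundary = clamp[1] if y[ev_best.argmax()] else clamp[0]
        hi = ev_best[y == 1]
        lo = ev_best[y == 0]
        if len(hi) and len(lo) and hi.max() < lo.min():
            value = float((hi.max() + lo.min()) / 2)
            return NoveltyCalibration(np.nan, np.nan, value, n, quality_flag="separation")
        return NoveltyCalibration(np.nan, np.nan, boundary, n, quality_flag="separation")
    if slope >= 0:
        # choosing novel should become *less* likely as the alternative improves
        value = clamp[1] if np.mean(y) >= 0.5 else clamp[0]
        return NoveltyCalibration(intercept, slope, value, n, quality_flag="degenerate_slope")
    value = float(np.clip(-intercept / slope, clamp[0], clamp[1]))
    return NoveltyCalibration(intercept, slope, value, n)


def novelty_indifference(
    session: Session | pd.DataFrame,
    params: AgentParams | None = None,
    novel_ids=None,
    min_trials: int = 10,
) -> NoveltyCalibration:
    """Calibrate the subjective value of novelty from one session.

    Considers trials on which a novel stimulus is at its second
    presentation; the regressor is the replayed EV of the best on-screen
    alternative (the third option is ignored), the outcome is whether a
    second-presentation novel stimulus was chosen. EV replay uses
    ``params`` (default: fixed population learning rate).
    """
    params = params or AgentParams()
    if isinstance(session, Session):
        events = session.events
        novel = session.novel_ids if novel_ids is None else frozenset(novel_ids)
    else:
        events = session
        novel = _novel_ids(events, novel_ids)
    if len(events) == 0:
        raise ValueError("empty session")
    traj = compute_trajectories(session, params)
    offered = events[["stim_left", "stim_middle", "stim_right"]].to_numpy(dtype=int)
    pres = events[["pres_left", "pres_middle", "pres_right"]].to_numpy(dtype=int)
    chosen = events["chosen"].to_numpy(dtype=int)
    evs = traj[["ev_left", "ev_middle", "ev_right"]].to_numpy(dtype=float)

    is_novel = np.isin(offered, list(novel))
    second_novel = is_novel & (pres == 2)
    has_opportunity = second_novel.any(axis=1) & (~second_novel).any(axis=1)
    ev_best = np.where(second_novel, -np.inf, evs).max(axis=1)
    pos = np.argmax(offered == chosen[:, None], axis=1)
    chose_novel = second_novel[np.arange(len(events)), pos]

    mask = has_opportunity
    n_opp = int(mask.sum())
    if n_opp < min_trials:
        warnings.warn(
            f"only {n_opp} second-appearance trials; calibration is unreliable",
            stacklevel=2,
        )
    if n_opp == 0:
        return NoveltyCalibration(np.nan, np.nan, np.nan, 0, quality_flag="no_trials")
    return fit_indifference(ev_best[mask], chose_novel[mask])


def novelty_propensity(indifference_evs) -> np.ndarray:
    """Z-score indifference values across a cohort to form the NP covariate.

    Higher NP = the subject assigns greater subjective value to novelty.
    A cohort needs at least two subjects and non-zero variance.
    """
    x = np.asarray(indifference_evs, dtype=float)
    if x.size < 2:
        raise ValueError("novelty propensity needs a cohort of >= 2 subjects")
    if np.isclose(x.std(), 0):
        raise ValueError("zero variance in indifference values; NP undefined")
    return stats.zscore(x)


def augment_events(
    session: Session | pd.DataFrame,
    params: AgentParams | None = None,
    novel_ids=None,
) -> pd.DataFrame:
    """Events table with model columns appended: ev_chosen, rpe, explore."""
    events = session.events if isinstance(session, Session) else session
    if isinstance(session, Session) and novel_ids is None:
        novel_ids = session.novel_ids
    traj = compute_trajectories(session, params)
    out = label_explore(events, novel_ids)
    out["ev_chosen"] = traj["ev_chosen"] if len(events) else pd.Series(dtype=float)
    out["rpe"] = traj["rpe"] if len(events) else pd.Series(dtype=float)
    return out
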