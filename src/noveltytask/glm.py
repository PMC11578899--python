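"""Individual-level parametric-modulation GLM on an ROI-style signal.

The subject-level analysis couples the trial-by-trial reward prediction
error to a BOLD-like time series. The design has a baseline event regressor
(every trial, unit weight), an RPE modulator restricted to Explore trials
and an RPE modulator restricted to Non-Explore trials; modulator weights
are mean-centered within condition *before* convolution with the canonical
double-gamma hemodynamic response function, so the modulators measure
signal coupling to RPE over and above the mean event response. The unit of
analysis is a single extracted time series; there is no volumetric or
NIfTI handling. Fitted coupling coefficients are in signal units per
dollar of RPE and feed the group-level ANCOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GlmConfig",
    "DesignMatrix",
    "BetaEstimates",
    "canonical_hrf",
    "build_design",
    "simulate_bold",
    "fit_glm",
    "estimate_couplings",
]

_HRF_PEAK_DELAY = 6.0  # shape parameter of the response gamma
_HRF_UNDER_DELAY = 16.0  # shape parameter of the undershoot gamma
_HRF_UNDER_RATIO = 6.0
_HRF_SUPPORT = 32.0  # seconds; effectively zero beyond this

# unit-peak normalization constant, computed once on a fine grid
_t = np.arange(0, _HRF_SUPPORT, 0.01)
_PEAK_NORM = float(
    (stats.gamma.pdf(_t, _HRF_PEAK_DELAY) - stats.gamma.pdf(_t, _HRF_UNDER_DELAY) / _HRF_UNDER_RATIO).max()
)
del _t


def canonical_hrf(t) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Difference of two gamma densities (response peaking near 5 s, undershoot
    near 15 s, back to ~0 by 32 s), evaluated at time(s) ``t`` in seconds.
    Zero for t <= 0.
    """
    t = np.asarray(t, dtype=float)
    h = (
        stats.gamma.pdf(t, _HRF_PEAK_DELAY)
        - stats.gamma.pdf(t, _HRF_UNDER_DELAY) / _HRF_UNDER_RATIO
    ) / _PEAK_NORM
    return np.where(t > 0, h, 0.0)


@dataclass
class GlmConfig:
    """Timing of the simulated acquisition."""

    tr: float = 2.5
    oversample_dt: float = 0.1
    drift_order: int = 0
    noise_sd: float = 1.0
    ar1: float = 0.0

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.oversample_dt <= 0:
            raise ValueError("tr and oversample_dt must be positive")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")


@dataclass
class DesignMatrix:
    """GLM design sampled at TR resolution.

    ``frame`` columns: ``events`` (baseline event regressor),
    ``rpe_explore`` and ``rpe_nonexplore`` (mean-centered RPE modulators
    convolved with the HRF), ``intercept``, and optional polynomial drift
    columns.
    """

    frame: pd.DataFrame
    tr: float

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_scans(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class BetaEstimates:
    """OLS coupling estimates for one subject."""

    b_explore: float
    b_nonexplore: float
    se_explore: float
    se_nonexplore: float
    residual_var: float
    r_squared: float
    params: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.b_explore) and np.isfinite(self.b_nonexplore)):
            raise ValueError("coupling estimates must be finite")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")


def _boxcar_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    weights: np.ndarray,
    n_scans: int,
    tr: float,
    dt: float,
) -> np.ndarray:
    """Weighted boxcar train convolved with the HRF, sampled at TR."""
    t_end = n_scans * tr
    n_fine = int(np.ceil(t_end / dt)) + 1
    fine = np.zeros(n_fine)
    for onset, dur, w in zip(onsets, durations, weights):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        fine[i0:min(i1, n_fine)] += w
    hrf = canonical_hrf(np.arange(0, _HRF_SUPPORT + dt, dt))
    conv = np.convolve(fine, hrf)[:n_fine] * dt
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return conv[np.minimum(scan_idx, n_fine - 1)]


def build_design(
    events: pd.DataFrame,
    tr: float = 2.5,
    n_scans: int | None = None,
    drift_order: int = 0,
    dt: float = 0.1,
) -> DesignMatrix:
    """Build the parametric-modulation design from labeled events.

    ``events`` needs columns onset, duration, rpe and a boolean explore
    column (see :func:`noveltytask.inference.augment_events`). RPE weights
    are mean-centered within each condition before convolution. ``n_scans``
    defaults to covering the last event plus the HRF support.
    """
    required = {"onset", "duration", "rpe", "explore"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float)
    rpe = events["rpe"].to_numpy(dtype=float)
    explore = events["explore"].to_numpy(dtype=bool)
    if n_scans is None:
        n_scans = int(np.ceil(((onsets + durations).max() + _HRF_SUPPORT) / tr))
    t_end = n_scans * tr
    if ((onsets + durations) > t_end).any():
        raise ValueError("event extends beyond the scan window")

    def centered(mask: np.ndarray) -> np.ndarray:
        w = np.zeros_like(rpe)
        if mask.any():
            w[mask] = rpe[mask] - rpe[mask].mean()
        return w

    cols = {
        "events": _boxcar_regressor(onsets, durations, np.ones_like(rpe), n_scans, tr, dt),
        "rpe_explore": _boxcar_regressor(onsets, durations, centered(explore), n_scans, tr, dt),
        "rpe_nonexplore": _boxcar_regressor(
            onsets, durations, centered(~explore), n_scans, tr, dt
        ),
        "intercept": np.ones(n_scans),
    }
    if drift_order > 0:
        tt = np.linspace(-1, 1, n_scans)
        for k in range(1, drift_order + 1):
            cols[f"drift_{k}"] = tt**k
    return DesignMatrix(frame=pd.DataFrame(cols), tr=tr)


def simulate_bold(
    design: DesignMatrix,
    betas: dict[str, float],
    noise_sd: float,
    rng: np.random.Generator,
    ar1: float = 0.0,
) -> np.ndarray:
    """Simulate the ROI signal: design x betas plus (optionally AR(1)) noise.

    ``betas`` maps design column names to true coefficients; unnamed
    columns get coefficient 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    unknown = set(betas) - set(design.columns)
    if unknown:
        raise ValueError(f"betas for unknown design columns: {sorted(unknown)}")
    b = np.array([betas.get(c, 0.0) for c in design.columns])
    signal = design.matrix @ b
    if noise_sd > 0:
        eps = rng.normal(0, noise_sd, design.n_scans)
        if ar1 > 0:
            for i in range(1, len(eps)):
                eps[i] += ar1 * eps[i - 1]
            eps *= np.sqrt(1 - ar1**2)  # keep marginal sd = noise_sd
        signal = signal + eps
    return signal


def fit_glm(signal: np.ndarray, design: DesignMatrix) -> BetaEstimates:
    """Ordinary least squares fit of the signal on the design.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    X = design.matrix
    y = np.asarray(signal, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("signal length does not match the design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # columns whose removal does not reduce rank are in the collinear set
        bad = [
            design.columns[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: {bad}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    idx = {c: j for j, c in enumerate(design.columns)}
    return BetaEstimates(
        b_explore=float(beta[idx["rpe_explore"]]),
        b_nonexplore=float(beta[idx["rpe_nonexplore"]]),
        se_explore=float(se[idx["rpe_explore"]]),
        se_nonexplore=float(se[idx["rpe_nonexplore"]]),
        residual_var=sigma2,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        params={c: float(b) for c, b in zip(design.columns, beta)},
    )


def estimate_couplings(
    session,
    b_explore: float,
    b_nonexplore: float,
    rng: np.random.Generator,
    config: GlmConfig | None = None,
    params=None,
    event_amplitude: float = 1.0,
) -> BetaEstimates:
    """End-to-end per-subject estimate: events -> design -> signal -> OLS.

    Builds the subject's design from their own session (RPE replayed at the
    population learning rate unless ``params`` is given), simulates a noisy
    signal with the supplied true couplings, and refits by OLS. This is the
    package's stand-in for the RPE-modulated BOLD response of one subject.
    """
    from .inference import augment_events

    config = config or GlmConfig()
    events = augment_events(session, params=params)
    design = build_design(events, tr=config.tr, drift_order=config.drift_order,
                          dt=config.oversample_dt)
    signal = simulate_bold(
        design,
        {
            "events": event_amplitude,
            "rpe_explore": b_explore,
            "rpe_nonexplore": b_nonexplore,
        },
        noise_sd=config.noise_sd,
        rng=rng,
        ar1=config.ar1,
    )
    return fit_glm(signal, design)
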