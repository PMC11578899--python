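"""Group-level 2(Abuse) x 2(Neglect) x 2(Explore) ANCOVA with NP covariate.

The within-subject Explore factor has two levels, so the mixed design
decomposes exactly into two between-subject OLS models:

* the subject mean M = (b_explore + b_nonexplore) / 2 carries every
  between-subject effect (Abuse, Neglect, Abuse x Neglect, NP and, by
  default, the NP-by-group interactions);
* the within-subject difference D = b_explore - b_nonexplore carries the
  Explore main effect (the intercept of the D model) and every
  Explore-by-X interaction.

Factors are effect-coded (high = +1, low = -1) and sums of squares are
Type III (each single-df term tested by the increase in residual SS when
its column is dropped from the full model), matching the multivariate-
model convention of standard neuroimaging group tools. Effect sizes are
partial eta squared, SS_effect / (SS_effect + SS_error).

Cluster-extent thresholding of a voxelwise p-value grid (binarize at the
initial p, keep face-connected components of at least k voxels) is provided
as the desk-scale analog of the map-level correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "BETWEEN_EFFECTS",
    "ExploreAncova",
    "ExploreAncovaResults",
    "AncovaTable",
    "ClusterMap",
    "run_ancova",
    "posthoc_tests",
    "partial_eta_squared",
    "cluster_threshold",
]

#: term name -> factors multiplied into its design column
_TERMS_FULL = {
    "abuse": ("A",),
    "neglect": ("N",),
    "abuse:neglect": ("A", "N"),
    "np": ("P",),
    "abuse:np": ("A", "P"),
    "neglect:np": ("N", "P"),
    "abuse:neglect:np": ("A", "N", "P"),
}
_TERMS_BASIC = {k: v for k, v in _TERMS_FULL.items() if "P" not in v or k == "np"}

BETWEEN_EFFECTS = tuple(_TERMS_FULL)


@dataclass
class AncovaTable:
    """F, dfs, p and partial eta squared for every effect in the design."""

    table: pd.DataFrame

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]

    def pvalue(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial eta squared: SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0:
        return 0.0
    return ss_effect / (ss_effect + ss_error)


def _type3_anova(
    y: np.ndarray, X: np.ndarray, names: list[str], test_intercept: str | None = None
) -> list[dict]:
    """Single-df Type-III tests by drop-one-column model comparison."""
    n, p = X.shape
    df2 = n - p
    if df2 <= 0:
        raise ValueError(
            f"no residual degrees of freedom (n={n}, parameters={p}); "
            "reduce the model or add subjects"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    rss_full = float(((y - X @ beta) ** 2).sum())
    rows = []
    for j, name in enumerate(names):
        if name == "intercept" and test_intercept is None:
            continue
        Xr = np.delete(X, j, axis=1)
        br, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
        ss = float(((y - Xr @ br) ** 2).sum()) - rss_full
        ss = max(ss, 0.0)
        ms_err = rss_full / df2
        F = ss / ms_err if ms_err > 0 else np.inf
        label = test_intercept if name == "intercept" else name
        rows.append(
            {
                "effect": label,
                "F": F,
                "df1": 1,
                "df2": df2,
                "p": float(stats.f.sf(F, 1, df2)),
                "partial_eta_sq": partial_eta_squared(ss, rss_full),
                "ss_effect": ss,
                "ss_error": rss_full,
            }
        )
    return rows


class ExploreAncova:
    """Mixed 2x2x2 ANCOVA model of per-subject RPE couplings.

    Parameters
    ----------
    data : DataFrame
        One row per subject with columns ``b_explore``, ``b_nonexplore``
        (condition-wise coupling estimates), boolean ``abuse`` and
        ``neglect`` exposure indicators, and the ``np`` covariate.
    include_np_interactions : bool
        Model NP-by-group interaction terms (default True, matching a
        multivariate group model that crosses the covariate with every
        factor). Requires enough subjects for 8 between-subject parameters.

    Examples
    --------
    >>> res = ExploreAncova(cohort_df).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, include_np_interactions: bool = True) -> None:
        required = {"b_explore", "b_nonexplore", "abuse", "neglect", "np"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data missing columns: {sorted(missing)}")
        if data[["b_explore", "b_nonexplore", "np"]].isna().any().any():
            raise ValueError("couplings and NP must be finite")
        counts = data.groupby(["abuse", "neglect"]).size()
        if len(counts) < 4 or (counts < 2).any():
            raise ValueError("every Abuse x Neglect cell needs at least 2 subjects")
        if np.isclose(float(np.asarray(data["np"], dtype=float).std()), 0.0):
            raise ValueError("NP covariate has zero variance")
        self.data = data.reset_index(drop=True)
        self.include_np_interactions = include_np_interactions
        self.terms = dict(_TERMS_FULL if include_np_interactions else _TERMS_BASIC)

    @classmethod
    def from_cohort(cls, subjects, **kwargs) -> "ExploreAncova":
        """Build from a list of SubjectRecord (see :mod:`noveltytask.cohort`)."""
        from .cohort import cohort_frame

        return cls(cohort_frame(subjects), **kwargs)

    def _design(self) -> tuple[np.ndarray, list[str]]:
        d = self.data
        A = np.where(d["abuse"].to_numpy(dtype=bool), 1.0, -1.0)
        N = np.where(d["neglect"].to_numpy(dtype=bool), 1.0, -1.0)
        P = d["np"].to_numpy(dtype=float)
        base = {"A": A, "N": N, "P": P}
        cols = [np.ones(len(d))]
        names = ["intercept"]
        for name, factors in self.terms.items():
            col = np.ones(len(d))
            for f in factors:
                col = col * base[f]
            cols.append(col)
            names.append(name)
        return np.column_stack(cols), names

    def fit(self) -> "ExploreAncovaResults":
        """Run both sub-models and assemble the full effect table."""
        X, names = self._design()
        d = self.data
        M = (d["b_explore"].to_numpy(float) + d["b_nonexplore"].to_numpy(float)) / 2.0
        D = d["b_explore"].to_numpy(float) - d["b_nonexplore"].to_numpy(float)
        rows = _type3_anova(M, X, names)
        within = _type3_anova(D, X, names, test_intercept="explore")
        for r in within:
            if r["effect"] != "explore":
                r["effect"] = f"explore:{r['effect']}"
        rows += within
        table = pd.DataFrame(rows).set_index("effect")
        return ExploreAncovaResults(self, AncovaTable(table))


class ExploreAncovaResults:
    """Fitted ANCOVA: effect table, post-hoc t tests, summary."""

    def __init__(self, model: ExploreAncova, anova: AncovaTable) -> None:
        self.model = model
        self.anova = anova

    @property
    def table(self) -> pd.DataFrame:
        return self.anova.table

    def pvalue(self, effect: str) -> float:
        return self.anova.pvalue(effect)

    def posthoc(self, effect: str) -> pd.DataFrame:
        return posthoc_tests(self.model.data, effect)

    def summary(self) -> str:
        lines = [
            "2 (Abuse) x 2 (Neglect) x 2 (Explore) ANCOVA, NP covariate",
            "Type III sums of squares, effect coding",
            "=" * 66,
            f"{'effect':<28}{'F':>9}{'df':>8}{'p':>10}{'pEta^2':>9}",
            "-" * 66,
        ]
        for effect, r in self.table.iterrows():
            lines.append(
                f"{effect:<28}{r['F']:>9.3f}{int(r['df1']):>4},{int(r['df2']):<4}"
                f"{r['p']:>9.4g}{r['partial_eta_sq']:>9.4f}"
            )
        return "\n".join(lines)

    def plot_coupling_means(self, ax=None):
        """Group x condition coupling means with standard-error bars."""
        import matplotlib.pyplot as plt

        d = self.model.data
        if ax is None:
            _, ax = plt.subplots()
        for cond, col in (("Explore", "b_explore"), ("Non-Explore", "b_nonexplore")):
            means = d.groupby("neglect")[col].mean()
            sems = d.groupby("neglect")[col].sem()
            ax.errorbar(
                ["low neglect", "high neglect"],
                [means[False], means[True]],
                yerr=[sems[False], sems[True]],
                marker="o",
                label=cond,
            )
        ax.set_ylabel("RPE coupling (signal / $)")
        ax.legend()
        return ax


def run_ancova(data: pd.DataFrame, include_np_interactions: bool = True) -> AncovaTable:
    """Fit the mixed ANCOVA; functional wrapper around :class:`ExploreAncova`."""
    return ExploreAncova(data, include_np_interactions=include_np_interactions).fit().anova


def _two_sample_t(high: np.ndarray, low: np.ndarray) -> dict:
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each group needs at least 2 subjects for a t test")
    t, p = stats.ttest_ind(high, low)
    return {
        "t": float(t),  # positive t = exposed group higher
        "df": len(high) + len(low) - 2,
        "p": float(p),
        "mean_high": float(np.mean(high)),
        "mean_low": float(np.mean(low)),
    }


def posthoc_tests(data: pd.DataFrame, effect: str) -> pd.DataFrame:
    """Post-hoc two-sample t tests for a main effect or an Explore interaction.

    For a main effect (``"abuse"`` or ``"neglect"``), the exposed and
    unexposed groups are compared on the condition-averaged coupling. For an
    Explore interaction (``"explore:abuse"`` / ``"explore:neglect"``), the
    groups are compared within each condition separately. t is signed
    exposed-minus-unexposed, so a lower mean in the exposed group gives a
    negative t.
    """
    effect = effect.lower()
    factor = effect.split(":")[-1]
    if factor not in ("abuse", "neglect"):
        raise ValueError(f"no post-hoc contrast defined for effect {effect!r}")
    grp = data[factor].to_numpy(dtype=bool)
    rows = []
    if effect.startswith("explore:"):
        for cond, col in (("explore", "b_explore"), ("nonexplore", "b_nonexplore")):
            y = data[col].to_numpy(dtype=float)
            rows.append({"contrast": f"{factor} ({cond})", **_two_sample_t(y[grp], y[~grp])})
    else:
        y = (
            data["b_explore"].to_numpy(dtype=float)
            + data["b_nonexplore"].to_numpy(dtype=float)
        ) / 2.0
        rows.append({"contrast": f"{factor} (mean)", **_two_sample_t(y[grp], y[~grp])})
    return pd.DataFrame(rows).set_index("contrast")


@dataclass
class Cluster:
    size: int
    peak_coord: tuple[int, ...]
    peak_stat: float
    label: int


@dataclass
class ClusterMap:
    """Surviving clusters after extent thresholding."""

    labels: np.ndarray
    clusters: list[Cluster]
    p_initial: float
    k_min: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_threshold(
    p_grid: np.ndarray,
    p_initial: float = 0.001,
    k_min: int = 17,
    stat_grid: np.ndarray | None = None,
) -> ClusterMap:
    """Extent-threshold a voxelwise p-value grid.

    Voxels with p < ``p_initial`` are binarized and grouped into
    face-connected components (no diagonal adjacency); components smaller
    than ``k_min`` voxels are discarded. ``stat_grid`` (same shape)
    supplies peak statistics; otherwise the peak is the most significant
    voxel's -log10 p.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if not 0 < p_initial < 1:
        raise ValueError("p_initial must be in (0, 1)")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if stat_grid is not None:
        stat_grid = np.asarray(stat_grid, dtype=float)
        if stat_grid.shape != p_grid.shape:
            raise ValueError("stat_grid shape must match p_grid")
    mask = p_grid < p_initial
    structure = ndimage.generate_binary_structure(p_grid.ndim, 1)  # faces only
    labeled, n_comp = ndimage.label(mask, structure=structure)
    out_labels = np.zeros_like(labeled)
    clusters: list[Cluster] = []
    next_label = 1
    for comp in range(1, n_comp + 1):
        voxels = np.argwhere(labeled == comp)
        if len(voxels) < k_min:
            continue
        if stat_grid is not None:
            vals = stat_grid[tuple(voxels.T)]
            peak_idx = int(np.argmax(np.abs(vals)))
            peak_stat = float(vals[peak_idx])
        else:
            vals = -np.log10(np.maximum(p_grid[tuple(voxels.T)], 1e-300))
            peak_idx = int(np.argmax(vals))
            peak_stat = float(vals[peak_idx])
        coord = tuple(int(c) for c in voxels[peak_idx])
        out_labels[labeled == comp] = next_label
        clusters.append(
            Cluster(size=len(voxels), peak_coord=coord, peak_stat=peak_stat, label=next_label)
        )
        next_label += 1
    return ClusterMap(labels=out_labels, clusters=clusters, p_initial=p_initial, k_min=k_min)
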