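"""Per-guild temporal dynamics: random-intercept LMM daily trajectories,
LMM-based differential abundance with BH control, dynamic-time-warping
trajectory clustering, and CUSUM change-point detection.

The trajectory model is ``log(abundance + pseudocount) ~ day + (1 | participant)``
with day as a categorical fixed effect.  Two codings are offered: the
intervention-window coding collapses the whole habitual-diet phase into the
reference level, so the intercept is the mean habitual-diet log abundance and
each intervention day's trajectory value is intercept + day coefficient; the
full-series coding keeps every day with day 0 as reference, producing the
28-day daily series consumed by the time-delayed association screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import silhouette_score
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import statsmodels.formula.api as smf

from .design import NORMAL, StudyDesign
from .stats import bh_adjust


@dataclass
class TrajectoryFit:
    """One guild's fitted daily trajectory."""

    feature: str
    intercept: float
    day_effects: pd.Series        # beta_d per non-reference day
    day_pvalues: pd.Series        # Wald p per non-reference day
    sigma2_participant: float
    sigma2_residual: float
    converged: bool

    def trajectory(self) -> pd.Series:
        """T(d) = intercept + beta_d over the modelled days."""
        return (self.intercept + self.day_effects).rename(self.feature)


def default_pseudocount(values: np.ndarray) -> float:
    """Half the minimum nonzero value — scale-aware log offset."""
    nz = values[values > 0]
    if nz.size == 0:
        raise ValueError("all-zero abundance series")
    return float(nz.min()) / 2.0


def _series_frame(series: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Normalise (participant, day)-indexed values to long columns."""
    if isinstance(series, pd.DataFrame):
        series = series.iloc[:, 0]
    df = series.rename("value").reset_index()
    if not {"participant", "day"} <= set(df.columns):
        raise ValueError("series must be indexed by (participant, day)")
    return df


def fit_trajectory(
    series: pd.Series,
    design: StudyDesign | None = None,
    reference: str = "normal",
    pseudocount: float | None = None,
    feature: str = "feature",
) -> TrajectoryFit:
    """Fit the random-intercept daily-trajectory LMM for one feature.

    ``series`` holds one feature's nonnegative values indexed by
    (participant, day).  With ``reference='normal'`` all habitual-diet days
    share the reference level; with ``reference='day0'`` every day is its
    own level and day 0 is the reference (full 28-day series).  REML fit;
    on non-convergence falls back to per-day fixed-effect means with a
    warning.
    """
    df = _series_frame(series)
    if df["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants for a random intercept")
    if (df["value"] < 0).any():
        raise ValueError("abundances must be nonnegative")
    if pseudocount is None:
        pseudocount = (default_pseudocount(df["value"].to_numpy())
                       if (df["value"] == 0).any() else 0.0)
    df["logy"] = np.log(df["value"] + pseudocount)

    if reference == "normal":
        if design is None:
            design = StudyDesign()
        df["day_level"] = [
            "ref" if design.phase_of_day[d] == NORMAL else f"d{d:02d}"
            for d in df["day"]
        ]
    elif reference == "day0":
        ref_day = df["day"].min()
        df["day_level"] = [
            "ref" if d == ref_day else f"d{d:02d}" for d in df["day"]
        ]
    else:
        raise ValueError("reference must be 'normal' or 'day0'")

    model = smf.mixedlm(
        "logy ~ C(day_level, Treatment('ref'))", df, groups=df["participant"]
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True)
            if not fit.converged:
                raise RuntimeError("REML did not converge")
            params = fit.fe_params
            pvals = fit.pvalues[params.index]
            sigma2_b = float(np.squeeze(fit.cov_re))
            sigma2_e = float(fit.scale)
        except Exception:
            converged = False
            warnings.warn(f"{feature}: LMM did not converge; "
                          "falling back to per-day fixed-effect means")
            means = df.groupby("day_level")["logy"].mean()
            params = pd.Series(
                {"Intercept": means["ref"],
                 **{f"C(day_level, Treatment('ref'))[T.{lvl}]": means[lvl] - means["ref"]
                    for lvl in means.index if lvl != "ref"}}
            )
            pvals = pd.Series(np.nan, index=params.index)
            sigma2_b, sigma2_e = np.nan, np.nan

    def level_day(name: str) -> int:
        return int(name.split("[T.d")[1].rstrip("]"))

    eff = {level_day(k): v for k, v in params.items() if "[T.d" in k}
    pv = {level_day(k): v for k, v in pvals.items() if "[T.d" in k}
    days = sorted(eff)
    return TrajectoryFit(
        feature=feature,
        intercept=float(params["Intercept"]),
        day_effects=pd.Series([eff[d] for d in days], index=days),
        day_pvalues=pd.Series([pv[d] for d in days], index=days),
        sigma2_participant=sigma2_b,
        sigma2_residual=sigma2_e,
        converged=converged,
    )


def daily_series(
    table: pd.DataFrame,
    design: StudyDesign | None = None,
    reference: str = "day0",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """LMM-estimated daily series for every column of a feature table.

    ``table`` is (participant, day) x feature.  Returns day x feature
    population-level trajectory estimates (intercept + day effects, with
    the reference day carrying the intercept alone).
    """
    out = {}
    for col in table.columns:
        fit = fit_trajectory(table[col], design=design, reference=reference,
                             pseudocount=pseudocount, feature=col)
        traj = fit.trajectory()
        if reference == "day0":
            ref_day = int(table.index.get_level_values("day").min())
            traj = pd.concat([pd.Series({ref_day: fit.intercept}), traj]).sort_index()
        out[col] = traj
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# differential abundance


def differential_abundance(
    cag_abundance: pd.DataFrame,
    design: StudyDesign | None = None,
    contrast: str = "endpoint",
    fdr_alpha: float = 0.05,
    bias_correction: bool = True,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """LMM differential-abundance calls per CAG with BH control.

    ``contrast='endpoint'`` compares the last intervention day against the
    last habitual-diet day with a participant random intercept;
    ``contrast='whole'`` compares the whole intervention window against the
    habitual phase with participant and day random effects.  An optional
    compositional bias correction recenters the effect estimates on their
    kernel-density mode across CAGs before recomputing p-values
    (LinDA-like; disabled below 3 CAGs).
    """
    if design is None:
        design = StudyDesign()
    if contrast == "endpoint":
        d_ref = max(design.days_in_phase(NORMAL))
        d_alt = max(design.days)
    elif contrast != "whole":
        raise ValueError("contrast must be 'endpoint' or 'whole'")

    rows = []
    for cag in cag_abundance.columns:
        df = _series_frame(cag_abundance[cag])
        pc = pseudocount
        if pc is None:
            pc = (default_pseudocount(df["value"].to_numpy())
                  if (df["value"] == 0).any() else 0.0)
        df["logy"] = np.log(df["value"] + pc)
        if contrast == "endpoint":
            df = df[df["day"].isin([d_ref, d_alt])].copy()
            df["treat"] = (df["day"] == d_alt).astype(float)
        else:
            df["treat"] = [
                float(design.phase_of_day[d] != NORMAL) for d in df["day"]
            ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                if contrast == "whole":
                    model = smf.mixedlm(
                        "logy ~ treat", df, groups=np.ones(len(df)),
                        re_formula="0",
                        vc_formula={"participant": "0 + C(participant)",
                                    "day": "0 + C(day)"},
                    )
                else:
                    model = smf.mixedlm("logy ~ treat", df, groups=df["participant"])
                fit = model.fit(reml=True)
                effect = float(fit.fe_params["treat"])
                se = float(fit.bse_fe["treat"])
            except Exception:
                means = df.groupby("treat")["logy"].mean()
                effect = float(means.get(1.0, np.nan) - means.get(0.0, np.nan))
                se = np.nan
        rows.append({"cag": cag, "effect": effect, "se": se})
    table = pd.DataFrame(rows).set_index("cag")

    if bias_correction and len(table) >= 3:
        effects = table["effect"].to_numpy()
        kde = sps.gaussian_kde(effects)
        grid = np.linspace(effects.min(), effects.max(), 512)
        mode = float(grid[np.argmax(kde(grid))])
        table["effect_corrected"] = table["effect"] - mode
    else:
        table["effect_corrected"] = table["effect"]

    z = np.where(
        table["se"] > 0, table["effect_corrected"] / table["se"], 0.0
    )
    p = 2.0 * sps.norm.sf(np.abs(z))
    # degenerate zero-variance, zero-effect series: p = 1 by convention
    p = np.where(
        (table["se"].isna() | (table["se"] == 0)) & (table["effect_corrected"] == 0),
        1.0, p,
    )
    table["p"] = p
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["direction"] = np.where(
        table["q"] < fdr_alpha,
        np.where(table["effect_corrected"] > 0, "increase", "decrease"),
        "unchanged",
    )
    return table


# ---------------------------------------------------------------------------
# dynamic time warping


def dtw_distance(t1, t2) -> float:
    """Classic DTW accumulated cost, symmetric2 step pattern, |a - b| cost.

    Diagonal steps count the local cost twice; no window constraint.
    """
    a = np.asarray(t1, dtype=float)
    b = np.asarray(t2, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN in DTW input")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[1, 1] = cost[0, 0]          # starting cell carries weight 1
    for i in range(1, n + 1):
        c = cost[i - 1]
        for j in range(1, m + 1):
            if i == 1 and j == 1:
                continue
            acc[i, j] = min(
                acc[i - 1, j] + c[j - 1],
                acc[i, j - 1] + c[j - 1],
                acc[i - 1, j - 1] + 2.0 * c[j - 1],
            )
    return float(acc[n, m])


def dtw_matrix(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Pairwise DTW distances between trajectory columns."""
    cols = list(trajectories.columns)
    n = len(cols)
    d = np.zeros((n, n))
    arrays = [trajectories[c].to_numpy() for c in cols]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(arrays[i], arrays[j])
    return pd.DataFrame(d, index=cols, columns=cols)


@dataclass
class TemporalClusters:
    """DTW + Ward.D2 clustering of guild trajectories."""

    dtw: pd.DataFrame
    cluster_of_cag: dict[str, str]
    chosen_k: int
    silhouettes: dict[int, float]
    linkage: np.ndarray | None = None


def cluster_trajectories(
    trajectories: pd.DataFrame,
    k_range: range | None = None,
    relative_to_normal: bool = True,
    design: StudyDesign | None = None,
) -> TemporalClusters:
    """Cluster guild trajectories by DTW distance and Ward.D2 linkage.

    By default each trajectory is first expressed relative to its
    habitual-diet mean (so clusters capture response shape, not level).
    k is chosen by maximal mean silhouette width over ``k_range``, ties to
    the smaller k.
    """
    if trajectories.shape[1] < 3:
        raise ValueError("need at least 3 trajectories to cluster")
    traj = trajectories.copy()
    if relative_to_normal:
        if design is None:
            design = StudyDesign()
        normal_days = [d for d in design.days_in_phase(NORMAL)
                       if d in traj.index]
        if normal_days:
            traj = traj - traj.loc[normal_days].mean()
        interv = [d for d in traj.index if design.phase_of_day.get(d) != NORMAL]
        if interv:
            traj = traj.loc[interv]

    dtw = dtw_matrix(traj)
    d = dtw.to_numpy()
    n = d.shape[0]
    off = d[np.triu_indices(n, k=1)]
    if np.allclose(off, off[0]):
        # constant distance matrix: k undefined, everything in one cluster
        return TemporalClusters(
            dtw, {c: "tc1" for c in dtw.columns}, 1, {}, None
        )
    if k_range is None:
        k_range = range(2, min(9, n))
    linkage = hierarchy.linkage(squareform(d, checks=False), method="ward")
    sils: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = hierarchy.fcluster(linkage, k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sils[k] = float(silhouette_score(d, labels, metric="precomputed"))
        labels_by_k[k] = labels
    if not sils:
        return TemporalClusters(dtw, {c: "tc1" for c in dtw.columns}, 1, {}, linkage)
    best = max(sorted(sils), key=lambda k: (sils[k], -k))
    labels = labels_by_k[best]
    cluster_of_cag = {c: f"tc{l}" for c, l in zip(dtw.columns, labels)}
    return TemporalClusters(dtw, cluster_of_cag, best, sils, linkage)


# ---------------------------------------------------------------------------
# change-point detection


@dataclass
class ChangePoint:
    series_id: str
    location: int | None     # index of the first point of the second segment
    statistic: float
    p: float


def _cusum_stat(x: np.ndarray) -> tuple[int, float]:
    """Max standardized two-segment mean difference over interior splits.

    The mean difference at split k is scaled by sqrt(k(n-k)/n) and divided
    by the pooled within-segment standard deviation (a two-sample
    t-statistic), so a genuine level shift stands out against splits that
    leave a shift inside one segment.
    """
    n = x.size
    k = np.arange(1, n)
    csum = np.cumsum(x)
    csum2 = np.cumsum(x ** 2)
    total, total2 = csum[-1], csum2[-1]
    mean1 = csum[:-1] / k
    mean2 = (total - csum[:-1]) / (n - k)
    ss_within = (csum2[:-1] - k * mean1 ** 2) + (
        (total2 - csum2[:-1]) - (n - k) * mean2 ** 2
    )
    sigma = np.sqrt(np.maximum(ss_within, 0.0) / max(n - 2, 1))
    diff = np.abs(mean1 - mean2) * np.sqrt(k * (n - k) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(sigma > 0, diff / sigma,
                        np.where(diff > 0, np.inf, 0.0))
    best = int(np.argmax(stat))
    return best + 1, float(stat[best])


def detect_changepoint(
    series,
    n_perm: int = 999,
    seed: int | None = None,
    series_id: str = "series",
    null: str = "permutation",
) -> ChangePoint:
    """Single change-point detection by a t-standardized CUSUM scan.

    The statistic is the maximal standardized difference of segment means
    over interior split points.  The default null shuffles the series
    (exchangeability — appropriate for the weakly autocorrelated daily
    residuals this scan is applied to); ``null='circular'`` uses random
    circular shifts instead, preserving autocorrelation at the price of a
    much coarser attainable p-value (only n - 1 distinct rotations exist).
    Constant series yield no change-point and p = 1.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    if np.allclose(x, x[0]):
        return ChangePoint(series_id, None, 0.0, 1.0)
    loc, stat = _cusum_stat(x)
    rng = np.random.default_rng(seed)
    if null == "circular":
        shifts = rng.integers(1, n, size=n_perm)
        distinct = np.unique(shifts)
        stat_of_shift = {s: _cusum_stat(np.roll(x, s))[1] for s in distinct}
        perm_stats = np.array([stat_of_shift[s] for s in shifts])
    elif null == "permutation":
        perm_stats = np.array(
            [_cusum_stat(rng.permutation(x))[1] for _ in range(n_perm)]
        )
    else:
        raise ValueError("null must be 'permutation' or 'circular'")
    p = (1.0 + (perm_stats >= stat).sum()) / (n_perm + 1.0)
    return ChangePoint(series_id, loc, stat, p)
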