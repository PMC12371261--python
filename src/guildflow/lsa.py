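"""Delay-limited local similarity analysis between time series.

Local similarity analysis (LSA) scores the strongest contiguously
co-varying stretch of two equal-length series, allowing the second series
to lag or lead the first by up to ``max_delay`` steps.  Series are first
rank-normalised to normal quantiles ("percentileZ").  The dynamic program

    P(i, j) = max(0, P(i-1, j-1) + x_i * y_j)      (positive association)
    N(i, j) = max(0, N(i-1, j-1) - x_i * y_j)      (negative association)

over cells with |j - i| <= max_delay reduces, along each diagonal
d = j - i, to the maximal contiguous subarray sum of the lagged products
x_i * y_{i+d} (clamped at zero), which is how it is computed here.  The
local similarity score is the overall maximum divided by the series
length; its sign records whether the positive or negative accumulator won
and the delay is the diagonal offset of the winning cell.  A positive
delay means the first series (the guild) precedes the second (the
metabolite).

Significance is available by explicit permutation or by a theoretical tail
approximation: under the null the partial sums of products of two
independent standardized series behave like a random walk, and the
max-over-windows absolute partial sum converges (after sqrt(n) scaling) to
the range of a Brownian motion on [0, 1], whose tail is

    P(R > r) = 8 * sum_{k>=1} (-1)^(k-1) * k * Phi_bar(k r).

Independent diagonals are combined as 1 - (1 - p_single)^(2 max_delay + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust


@dataclass
class NormalizedSeries:
    """Rank -> normal-quantile ("percentileZ") transformed series."""

    values: np.ndarray
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.values.size


def normalize_percentile_z(series) -> NormalizedSeries:
    """Map ranks r_i (average ties) to normal quantiles Phi^-1(r_i / (n+1))."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.size < 4:
        warnings.warn("fewer than 4 observations; normal quantiles are coarse")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in series")
    if np.allclose(x, x[0]):
        return NormalizedSeries(np.zeros(x.size), degenerate=True)
    ranks = sps.rankdata(x, method="average")
    return NormalizedSeries(sps.norm.ppf(ranks / (x.size + 1.0)))


def _max_subarray(values: np.ndarray) -> tuple[float, int]:
    """Kadane maximum (zero-clamped) contiguous sum and its end index."""
    best, cur, best_end = 0.0, 0.0, -1
    for i, v in enumerate(values):
        cur = max(0.0, cur + v)
        if cur > best:
            best, best_end = cur, i
    return best, best_end


def local_similarity(
    x: NormalizedSeries | np.ndarray,
    y: NormalizedSeries | np.ndarray,
    max_delay: int = 3,
) -> tuple[float, int, int]:
    """Local similarity (score, delay, sign) between two normalized series.

    Ties between cells are broken toward the smaller |delay|, then toward
    the positive accumulator, making results deterministic.
    """
    xv = x.values if isinstance(x, NormalizedSeries) else np.asarray(x, float)
    yv = y.values if isinstance(y, NormalizedSeries) else np.asarray(y, float)
    if xv.size != yv.size:
        raise ValueError("series lengths differ")
    if max_delay < 0:
        raise ValueError("max_delay must be >= 0")
    n = xv.size
    best = (0.0, 0, 1)
    for d in sorted(range(-max_delay, max_delay + 1), key=lambda d: (abs(d), -d)):
        if d >= 0:
            prod = xv[: n - d] * yv[d:]
        else:
            prod = xv[-d:] * yv[: n + d]
        for sign, vals in ((1, prod), (-1, -prod)):
            s, _ = _max_subarray(vals)
            if s > best[0] + 1e-15:
                best = (s, d, sign)
    score, delay, sign = best
    return score / n, delay, sign


def _null_scores(
    x: np.ndarray, y: np.ndarray, max_delay: int, perm_idx: np.ndarray
) -> np.ndarray:
    """Unsigned null LS scores under shuffling of x, vectorised over perms.

    ``perm_idx`` is an (n_perm, n) array of permutation indices; the
    zero-clamped running maximum (Kadane) is advanced across all
    permutations at once for each diagonal and sign.
    """
    n = x.size
    xp = x[perm_idx]
    best = np.zeros(perm_idx.shape[0])
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            prod = xp[:, : n - d] * y[d:]
        else:
            prod = xp[:, -d:] * y[: n + d]
        for vals in (prod, -prod):
            cur = np.zeros(perm_idx.shape[0])
            mx = np.zeros(perm_idx.shape[0])
            for i in range(vals.shape[1]):
                cur = np.maximum(0.0, cur + vals[:, i])
                np.maximum(mx, cur, out=mx)
            np.maximum(best, mx, out=best)
    return best / n


def brownian_range_sf(r: float, terms: int = 32) -> float:
    """Tail P(R > r) of the range of standard Brownian motion on [0, 1]."""
    if r <= 0:
        return 1.0
    k = np.arange(1, terms + 1, dtype=float)
    tail = 8.0 * np.sum((-1.0) ** (k - 1) * k * sps.norm.sf(k * r))
    return float(np.clip(tail, 0.0, 1.0))


def lsa_significance(
    x: NormalizedSeries | np.ndarray,
    y: NormalizedSeries | np.ndarray,
    max_delay: int = 3,
    method: str = "permutation",
    n_perm: int = 1000,
    seed: int | None = None,
    score: float | None = None,
) -> float:
    """Two-directional p-value for the local similarity score of (x, y).

    ``permutation`` shuffles one series and recomputes the score with the
    add-one estimator; ``theoretical`` applies the Brownian-range tail to
    the variance-standardized sqrt(n)-scaled score on each of the
    2*max_delay + 1 diagonals, treated as independent.
    """
    xv = x.values if isinstance(x, NormalizedSeries) else np.asarray(x, float)
    yv = y.values if isinstance(y, NormalizedSeries) else np.asarray(y, float)
    n = xv.size
    if score is None:
        score, _, _ = local_similarity(xv, yv, max_delay)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        null = _null_scores(xv, yv, max_delay, perm_idx)
        exceed = int((null >= abs(score) - 1e-12).sum())
        return (1.0 + exceed) / (n_perm + 1.0)
    if method == "theoretical":
        if n < 8:
            raise ValueError("theoretical approximation needs n >= 8")
        sigma2 = (xv ** 2).mean() * (yv ** 2).mean()
        if sigma2 <= 0:
            return 1.0
        r = np.sqrt(n) * abs(score) / np.sqrt(sigma2)
        p_single = brownian_range_sf(r)
        p = 1.0 - (1.0 - p_single) ** (2 * max_delay + 1)
        return float(np.clip(p, 0.0, 1.0))
    raise ValueError("method must be 'permutation' or 'theoretical'")


@dataclass
class LsaHit:
    """One guild-metabolite association retained by the screen."""

    x: str
    y: str
    score: float
    delay: int
    sign: int
    p: float
    q: float


def lsa_screen(
    x_series: pd.DataFrame,
    y_series: pd.DataFrame,
    max_delay: int = 3,
    fdr_alpha: float = 0.05,
    method: str = "permutation",
    n_perm: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every x-column against every y-column; BH over all pairs.

    ``x_series`` (e.g. guild daily trajectories) and ``y_series`` (e.g.
    metabolite daily trajectories) share a day index.  Returns the full
    pair table with columns x, y, score, delay, sign, p, q and a
    ``hit`` flag for q < ``fdr_alpha``; a positive delay means the x
    series precedes the y series.  In permutation mode one set of
    permutation indices is shared by every pair, keeping the screen fast
    while each pair's null stays conditional on its own y ordering.
    """
    if x_series.empty or y_series.empty:
        raise ValueError("empty input series")
    if not x_series.index.equals(y_series.index):
        raise ValueError("x and y must share a common day grid")
    xs = {c: normalize_percentile_z(x_series[c]) for c in x_series.columns}
    ys = {c: normalize_percentile_z(y_series[c]) for c in y_series.columns}
    rng = np.random.default_rng(seed)
    n = next(iter(xs.values())).n
    perm_idx = (np.argsort(rng.random((n_perm, n)), axis=1)
                if method == "permutation" else None)
    rows = []
    for cx, nx in xs.items():
        for cy, ny in ys.items():
            score, delay, sign = local_similarity(nx, ny, max_delay)
            if method == "permutation":
                null = _null_scores(nx.values, ny.values, max_delay, perm_idx)
                p = (1.0 + int((null >= score - 1e-12).sum())) / (n_perm + 1.0)
            else:
                p = lsa_significance(
                    nx, ny, max_delay=max_delay, method=method,
                    score=score * sign,
                )
            rows.append({"x": cx, "y": cy, "score": score * sign,
                         "delay": delay, "sign": sign, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["hit"] = out["q"] < fdr_alpha
    out["direction"] = np.where(
        out["delay"] > 0, "x_precedes_y",
        np.where(out["delay"] < 0, "y_precedes_x", "synchronous"),
    )
    return out.sort_values(["q", "p"]).reset_index(drop=True)
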