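"""Shared statistical primitives: BH step-up FDR, fast (strata-)PERMANOVA,
and a Dunn post-hoc test for Kruskal-Wallis."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; monotone in p.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, int]:
    """Total and within-group sums of squares from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.where(labels == g)[0]
        if idx.size < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within, groups.size


def _pseudo_f(ss_total: float, ss_within: float, k: int, n: int) -> float:
    ss_among = ss_total - ss_within
    denom = ss_within / (n - k)
    if denom <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (k - 1)) / denom


def permanova(
    distance: np.ndarray | pd.DataFrame,
    grouping,
    strata=None,
    n_perm: int = 999,
    seed: int | None = None,
    return_permuted_f: bool = False,
    return_permutations: bool = False,
):
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the sum of squared inter-point distances by ``grouping`` and
    compares the pseudo-F against label permutations.  When ``strata`` is
    given, labels are permuted only within each stratum (e.g. within
    participants for repeated measures).  Add-one p-value.

    Returns ``(pseudo_F, R2, p)`` (plus the permuted F values when
    requested, used by tests to audit the permutation scheme).
    """
    d = np.asarray(distance, dtype=float)
    labels = np.asarray(grouping)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("grouping length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("singleton groups are not testable")
    d2 = d ** 2
    ss_total, ss_within, k = _permanova_ss(d2, labels)
    f_obs = _pseudo_f(ss_total, ss_within, k, n)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    if strata is None:
        blocks = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        blocks = [np.where(strata == s)[0] for s in np.unique(strata)]
    f_perm = np.empty(n_perm)
    perm_labels = labels.copy()
    perm_log = np.empty((n_perm, n), dtype=labels.dtype) if return_permutations else None
    for i in range(n_perm):
        for idx in blocks:
            perm_labels[idx] = labels[idx][rng.permutation(idx.size)]
        if perm_log is not None:
            perm_log[i] = perm_labels
        _, ss_w, _ = _permanova_ss(d2, perm_labels)
        f_perm[i] = _pseudo_f(ss_total, ss_w, k, n)
    p = (1.0 + (f_perm >= f_obs).sum()) / (n_perm + 1.0)
    extras = []
    if return_permuted_f:
        extras.append(f_perm)
    if return_permutations:
        extras.append(perm_log)
    if extras:
        return (f_obs, r2, p, *extras)
    return f_obs, r2, p


def permanova_two_group_fast(
    d: np.ndarray,
    in_group1: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    exact_limit: int = 20_000,
) -> tuple[float, float]:
    """Vectorised free-permutation PERMANOVA for a binary split.

    Used by the guild-partition descent, where the split is always into two
    candidate clusters and labels permute freely over taxa.  When the
    number of distinct group-1 subsets is at most ``exact_limit`` the full
    arrangement set is enumerated and the p-value is exact (the observed
    arrangement counts itself); otherwise Monte-Carlo permutations with the
    add-one estimator are used.  Returns (pseudo_F, p).
    """
    from itertools import combinations
    from math import comb

    n = d.shape[0]
    d2 = d ** 2
    n1 = int(in_group1.sum())
    n2 = n - n1
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    def f_from_indicator(z: np.ndarray) -> np.ndarray:
        # z: n x m one-hot of group-1 membership for m permutations
        s1 = np.einsum("im,ij,jm->m", z, d2, z) / 2.0
        zc = 1.0 - z
        s2 = np.einsum("im,ij,jm->m", zc, d2, zc) / 2.0
        ss_within = s1 / n1 + s2 / n2
        ss_among = ss_total - ss_within
        denom = ss_within / (n - 2)
        return np.where(denom > 0, ss_among / denom, np.inf)

    f_obs = float(f_from_indicator(in_group1.astype(float)[:, None])[0])

    if comb(n, n1) <= exact_limit:
        exceed = 0
        total = 0
        batch_idx = []
        tol = 1e-12 * max(1.0, abs(f_obs))
        for subset in combinations(range(n), n1):
            batch_idx.append(subset)
            if len(batch_idx) == 1024:
                z = np.zeros((n, len(batch_idx)))
                z[np.array(batch_idx).T, np.arange(len(batch_idx))[None, :]] = 1.0
                exceed += int((f_from_indicator(z) >= f_obs - tol).sum())
                total += len(batch_idx)
                batch_idx = []
        if batch_idx:
            z = np.zeros((n, len(batch_idx)))
            z[np.array(batch_idx).T, np.arange(len(batch_idx))[None, :]] = 1.0
            exceed += int((f_from_indicator(z) >= f_obs - tol).sum())
            total += len(batch_idx)
        return f_obs, exceed / total

    batch = max(1, min(n_perm, 256))
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        z = np.zeros((n, b))
        for m in range(b):
            z[rng.choice(n, n1, replace=False), m] = 1.0
        exceed += int((f_from_indicator(z) >= f_obs).sum())
        done += b
    p = (1.0 + exceed) / (n_perm + 1.0)
    return f_obs, p


# ---------------------------------------------------------------------------
# Dunn's post-hoc test


def dunn_test(groups: dict[str, np.ndarray], adjust: bool = True) -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test after Kruskal-Wallis.

    Z statistic for groups A, B: (mean rank A - mean rank B) / SE with the
    tie-corrected pooled variance; two-sided p, optionally BH-adjusted.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = values.size
    ranks = sps.rankdata(values)
    offsets = np.cumsum([0] + [sizes[g] for g in names[:-1]])
    mean_rank = {
        g: ranks[o:o + sizes[g]].mean() for g, o in zip(names, offsets)
    }
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = names[a], names[b]
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[ga] + 1.0 / sizes[gb])
            )
            z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": ga, "group_b": gb, "z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
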