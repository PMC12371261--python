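"""Compositional (SparCC-style) correlation inference per participant.

Relative abundances live on the simplex, so ordinary Pearson correlations
between taxa are distorted by closure.  The SparCC model works from the
pairwise log-ratio variances

    t_ij = Var[ log(x_i / x_j) ] = omega_i^2 + omega_j^2 - 2 rho_ij omega_i omega_j,

assumes the network is sparse (sum of cross terms ~ 0), solves the
resulting linear system for the basis variances omega_i^2, and recovers the
basis correlations rho_ij.  Strongly correlated pairs violate the sparsity
assumption and are iteratively excluded from the system and re-solved.
Uncertainty about the underlying fractions is handled by resampling
fractions from a Dirichlet posterior over a configurable read depth and
taking the median estimate.  Two-sided significance comes from permutations
that shuffle each taxon's samples independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OMEGA_FLOOR = 1e-10


@dataclass
class BasisCorrelation:
    """Estimated basis variances and correlations for one participant."""

    taxa: list[str]
    rho: np.ndarray                       # taxon x taxon, symmetric, unit diagonal
    omega2: np.ndarray                    # per-taxon basis variance (floored at >= 0)
    excluded_pairs: set[tuple[str, str]] = field(default_factory=set)

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.taxa, columns=self.taxa)


@dataclass
class ParticipantNetwork:
    """Significant co-abundance edges of one participant."""

    participant: str
    edges: pd.DataFrame   # columns: taxon_i, taxon_j, rho, p, sign
    n_samples: int


def prevalence_filter(matrix: pd.DataFrame, threshold: float = 0.45) -> pd.DataFrame:
    """Keep taxa present in strictly more than ``threshold`` of the samples.

    ``matrix`` is one participant's sample x taxon abundance table.  A taxon
    observed on 13 of 28 days (46.4%) passes the default 45% cut-off.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    frac = (matrix > 0).mean(axis=0)
    kept = matrix.loc[:, frac > threshold]
    if kept.shape[1] == 0:
        raise ValueError("prevalence filter removed every taxon; degenerate input")
    return kept


# ---------------------------------------------------------------------------
# core estimator


def _logratio_variances(log_x: np.ndarray) -> np.ndarray:
    """t_ij = Var(log x_i - log x_j) from the covariance of the logs."""
    cov = np.cov(log_x, rowvar=False)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def _solve_basis(t: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Solve the sparsity-approximation linear system for omega^2.

    ``mask`` marks pairs still participating (True = included).  For each
    taxon i: sum_{j in N_i} t_ij = |N_i| omega_i^2 + sum_{j in N_i} omega_j^2.
    """
    p = t.shape[0]
    m = mask.astype(float)
    np.fill_diagonal(m, 0.0)
    a = np.diag(m.sum(axis=1)) + m
    r = (t * m).sum(axis=1)
    try:
        omega2 = np.linalg.solve(a, r)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular basis-variance system (taxa with no usable pairs: "
            f"{np.where(m.sum(axis=1) == 0)[0].tolist()})"
        ) from exc
    return np.maximum(omega2, OMEGA_FLOOR)


def _rho_from_basis(t: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    omega = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _one_pass(t: np.ndarray, n_exclusion: int, exclusion_threshold: float
              ) -> tuple[np.ndarray, set[tuple[int, int]], np.ndarray]:
    """Basis solve with iterative strong-pair exclusion on one t matrix."""
    p = t.shape[0]
    mask = ~np.eye(p, dtype=bool)
    excluded: set[tuple[int, int]] = set()
    omega2 = _solve_basis(t, mask)
    rho = _rho_from_basis(t, omega2)
    for _ in range(n_exclusion):
        probe = np.where(mask, np.abs(rho), 0.0)
        np.fill_diagonal(probe, 0.0)
        i, j = np.unravel_index(np.argmax(probe), probe.shape)
        if probe[i, j] <= exclusion_threshold:
            break
        mask[i, j] = mask[j, i] = False
        excluded.add((min(i, j), max(i, j)))
        # taxa left with a single partner make the system ill-posed; stop
        if (mask.sum(axis=1) < 2).any():
            mask[i, j] = mask[j, i] = True
            excluded.discard((min(i, j), max(i, j)))
            break
        omega2 = _solve_basis(t, mask)
        rho = _rho_from_basis(t, omega2)
    return rho, excluded, omega2


def _dirichlet_fractions(rng: np.random.Generator, counts: np.ndarray) -> np.ndarray:
    """One draw of fractions per sample from Dirichlet(counts + 1)."""
    g = rng.gamma(counts + 1.0)
    return g / g.sum(axis=1, keepdims=True)


def sparcc_correlation(
    matrix: pd.DataFrame,
    n_inner: int = 50,
    n_exclusion: int = 10,
    exclusion_threshold: float = 0.1,
    depth: float = 10_000.0,
    seed: int | None = None,
) -> BasisCorrelation:
    """Estimate basis correlations from one participant's sample x taxon table.

    Per inner iteration the relative abundances (rescaled to ``depth``
    pseudo-counts) are resampled from a Dirichlet posterior with a +1
    pseudocount, the log-ratio variance matrix is formed, the sparsity
    system solved, and up to ``n_exclusion`` strongly-correlated pairs
    (|rho| above ``exclusion_threshold``) excluded and re-solved.  The
    returned correlation is the entrywise median over inner iterations.
    """
    values = np.asarray(matrix, dtype=float)
    n, p = values.shape
    if p < 4:
        raise ValueError("need at least 4 taxa for basis-variance estimation")
    if n < 10:
        warnings.warn(f"only {n} samples; correlation estimates will be noisy")
    if (values.sum(axis=0) == 0).any():
        bad = matrix.columns[(values.sum(axis=0) == 0)].tolist()
        raise ValueError(f"all-zero taxa: {bad}")
    rng = np.random.default_rng(seed)
    counts = values / values.sum(axis=1, keepdims=True) * depth

    rhos = np.empty((n_inner, p, p))
    omega2s = np.empty((n_inner, p))
    excluded_all: set[tuple[int, int]] = set()
    for it in range(n_inner):
        frac = _dirichlet_fractions(rng, counts)
        t = _logratio_variances(np.log(frac))
        rho, excl, omega2 = _one_pass(t, n_exclusion, exclusion_threshold)
        rhos[it] = rho
        omega2s[it] = omega2
        excluded_all |= excl

    rho_med = np.median(rhos, axis=0)
    rho_med = np.clip((rho_med + rho_med.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho_med, 1.0)
    taxa = list(matrix.columns)
    excluded = {(taxa[i], taxa[j]) for i, j in excluded_all}
    return BasisCorrelation(taxa, rho_med, np.median(omega2s, axis=0), excluded)


# ---------------------------------------------------------------------------
# permutation significance


def _batched_null_rhos(log_x: np.ndarray, n_perm: int, rng: np.random.Generator,
                       batch: int = 64) -> np.ndarray:
    """Null rho matrices under independent within-taxon sample shuffling.

    Each permutation destroys all between-taxon structure while preserving
    marginals; the basis system is solved in a single pass (no posterior
    resampling, no exclusion) per replicate.
    """
    n, p = log_x.shape
    out = np.empty((n_perm, p, p))
    eye = np.eye(p, dtype=bool)
    for start in range(0, n_perm, batch):
        b = min(batch, n_perm - start)
        order = np.argsort(rng.random((b, n, p)), axis=1)
        perm = np.take_along_axis(np.broadcast_to(log_x, (b, n, p)), order, axis=1)
        centered = perm - perm.mean(axis=1, keepdims=True)
        cov = np.einsum("bni,bnj->bij", centered, centered) / (n - 1)
        v = np.einsum("bii->bi", cov)
        t = v[:, :, None] + v[:, None, :] - 2.0 * cov
        t[:, eye] = 0.0
        np.maximum(t, 0.0, out=t)
        # uniform (no-exclusion) closed-form solve of the sparsity system
        r = t.sum(axis=2)
        total = r.sum(axis=1) / (2.0 * (p - 1.0))
        omega2 = np.maximum((r - total[:, None]) / (p - 2.0), OMEGA_FLOOR)
        omega = np.sqrt(omega2)
        rho = (omega2[:, :, None] + omega2[:, None, :] - t) / (
            2.0 * omega[:, :, None] * omega[:, None, :]
        )
        np.clip(rho, -1.0, 1.0, out=rho)
        out[start:start + b] = rho
    return out


def permutation_pvalues(
    matrix: pd.DataFrame,
    observed: BasisCorrelation,
    n_perm: int = 1000,
    seed: int | None = None,
    depth: float = 10_000.0,
) -> pd.DataFrame:
    """Two-sided permutation p-values for every taxon pair.

    Uses the add-one estimator p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1),
    whose smallest attainable value is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(matrix, dtype=float)
    frac = (values / values.sum(axis=1, keepdims=True) * depth + 1.0)
    frac = frac / frac.sum(axis=1, keepdims=True)
    log_x = np.log(frac)
    rng = np.random.default_rng(seed)
    null = _batched_null_rhos(log_x, n_perm, rng)
    obs = np.abs(observed.rho)
    exceed = (np.abs(null) >= obs[None, :, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(p, 0.0)
    return pd.DataFrame(p, index=observed.taxa, columns=observed.taxa)


def build_participant_network(
    observed: BasisCorrelation,
    pvalues: pd.DataFrame,
    participant: str,
    n_samples: int,
    alpha: float = 0.05,
) -> ParticipantNetwork:
    """Edges are taxon pairs with p <= alpha (inclusive); sign = sign(rho)."""
    taxa = observed.taxa
    p = pvalues.loc[taxa, taxa].to_numpy()
    iu = np.triu_indices(len(taxa), k=1)
    keep = p[iu] <= alpha
    rows = {
        "taxon_i": np.asarray(taxa)[iu[0][keep]],
        "taxon_j": np.asarray(taxa)[iu[1][keep]],
        "rho": observed.rho[iu][keep],
        "p": p[iu][keep],
    }
    edges = pd.DataFrame(rows)
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    return ParticipantNetwork(participant, edges, n_samples)
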