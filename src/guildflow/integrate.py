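"""Cross-omics sample-level statistics: Bray-Curtis distances,
strata-restricted PERMANOVA, covariate-adjusted PCoA, Procrustes
concordance, repeated-measures correlation and mixed-model causal
mediation.

Repeated-measures designs violate the independence assumptions of the
ordinary versions of these tools: PERMANOVA permutations are therefore
restricted within participants, ordination projects the participant effect
out of the Gower-centered distance matrix before eigendecomposition,
correlation is estimated on within-participant-centered variables
(rmcorr), and mediation uses random-intercept linear mixed models with
quasi-Bayesian uncertainty propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import procrustes as _procrustes
from scipy.spatial.distance import pdist, squareform
import statsmodels.formula.api as smf

from .stats import permanova  # noqa: F401  (re-exported: sample-level tests live here)


def bray_curtis(samples: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between rows of a sample x feature table."""
    d = squareform(pdist(samples.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=samples.index, columns=samples.index)


# ---------------------------------------------------------------------------
# covariate-adjusted PCoA


def adjusted_pcoa(
    distance: pd.DataFrame,
    covariate: pd.Series | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-coordinates analysis with a covariate projected out.

    Gower-centers G = -1/2 J D^(2) J, removes the covariate's hat-matrix
    projection on both sides (E = (I-H) G (I-H)) and eigendecomposes E;
    coordinates come from the positive eigenpairs.  With no covariate this
    is classical PCoA.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    if covariate is not None:
        cov = pd.Series(covariate)
        if list(cov.index) != list(distance.index):
            cov = cov.loc[distance.index]
        dummies = pd.get_dummies(cov.astype(str)).to_numpy(dtype=float)
        if dummies.shape[1] >= n or np.unique(cov).size == 1:
            raise ValueError("covariate absorbs all variation; adjustment removes everything")
        x = np.column_stack([np.ones(n), dummies[:, :-1]])
        h = x @ np.linalg.pinv(x.T @ x) @ x.T
        p = np.eye(n) - h
        g = p @ g @ p
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals.max(), 0) * 1e-10
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=distance.index, columns=cols), evals


# ---------------------------------------------------------------------------
# Procrustes


def procrustes_test(
    x: pd.DataFrame | np.ndarray,
    y: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Procrustes m^2 between two ordinations with a permutation test.

    Y is optimally translated/rotated/scaled onto X; m^2 is the scaled
    residual sum of squares.  p comes from row-shuffling Y (protest-style,
    add-one estimator).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape[0] != ya.shape[0]:
        raise ValueError("row mismatch between ordinations")
    k = min(xa.shape[1], ya.shape[1])
    if k == 0:
        raise ValueError("rank-0 input")
    xa, ya = xa[:, :k], ya[:, :k]
    _, _, m2 = _procrustes(xa, ya)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        _, _, m2p = _procrustes(xa, ya[rng.permutation(ya.shape[0])])
        if m2p <= m2:
            exceed += 1
    return float(m2), (1.0 + exceed) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# repeated-measures correlation


@dataclass
class RmcorrResult:
    r: float
    df: int
    p: float
    slope: float


def rmcorr(x, y, participants) -> RmcorrResult:
    """Common within-participant correlation (ANCOVA decomposition).

    Fits y ~ participant + x (common slope); r_rm is the signed square root
    of SS_x / (SS_x + SS_error) with df = N - k - 1 for k participants.
    With a single participant this reduces to the ordinary Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    participants = np.asarray(participants)
    if x.size != y.size or x.size != participants.size:
        raise ValueError("x, y and participants must have equal length")
    uniq = np.unique(participants)
    k = uniq.size
    n = x.size
    df = n - k - 1
    if df < 1:
        raise ValueError("not enough observations for rmcorr")
    xc = x.copy().astype(float)
    yc = y.copy().astype(float)
    for u in uniq:
        m = participants == u
        if np.allclose(x[m], x[m][0]):
            warnings.warn(f"participant {u!r} has constant x; contributes no slope")
        xc[m] -= x[m].mean()
        yc[m] -= y[m].mean()
    ss_xx = float(xc @ xc)
    if ss_xx == 0:
        raise ValueError("no within-participant variation in x")
    slope = float(xc @ yc) / ss_xx
    ss_x = slope ** 2 * ss_xx                     # SS explained by x after participant
    ss_err = float(yc @ yc) - ss_x
    if ss_x + ss_err <= 0:
        return RmcorrResult(0.0, df, 1.0, slope)
    r = np.sign(slope) * np.sqrt(ss_x / (ss_x + ss_err))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RmcorrResult(r, df, p, slope)


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Quasi-Bayesian mediation summary.

    ACME/ADE/total are means over coefficient draws; in this linear model
    total = ACME + ADE holds exactly.  ``a`` and ``b`` are the point
    estimates of the treatment->mediator and mediator->outcome paths.
    """

    acme: float
    ade: float
    total: float
    proportion_mediated: float
    p_acme: float
    ci_acme: tuple[float, float]
    a: float
    b: float
    c_prime: float


def _mixed_fit(formula: str, df: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant"])
        fit = model.fit(reml=True)
    if not fit.converged:
        raise RuntimeError(f"mixed model did not converge: {formula}")
    return fit


def mediate(
    treatment,
    mediator,
    outcome,
    participants,
    n_sims: int = 1000,
    seed: int | None = None,
) -> MediationResult:
    """Causal mediation with participant random intercepts.

    Mediator model M ~ T + (1|participant); outcome model
    Y ~ T + M + (1|participant).  Draws (a) and (b, c') from the asymptotic
    normal of the fixed effects (the outcome pair jointly, with its
    estimated covariance); ACME = mean(a*b), ADE = mean(c'),
    total = ACME + ADE; two-sided p for ACME from the draw distribution.
    """
    df = pd.DataFrame({
        "t": np.asarray(treatment, dtype=float),
        "m": np.asarray(mediator, dtype=float),
        "y": np.asarray(outcome, dtype=float),
        "participant": np.asarray(participants),
    })
    med_fit = _mixed_fit("m ~ t", df)
    out_fit = _mixed_fit("y ~ t + m", df)

    a_hat = float(med_fit.fe_params["t"])
    a_se = float(med_fit.bse_fe["t"])
    b_hat = float(out_fit.fe_params["m"])
    c_hat = float(out_fit.fe_params["t"])
    cov_out = out_fit.cov_params().loc[["t", "m"], ["t", "m"]].to_numpy()

    rng = np.random.default_rng(seed)
    a_draws = rng.normal(a_hat, a_se, size=n_sims)
    cm_draws = rng.multivariate_normal([c_hat, b_hat], cov_out, size=n_sims)
    acme_draws = a_draws * cm_draws[:, 1]
    ade_draws = cm_draws[:, 0]
    total_draws = acme_draws + ade_draws

    acme = float(acme_draws.mean())
    ade = float(ade_draws.mean())
    total = float(total_draws.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_draws = np.where(total_draws != 0, acme_draws / total_draws, np.nan)
    prop = float(np.nanmedian(prop_draws))
    lo, hi = np.percentile(acme_draws, [2.5, 97.5])
    tail = min((acme_draws <= 0).mean(), (acme_draws >= 0).mean())
    p_acme = float(min(1.0, 2.0 * max(tail, 1.0 / n_sims)))
    return MediationResult(
        acme=acme, ade=ade, total=total, proportion_mediated=prop,
        p_acme=p_acme, ci_acme=(float(lo), float(hi)),
        a=a_hat, b=b_hat, c_prime=c_hat,
    )
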