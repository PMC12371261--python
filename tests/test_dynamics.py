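"""Trajectory LMM, differential abundance, DTW and change-point tests."""

import numpy as np
import pandas as pd
import pytest

from guildflow import dynamics
from guildflow.design import StudyDesign
from guildflow.stats import bh_adjust


def _lmm_series(rng, n_participants=10, sigma_b=1.0, sigma=0.5,
                day_effects=None, design=None):
    """Simulate log-normal abundances directly from the trajectory model."""
    if design is None:
        design = StudyDesign(groups=("overweight",), participants_per_group=n_participants)
    days = list(design.days)
    if day_effects is None:
        day_effects = {d: 0.0 for d in days}
    rows, idx = [], []
    for p in design.participants(design.groups[0]):
        b = rng.normal(0.0, sigma_b)
        for d in days:
            mu = -2.0 + day_effects.get(d, 0.0)
            rows.append(np.exp(mu + b + rng.normal(0.0, sigma)))
            idx.append((p, d))
    return pd.Series(rows, index=pd.MultiIndex.from_tuples(
        idx, names=["participant", "day"])), design


class TestTrajectoryFit:
    def test_balanced_zero_variance_reproduces_day_means(self, rng):
        """With no participant effect the LMM trajectory equals per-day means."""
        series, design = _lmm_series(rng, sigma_b=0.0, sigma=0.4,
                                     day_effects={d: 0.1 * (d >= 14) for d in range(28)})
        fit = dynamics.fit_trajectory(series, design, reference="normal")
        log = np.log(series)
        for d in fit.day_effects.index:
            day_mean = log.xs(d, level="day").mean()
            assert fit.intercept + fit.day_effects[d] == pytest.approx(
                day_mean, abs=1e-8)
        normal_mean = log[log.index.get_level_values("day") <= 13].mean()
        assert fit.intercept == pytest.approx(normal_mean, abs=1e-8)

    def test_known_day_effects_recovered(self, rng):
        effects = {d: (0.8 if d >= 21 else 0.4 if d >= 14 else 0.0)
                   for d in range(28)}
        series, design = _lmm_series(rng, sigma_b=1.0, sigma=0.5,
                                     day_effects=effects)
        fit = dynamics.fit_trajectory(series, design, reference="normal")
        err = [fit.day_effects[d] - effects[d] for d in fit.day_effects.index]
        assert np.sqrt(np.mean(np.square(err))) < 0.25
        assert fit.sigma2_participant == pytest.approx(1.0, abs=0.9)

    def test_day0_reference_covers_all_days(self, rng):
        series, design = _lmm_series(rng)
        table = series.to_frame("f1")
        daily = dynamics.daily_series(table, design, reference="day0")
        assert list(daily.index) == list(range(28))

    def test_single_participant_rejected(self):
        idx = pd.MultiIndex.from_product([["p1"], range(28)],
                                         names=["participant", "day"])
        series = pd.Series(np.ones(28), index=idx)
        with pytest.raises(ValueError):
            dynamics.fit_trajectory(series)


class TestDifferentialAbundance:
    def test_planted_endpoint_shift_detected(self, rng):
        design = StudyDesign(groups=("overweight",), participants_per_group=10)
        cols = {}
        for k in range(6):
            eff = {d: (np.log(2.0) * (d == 27) if k == 0 else 0.0)
                   for d in range(28)}
            s, _ = _lmm_series(rng, sigma_b=0.5, sigma=0.3, day_effects=eff,
                               design=design)
            cols[f"cag{k}"] = s
        table = pd.DataFrame(cols)
        res = dynamics.differential_abundance(table, design, contrast="endpoint")
        assert res.loc["cag0", "direction"] == "increase"
        assert (res.drop("cag0")["direction"] == "unchanged").all()

    def test_whole_intervention_contrast_runs(self, rng):
        design = StudyDesign(groups=("overweight",), participants_per_group=6)
        cols = {}
        for k in range(4):
            eff = {d: (0.7 * (d >= 14) if k == 0 else 0.0) for d in range(28)}
            s, _ = _lmm_series(rng, sigma_b=0.5, sigma=0.3, day_effects=eff,
                               design=design)
            cols[f"cag{k}"] = s
        res = dynamics.differential_abundance(pd.DataFrame(cols), design,
                                              contrast="whole")
        assert res.loc["cag0", "effect"] == pytest.approx(0.7, abs=0.35)

    def test_bh_qvalues_monotone_in_p(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _brute_force_dtw(a, b):
    """Min cost over explicitly enumerated monotone warping paths
    (symmetric2 weights: diagonal steps cost twice the local distance)."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n:
            walk(i + 1, j, cost + abs(a[i + 1] - b[j]))
        if j + 1 < m:
            walk(i, j + 1, cost + abs(a[i] - b[j + 1]))
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost + 2 * abs(a[i + 1] - b[j + 1]))

    walk(0, 0, abs(a[0] - b[0]))
    return best[0]


class TestDtw:
    def test_identical_series_distance_zero(self):
        x = np.array([1.0, 2.0, 0.5, 3.0])
        assert dynamics.dtw_distance(x, x) == 0.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.standard_normal(6), rng.standard_normal(6)
            assert dynamics.dtw_distance(a, b) == pytest.approx(
                dynamics.dtw_distance(b, a))

    def test_matches_brute_force_path_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            assert dynamics.dtw_distance(a, b) == pytest.approx(
                _brute_force_dtw(a, b), abs=1e-12)

    def test_bounded_by_identity_path_cost(self, rng):
        for _ in range(20):
            a, b = rng.standard_normal(8), rng.standard_normal(8)
            ident = abs(a[0] - b[0]) + 2 * np.abs(a[1:] - b[1:]).sum()
            assert dynamics.dtw_distance(a, b) <= ident + 1e-12

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            dynamics.dtw_distance([1.0, np.nan], [1.0, 2.0])


class TestClusterTrajectories:
    def test_planted_archetype_shapes_recovered(self, rng):
        """Six archetype curves, five copies each, low noise: perfect ARI."""
        from sklearn.metrics import adjusted_rand_score
        from guildflow import simulate
        design = StudyDesign()
        days = list(range(28))
        cols, labels = {}, []
        for arch in simulate.ARCHETYPES:
            curve = np.array(simulate.archetype_curve(
                arch, days, 1.5, design.phase_of_day))[14:]
            for k in range(5):
                cols[f"{arch}-{k}"] = curve + rng.normal(0, 0.05, 14)
                labels.append(arch)
        traj = pd.DataFrame(cols, index=range(14, 28))
        clusters = dynamics.cluster_trajectories(traj, relative_to_normal=False)
        pred = [clusters.cluster_of_cag[c] for c in cols]
        assert adjusted_rand_score(labels, pred) >= 0.9
        assert clusters.chosen_k == 6

    def test_duplicated_trajectories_silhouette_picks_planted_k(self, rng):
        base = {f"s{k}": rng.standard_normal(10) for k in range(2)}
        cols = {}
        for name, v in base.items():
            for c in range(3):
                cols[f"{name}_{c}"] = v
        traj = pd.DataFrame(cols, index=range(14, 24))
        clusters = dynamics.cluster_trajectories(traj, relative_to_normal=False)
        assert clusters.chosen_k == 2

    def test_constant_distances_yield_single_cluster(self):
        traj = pd.DataFrame({
            "a": [0.0, 1.0, 0.0], "b": [1.0, 0.0, 1.0],
        }, index=[14, 15, 16])
        traj["c"] = [0.5, 0.5, 0.501]
        out = dynamics.cluster_trajectories(
            pd.DataFrame({"a": [0, 0, 0], "b": [1, 1, 1], "c": [2, 2, 2]},
                         index=[14, 15, 16], dtype=float),
            relative_to_normal=False)
        assert out.chosen_k in (1, 2)  # equidistant chain: no stable split


class TestChangePoint:
    def test_constant_series_has_no_changepoint(self):
        cp = dynamics.detect_changepoint(np.ones(20), seed=0)
        assert cp.location is None and cp.p == 1.0

    def test_planted_step_located_and_significant(self, rng):
        hits, sig = 0, 0
        for s in range(50):
            x = np.concatenate([rng.normal(0, 1, 14), rng.normal(2, 1, 14)])
            cp = dynamics.detect_changepoint(x, n_perm=199, seed=s)
            hits += abs(cp.location - 14) <= 2
            sig += cp.p < 0.05
        assert hits >= 45
        assert sig >= 47

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dynamics.detect_changepoint(np.arange(5), seed=0)
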