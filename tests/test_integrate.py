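"""Sample-level statistics: distances, (strata-)PERMANOVA, adjusted PCoA,
Procrustes, repeated-measures correlation and mediation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from guildflow import integrate
from guildflow.stats import permanova


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        df = pd.DataFrame(
            [[0.5, 0.5, 0.0, 0.0],
             [0.5, 0.5, 0.0, 0.0],
             [0.0, 0.0, 0.7, 0.3]],
            index=["a", "b", "c"],
        )
        d = integrate.bray_curtis(df)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == pytest.approx(1.0)


class TestPermanova:
    def test_strata_permutations_stay_within_participants(self, rng):
        x = rng.standard_normal((12, 3))
        d = squareform(pdist(x))
        labels = np.array(["a", "b"] * 6)
        strata = np.repeat([f"p{i}" for i in range(6)], 2)
        _, _, _, perms = permanova(d, labels, strata=strata, n_perm=50,
                                   seed=0, return_permutations=True)
        for perm in perms:
            for s in np.unique(strata):
                idx = strata == s
                assert sorted(perm[idx]) == sorted(labels[idx])

    def test_inflated_between_group_distance_saturates_p(self, rng):
        x = rng.standard_normal((16, 3))
        x[8:] += 6.0
        d = squareform(pdist(x))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        _, r2, p = permanova(d, labels, n_perm=99, seed=1)
        assert p == 1.0 / 100.0
        assert r2 > 0.5

    def test_monte_carlo_p_tracks_exact_enumeration(self, rng):
        """Small fixtures: exhaustive label enumeration vs sampled p."""
        for trial in range(5):
            x = rng.standard_normal((6, 2))
            d = squareform(pdist(x))
            labels = np.array(["a"] * 3 + ["b"] * 3)
            d2 = d ** 2

            def f_of(lab):
                from guildflow.stats import _permanova_ss, _pseudo_f
                sst, ssw, k = _permanova_ss(d2, np.asarray(lab))
                return _pseudo_f(sst, ssw, k, 6)

            f_obs = f_of(labels)
            perms = set(itertools.permutations(labels))
            exact = np.mean([f_of(lab) >= f_obs - 1e-12 for lab in perms])
            _, _, p_mc = permanova(d, labels, n_perm=1999, seed=trial)
            assert p_mc == pytest.approx(exact, abs=0.05)

    def test_singleton_group_rejected(self, rng):
        d = squareform(pdist(rng.standard_normal((5, 2))))
        with pytest.raises(ValueError):
            permanova(d, np.array(["a", "a", "a", "a", "b"]), n_perm=9)


class TestAdjustedPcoa:
    def test_matches_reference_pcoa_without_covariate(self, rng):
        pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        x = rng.standard_normal((10, 4))
        d = pd.DataFrame(squareform(pdist(x)))
        mine, evals = integrate.adjusted_pcoa(d)
        ref = skbio_pcoa(SkbioDM(d.to_numpy()), number_of_dimensions=3)
        for k in range(3):
            a = mine.iloc[:, k].to_numpy()
            b = ref.samples.iloc[:, k].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_euclidean_distance_reproduces_pca_scores(self, rng):
        x = rng.standard_normal((12, 5))
        d = pd.DataFrame(squareform(pdist(x)))
        coords, _ = integrate.adjusted_pcoa(d)
        xc = x - x.mean(0)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        scores = xc @ vt.T
        for k in range(3):
            assert np.allclose(np.abs(coords.iloc[:, k]), np.abs(scores[:, k]),
                               atol=1e-8)

    def test_participant_adjustment_removes_offset_variance(self, rng):
        # 4 participants x 7 samples with dominating participant offsets
        offsets = rng.normal(0, 10, size=(4, 3))
        rows, labels = [], []
        for i in range(4):
            for _ in range(7):
                rows.append(offsets[i] + rng.normal(0, 1, 3))
                labels.append(f"p{i}")
        x = np.array(rows)
        d = pd.DataFrame(squareform(pdist(x)))
        cov = pd.Series(labels, index=d.index)
        coords, _ = integrate.adjusted_pcoa(d, cov)
        grand = coords.to_numpy()
        groups = np.array(labels)
        between = sum(
            (groups == g).sum() * np.sum(grand[groups == g].mean(0) ** 2)
            for g in np.unique(groups)
        )
        total = np.sum(grand ** 2)
        assert between / total < 0.05

    def test_single_participant_covariate_rejected(self, rng):
        d = pd.DataFrame(squareform(pdist(rng.standard_normal((6, 2)))))
        with pytest.raises(ValueError):
            integrate.adjusted_pcoa(d, pd.Series(["p"] * 6, index=d.index))


class TestProcrustes:
    def test_rotated_scaled_copy_has_zero_m2(self, rng):
        x = rng.standard_normal((10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = 3.0 * x @ rot + 5.0
        m2, p = integrate.procrustes_test(x, y, n_perm=49, seed=0)
        assert m2 < 1e-10
        assert p == 1.0 / 50.0

    def test_m2_invariant_to_prescaling(self, rng):
        x = rng.standard_normal((12, 3))
        y = rng.standard_normal((12, 3))
        m2a, _ = integrate.procrustes_test(x, y, n_perm=9, seed=1)
        m2b, _ = integrate.procrustes_test(x, 10.0 * y, n_perm=9, seed=1)
        assert m2a == pytest.approx(m2b, abs=1e-12)

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            integrate.procrustes_test(rng.standard_normal((5, 2)),
                                      rng.standard_normal((6, 2)))


class TestRmcorr:
    FIXTURE = pd.DataFrame({
        "participant": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
        "x": [1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 5.0, 6.0, 0.0, 1.0, 2.0, 5.0],
        "y": [2.1, 2.9, 4.2, 5.1, 1.0, 1.8, 3.1, 3.9, 7.0, 7.4, 8.1, 9.9],
    })

    def test_matches_hand_computed_ancova_decomposition(self):
        df = self.FIXTURE
        # oracle: explicit least squares on [participant dummies | x]
        dummies = pd.get_dummies(df["participant"]).to_numpy(float)
        design = np.column_stack([dummies, df["x"]])
        beta, *_ = np.linalg.lstsq(design, df["y"], rcond=None)
        resid_full = df["y"] - design @ beta
        ss_err = float(resid_full @ resid_full)
        beta0, *_ = np.linalg.lstsq(dummies, df["y"], rcond=None)
        resid_null = df["y"] - dummies @ beta0
        ss_null = float(resid_null @ resid_null)
        ss_x = ss_null - ss_err
        r_expected = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + ss_err))
        res = integrate.rmcorr(df["x"], df["y"], df["participant"])
        assert res.r == pytest.approx(r_expected, abs=1e-10)
        assert res.df == len(df) - 3 - 1

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        df = self.FIXTURE
        ref = pg.rm_corr(data=df, x="x", y="y", subject="participant")
        res = integrate.rmcorr(df["x"], df["y"], df["participant"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_single_participant_reduces_to_pearson(self, rng):
        from scipy import stats as sps
        x = rng.standard_normal(15)
        y = 0.5 * x + rng.standard_normal(15)
        res = integrate.rmcorr(x, y, np.repeat("p1", 15))
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_noiseless_common_slope_gives_unit_r(self):
        x = np.tile(np.arange(5.0), 3)
        intercepts = np.repeat([0.0, 10.0, -4.0], 5)
        y = x + intercepts
        res = integrate.rmcorr(x, y, np.repeat(["a", "b", "c"], 5))
        assert res.r == pytest.approx(1.0)

    def test_invariant_to_per_participant_recentering(self, rng):
        df = self.FIXTURE.copy()
        res1 = integrate.rmcorr(df["x"], df["y"], df["participant"])
        shift = df["participant"].map({"a": 5.0, "b": -2.0, "c": 9.0})
        res2 = integrate.rmcorr(df["x"] + shift, df["y"] - 3 * shift,
                                df["participant"])
        assert res2.r == pytest.approx(res1.r, abs=1e-12)


class TestMediate:
    def _simulate(self, rng, a=1.0, b=0.5, c=0.3, n_part=10, n_obs=14,
                  sd_b=0.5, sd_e=0.5):
        rows = []
        for i in range(n_part):
            u_m, u_y = rng.normal(0, sd_b, 2)
            for _ in range(n_obs):
                t = rng.standard_normal()
                m = a * t + u_m + rng.normal(0, sd_e)
                y = c * t + b * m + u_y + rng.normal(0, sd_e)
                rows.append((t, m, y, f"p{i}"))
        df = pd.DataFrame(rows, columns=["t", "m", "y", "participant"])
        return df

    def test_point_estimates_satisfy_effect_decomposition(self, rng):
        df = self._simulate(rng)
        res = integrate.mediate(df["t"], df["m"], df["y"], df["participant"],
                                n_sims=500, seed=1)
        assert res.total == pytest.approx(res.acme + res.ade, abs=1e-8)

    def test_planted_indirect_effect_recovered(self, rng):
        df = self._simulate(rng, a=1.0, b=0.5)
        res = integrate.mediate(df["t"], df["m"], df["y"], df["participant"],
                                n_sims=1000, seed=2)
        assert res.acme == pytest.approx(0.5, abs=0.15)
        assert res.p_acme < 0.05

    def test_null_mediator_path_covered(self, rng):
        covered = 0
        for s in range(20):
            df = self._simulate(rng, a=1.0, b=0.0)
            res = integrate.mediate(df["t"], df["m"], df["y"],
                                    df["participant"], n_sims=500, seed=s)
            lo, hi = res.ci_acme
            covered += lo <= 0.0 <= hi
        assert covered >= 17
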