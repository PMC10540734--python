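from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dielprot.patterns import (
    category_enrichment,
    cluster_profiles,
    pair_protein_phospho,
    pca_profiles,
    peak_phase_distribution,
)

ZTS = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0]


def _cosine_profiles(phases, n_each, noise, seed, amp=1.0):
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    for g, phi in enumerate(phases):
        for i in range(n_each):
            prof = 1 + amp * np.cos(2 * np.pi * (np.array(ZTS) - phi) / 24)
            rows.append(prof + rng.normal(0, noise, size=len(ZTS)))
            ids.append(f"g{g}_{i}")
    return pd.DataFrame(rows, index=ids, columns=ZTS)


class TestPCA:
    def test_matches_hand_svd_on_toy_matrix(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 2.0, 0.0]], columns=[0.0, 4.0, 8.0])
        res = pca_profiles(m)
        centred = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        np.testing.assert_allclose(np.abs(res.scores.to_numpy()), np.abs(u * s), atol=1e-9)
        np.testing.assert_allclose(
            res.variance_fraction.to_numpy(), s**2 / (s**2).sum(), atol=1e-12
        )

    def test_variance_fractions_sum_to_one(self):
        m = _cosine_profiles([0, 12], 10, 0.1, 3)
        res = pca_profiles(m)
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        m = _cosine_profiles([0, 8], 10, 0.05, 4)
        res1, res2 = pca_profiles(m), pca_profiles(-1 * m + 10)
        for pc in res1.loadings.columns:
            j = res1.loadings[pc].abs().idxmax()
            assert res1.loadings.loc[j, pc] > 0

    def test_reconstruction_identity(self):
        m = _cosine_profiles([0, 6, 12], 8, 0.2, 5)
        res = pca_profiles(m)
        centred = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        np.testing.assert_allclose(res.reconstruct().to_numpy(), centred, atol=1e-9)

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.ones((5, 6)), columns=ZTS)
        with pytest.raises(ValueError, match="variance"):
            pca_profiles(m)


class TestClustering:
    def test_two_planted_antiphase_groups_recovered(self):
        m = _cosine_profiles([0, 12], 50, 0.05, 7)
        labels = cluster_profiles(m, min_cluster_size=20)
        truth = pd.Series([i.split("_")[0] for i in m.index], index=m.index)
        assert labels.nunique() == 2
        # adjusted Rand = 1 <=> label sets coincide up to renaming
        ct = pd.crosstab(labels, truth).to_numpy()
        assert sorted(ct.max(axis=1)) == sorted(ct.sum(axis=1))
        assert (ct > 0).sum() == 2

    def test_duplicated_profile_single_cluster(self):
        prof = 1 + np.cos(2 * np.pi * (np.array(ZTS) - 4) / 24)
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            np.tile(prof, (40, 1)) + rng.normal(0, 1e-3, size=(40, 6)),
            index=[f"f{i}" for i in range(40)], columns=ZTS,
        )
        labels = cluster_profiles(m, min_cluster_size=20)
        assert set(labels) == {"P1"}

    def test_oversized_min_cluster_forces_unassigned(self):
        m = _cosine_profiles([0, 12], 30, 0.05, 8)
        labels = cluster_profiles(m, min_cluster_size=40)
        assert (labels == "unassigned").any()

    def test_feature_order_invariance(self):
        m = _cosine_profiles([0, 8, 16], 25, 0.1, 9)
        a = cluster_profiles(m)
        b = cluster_profiles(m.sample(frac=1.0, random_state=1)).reindex(m.index)
        ct = pd.crosstab(a, b)
        assert (ct.to_numpy() > 0).sum() == len(ct)

    def test_fewer_features_than_min_size_warns_unassigned(self):
        m = _cosine_profiles([0], 5, 0.1, 10)
        with pytest.warns(UserWarning):
            labels = cluster_profiles(m, min_cluster_size=20)
        assert (labels == "unassigned").all()


class TestPeakPhaseDistribution:
    def _results(self, peaks, rhythmic=None):
        f = pd.DataFrame({"peak_zt": peaks})
        f["rhythmic"] = True if rhythmic is None else rhythmic
        return f

    def test_single_bin(self):
        out = peak_phase_distribution(self._results([8.0] * 10))
        assert out.loc[8.0, "fraction"] == 1.0

    def test_fractions_sum_to_one(self):
        out = peak_phase_distribution(self._results([0.0, 4.0, 8.0, 8.0, 20.0]))
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_zero_rhythmic_rejected(self):
        with pytest.raises(ValueError):
            peak_phase_distribution(self._results([4.0], rhythmic=[False]))

    def test_uniform_planted_phases_near_uniform(self):
        from dielprot.preprocess import mean_normalize
        from dielprot.rhythm import DielRhythmModel
        from dielprot.simulate import SimSpec, generate_ld_dataset

        spec = SimSpec(n_features=600, frac_rhythmic=1.0, fold_range=(4.0, 4.0),
                       noise_cv=0.05, seed=21, phase_choices=tuple(ZTS))
        table, _ = generate_ld_dataset(spec)
        res = DielRhythmModel(mean_normalize(table)).fit()
        out = peak_phase_distribution(res.frame)
        chi2, p = stats.chisquare(out["count"])
        assert p > 0.01


class TestPairing:
    def test_enumerated_fraction(self):
        prot = pd.DataFrame({"peak_zt": [4.0]}, index=["X"])
        mot = pd.DataFrame({"peak_zt": [4.0, 0.0]}, index=["X@1", "X@2"])
        locus = pd.Series({"X@1": "X", "X@2": "X"})
        pairs, frac = pair_protein_phospho(prot, mot, locus)
        assert frac == 0.5 and len(pairs) == 2

    def test_independent_phases_differ_five_sixths(self):
        rng = np.random.default_rng(31)
        loci = [f"L{i}" for i in range(800)]
        prot = pd.DataFrame({"peak_zt": rng.choice(ZTS, 800)}, index=loci)
        mids = [f"{l}@1" for l in loci]
        mot = pd.DataFrame({"peak_zt": rng.choice(ZTS, 800)}, index=mids)
        locus = pd.Series(dict(zip(mids, loci)))
        _, frac = pair_protein_phospho(prot, mot, locus)
        assert frac == pytest.approx(5 / 6, abs=0.05)

    def test_identical_phases_fraction_zero(self):
        prot = pd.DataFrame({"peak_zt": [0.0, 8.0]}, index=["A", "B"])
        mot = pd.DataFrame({"peak_zt": [0.0, 8.0]}, index=["A@1", "B@1"])
        locus = pd.Series({"A@1": "A", "B@1": "B"})
        _, frac = pair_protein_phospho(prot, mot, locus)
        assert frac == 0.0

    def test_empty_join_rejected(self):
        prot = pd.DataFrame({"peak_zt": [0.0]}, index=["A"])
        mot = pd.DataFrame({"peak_zt": [0.0]}, index=["B@1"])
        with pytest.raises(ValueError):
            pair_protein_phospho(prot, mot, pd.Series({"B@1": "B"}))


class TestCategoryEnrichment:
    def test_fisher_matches_hypergeometric_enumeration(self):
        # 2x2 table [[3,1],[1,3]]: members {4 feats}, term holds 3 of them
        background = {f"f{i}" for i in range(8)}
        members = {"f0", "f1", "f2", "f3"}
        term = {"f0", "f1", "f2", "f7"}
        out = category_enrichment(members, background, {"T": term}, mode="fisher")
        # exact two-sided hypergeometric enumeration
        N, K, n = 8, 4, 4
        probs = {k: Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n)) for k in range(5)}
        p_obs = probs[3]
        p_two = float(sum(v for v in probs.values() if v <= p_obs))
        assert p_two == pytest.approx(34 / 70)
        assert out.loc["T", "p"] == pytest.approx(p_two, rel=1e-9)

    def test_term_equal_background_p_one(self):
        bg = {f"f{i}" for i in range(10)}
        out = category_enrichment(set(list(bg)[:4]), bg, {"all": bg}, mode="fisher")
        assert out.loc["all", "p"] == pytest.approx(1.0)

    def test_planted_loading_enrichment_ranks_first(self):
        rng = np.random.default_rng(41)
        feats = [f"f{i}" for i in range(100)]
        load = pd.Series(rng.uniform(0, 0.2, 100), index=feats)
        load.iloc[:15] += 0.8  # planted term gets top loadings
        annotation = {"planted": set(feats[:15]), "random": set(feats[40:55])}
        out = category_enrichment(set(feats), set(feats), annotation,
                                  mode="ks_on_loadings", loadings=load)
        assert out.index[0] == "planted"

    def test_members_must_be_subset(self):
        with pytest.raises(ValueError):
            category_enrichment({"a"}, {"b"}, {"t": {"b"}})
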