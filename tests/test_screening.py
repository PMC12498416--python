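"""Featurization, the RF+GP surrogate, acquisition, campaigns, clustering
and the CNS MPO filter."""

import numpy as np
import pytest
from scipy import stats

from rdkit import DataStructs

import seedkin as sk
from seedkin.screening import FeaturizationError, morgan_fingerprint


class TestFeaturize:
    def test_deterministic(self):
        a = sk.featurize("CCO")
        b = sk.featurize("CCO")
        np.testing.assert_array_equal(a, b)

    def test_canonicalization_invariance(self):
        a = sk.featurize("c1ccccc1")
        b = sk.featurize("C1=CC=CC=C1")
        np.testing.assert_array_equal(a, b)

    def test_disjoint_molecules_zero_tanimoto(self):
        # no shared circular environments -> brute-force bit overlap is 0
        a = sk.featurize("CCCCCC").astype(bool)
        b = sk.featurize("c1ccncc1").astype(bool)
        inter = np.sum(a & b)
        union = np.sum(a | b)
        assert inter / union == 0.0
        assert sk.tanimoto_similarity("CCCCCC", "c1ccncc1") == 0.0

    def test_invalid_smiles_rejected_with_reason(self):
        with pytest.raises(FeaturizationError, match="unparseable"):
            sk.featurize("not_a_molecule((")

    def test_descriptor_block_appended(self):
        assert sk.featurize("CCO", descriptors=True).size == 2048 + 6


def _toy_training_set(n=24, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, 32)).astype(float)
    y = X[:, 0] * 1.5 + X[:, 1] * 0.5 + 1.0
    return X, y


class TestSurrogate:
    def test_gp_interpolates_training_residuals(self):
        X, y = _toy_training_set()
        model = sk.train_surrogate(X, y, n_trees=50)
        pred, _ = model.predict(X)
        # RF + GP residual correction should nearly interpolate clean data
        assert np.max(np.abs(pred - y)) < 0.2

    def test_zero_residuals_give_negligible_gp_correction(self):
        X, _ = _toy_training_set()
        y = X[:, 0]  # exactly representable by the forest
        model = sk.train_surrogate(X, y, n_trees=200)
        resid_mean, _ = model.gp.predict(X, return_std=True)
        assert np.max(np.abs(resid_mean)) < 0.05

    def test_constant_targets_warn_and_fall_back(self):
        X, _ = _toy_training_set()
        with pytest.warns(UserWarning, match="constant targets"):
            model = sk.train_surrogate(X, np.ones(len(X)))
        pred, sd = model.predict(X)
        assert np.allclose(pred, 1.0, atol=0.05)
        assert np.all(sd >= 0)

    def test_needs_eight_molecules(self):
        X, y = _toy_training_set(n=5)
        with pytest.raises(ValueError):
            sk.train_surrogate(X, y)

    def test_beats_label_shuffled_control_on_smooth_landscape(
            self, small_library):
        records, oracle, _ = small_library
        feats = np.stack([sk.featurize(r.smiles, n_bits=512)
                          for r in records])
        y = np.array([oracle(r) for r in records])
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(records))
            train, test = idx[:80], idx[80:160]
            model = sk.train_surrogate(feats[train], y[train],
                                       random_state=seed, n_trees=100)
            rho = stats.spearmanr(model.predict(feats[test])[0],
                                  y[test]).statistic
            y_shuf = y[train].copy()
            rng.shuffle(y_shuf)
            shuf = sk.train_surrogate(feats[train], y_shuf,
                                      random_state=seed, n_trees=100)
            rho_shuf = stats.spearmanr(shuf.predict(feats[test])[0],
                                       y[test]).statistic
            wins += rho > rho_shuf
        assert wins >= 9


class TestAcquisition:
    def test_beta_zero_ranks_by_mean(self):
        mean = np.array([1.0, 3.0, 2.0])
        sd = np.array([9.0, 0.1, 5.0])
        scores = sk.acquisition_score(mean, sd, beta=0.0)
        assert np.argmax(scores) == 1

    def test_equal_means_rank_by_sd(self):
        scores = sk.acquisition_score(np.ones(3),
                                      np.array([0.1, 2.0, 1.0]), beta=1.0)
        assert np.argmax(scores) == 1

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            sk.acquisition_score(np.ones(2), np.ones(2), beta=-0.5)

    def test_top_pick_novelty_non_decreasing_in_beta(self, small_library):
        # brute force over the library: with larger beta the top pick's
        # distance to the tested set must not shrink
        records, oracle, _ = small_library
        feats = np.stack([sk.featurize(r.smiles, n_bits=512)
                          for r in records])
        rng = np.random.default_rng(1)
        train = rng.permutation(len(records))[:60]
        y = np.array([oracle(records[i]) for i in train])
        model = sk.train_surrogate(feats[train], y, n_trees=100)
        pool = np.setdiff1d(np.arange(len(records)), train)
        mean, sd = model.predict(feats[pool])
        fps = [morgan_fingerprint(r.smiles) for r in records]

        def novelty(i):
            return 1.0 - max(DataStructs.TanimotoSimilarity(fps[i], fps[j])
                             for j in train)

        novs = []
        for beta in (0.0, 1.0, 4.0, 16.0):
            top = pool[np.argmax(sk.acquisition_score(mean, sd, beta))]
            novs.append(novelty(top))
        assert all(b >= a - 1e-12 for a, b in zip(novs, novs[1:]))


def _tiny_library(n=40):
    recs = [sk.MoleculeRecord(id=f"T{i:03d}", smiles="C" * (i % 6 + 1))
            for i in range(n)]
    return recs


class TestSelectBatch:
    def _state(self, n=12):
        recs = _tiny_library(n)
        for i, r in enumerate(recs):
            r.features = np.zeros(4)
        return sk.CampaignState(library=recs)

    def test_whole_pool_when_batch_equals_pool(self):
        st = self._state(6)
        scores = {m.id: 1.0 for m in st.library}
        assert len(sk.select_batch(st, 6, scores)) == 6

    def test_tested_molecules_never_returned(self):
        st = self._state(8)
        st.library[0].measured_t12_norm = 1.2
        scores = {m.id: 1.0 for m in st.untested}
        assert st.library[0].id not in sk.select_batch(st, 5, scores)

    def test_cutoff_one_is_pure_greedy_topk(self):
        st = self._state(10)
        scores = {m.id: float(i) for i, m in enumerate(st.library)}
        greedy = sk.select_batch(st, 3, scores)
        with_cut = sk.select_batch(st, 3, scores, diversity_cutoff=1.0)
        assert greedy == with_cut

    def test_ties_broken_lexicographically(self):
        st = self._state(10)
        scores = {m.id: 1.0 for m in st.library}
        assert sk.select_batch(st, 4, scores) == sorted(
            m.id for m in st.library)[:4]

    def test_pool_exhaustion_raises(self):
        st = self._state(3)
        with pytest.raises(ValueError, match="pool"):
            sk.select_batch(st, 5, {m.id: 1.0 for m in st.library})


class TestCampaign:
    def test_constant_oracle_gives_zero_hit_rate(self, small_library):
        records, _, _ = small_library
        st = sk.run_campaign(records[:60], lambda m: 1.0,
                             batch_sizes=(10,), rng_seed=0,
                             initial_size=12, n_trees=20)
        assert all(h["hit_rate"] == 0.0 for h in st.history)

    def test_same_seed_bit_identical_history(self, small_library):
        records, oracle, _ = small_library
        kw = dict(batch_sizes=(10, 10), rng_seed=42, initial_size=20,
                  n_trees=30)
        a = sk.run_campaign(records[:100], oracle, **kw)
        b = sk.run_campaign(records[:100], oracle, **kw)
        assert a.history == b.history
        assert [m.id for m in a.tested] == [m.id for m in b.tested]

    def test_tested_grows_by_batch_size_each_iteration(self, small_library):
        records, oracle, _ = small_library
        st = sk.run_campaign(records[:100], oracle, batch_sizes=(8, 12),
                             rng_seed=1, initial_size=16, n_trees=30)
        assert [h["n_tested"] for h in st.history] == [16, 8, 12]
        assert len(st.tested) == 36
        assert len({m.id for m in st.tested}) == 36  # no molecule twice

    def test_initial_ids_respected(self, small_library):
        records, oracle, _ = small_library
        ids = [r.id for r in records[:10]]
        st = sk.run_campaign(records[:80], oracle, batch_sizes=(8,),
                             rng_seed=0, initial_ids=ids, n_trees=30)
        tested0 = [m.id for m in st.library if m.iteration_tested == 0]
        assert sorted(tested0) == sorted(ids)


class TestTanimotoCluster:
    def test_duplicates_form_single_cluster(self):
        clusters = sk.tanimoto_cluster(["CCO", "OCC", "CCO"])
        assert len(clusters) == 1
        assert sorted(clusters[0]) == [0, 1, 2]

    def test_dissimilar_molecules_are_singletons(self):
        smi = ["CCCCCC", "c1ccncc1", "C1CC1", "CC(=O)OC"]
        clusters = sk.tanimoto_cluster(smi, cutoff=0.78)
        assert len(clusters) == 4

    def test_members_within_cutoff_of_centroid_brute_force(self,
                                                           small_library):
        records, _, _ = small_library
        smi = [r.smiles for r in records[:50]]
        cutoff = 0.78
        clusters = sk.tanimoto_cluster(smi, cutoff=cutoff)
        fps = [morgan_fingerprint(s) for s in smi]
        # full pairwise similarity matrix as the independent check
        for members in clusters:
            centroid = members[0]
            for m in members[1:]:
                sim = DataStructs.TanimotoSimilarity(fps[centroid], fps[m])
                assert sim >= cutoff - 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sk.tanimoto_cluster([])


class TestCnsMpo:
    # hand-computed desirability table: (smiles, expected score, abs tol)
    CASES = [
        # benzene: clogP 1.69 -> 1; clogD 1.69 -> 1; MW 78 -> 1;
        # TPSA 0 -> 0; HBD 0 -> 1; no basic centre -> 1  => 5.0
        ("c1ccccc1", 5.0, 0.01),
        # pyridine: clogP 1.08, TPSA 12.9 -> 0, pKa proxy 5.2 -> 1 => 5.0
        ("c1ccncc1", 5.0, 0.01),
        # phenol: TPSA 20.23 -> ~0.01, HBD 1 -> 0.833 => ~4.85
        ("Oc1ccccc1", 4.84, 0.05),
        # hexadecane: clogP 6.9 -> 0 both; MW 226 -> 1; TPSA 0 -> 0;
        # HBD 0 -> 1; pKa -> 1  => 3.0
        ("CCCCCCCCCCCCCCCC", 3.0, 0.01),
    ]

    @pytest.mark.parametrize("smiles,expected,tol", CASES)
    def test_scores_match_hand_computed_table(self, smiles, expected, tol):
        score, comps = sk.cns_mpo_score(smiles)
        assert score == pytest.approx(expected, abs=tol)
        assert all(0.0 <= v <= 1.0 for v in comps.values())
        assert 0.0 <= score <= 6.0

    def test_component_outside_range_contributes_zero(self):
        _, comps = sk.cns_mpo_score("CCCCCCCCCCCCCCCC")  # clogP ~ 6.9
        assert comps["clogP"] == 0.0
        assert comps["clogD"] == 0.0

    def test_filter_splits_by_threshold(self):
        mols = [sk.MoleculeRecord("ok", "c1ccccc1"),
                sk.MoleculeRecord("greasy", "CCCCCCCCCCCCCCCC")]
        passing, scores, rejected = sk.cns_mpo_filter(mols, threshold=4.0)
        assert [m.id for m in passing] == ["ok"]
        assert rejected[0][0] == "greasy"
        assert set(scores) == {"ok", "greasy"}
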