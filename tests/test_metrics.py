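import itertools

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from molcycle.metrics import (
    ActivationStats,
    activation_stats,
    conversion_metrics,
    descriptor_activations,
    fcd,
    fingerprint,
    frag_similarity,
    fragment_vector,
    intdiv,
    property_profile,
    scaff_similarity,
    scaffold_vector,
    snn,
    tanimoto,
)
from molcycle.mol_features import PRESETS, parse_molecule


def random_bitsets(rng, n, max_bits=40):
    return [
        frozenset(rng.choice(2048, size=rng.integers(1, max_bits), replace=False).tolist())
        for _ in range(n)
    ]


class TestTanimoto:
    def test_identity(self):
        assert tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint(self):
        assert tanimoto({1, 2}, {3, 4}) == 0.0

    def test_hand_example(self):
        assert tanimoto({1, 3, 5}, {3, 5, 7}) == 0.5

    def test_both_empty(self):
        assert tanimoto(set(), set()) == 1.0

    def test_symmetry_and_range(self, rng):
        for a, b in itertools.combinations(random_bitsets(rng, 8), 2):
            t = tanimoto(a, b)
            assert 0.0 <= t <= 1.0
            assert t == tanimoto(b, a)

    def test_against_rdkit(self):
        # independent route: RDKit bit vectors + its own Tanimoto
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        smiles = ["CCO", "CCCO", "c1ccccc1", "Cc1ccccc1", "C1CCCCC1"]
        mols = [Chem.MolFromSmiles(s) for s in smiles]
        fps_rdkit = [gen.GetFingerprint(m) for m in mols]
        fps_mine = [fingerprint(s) for s in smiles]
        for i in range(len(mols)):
            for j in range(len(mols)):
                expected = DataStructs.TanimotoSimilarity(fps_rdkit[i], fps_rdkit[j])
                assert tanimoto(fps_mine[i], fps_mine[j]) == pytest.approx(expected)


class TestSNN:
    def test_subset_gives_one(self, rng):
        r = random_bitsets(rng, 10)
        assert snn(r[:4], r) == 1.0

    def test_single_generated(self):
        g = [frozenset({1, 2})]
        r = [frozenset({1, 3}), frozenset({9, 10, 11})]
        # best match is {1,3}: intersection 1, union 3
        assert snn(g, r) == pytest.approx(1 / 3)

    def test_double_loop_oracle(self, rng):
        g = random_bitsets(rng, 23)
        r = random_bitsets(rng, 31)
        expected = np.mean([max(tanimoto(a, b) for b in r) for a in g])
        assert snn(g, r) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            snn([], random_bitsets(rng, 3))


class TestIntDiv:
    def test_identical_molecules(self):
        fps = [frozenset({1, 2, 3})] * 5
        assert intdiv(fps, 1) == pytest.approx(0.0)
        assert intdiv(fps, 2) == pytest.approx(0.0)

    def test_two_orthogonal_p1(self):
        fps = [frozenset({1}), frozenset({2})]
        assert intdiv(fps, 1) == pytest.approx(0.5)

    def test_two_orthogonal_p2(self):
        fps = [frozenset({1}), frozenset({2})]
        assert intdiv(fps, 2) == pytest.approx(1 - np.sqrt(0.5))

    def test_enumeration_oracle(self, rng):
        fps = random_bitsets(rng, 17)
        for p in (1, 2):
            pairs = [tanimoto(a, b) ** p for a in fps for b in fps]
            expected = 1 - np.mean(pairs) ** (1 / p)
            assert intdiv(fps, p) == pytest.approx(expected, rel=1e-12)

    def test_bad_p(self, rng):
        with pytest.raises(ValueError):
            intdiv(random_bitsets(rng, 3), 3)


class TestFragScaff:
    def test_benzene_toluene_share_scaffold(self):
        counts = scaffold_vector(["c1ccccc1", "Cc1ccccc1"])
        assert counts == {"c1ccccc1": 2}

    def test_duplicates_double(self):
        mols = ["CCOc1ccccc1", "CCN(CC)CC"]
        single = fragment_vector(mols)
        double = fragment_vector(mols * 2)
        assert double == {k: 2 * v for k, v in single.items()}

    def test_empty_map(self):
        assert fragment_vector([]) == {}
        assert scaffold_vector([]) == {}

    def test_identical_sets_give_one(self):
        mols = ["CCOc1ccccc1", "Cc1ccc(O)cc1", "c1ccc2ccccc2c1"]
        assert frag_similarity(mols, list(mols)) == pytest.approx(1.0)
        assert scaff_similarity(mols, list(mols)) == pytest.approx(1.0)

    def test_disjoint_vocabulary_zero(self):
        a = {"fragA": 3}
        b = {"fragB": 2}
        assert frag_similarity(a, b) == pytest.approx(0.0)

    def test_hand_cosine(self):
        a = {"k1": 1, "k2": 1}
        b = {"k1": 1, "k3": 1}
        assert frag_similarity(a, b) == pytest.approx(0.5)
        assert frag_similarity(a, b, as_distance=True) == pytest.approx(0.5)

    def test_symmetry(self):
        g = ["CCO", "CCOc1ccccc1"]
        r = ["CCN", "c1ccc2ccccc2c1"]
        assert frag_similarity(g, r) == pytest.approx(frag_similarity(r, g))
        assert scaff_similarity(
            ["c1ccccc1", "c1ccncc1"], ["c1ccccc1", "C1CCCCC1"]
        ) == pytest.approx(
            scaff_similarity(["c1ccccc1", "C1CCCCC1"], ["c1ccccc1", "c1ccncc1"])
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            frag_similarity({}, {})


class TestFCD:
    def test_identical_zero(self, rng):
        mu = rng.standard_normal(4)
        A = rng.standard_normal((4, 4))
        sigma = A @ A.T
        s = ActivationStats(mu, sigma)
        assert fcd(s, s) == pytest.approx(0.0, abs=1e-8)

    def test_1d_mean_shift(self):
        a = ActivationStats(np.array([0.0]), np.array([[1.0]]))
        b = ActivationStats(np.array([1.0]), np.array([[1.0]]))
        assert fcd(a, b) == pytest.approx(1.0)

    def test_1d_variance_gap(self):
        a = ActivationStats(np.array([0.0]), np.array([[1.0]]))
        b = ActivationStats(np.array([0.0]), np.array([[4.0]]))
        # 1 + 4 - 2*sqrt(1*4) = 1
        assert fcd(a, b) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        def stats():
            mu = rng.standard_normal(3)
            A = rng.standard_normal((3, 3))
            return ActivationStats(mu, A @ A.T)

        a, b = stats(), stats()
        assert fcd(a, b) == pytest.approx(fcd(b, a), rel=1e-6)

    def test_diagonal_closed_form(self, rng):
        # for diagonal covariances: sum mu-diff^2 + sum (sqrt(va)-sqrt(vb))^2
        mu_a, mu_b = rng.standard_normal(5), rng.standard_normal(5)
        va, vb = rng.uniform(0.5, 2.0, 5), rng.uniform(0.5, 2.0, 5)
        a = ActivationStats(mu_a, np.diag(va))
        b = ActivationStats(mu_b, np.diag(vb))
        expected = np.sum((mu_a - mu_b) ** 2) + np.sum((np.sqrt(va) - np.sqrt(vb)) ** 2)
        assert fcd(a, b) == pytest.approx(expected, rel=1e-8)

    def test_asymmetric_sigma_rejected(self):
        with pytest.raises(ValueError):
            ActivationStats(np.zeros(2), np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestActivationStats:
    def test_textbook_oracle(self, rng):
        data = rng.standard_normal((20, 5))
        stats = activation_stats(list(range(20)), model=lambda m: data)
        mu_ref = data.sum(axis=0) / 20
        cov_ref = (data - mu_ref).T @ (data - mu_ref) / 19
        np.testing.assert_allclose(stats.mu, mu_ref, atol=1e-10)
        np.testing.assert_allclose(stats.sigma, cov_ref, atol=1e-10)

    def test_duplicated_molecule_zero_cov(self):
        mols = [parse_molecule("CCO")] * 10
        stats = activation_stats(mols)
        np.testing.assert_allclose(stats.sigma, 0.0, atol=1e-12)

    def test_set_against_itself_zero_fcd(self, small_library):
        s = activation_stats(small_library)
        assert fcd(s, s) == pytest.approx(0.0, abs=1e-8)

    def test_too_few(self):
        with pytest.raises(ValueError):
            activation_stats([parse_molecule("CCO")])

    def test_descriptor_shape(self, small_library):
        acts = descriptor_activations(small_library)
        assert acts.shape == (len(small_library), 9)
        assert np.all(np.isfinite(acts))


class TestConversionMetrics:
    def _spec(self):
        return PRESETS["aliphatic_rings"]

    def test_identity_generator(self):
        sources = [parse_molecule(s) for s in ("C1CCCCC1", "CC1CCCCC1")]
        report = conversion_metrics(sources, list(sources), set(), self._spec(), "x_to_y")
        assert report.valid == 1.0
        assert report.non_identity == 0.0
        assert report.success_rate == 0.0

    def test_worked_four_molecule_example(self):
        # 4 sources; 3 decode; of those, 2 are non-identical and land in the
        # target count set -> valid 0.75, success 0.5
        sources = [parse_molecule(s) for s in
                   ("C1CCCCC1", "CC1CCCCC1", "OC1CCCCC1", "C1CCCC1")]
        generated = [
            parse_molecule("C1CCC2CCCCC2C1"),  # decalin: 2 rings, success
            parse_molecule("C1CC2CCC1C2"),  # norbornane: 2 rings, success
            None,  # decode failure
            parse_molecule("C1CCCC1"),  # identical to its source
        ]
        report = conversion_metrics(sources, generated, set(), self._spec(), "x_to_y")
        assert report.valid == pytest.approx(0.75)
        assert report.success_rate == pytest.approx(0.5)
        assert report.non_identity == pytest.approx(2 / 3)
        assert report.uniqueness == pytest.approx(1.0)

    def test_mode_collapse_uniqueness(self):
        sources = [parse_molecule(s) for s in
                   ("C1CCCCC1", "CC1CCCCC1", "OC1CCCCC1", "C1CCCC1")]
        same = parse_molecule("C1CCC2CCCCC2C1")
        report = conversion_metrics(sources, [same] * 4, set(), self._spec(), "x_to_y")
        assert report.uniqueness == pytest.approx(0.25)

    def test_novelty_against_train_set(self):
        sources = [parse_molecule("C1CCCCC1")]
        gen = [parse_molecule("C1CCC2CCCCC2C1")]
        train = {gen[0].canonical}
        report = conversion_metrics(sources, gen, train, self._spec(), "x_to_y")
        assert report.novelty == 0.0
        report2 = conversion_metrics(sources, gen, set(), self._spec(), "x_to_y")
        assert report2.novelty == 1.0

    def test_direction_target_counts(self):
        # y_to_x: success requires landing in X's count set (exactly 1 ring)
        sources = [parse_molecule("C1CCC2CCCCC2C1")]
        gen = [parse_molecule("C1CCCCC1")]
        report = conversion_metrics(sources, gen, set(), self._spec(), "y_to_x")
        assert report.success_rate == 1.0

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            conversion_metrics([parse_molecule("CCO")], [], set(), self._spec(), "x_to_y")

    def test_order_permutation_invariant(self, rng):
        sources = [parse_molecule(s) for s in
                   ("C1CCCCC1", "CC1CCCCC1", "OC1CCCCC1", "C1CCCC1")]
        generated = [parse_molecule(s) for s in
                     ("C1CCC2CCCCC2C1", "C1CC2CCC1C2", "C1CCCCC1", "CC1CCCCC1")]
        base = conversion_metrics(sources, generated, set(), self._spec(), "x_to_y")
        perm = rng.permutation(4)
        shuffled = conversion_metrics([sources[i] for i in perm],
                                      [generated[i] for i in perm],
                                      set(), self._spec(), "x_to_y")
        assert base.as_dict() == shuffled.as_dict()


class TestPropertyProfile:
    def test_ethanol_mw(self):
        prof = property_profile([parse_molecule("CCO")])
        assert prof.mw[0] == pytest.approx(46.07, abs=0.01)

    def test_sa_range(self, toy_valid):
        prof = property_profile(toy_valid)
        assert np.all(prof.sa >= 1.0)
        assert np.all(prof.sa <= 10.0)

    def test_duplicate_mean_equals_single(self):
        single = property_profile([parse_molecule("CCO")])
        dup = property_profile([parse_molecule("CCO")] * 5)
        assert dup.summary["mw"]["mean"] == pytest.approx(single.mw[0])
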