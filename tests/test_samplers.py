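from itertools import combinations

import numpy as np
import pytest

from molsample.fingerprints_io import FingerprintDataset
from molsample.samplers import (
    SAMPLER_NAMES,
    apply_sampler,
    augmented_random_oversample,
    augmented_random_undersample,
    build_mcf,
    kmedoids_restart_undersample,
    kmedoids_swap_undersample,
    random_oversample,
    random_undersample,
    sample_none,
    smote,
)
from molsample.similarity import tanimoto

from .conftest import random_imbalanced


# ---------------------------------------------------------------------------
# MCF construction
# ---------------------------------------------------------------------------


class TestBuildMCF:
    def test_worked_example(self):
        rows = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0]], dtype=np.uint8)
        profile = build_mcf(rows, rows)
        # per-bit freqs [1, 2/3, 1/3, 0]; threshold = mean = 0.5; mean set bits = 2
        assert profile.avg_frequency == pytest.approx(0.5)
        assert profile.n_features == 2
        assert [b for b, _ in profile.candidate_bits] == [0, 1]
        assert profile.candidate_bits[0][1] == pytest.approx(1.0)
        assert profile.candidate_bits[1][1] == pytest.approx(2 / 3)
        np.testing.assert_array_equal(profile.fingerprint, [1, 1, 0, 0])
        assert not profile.fallback_used

    def test_identical_rows_reproduce_row(self):
        row = np.array([1, 0, 1, 0, 1], dtype=np.uint8)
        rows = np.tile(row, (4, 1))
        profile = build_mcf(rows, rows)
        np.testing.assert_array_equal(profile.fingerprint, row)

    def test_all_zero_reference_errors(self):
        rows = np.zeros((3, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="no set bits"):
            build_mcf(rows, rows)

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            build_mcf(np.empty((0, 4)), np.ones((2, 4)))
        with pytest.raises(ValueError):
            build_mcf(np.ones((2, 0)), np.ones((2, 0)))

    def test_separate_frequency_base(self):
        # threshold and n_features from reference; candidate freqs from the base
        ref = np.array([[1, 1, 0, 0]], dtype=np.uint8)  # avg_freq 0.5, n_features 2
        base = np.array([[0, 0, 1, 1], [0, 1, 1, 1]], dtype=np.float64)
        profile = build_mcf(ref, base)
        # base freqs [0, .5, 1, 1]: bits 2, 3 exceed 0.5
        assert [b for b, _ in profile.candidate_bits] == [2, 3]
        np.testing.assert_array_equal(profile.fingerprint, [0, 0, 1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_n_features_is_round_half_up_of_mean_setbits(self, seed):
        rng = np.random.default_rng(seed)
        rows = (rng.random((rng.integers(2, 12), 16)) < 0.5).astype(np.uint8)
        if rows.sum() == 0:
            rows[0, 0] = 1
        profile = build_mcf(rows, rows)
        mean_setbits = rows.sum(axis=1).mean()
        import math

        assert profile.n_features == int(math.floor(mean_setbits + 0.5))
        assert profile.n_features == int(profile.fingerprint.sum())

    def test_scarcity_fallback_flagged(self):
        # uniform frequencies: no bit strictly exceeds the average -> fallback
        rows = np.ones((3, 4), dtype=np.uint8)
        profile = build_mcf(rows, rows)
        assert profile.fallback_used
        assert profile.n_features == 4
        np.testing.assert_array_equal(profile.fingerprint, [1, 1, 1, 1])

    def test_set_bits_exceed_threshold_unless_fallback(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            rows = (rng.random((8, 12)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            if rows.sum() == 0:
                continue
            profile = build_mcf(rows, rows)
            if not profile.fallback_used:
                freqs = rows.mean(axis=0)
                for j in np.flatnonzero(profile.fingerprint):
                    assert freqs[j] > profile.avg_frequency


# ---------------------------------------------------------------------------
# uniform contract over all nine conditions
# ---------------------------------------------------------------------------

BALANCING = [n for n in SAMPLER_NAMES if n != "none"]
UNDER = ["randus", "augrandus", "kmedoids1", "kmedoids2"]
OVER = ["randos", "augrandos", "smotetc", "smotevdm"]


@pytest.mark.parametrize("name", BALANCING)
def test_exact_balance(name, medium_imbalanced):
    result = apply_sampler(name, medium_imbalanced, seed=3)
    counts = result.dataset.class_counts()
    assert counts[0] == counts[1]


@pytest.mark.parametrize("name", SAMPLER_NAMES)
def test_determinism(name, medium_imbalanced):
    r1 = apply_sampler(name, medium_imbalanced, seed=11)
    r2 = apply_sampler(name, medium_imbalanced, seed=11)
    np.testing.assert_array_equal(r1.dataset.X, r2.dataset.X)
    np.testing.assert_array_equal(r1.dataset.y, r2.dataset.y)
    assert r1.dataset.ids == r2.dataset.ids
    assert r1.audit_json() == r2.audit_json()


@pytest.mark.parametrize("name", UNDER)
def test_undersamplers_return_subsets(name, medium_imbalanced):
    result = apply_sampler(name, medium_imbalanced, seed=5)
    original = {(i, tuple(row)) for i, row in zip(medium_imbalanced.ids, medium_imbalanced.X)}
    for i, row in zip(result.dataset.ids, result.dataset.X):
        assert (i, tuple(row)) in original


@pytest.mark.parametrize("name", OVER)
def test_oversamplers_are_supersets(name, medium_imbalanced):
    result = apply_sampler(name, medium_imbalanced, seed=5)
    n = medium_imbalanced.n_samples
    assert result.dataset.ids[:n] == medium_imbalanced.ids
    np.testing.assert_array_equal(result.dataset.X[:n], medium_imbalanced.X)
    np.testing.assert_array_equal(result.dataset.y[:n], medium_imbalanced.y)


@pytest.mark.parametrize("name", BALANCING)
def test_single_class_input_errors(name):
    ds = FingerprintDataset(ids=["a", "b"], X=np.ones((2, 4)), y=[0, 0])
    with pytest.raises(ValueError, match="both classes"):
        apply_sampler(name, ds, seed=0)


@pytest.mark.parametrize("name", BALANCING)
def test_minority_label_not_hardwired(name):
    # class 1 is the MAJORITY here; samplers must balance all the same
    ds = random_imbalanced(seed=9, n_majority=16, n_minority=6)
    flipped = FingerprintDataset(ids=ds.ids, X=ds.X, y=1 - ds.y)
    result = apply_sampler(name, flipped, seed=2)
    counts = result.dataset.class_counts()
    assert counts[0] == counts[1] == (6 if name in UNDER else 16)


def test_unknown_sampler_name(medium_imbalanced):
    with pytest.raises(ValueError, match="valid methods"):
        apply_sampler("bogus", medium_imbalanced)


# ---------------------------------------------------------------------------
# individual samplers
# ---------------------------------------------------------------------------


class TestSampleNone:
    def test_identity(self, tiny_imbalanced):
        result = sample_none(tiny_imbalanced, seed=0)
        np.testing.assert_array_equal(result.dataset.X, tiny_imbalanced.X)
        np.testing.assert_array_equal(result.dataset.y, tiny_imbalanced.y)
        assert result.dataset.ids == tiny_imbalanced.ids

    def test_empty_audit(self, tiny_imbalanced):
        result = sample_none(tiny_imbalanced, seed=0)
        assert result.removed_indices == []
        assert result.duplicated_indices == []
        assert result.synthetic_parents == []
        assert result.iterations == 0


class TestRandomUndersample:
    def test_sizes_and_removed(self, tiny_imbalanced):
        result = random_undersample(tiny_imbalanced, seed=1)
        counts = result.dataset.class_counts()
        assert counts == {0: 4, 1: 4}
        assert len(result.removed_indices) == 6
        assert all(tiny_imbalanced.y[i] == 0 for i in result.removed_indices)

    def test_minority_untouched(self, tiny_imbalanced):
        result = random_undersample(tiny_imbalanced, seed=1)
        kept_min = [i for i in result.dataset.ids if tiny_imbalanced.y[tiny_imbalanced.ids.index(i)] == 1]
        assert len(kept_min) == 4

    def test_already_balanced_unchanged(self):
        ds = random_imbalanced(seed=2, n_majority=5, n_minority=5)
        result = random_undersample(ds, seed=0)
        assert result.dataset.ids == ds.ids
        assert result.removed_indices == []

    def test_same_seed_same_removal(self, tiny_imbalanced):
        r1 = random_undersample(tiny_imbalanced, seed=7)
        r2 = random_undersample(tiny_imbalanced, seed=7)
        assert r1.removed_indices == r2.removed_indices


class TestAugmentedRandomUndersample:
    def test_conservation(self):
        ds = random_imbalanced(seed=3, n_majority=10, n_minority=5)
        result = augmented_random_undersample(ds, seed=4)
        assert result.dataset.class_counts() == {0: 5, 1: 5}
        assert len(result.removed_indices) == 5

    def test_audit_replay(self):
        """Replay the trail: every removed row had Tanimoto-to-MCF >= the
        batch threshold at the step it was removed, against the recomputed MCF."""
        ds = random_imbalanced(seed=5, n_majority=24, n_minority=6, n_bits=20)
        result = augmented_random_undersample(ds, seed=8, batch_fraction=0.3,
                                              removal_fraction=0.5)
        min_idx = [i for i in range(ds.n_samples) if ds.y[i] == 1]
        surviving = [i for i in range(ds.n_samples) if ds.y[i] == 0]
        from molsample.samplers import build_mcf as rebuild

        for step in result.iteration_log:
            maj_rows = ds.X[surviving]
            freq_rows = np.vstack([ds.X[min_idx], maj_rows])
            profile = rebuild(maj_rows, freq_rows)
            assert sorted(np.flatnonzero(profile.fingerprint)) == sorted(step["mcf_bits"])
            for i in step["removed"]:
                assert i in step["batch_indices"]
                sim = tanimoto(ds.X[i], profile.fingerprint)
                assert sim >= step["threshold_similarity"] - 1e-12
            surviving = [i for i in surviving if i not in set(step["removed"])]
        assert len(surviving) == len(min_idx)

    def test_full_fractions_terminate_with_cap(self):
        ds = random_imbalanced(seed=6, n_majority=12, n_minority=4)
        result = augmented_random_undersample(ds, seed=1, batch_fraction=1.0,
                                              removal_fraction=1.0)
        assert result.dataset.class_counts() == {0: 4, 1: 4}
        assert result.iterations == 1

    def test_bad_fractions(self, tiny_imbalanced):
        with pytest.raises(ValueError, match="fraction"):
            augmented_random_undersample(tiny_imbalanced, batch_fraction=0.0)
        with pytest.raises(ValueError, match="fraction"):
            augmented_random_undersample(tiny_imbalanced, removal_fraction=1.5)


class TestRandomOversample:
    def test_sizes(self, tiny_imbalanced):
        result = random_oversample(tiny_imbalanced, seed=1)
        assert result.dataset.class_counts() == {0: 10, 1: 10}
        assert len(result.duplicated_indices) == 6

    def test_appended_rows_are_copies(self, tiny_imbalanced):
        result = random_oversample(tiny_imbalanced, seed=1)
        minority_rows = {tuple(r) for r in tiny_imbalanced.X[tiny_imbalanced.y == 1]}
        for row in result.dataset.X[tiny_imbalanced.n_samples:]:
            assert tuple(row) in minority_rows

    def test_parents_recorded(self, tiny_imbalanced):
        result = random_oversample(tiny_imbalanced, seed=3)
        for n, parent in enumerate(result.duplicated_indices):
            assert tiny_imbalanced.y[parent] == 1
            np.testing.assert_array_equal(
                result.dataset.X[tiny_imbalanced.n_samples + n],
                tiny_imbalanced.X[parent],
            )


class TestAugmentedRandomOversample:
    def test_conservation(self):
        ds = random_imbalanced(seed=8, n_majority=12, n_minority=3)
        result = augmented_random_oversample(ds, seed=2)
        assert result.dataset.class_counts() == {0: 12, 1: 12}
        assert result.dataset.n_samples == 15 + 9

    def test_audit_replay(self):
        """Each duplicated ancestor belonged to the most-dissimilar batch of
        its iteration, replayed against the recomputed MCF."""
        ds = random_imbalanced(seed=9, n_majority=20, n_minority=5, n_bits=20)
        result = augmented_random_oversample(ds, seed=3, batch_fraction=0.4,
                                             duplication_fraction=0.5)
        for step in result.iteration_log:
            for anc in step["duplicated"]:
                assert anc in step["batch_ancestors"]
                assert ds.y[anc] == 1

    def test_identical_minority_terminates(self):
        X = np.vstack([np.ones((8, 6)), np.tile([1, 0, 1, 0, 1, 0], (2, 1))]).astype(np.uint8)
        ds = FingerprintDataset(ids=[f"c{i}" for i in range(10)], X=X,
                                y=[0] * 8 + [1] * 2)
        result = augmented_random_oversample(ds, seed=0)
        assert result.dataset.class_counts() == {0: 8, 1: 8}
        for row in result.dataset.X[10:]:
            np.testing.assert_array_equal(row, [1, 0, 1, 0, 1, 0])


def brute_force_best_cost(S: np.ndarray, n_medoids: int) -> float:
    """Exhaustive k-medoids oracle: max over all medoid subsets of the
    total similarity of each row to its most-similar medoid."""
    m = S.shape[0]
    best = -np.inf
    for combo in combinations(range(m), n_medoids):
        cost = S[:, combo].max(axis=1).sum()
        best = max(best, cost)
    return float(best)


def brute_tanimoto_matrix(rows: np.ndarray) -> np.ndarray:
    m = len(rows)
    S = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            S[i, j] = tanimoto(rows[i], rows[j])
    return S


class TestKMedoidsRestart:
    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_matches_bruteforce(self, seed):
        ds = random_imbalanced(seed=seed, n_majority=6, n_minority=2, n_bits=10)
        result = kmedoids_restart_undersample(ds, seed=seed, exhaustive=True)
        S = brute_tanimoto_matrix(ds.X[ds.y == 0])
        assert result.iteration_log[0]["best_cost"] == pytest.approx(
            brute_force_best_cost(S, 2)
        )
        assert result.iterations == 15  # C(6,2) draws

    def test_best_cost_is_max_of_draws(self, medium_imbalanced):
        result = kmedoids_restart_undersample(medium_imbalanced, seed=4, restarts=20)
        log = result.iteration_log[0]
        assert log["best_cost"] == pytest.approx(max(log["costs"]))
        assert result.iterations == 20

    def test_medoid_count_is_minority_count(self, medium_imbalanced):
        result = kmedoids_restart_undersample(medium_imbalanced, seed=0, restarts=5)
        assert result.params["n_medoids"] == 12
        assert result.dataset.class_counts() == {0: 12, 1: 12}

    def test_kept_majority_are_input_rows(self, medium_imbalanced):
        result = kmedoids_restart_undersample(medium_imbalanced, seed=0, restarts=5)
        input_ids = set(medium_imbalanced.ids)
        assert set(result.dataset.ids) <= input_ids


class TestKMedoidsSwap:
    def test_final_cost_at_least_initial(self, medium_imbalanced):
        result = kmedoids_swap_undersample(medium_imbalanced, seed=5)
        log = result.iteration_log[0]
        assert log["best_cost"] >= log["initial_cost"]
        assert log["best_cost"] == pytest.approx(max(log["evaluated_costs"]))

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_by_bruteforce_optimum(self, seed):
        ds = random_imbalanced(seed=20 + seed, n_majority=5, n_minority=2, n_bits=10)
        result = kmedoids_swap_undersample(ds, seed=seed, swaps_per_medoid=30)
        S = brute_tanimoto_matrix(ds.X[ds.y == 0])
        optimum = brute_force_best_cost(S, 2)
        log = result.iteration_log[0]
        assert log["initial_cost"] <= log["best_cost"] <= optimum + 1e-12

    def test_output_majority_subset_of_input(self, medium_imbalanced):
        result = kmedoids_swap_undersample(medium_imbalanced, seed=1)
        input_rows = {(i, tuple(r)) for i, r in zip(medium_imbalanced.ids, medium_imbalanced.X)}
        for i, row in zip(result.dataset.ids, result.dataset.X):
            assert (i, tuple(row)) in input_rows


class TestSMOTE:
    def test_two_of_three_vote_hand_example(self):
        # minority: seed [1,1,0] with neighbours [1,0,0] and [1,1,1] -> [1,1,0]
        X = np.array(
            [[0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 1, 1],
             [1, 1, 0], [1, 0, 0], [1, 1, 1]],
            dtype=np.uint8,
        )
        ds = FingerprintDataset(ids=[f"c{i}" for i in range(7)], X=X,
                                y=[0, 0, 0, 0, 1, 1, 1])
        result = smote(ds, seed=0, k=2)
        assert result.dataset.class_counts() == {0: 4, 1: 4}
        syn = result.dataset.X[7]
        s, n1, n2 = result.synthetic_parents[0]
        votes = ds.X[s].astype(int) + ds.X[n1] + ds.X[n2]
        np.testing.assert_array_equal(syn, (votes >= 2).astype(np.uint8))
        # any seed picks both of its 2 neighbours: vote over all three minority rows
        np.testing.assert_array_equal(syn, [1, 1, 0])

    def test_identical_parents_identical_child(self):
        X = np.vstack([np.zeros((6, 4)), np.tile([1, 0, 1, 0], (3, 1))]).astype(np.uint8)
        ds = FingerprintDataset(ids=[f"c{i}" for i in range(9)], X=X,
                                y=[0] * 6 + [1] * 3)
        result = smote(ds, seed=1, k=2)
        for row in result.dataset.X[9:]:
            np.testing.assert_array_equal(row, [1, 0, 1, 0])

    def test_size_arithmetic(self):
        ds = random_imbalanced(seed=30, n_majority=20, n_minority=8)
        result = smote(ds, seed=2, k=5)
        assert len(result.synthetic_parents) == 12
        assert result.dataset.class_counts() == {0: 20, 1: 20}

    @pytest.mark.parametrize("metric", ["tanimoto", "vdm"])
    def test_every_bit_agrees_with_two_parents(self, metric):
        ds = random_imbalanced(seed=31, n_majority=25, n_minority=8, n_bits=24)
        result = smote(ds, seed=3, k=4, metric=metric)
        n = ds.n_samples
        for r, (s, n1, n2) in enumerate(result.synthetic_parents):
            child = result.dataset.X[n + r].astype(int)
            votes = ds.X[s].astype(int) + ds.X[n1] + ds.X[n2]
            agree = (child == 1) & (votes >= 2) | (child == 0) & (votes <= 1)
            assert agree.all()

    def test_parents_are_minority_rows(self):
        ds = random_imbalanced(seed=32, n_majority=15, n_minority=7)
        result = smote(ds, seed=4, k=3)
        for triple in result.synthetic_parents:
            assert len(set(triple)) == 3  # seed and two distinct neighbours
            for p in triple:
                assert ds.y[p] == 1

    def test_k_too_large_for_minority(self):
        ds = random_imbalanced(seed=33, n_majority=12, n_minority=4)
        with pytest.raises(ValueError, match="lower k"):
            smote(ds, seed=0, k=5)

    def test_seed_rows_cycle_evenly(self):
        # oversampling above 100%: reuse counts differ by at most one per pass
        ds = random_imbalanced(seed=34, n_majority=30, n_minority=6)
        result = smote(ds, seed=5, k=3)
        seeds_used = [s for s, _, _ in result.synthetic_parents]
        counts = {s: seeds_used.count(s) for s in set(seeds_used)}
        assert max(counts.values()) - min(counts.values()) <= 1
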