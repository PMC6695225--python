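"""Synthetic generators: determinism, planted signal, toy structures."""

import numpy as np
import pytest

from rawmsa.labels import classify_rsa, contact_map_from_coords, long_range_pairs
from rawmsa.synthetic import (
    SS_EMISSION_SETS,
    SyntheticConfig,
    generate_contact_msa,
    generate_ss_msa,
    generate_toy_structure,
)


class TestConfig:
    def test_transition_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SyntheticConfig(ss_transition=np.ones((3, 3)))

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            SyntheticConfig(emission_strength=1.5)


class TestSsGenerator:
    def test_deterministic_per_seed(self):
        cfg = SyntheticConfig(L=40, N=10, seed=11)
        a1, l1 = generate_ss_msa(cfg)
        a2, l2 = generate_ss_msa(cfg)
        assert a1.sequences == a2.sequences
        assert np.array_equal(l1.ss3, l2.ss3)

    def test_labels_match_alignment_width(self):
        aln, labels = generate_ss_msa(SyntheticConfig(L=55, N=8, seed=0))
        assert labels.length == aln.length == 55
        assert aln.n_sequences == 8

    def test_master_row_has_no_gaps(self):
        aln, _ = generate_ss_msa(SyntheticConfig(L=50, N=20, gap_rate=0.3, seed=2))
        assert "-" not in aln.master

    def test_noiseless_limit_identifies_class_exactly(self):
        cfg = SyntheticConfig(L=30, N=15, emission_strength=1.0, gap_rate=0.0, seed=5)
        aln, labels = generate_ss_msa(cfg)
        for i, ss in enumerate(labels.ss3):
            column = {seq[i] for seq in aln.sequences}
            assert column <= set(SS_EMISSION_SETS[ss])

    def test_class_frequencies_near_stationary_distribution(self):
        # symmetric sticky chain -> uniform stationary distribution (1/3 each);
        # the sticky chain's long runs make per-protein frequencies heavily
        # autocorrelated, so pool enough proteins for the band to be ~3 sigma
        counts = {"H": 0, "E": 0, "C": 0}
        total = 0
        for i in range(150):
            _, labels = generate_ss_msa(SyntheticConfig(L=60, N=2, seed=100 + i))
            for c in labels.ss3:
                counts[c] += 1
                total += 1
        for c, n in counts.items():
            assert abs(n / total - 1 / 3) < 0.05

    def test_rsa_labels_consistent_with_thresholds(self):
        _, labels = generate_ss_msa(SyntheticConfig(L=40, N=5, seed=9))
        for frac, c4, c2 in zip(labels.rsa, labels.rsa4, labels.rsa2):
            assert classify_rsa(frac, "four") == c4
            assert classify_rsa(frac, "two") == c2


def column_mutual_information(a, b):
    m = 0.0
    for x in set(a):
        pa = (a == x).mean()
        for y in set(b):
            pb = (b == y).mean()
            pxy = ((a == x) & (b == y)).mean()
            if pxy > 0:
                m += pxy * np.log(pxy / (pa * pb))
    return m


class TestContactGenerator:
    def test_deterministic_per_seed(self):
        cfg = SyntheticConfig(L=30, N=10, seed=4)
        a1, c1 = generate_contact_msa(cfg)
        a2, c2 = generate_contact_msa(cfg)
        assert a1.sequences == a2.sequences
        assert np.array_equal(c1.values, c2.values)

    def test_short_proteins_rejected(self):
        with pytest.raises(ValueError):
            generate_contact_msa(SyntheticConfig(L=24, N=10))

    def test_map_symmetric_with_only_planted_long_range_contacts(self):
        _, cmap = generate_contact_msa(SyntheticConfig(L=40, N=10, seed=8))
        assert np.array_equal(cmap.values, cmap.values.T)
        planted = [
            (i, j)
            for i in range(40)
            for j in range(i + 1, 40)
            if cmap.values[i, j]
        ]
        assert planted  # something was planted
        assert all(j - i > 23 for i, j in planted)

    def test_zero_coupling_removes_covariation(self):
        cfg = SyntheticConfig(L=30, N=500, coupling_strength=0.0, seed=6)
        aln, cmap = generate_contact_msa(cfg)
        arr = np.array([list(s) for s in aln.sequences])
        rng = np.random.default_rng(0)
        for i, j in [(a - 1, b - 1) for a, b in sorted(long_range_pairs(30))[:5]]:
            raw = column_mutual_information(arr[:, i], arr[:, j])
            null = np.mean(
                [column_mutual_information(rng.permutation(arr[:, i]), arr[:, j]) for _ in range(3)]
            )
            assert abs(raw - null) < 0.05

    def test_planted_pairs_have_highest_mutual_information(self):
        # bias-corrected MI (permutation null) separates planted pairs from
        # the 99th percentile of background long-range pairs
        cfg = SyntheticConfig(L=60, N=1000, seed=3)
        aln, cmap = generate_contact_msa(cfg)
        arr = np.array([list(s) for s in aln.sequences])
        rng = np.random.default_rng(0)

        def corrected(i, j):
            raw = column_mutual_information(arr[:, i], arr[:, j])
            null = np.mean(
                [column_mutual_information(rng.permutation(arr[:, i]), arr[:, j]) for _ in range(2)]
            )
            return raw - null

        eligible = [(a - 1, b - 1) for a, b in sorted(long_range_pairs(60))]
        planted = [p for p in eligible if cmap.values[p]]
        background = [p for p in eligible if not cmap.values[p]]
        background = [background[k] for k in rng.choice(len(background), 150, replace=False)]
        planted_mi = [corrected(*p) for p in planted]
        background_mi = [corrected(*p) for p in background]
        assert min(planted_mi) > np.percentile(background_mi, 99)


class TestToyStructure:
    def test_straight_chain_contacts_within_two_neighbours(self):
        coords, cmap = generate_toy_structure(10, seed=0)
        recomputed = contact_map_from_coords(coords)
        assert np.array_equal(recomputed.values, cmap.values)
        idx = np.arange(10)
        expected = (np.abs(idx[:, None] - idx[None, :]) <= 2).astype(np.int8)
        assert np.array_equal(cmap.values, expected)

    def test_minimal_chain_is_in_contact(self):
        coords, cmap = generate_toy_structure(2, seed=1)
        assert cmap.values[0, 1] == 1
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(3.8)

    def test_rigid_motion_leaves_contact_map_unchanged(self):
        _, c1 = generate_toy_structure(15, seed=0)
        coords2, c2 = generate_toy_structure(15, seed=99)
        assert np.array_equal(c1.values, c2.values)
        assert np.array_equal(contact_map_from_coords(coords2).values, c2.values)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_toy_structure(1)
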