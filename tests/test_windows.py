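"""Window extraction, identity clustering, balancing and I/O."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from khiblearn.windows import (
    ClusterSet,
    PeptideWindow,
    ProteinRecord,
    balance_and_split,
    build_windows,
    enumerate_negative_windows,
    extract_window,
    greedy_cluster,
    read_fasta,
    read_site_table,
    read_windows_tsv,
    window_identity,
    write_fasta,
    write_site_table,
    write_windows_tsv,
)
from khiblearn.simulate import AA20

from conftest import random_window


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

class TestExtractWindow:
    def test_exact_fit_no_padding(self, rng):
        seq = random_window(rng, flank=21)
        prot = ProteinRecord("P1", seq)
        w = extract_window(prot, 22, flank=21)
        assert w.sequence == seq and "X" not in w.sequence

    def test_left_padding(self):
        w = extract_window(ProteinRecord("P1", "MKAV"), 2, flank=2, strict=True)
        assert w.sequence == "XMKAV"

    def test_boundary_site_heavy_padding(self):
        w = extract_window(ProteinRecord("P1", "KR"), 1, flank=21)
        assert w.sequence == "X" * 21 + "KR" + "X" * 20
        assert w.centre == "K"

    def test_position_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            extract_window(ProteinRecord("P1", "MKAV"), 9, flank=2)

    def test_strict_mode_rejects_non_lysine_centre(self):
        with pytest.raises(ValueError, match="P1.*position 1"):
            extract_window(ProteinRecord("P1", "MKAV"), 1, flank=2)
        # non-strict allows it
        w = extract_window(ProteinRecord("P1", "MKAV"), 1, flank=2, strict=False)
        assert w.centre == "M"

    def test_nonstandard_residues_mapped_to_pad(self, caplog):
        with caplog.at_level(logging.WARNING):
            prot = ProteinRecord("P1", "MKUB")
        assert prot.sequence == "MKXX"
        assert "non-standard" in caplog.text

    def test_window_invariants_enforced(self):
        with pytest.raises(ValueError, match="length"):
            PeptideWindow("AKA", flank=2)
        with pytest.raises(ValueError, match="contiguous"):
            PeptideWindow("AXKAA", flank=2)


class TestEnumerateNegatives:
    def test_skips_annotated_positives(self):
        prot = ProteinRecord("P1", "AKAKA")
        wins = enumerate_negative_windows(prot, {2}, flank=1)
        assert len(wins) == 1
        assert wins[0].sequence == "AKA" and wins[0].source == ("P1", 4)
        assert wins[0].label == "negative"

    def test_no_lysines_gives_empty(self):
        assert enumerate_negative_windows(ProteinRecord("P1", "AGAGA"), {1}, 1) == []

    def test_count_matches_direct_residue_scan(self, rng):
        seq = "".join(AA20[i] for i in rng.integers(0, 20, size=200))
        k_positions = [i + 1 for i, c in enumerate(seq) if c == "K"]
        if len(k_positions) < 4:
            seq = seq[:50] + "KKKK" + seq[54:]
            k_positions = [i + 1 for i, c in enumerate(seq) if c == "K"]
        positives = set(k_positions[:3])
        prot = ProteinRecord("P1", seq)
        wins = enumerate_negative_windows(prot, positives, flank=21)
        assert len(wins) == len(k_positions) - 3
        assert [w.source[1] for w in wins] == sorted(w.source[1] for w in wins)


# ---------------------------------------------------------------------------
# identity + clustering
# ---------------------------------------------------------------------------

class TestIdentity:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetric_and_reflexive(self, seed):
        r = np.random.default_rng(seed)
        a = random_window(r, flank=5, n_pad_left=int(r.integers(0, 3)))
        b = random_window(r, flank=5, n_pad_right=int(r.integers(0, 3)))
        assert window_identity(a, b) == pytest.approx(window_identity(b, a))
        assert window_identity(a, a) == 1.0
        assert 0.0 <= window_identity(a, b) <= 1.0

    def test_pad_never_counts_as_match(self):
        assert window_identity("XKA", "XKA") == 1.0  # denominator excludes X-X
        assert window_identity("XKA", "AKA") == pytest.approx(2 / 3)


def _oracle_greedy(seqs, threshold):
    """All-pairs greedy clustering against representatives, no shortcuts."""
    clusters, reps = [], []
    for i, s in enumerate(seqs):
        for ci, rep in enumerate(reps):
            ident = window_identity(s, seqs[rep])
            if ident > threshold or ident == 1.0:
                clusters[ci].append(i)
                break
        else:
            clusters.append([i])
            reps.append(i)
    return clusters, reps


class TestGreedyCluster:
    def _windows(self, seqs, flank):
        return [PeptideWindow(s, flank, "unknown", ("P", i)) for i, s in enumerate(seqs)]

    def test_identical_windows_form_one_cluster(self, rng):
        w = random_window(rng, flank=3)
        cs = greedy_cluster(self._windows([w] * 5, 3), 0.4)
        assert len(cs) == 1 and sorted(cs.clusters[0]) == [0, 1, 2, 3, 4]

    def test_disjoint_windows_stay_singletons(self):
        cs = greedy_cluster(self._windows(["AAKAA", "CCKCC"], 2), 0.9)
        assert len(cs) == 2

    def test_matches_bruteforce_oracle(self, rng):
        seqs = [random_window(rng, flank=21) for _ in range(12)]
        # plant some near-duplicates so merging actually happens
        seqs += [seqs[0][:10] + seqs[1][10:], seqs[2]]
        wins = self._windows(seqs, 21)
        got = greedy_cluster(wins, 0.4, canonicalize=False)
        want_clusters, want_reps = _oracle_greedy(seqs, 0.4)
        assert got.clusters == want_clusters
        assert got.representatives == want_reps

    def test_mixed_lengths_rejected(self):
        wins = [PeptideWindow("AKA", 1), PeptideWindow("AAKAA", 2)]
        with pytest.raises(ValueError, match="mixed"):
            greedy_cluster(wins, 0.4)

    def test_threshold_one_merges_only_exact_duplicates(self, rng):
        a = random_window(rng, flank=3)
        b = a[:-1] + ("C" if a[-1] != "C" else "D")
        cs = greedy_cluster(self._windows([a, a, b], 3), 1.0)
        assert len(cs) == 2

    def test_cluster_count_bounded_and_partition(self, rng):
        wins = self._windows([random_window(rng, flank=4) for _ in range(30)], 4)
        cs = greedy_cluster(wins, 0.4)
        members = sorted(i for c in cs.clusters for i in c)
        assert members == list(range(30))
        assert len(cs) <= 30

    def test_representative_membership_enforced(self):
        with pytest.raises(ValueError, match="representative"):
            ClusterSet([[0, 1]], [2], 0.4)


# ---------------------------------------------------------------------------
# balancing and splitting
# ---------------------------------------------------------------------------

def _singleton_clusters(windows):
    return ClusterSet([[i] for i in range(len(windows))], list(range(len(windows))), 0.4)


class TestBalanceAndSplit:
    def _pools(self, rng, n_pos, n_neg, flank=5):
        pos = [
            PeptideWindow(random_window(rng, flank), flank, "positive", ("P", i))
            for i in range(n_pos)
        ]
        neg = [
            PeptideWindow(random_window(rng, flank), flank, "negative", ("N", i))
            for i in range(n_neg)
        ]
        return pos, neg

    def test_equal_class_counts(self, rng):
        pos, neg = self._pools(rng, 3, 10)
        sel, split = balance_and_split(
            pos, _singleton_clusters(pos), neg, _singleton_clusters(neg),
            test_fraction=1 / 3, n_folds=2, seed=1,
        )
        labels = [w.label for w in sel]
        assert len(sel) == 6
        assert labels.count("positive") == labels.count("negative") == 3

    def test_deterministic_given_seed(self, rng):
        pos, neg = self._pools(rng, 10, 30)
        args = (pos, _singleton_clusters(pos), neg, _singleton_clusters(neg))
        sel1, sp1 = balance_and_split(*args, n_folds=5, seed=7)
        sel2, sp2 = balance_and_split(*args, n_folds=5, seed=7)
        assert [w.sequence for w in sel1] == [w.sequence for w in sel2]
        assert np.array_equal(sp1.train_indices, sp2.train_indices)
        assert np.array_equal(sp1.fold_assignments, sp2.fold_assignments)

    def test_invariant_under_input_reordering(self, rng):
        pos, neg = self._pools(rng, 10, 30)
        args = (pos, _singleton_clusters(pos), neg, _singleton_clusters(neg))
        sel1, _ = balance_and_split(*args, n_folds=5, seed=7)
        perm = list(rng.permutation(len(neg)))
        neg2 = [neg[i] for i in perm]
        sel2, _ = balance_and_split(
            pos, _singleton_clusters(pos), neg2, _singleton_clusters(neg2),
            n_folds=5, seed=7,
        )
        assert [w.sequence for w in sel1] == [w.sequence for w in sel2]

    def test_stratified_folds_at_scale(self, rng):
        pos, neg = self._pools(rng, 500, 500)
        sel, split = balance_and_split(
            pos, _singleton_clusters(pos), neg, _singleton_clusters(neg),
            test_fraction=0.1, n_folds=10, seed=42,
        )
        assert len(split.test_indices) == 100
        y = np.array([1 if sel[i].label == "positive" else 0 for i in split.train_indices])
        for f in range(1, 11):
            mask = split.fold_assignments == f
            assert abs(mask.sum() - 90) <= 1
            assert abs(y[mask].sum() - 45) <= 1  # per-class balance within folds

    def test_insufficient_negatives(self, rng):
        pos, neg = self._pools(rng, 5, 3)
        with pytest.raises(ValueError, match="3 negative < 5 positive"):
            balance_and_split(pos, _singleton_clusters(pos), neg, _singleton_clusters(neg))


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_fasta_and_site_table_roundtrip(tmp_path, rng):
    prots = [ProteinRecord(f"P{i}", random_window(rng, 10)) for i in range(3)]
    write_fasta(prots, tmp_path / "p.fasta")
    back = read_fasta(tmp_path / "p.fasta")
    assert [(p.accession, p.sequence) for p in back] == [
        (p.accession, p.sequence) for p in prots
    ]
    from khiblearn.windows import SiteAnnotation

    sites = [SiteAnnotation("P0", 11, "positive"), SiteAnnotation("P1", 11, "negative")]
    write_site_table(sites, tmp_path / "s.tsv")
    assert read_site_table(tmp_path / "s.tsv") == sites


def test_windows_tsv_roundtrip(tmp_path, rng):
    wins = [
        PeptideWindow(random_window(rng, 5), 5, "positive", ("P1", 7)),
        PeptideWindow(random_window(rng, 5, n_pad_left=2), 5, "negative", ("P2", 3)),
    ]
    write_windows_tsv(wins, tmp_path / "w.tsv")
    assert read_windows_tsv(tmp_path / "w.tsv") == wins


def test_build_windows_enumerates_unannotated_lysines(rng):
    seq = "A" * 30 + "K" + "A" * 10 + "K" + "A" * 30
    prot = ProteinRecord("P1", seq)
    from khiblearn.windows import SiteAnnotation

    pos, neg = build_windows([prot], [SiteAnnotation("P1", 31, "positive")], flank=5)
    assert len(pos) == 1 and pos[0].centre == "K"
    assert len(neg) == 1 and neg[0].source == ("P1", 42)
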