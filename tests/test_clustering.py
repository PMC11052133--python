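import numpy as np
import pytest

from gctherm.clustering import (
    EmptyLibraryError,
    cluster_otus,
    library_coverage,
    pairwise_identity,
)
from gctherm.sequences import SequenceRecord
from gctherm.synthetic_data import generate_centroid, mutate_within_otu


def nw_oracle(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Independent Needleman-Wunsch oracle.

    Returns (optimal score, lowest identity, highest identity), where the
    identity bounds range over *all* optimal-score global alignments:
    min matches / max length and max matches / min length, computed by
    dynamic programming restricted to the optimal-alignment subgraph.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = np.arange(n + 1) * gap
    score[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i, j] = max(diag, score[i - 1, j] + gap, score[i, j - 1] + gap)
    # backward scores: optimal alignment of suffixes a[i:], b[j:]
    back = np.zeros((n + 1, m + 1))
    back[:, m] = np.arange(n, -1, -1) * gap
    back[n, :] = np.arange(m, -1, -1) * gap
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            diag = back[i + 1, j + 1] + (match if a[i] == b[j] else mismatch)
            back[i, j] = max(diag, back[i + 1, j] + gap, back[i, j + 1] + gap)
    opt = score[n, m]
    on_path = score + back == opt  # states lying on some optimal alignment
    NEG, POS = -(10**9), 10**9
    max_m = np.full((n + 1, m + 1), NEG); min_m = np.full((n + 1, m + 1), POS)
    max_l = np.full((n + 1, m + 1), NEG); min_l = np.full((n + 1, m + 1), POS)
    max_m[0, 0] = min_m[0, 0] = max_l[0, 0] = min_l[0, 0] = 0
    for i in range(n + 1):
        for j in range(m + 1):
            if not on_path[i, j] or (i == 0 and j == 0):
                continue
            for pi, pj, is_diag in ((i - 1, j - 1, True), (i - 1, j, False), (i, j - 1, False)):
                if pi < 0 or pj < 0 or (is_diag and (i == 0 or j == 0)):
                    continue
                step = (match if a[i - 1] == b[j - 1] else mismatch) if is_diag else gap
                if score[i, j] != score[pi, pj] + step or max_m[pi, pj] == NEG:
                    continue
                hit = int(is_diag and a[i - 1] == b[j - 1])
                max_m[i, j] = max(max_m[i, j], max_m[pi, pj] + hit)
                min_m[i, j] = min(min_m[i, j], min_m[pi, pj] + hit)
                max_l[i, j] = max(max_l[i, j], max_l[pi, pj] + 1)
                min_l[i, j] = min(min_l[i, j], min_l[pi, pj] + 1)
    lo = min_m[n, m] / max_l[n, m]
    hi = max_m[n, m] / min_l[n, m]
    return opt, lo, hi


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_case_and_ut_normalization(self):
        assert pairwise_identity("acgu", "ACGT") == 1.0

    def test_fully_different(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_single_substitution_hand_alignment(self):
        # gapless optimal alignment: 9 matches over length 10
        assert pairwise_identity("ACGTACGTAC", "ACGTTCGTAC") == pytest.approx(0.9)

    def test_symmetry(self):
        a, b = "ACGTACGTACGTTT", "ACGTTCGTACGT"
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_agrees_with_dp_oracle_on_random_pairs(self):
        from gctherm.clustering import _ALIGNER

        rng = np.random.default_rng(1234)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            la, lb = rng.integers(5, 61, size=2)
            a = "".join(bases[rng.integers(0, 4, size=la)])
            b = "".join(bases[rng.integers(0, 4, size=lb)])
            exp_score, lo, hi = nw_oracle(a, b)
            assert _ALIGNER.score(a, b) == pytest.approx(exp_score)
            # the chosen optimal alignment's identity must fall within the
            # oracle's bounds over all optimal alignments
            assert lo - 1e-9 <= pairwise_identity(a, b) <= hi + 1e-9


class TestClusterOtus:
    def test_identical_sequences_form_one_otu(self):
        records = [SequenceRecord(f"s{i}", "ACGTACGTACGTACGT") for i in range(5)]
        lib = cluster_otus(records, 0.97)
        assert len(lib.otus) == 1 and lib.otus[0].count == 5

    def test_distant_sequences_stay_apart(self):
        a = generate_centroid(56.0, 200, seed=1)
        b = generate_centroid(60.0, 200, seed=2)
        assert pairwise_identity(a, b) < 0.9
        lib = cluster_otus([a, b], 0.97)
        assert len(lib.otus) == 2

    def test_threshold_is_strict_inequality(self):
        # 97 matches of 100 -> identity exactly 0.97, NOT greater than 0.97
        a = "ACGT" * 25
        b = "TTT" + a[3:]
        assert pairwise_identity(a, b) == pytest.approx(0.97)
        assert len(cluster_otus([SequenceRecord("a", a), SequenceRecord("b", b)], 0.97).otus) == 2

    def test_planted_centroids_recovered_with_membership(self):
        rng = np.random.default_rng(7)
        centroids = [generate_centroid(p, 400, seed=s) for p, s in [(54, 11), (57, 12), (60, 13), (63, 14)]]
        records, truth = [], {}
        for ci, centroid in enumerate(centroids):
            for k in range(5):
                rec = mutate_within_otu(
                    centroid, 0.01, seed=int(rng.integers(2**31)), clone_id=f"c{ci}_{k}"
                )
                records.append(rec)
                truth[rec.id] = ci
        order = rng.permutation(len(records))
        records = [records[i] for i in order]
        lib = cluster_otus(records, 0.97)
        assert len(lib.otus) == 4
        for otu in lib.otus:
            assert len({truth[m] for m in otu.member_ids}) == 1

    def test_counts_partition_the_input(self):
        records = [generate_centroid(50 + i, 100, seed=i) for i in range(8)]
        lib = cluster_otus(records, 0.97)
        assert lib.total_clones == len(records)
        all_members = [m for o in lib.otus for m in o.member_ids]
        assert sorted(all_members) == sorted(r.id for r in records)

    def test_otus_sorted_by_descending_count(self):
        a = generate_centroid(55, 300, seed=3)
        b = generate_centroid(62, 300, seed=4)
        records = [mutate_within_otu(b, 0.005, seed=i, clone_id=f"b{i}") for i in range(3)]
        records += [mutate_within_otu(a, 0.005, seed=10 + i, clone_id=f"a{i}") for i in range(5)]
        counts = cluster_otus(records, 0.97).counts
        assert counts == sorted(counts, reverse=True) == [5, 3]

    def test_empty_input_raises(self):
        with pytest.raises(EmptyLibraryError):
            cluster_otus([], 0.97)


class TestCoverage:
    def test_published_zero_month_counts(self):
        # counts 48,11,4,4,3,2,1: one singleton of 73 clones -> 98.6%
        lib = _library_with_counts([48, 11, 4, 4, 3, 2, 1])
        assert library_coverage(lib) == pytest.approx(100 * (1 - 1 / 73))
        assert round(library_coverage(lib), 1) == 98.6

    def test_all_singletons(self):
        assert library_coverage(_library_with_counts([1, 1, 1])) == 0.0

    def test_no_singletons(self):
        assert library_coverage(_library_with_counts([5, 3, 2])) == 100.0


def _library_with_counts(counts):
    from gctherm.clustering import CloneLibrary, OtuRecord

    otus = []
    for i, c in enumerate(counts):
        members = [f"otu{i}_m{j}" for j in range(c)]
        otus.append(
            OtuRecord(
                otu_id=f"otu{i}",
                representative=SequenceRecord(members[0], "ACGT"),
                member_ids=members,
            )
        )
    return CloneLibrary(label="test", otus=otus)
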