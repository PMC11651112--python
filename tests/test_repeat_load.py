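"""Direct-repeat database, read matching, clustering, prevalence filtering."""

import numpy as np
import pytest

from crisprecol.repeat_load import (
    RepeatCluster,
    RepeatRecord,
    build_repeat_db,
    cluster_prevalence,
    cluster_repeats,
    count_matching_reads,
    filtered_load,
    pairwise_identity,
    read_fastq_sequences,
    read_repeat_fasta,
    reverse_complement,
    sample_repeat_presence,
)

# A 30-mer, the same with 6 substitutions (identity exactly 24/30 = 0.8),
# and the same with 10 substitutions (identity 20/30 ~ 0.667).
SEQ30 = "GGGTTTGGCTCATATGAACAAGTCTTTGCG"
SEQ30_6SUB = "GGATTTGCCTCACATGACCAAGGCTTTACG"
SEQ30_10SUB = "GAGTATGTCTTATTTGCACTAGCCTCTGAG"

REPEAT_A = "ATGCGTACGATCCTGAAGCTTGAC"  # 24 bp
REPEAT_B = "TTGGCCAATTCCGGAATTGGCCTA"  # 24 bp, unrelated


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestRepeatDB:
    def test_reverse_complement_arithmetic(self):
        assert reverse_complement("AAACC") == "GGTTT"
        assert reverse_complement(REPEAT_A) == "GTCAAGCTTCAGGATCGTACGCAT"

    def test_search_set_closed_under_revcomp(self):
        db = build_repeat_db([RepeatRecord("r1", REPEAT_A)])
        assert db.search_set == {REPEAT_A, reverse_complement(REPEAT_A)}

    def test_duplicates_collapse_with_provenance(self):
        db = build_repeat_db(
            [RepeatRecord("r1", REPEAT_A), RepeatRecord("r2", REPEAT_A)]
        )
        assert db.forward_set == {REPEAT_A}
        assert db.provenance[REPEAT_A] == ("r1", "r2")

    def test_palindrome_is_a_revcomp_fixed_point(self):
        half = "ATGCGTACG"
        palindrome = half + reverse_complement(half)  # 18 bp, revcomp == itself
        assert reverse_complement(palindrome) == palindrome
        db = build_repeat_db([RepeatRecord("p", palindrome)])
        assert len(db.search_set) == 1

    def test_rejects_non_acgt_and_short_sequences(self):
        with pytest.raises(ValueError, match="bad_one"):
            RepeatRecord("bad_one", "ATGCGTACGATCCTGAAGCTNGAC")
        with pytest.raises(ValueError, match="below minimum"):
            RepeatRecord("short", "ATGCGTACG")


class TestCountMatchingReads:
    def test_load_is_matched_over_total(self):
        db = build_repeat_db([RepeatRecord("r1", REPEAT_A)])
        rng = np.random.default_rng(0)
        reads = [
            _random_seq(rng, 40) + REPEAT_A + _random_seq(rng, 36),
            _random_seq(rng, 100),
            _random_seq(rng, 100),
            _random_seq(rng, 100),
        ]
        sl = count_matching_reads(reads, db, sample_id="s")
        assert (sl.matched_reads, sl.total_reads, sl.load) == (1, 4, 0.25)

    def test_read_with_two_repeats_counts_once(self):
        db = build_repeat_db([RepeatRecord("a", REPEAT_A), RepeatRecord("b", REPEAT_B)])
        sl = count_matching_reads([REPEAT_A + "AC" + REPEAT_B], db)
        assert sl.matched_reads == 1

    def test_strand_symmetry(self):
        db = build_repeat_db([RepeatRecord("a", REPEAT_A), RepeatRecord("b", REPEAT_B)])
        rng = np.random.default_rng(1)
        reads = [_random_seq(rng, 100) for _ in range(50)]
        reads[3] = reads[3][:10] + REPEAT_A + reads[3][10 + len(REPEAT_A):]
        reads[7] = reads[7][:50] + reverse_complement(REPEAT_B) + reads[7][50 + len(REPEAT_B):]
        fwd = count_matching_reads(reads, db)
        rc = count_matching_reads([reverse_complement(r) for r in reads], db)
        assert fwd.matched_reads == rc.matched_reads == 2

    def test_empty_read_set_is_an_error(self):
        db = build_repeat_db([RepeatRecord("a", REPEAT_A)])
        with pytest.raises(ValueError, match="no reads"):
            count_matching_reads([], db)


class TestClustering:
    def test_identity_examples(self):
        assert pairwise_identity(SEQ30, SEQ30) == 1.0
        assert pairwise_identity(SEQ30, SEQ30_6SUB) == pytest.approx(0.8)
        assert pairwise_identity(SEQ30, SEQ30_10SUB) == pytest.approx(20 / 30)

    def test_identity_matches_hamming_for_substitution_only_pairs(self):
        # independent closed form: 1 - hamming/length
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = _random_seq(rng, 32)
            k = int(rng.integers(0, 10))
            pos = rng.choice(32, size=k, replace=False)
            b = list(a)
            for p in pos:
                b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
            b = "".join(b)
            hamming = sum(x != y for x, y in zip(a, b))
            assert pairwise_identity(a, b) >= 1 - hamming / 32 - 1e-12

    def test_threshold_is_inclusive_at_exactly_080(self):
        assert len(cluster_repeats({SEQ30, SEQ30_6SUB})) == 1

    def test_dissimilar_pair_stays_separate(self):
        assert len(cluster_repeats({SEQ30, SEQ30_10SUB})) == 2

    def test_identical_sequences_form_one_cluster(self):
        (cl,) = cluster_repeats([SEQ30, SEQ30])
        assert cl.members == {SEQ30} and cl.representative == SEQ30

    def test_empty_input_gives_empty_output(self):
        assert cluster_repeats([]) == []

    def test_clusters_partition_the_input(self):
        rng = np.random.default_rng(3)
        seqs = {_random_seq(rng, int(rng.integers(24, 49))) for _ in range(30)}
        clusters = cluster_repeats(seqs)
        seen = [m for c in clusters for m in c.members]
        assert sorted(seen) == sorted(seqs)  # each sequence in exactly one cluster
        for c in clusters:
            assert c.representative in c.members

    def test_longest_sequence_founds_the_first_cluster(self):
        long = _random_seq(np.random.default_rng(4), 48)
        clusters = cluster_repeats({SEQ30, long})
        assert clusters[0].representative == long


class TestPrevalence:
    def _clusters(self):
        return [
            RepeatCluster("C0", REPEAT_A, frozenset({REPEAT_A})),
            RepeatCluster("C1", REPEAT_B, frozenset({REPEAT_B})),
        ]

    def test_prevalence_counts_samples_with_any_member(self):
        presence = {
            "s1": {REPEAT_A},
            "s2": {REPEAT_A},
            "s3": {reverse_complement(REPEAT_A)},  # reverse strand still counts
            "s4": set(),
        }
        out = cluster_prevalence(self._clusters(), presence)
        assert out[0].prevalence == 0.75
        assert out[1].prevalence == 0.0

    def test_single_sample_containing_cluster(self):
        out = cluster_prevalence(self._clusters()[:1], {"only": {REPEAT_A}})
        assert out[0].prevalence == 1.0

    def test_presence_extraction_from_reads(self):
        db = build_repeat_db([RepeatRecord("a", REPEAT_A), RepeatRecord("b", REPEAT_B)])
        rng = np.random.default_rng(5)
        pad = _random_seq(rng, 30)
        reads = {
            "s1": [pad + REPEAT_A + pad],
            "s2": [pad + reverse_complement(REPEAT_B) + pad],
            "s3": [pad],
        }
        presence = sample_repeat_presence(reads, db)
        assert presence == {
            "s1": frozenset({REPEAT_A}),
            "s2": frozenset({REPEAT_B}),
            "s3": frozenset(),
        }


class TestFilteredLoad:
    def _setup(self, rng):
        db = build_repeat_db([RepeatRecord("a", REPEAT_A), RepeatRecord("b", REPEAT_B)])
        reads = [_random_seq(rng, 100) for _ in range(20)]
        for i in range(6):
            reads[i] = reads[i][:20] + REPEAT_A + reads[i][20 + len(REPEAT_A):]
        for i in range(6, 10):
            reads[i] = reads[i][:20] + REPEAT_B + reads[i][20 + len(REPEAT_B):]
        return db, reads

    def test_everything_excluded_gives_zero_load(self):
        rng = np.random.default_rng(6)
        db, reads = self._setup(rng)
        clusters = cluster_prevalence(
            cluster_repeats(db.forward_set), {"s1": db.forward_set}
        )
        sl = filtered_load(reads, db, clusters, prevalence_cutoff=0.5)
        assert sl.matched_reads == 0

    def test_no_cluster_above_cutoff_is_a_noop(self):
        rng = np.random.default_rng(7)
        db, reads = self._setup(rng)
        clusters = cluster_prevalence(
            cluster_repeats(db.forward_set),
            {"s1": {REPEAT_A}, "s2": {REPEAT_B}, "s3": set(), "s4": set()},
        )
        assert all(c.prevalence <= 0.5 for c in clusters)
        assert (
            filtered_load(reads, db, clusters).matched_reads
            == count_matching_reads(reads, db).matched_reads
        )

    def test_mixed_case_matches_bruteforce_recount(self):
        rng = np.random.default_rng(8)
        db, reads = self._setup(rng)
        presence = {"s1": {REPEAT_A}, "s2": {REPEAT_A}, "s3": {REPEAT_A, REPEAT_B}}
        clusters = cluster_prevalence(cluster_repeats(db.forward_set), presence)
        sl = filtered_load(reads, db, clusters, prevalence_cutoff=0.5)
        # brute force: REPEAT_A is prevalent (3/3), only REPEAT_B survives
        surviving = {REPEAT_B, reverse_complement(REPEAT_B)}
        expected = sum(any(s in r for s in surviving) for r in reads)
        assert sl.matched_reads == expected

    def test_monotone_in_cutoff_and_bounded_by_unfiltered(self):
        rng = np.random.default_rng(9)
        db, reads = self._setup(rng)
        presence = {"s1": {REPEAT_A}, "s2": {REPEAT_A}, "s3": {REPEAT_B}, "s4": set()}
        clusters = cluster_prevalence(cluster_repeats(db.forward_set), presence)
        unfiltered = count_matching_reads(reads, db).matched_reads
        prev = 0
        for cutoff in (0.0, 0.3, 0.6, 1.0):
            m = filtered_load(reads, db, clusters, prevalence_cutoff=cutoff).matched_reads
            assert prev <= m <= unfiltered
            prev = m

    def test_cutoff_out_of_range_rejected(self):
        db = build_repeat_db([RepeatRecord("a", REPEAT_A)])
        clusters = cluster_prevalence(cluster_repeats(db.forward_set), {"s": set()})
        with pytest.raises(ValueError, match="prevalence_cutoff"):
            filtered_load(["A" * 30], db, clusters, prevalence_cutoff=1.5)


class TestIO:
    def test_fasta_and_fastq_round_trip(self, tmp_path):
        fasta = tmp_path / "repeats.fasta"
        fasta.write_text(f">r1\n{REPEAT_A}\n>r2\n{REPEAT_B}\n")
        recs = read_repeat_fasta(fasta)
        assert [r.sequence for r in recs] == [REPEAT_A, REPEAT_B]
        fastq = tmp_path / "reads.fastq"
        fastq.write_text("@read1\nACGTACGT\n+\nIIIIIIII\n")
        assert read_fastq_sequences(fastq) == ["ACGTACGT"]
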