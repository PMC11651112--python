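"""Per-sample CRISPR load from direct-repeat matches in raw reads.

The CRISPR load of a metagenomic sample is the fraction of reads that
contain a perfect (exact substring) match to a database of CRISPR
direct repeats.  The database holds every unique repeat together with
its reverse complement, so matching is strand-symmetric.  Because a few
taxa ubiquitous across samples could dominate this signal, repeats are
greedily clustered at an identity threshold (default 80%, word size 5)
and clusters present in more than half of the samples can be excluded
before recounting.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO

__all__ = [
    "RepeatRecord",
    "RepeatDB",
    "RepeatCluster",
    "SampleLoad",
    "reverse_complement",
    "build_repeat_db",
    "count_matching_reads",
    "pairwise_identity",
    "cluster_repeats",
    "cluster_prevalence",
    "sample_repeat_presence",
    "filtered_load",
    "read_repeat_fasta",
    "read_fastq_sequences",
    "loads_to_frame",
    "clusters_to_frame",
]

# Exact-substring matching makes very short motifs spuriously frequent;
# annotated CRISPR direct repeats are ~21 bp and longer.
MIN_REPEAT_LENGTH = 18

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatRecord:
    """A single direct-repeat sequence with provenance."""

    repeat_id: str
    sequence: str
    sample_of_origin: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"repeat {self.repeat_id!r}: invalid character(s) {sorted(bad)} "
                "(alphabet is strictly ACGT)"
            )
        if len(seq) < MIN_REPEAT_LENGTH:
            raise ValueError(
                f"repeat {self.repeat_id!r}: length {len(seq)} below minimum "
                f"{MIN_REPEAT_LENGTH}"
            )


@dataclass
class RepeatDB:
    """Deduplicated repeats plus reverse complements for searching.

    ``search_set`` is closed under reverse complement; ``provenance``
    maps each forward sequence to the repeat_ids that contributed it.
    """

    forward_set: frozenset[str]
    search_set: frozenset[str]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.search_set:
            if reverse_complement(s) not in self.search_set:
                raise ValueError("search_set is not closed under reverse complement")

    @property
    def search_sequences(self) -> tuple[str, ...]:
        """Deterministically ordered search sequences (longest first)."""
        return tuple(sorted(self.search_set, key=lambda s: (-len(s), s)))

    def restrict(self, keep: Iterable[str]) -> "RepeatDB":
        """Sub-database restricted to the given forward sequences."""
        fwd = frozenset(keep) & self.forward_set
        search = frozenset(s for f in fwd for s in (f, reverse_complement(f)))
        prov = {f: self.provenance.get(f, ()) for f in fwd}
        return RepeatDB(forward_set=fwd, search_set=search, provenance=prov)


@dataclass
class RepeatCluster:
    """A cluster of similar repeats with optional per-sample prevalence."""

    cluster_id: str
    representative: str
    members: frozenset[str]
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(f"cluster {self.cluster_id}: representative not a member")
        if self.prevalence is not None and not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"cluster {self.cluster_id}: prevalence outside [0, 1]")


@dataclass(frozen=True)
class SampleLoad:
    """Matched-read count and normalized CRISPR load for one sample."""

    sample_id: str
    matched_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"sample {self.sample_id!r}: total_reads must be > 0")
        if not 0 <= self.matched_reads <= self.total_reads:
            raise ValueError(
                f"sample {self.sample_id!r}: matched_reads outside [0, total_reads]"
            )

    @property
    def load(self) -> float:
        return self.matched_reads / self.total_reads


def build_repeat_db(repeats: Iterable[RepeatRecord]) -> RepeatDB:
    """Deduplicate repeats and close the search set under reverse complement."""
    provenance: dict[str, list[str]] = {}
    for rec in repeats:
        provenance.setdefault(rec.sequence, []).append(rec.repeat_id)
    forward = frozenset(provenance)
    search = frozenset(s for f in forward for s in (f, reverse_complement(f)))
    return RepeatDB(
        forward_set=forward,
        search_set=search,
        provenance={s: tuple(ids) for s, ids in provenance.items()},
    )


def count_matching_reads(
    reads: Iterable[str], db: RepeatDB, sample_id: str = "sample"
) -> SampleLoad:
    """Count reads containing any database sequence as an exact substring.

    Each read is counted at most once, regardless of how many database
    sequences it contains.  Matching is case-insensitive on the read
    side; reads containing N never match at positions overlapping the N
    (the database alphabet is strictly ACGT, so exact matching handles
    this without special casing).

    Raises
    ------
    ValueError
        On an empty read collection (the normalization is undefined).
    """
    seqs = db.search_sequences
    matched = 0
    total = 0
    for read in reads:
        total += 1
        r = read.upper()
        for s in seqs:
            if s in r:
                matched += 1
                break
    if total == 0:
        raise ValueError(f"sample {sample_id!r}: no reads (load undefined)")
    return SampleLoad(sample_id=sample_id, matched_reads=matched, total_reads=total)


_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -5
        a.extend_gap_score = -2
        _aligner = a
    return _aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions in the optimal global alignment.

    Identity is the number of identically aligned positions under a
    standard global alignment (match +1, mismatch -1, gap open -5,
    gap extend -2) divided by the length of the *shorter* sequence.
    For sequences of equal length differing only by substitutions this
    reduces to 1 - hamming/length, which is the sense in which an 80%
    threshold on ~30-bp repeats tolerates about 6 bp of difference.
    """
    if a == b:
        return 1.0
    aln = _get_aligner().align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def cluster_repeats(
    repeats: Iterable[str],
    identity_threshold: float = 0.8,
    word_size: int = 5,
) -> list[RepeatCluster]:
    """Greedy incremental clustering of repeat sequences by identity.

    Sequences are sorted by length descending (ties lexicographic) and
    each joins the first existing cluster whose representative is at
    least ``identity_threshold`` identical (inclusive), else founds a
    new cluster with itself as representative.  ``word_size`` is a
    k-mer prefilter: a pair sharing no k-mer of that length is assumed
    to fall below the threshold and is not aligned.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    ordered = sorted(set(repeats), key=lambda s: (-len(s), s))
    reps: list[str] = []
    rep_kmers: list[frozenset[str]] = []
    members: list[list[str]] = []
    for seq in ordered:
        km = _kmers(seq, word_size) if word_size else frozenset()
        for i, rep in enumerate(reps):
            if word_size and not (km & rep_kmers[i]):
                continue
            if pairwise_identity(seq, rep) >= identity_threshold:
                members[i].append(seq)
                break
        else:
            reps.append(seq)
            rep_kmers.append(km)
            members.append([seq])
    return [
        RepeatCluster(
            cluster_id=f"C{i:04d}", representative=rep, members=frozenset(mem)
        )
        for i, (rep, mem) in enumerate(zip(reps, members))
    ]


def sample_repeat_presence(
    reads_by_sample: Mapping[str, Iterable[str]], db: RepeatDB
) -> dict[str, frozenset[str]]:
    """Which forward repeats occur (either strand) in each sample's reads."""
    # map each search sequence back to its forward representative
    to_forward = {f: f for f in db.forward_set}
    for f in db.forward_set:
        to_forward.setdefault(reverse_complement(f), f)
    search = db.search_sequences
    presence: dict[str, frozenset[str]] = {}
    for sample, reads in reads_by_sample.items():
        found: set[str] = set()
        remaining = [s for s in search if to_forward[s] not in found]
        for read in reads:
            r = read.upper()
            hit = [s for s in remaining if s in r]
            if hit:
                found.update(to_forward[s] for s in hit)
                remaining = [s for s in remaining if to_forward[s] not in found]
                if not remaining:
                    break
        presence[sample] = frozenset(found)
    return presence


def cluster_prevalence(
    clusters: Sequence[RepeatCluster],
    sample_repeat_presence: Mapping[str, Iterable[str]],
) -> list[RepeatCluster]:
    """Fraction of samples containing >=1 member of each cluster.

    A sample "contains" a cluster when any member sequence, forward or
    reverse complement, is in the sample's repeat-presence set.
    """
    if not sample_repeat_presence:
        raise ValueError("cluster_prevalence requires at least one sample")
    n_samples = len(sample_repeat_presence)
    sample_sets = {s: frozenset(v) for s, v in sample_repeat_presence.items()}
    out = []
    for cl in clusters:
        probes = set(cl.members) | {reverse_complement(m) for m in cl.members}
        hits = sum(1 for ss in sample_sets.values() if probes & ss)
        out.append(replace(cl, prevalence=hits / n_samples))
    return out


def filtered_load(
    reads: Iterable[str],
    db: RepeatDB,
    clusters: Sequence[RepeatCluster],
    prevalence_cutoff: float = 0.5,
    sample_id: str = "sample",
) -> SampleLoad:
    """Load counted against repeats from non-prevalent clusters only.

    Clusters with ``prevalence > prevalence_cutoff`` (strictly greater)
    are removed; the load is recounted against a database rebuilt from
    the members of the surviving clusters.  The result can never exceed
    the unfiltered load.
    """
    if not 0.0 <= prevalence_cutoff <= 1.0:
        raise ValueError(f"prevalence_cutoff must be in [0, 1], got {prevalence_cutoff}")
    covered = frozenset(m for cl in clusters for m in cl.members)
    if not db.forward_set <= covered:
        missing = sorted(db.forward_set - covered)[:3]
        raise ValueError(f"clusters do not cover the repeat database (e.g. {missing})")
    for cl in clusters:
        if cl.prevalence is None:
            raise ValueError(f"cluster {cl.cluster_id} has no prevalence; "
                             "run cluster_prevalence first")
    keep = [m for cl in clusters if cl.prevalence <= prevalence_cutoff for m in cl.members]
    return count_matching_reads(reads, db.restrict(keep), sample_id=sample_id)


# ---------------------------------------------------------------------------
# I/O

def read_repeat_fasta(path: str | Path) -> list[RepeatRecord]:
    """Read direct repeats from a FASTA file."""
    return [
        RepeatRecord(repeat_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read the sequences of a FASTQ file (gzip accepted)."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def loads_to_frame(
    unfiltered: Sequence[SampleLoad], filtered: Sequence[SampleLoad] | None = None
) -> pd.DataFrame:
    """Tabulate sample loads as ``sample_id, matched_reads, total_reads, load[, filtered_*]``."""
    df = pd.DataFrame(
        {
            "sample_id": [l.sample_id for l in unfiltered],
            "matched_reads": [l.matched_reads for l in unfiltered],
            "total_reads": [l.total_reads for l in unfiltered],
            "load": [l.load for l in unfiltered],
        }
    )
    if filtered is not None:
        by_id = {l.sample_id: l for l in filtered}
        df["filtered_matched"] = [by_id[s].matched_reads for s in df["sample_id"]]
        df["filtered_load"] = [by_id[s].load for s in df["sample_id"]]
    return df


def clusters_to_frame(clusters: Sequence[RepeatCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "representative": [c.representative for c in clusters],
            "size": [len(c.members) for c in clusters],
            "prevalence": [c.prevalence for c in clusters],
        }
    )
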