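"""Greedy incremental centroid clustering of pooled protein sequences.

Implements the UCLUST-style discipline used to derive a non-redundant
representative sequence set from a genome population: sequences are processed
in decreasing length order and each query joins the first existing centroid it
matches at or above the fractional identity threshold (default 0.55, the
cutoff recommended for protein clustering), otherwise it founds a new cluster.

Percent identity comes from a global Needleman–Wunsch alignment under
BLOSUM62 with gap open 10 / extend 1; identity is the fraction of identical
alignment columns, excluding terminal-gap columns by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord

IdentityDef = Literal["internal", "all-columns"]

DEFAULT_THRESHOLD = 0.55
WORD_SIZE = 5


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aligner.mode = "global"
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    *,
    definition: IdentityDef = "internal",
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Fractional identity between two protein sequences in [0, 1].

    A single optimal global alignment is computed; identity is the number of
    identical residue columns divided by the number of alignment columns.
    Under the default ``"internal"`` definition, columns lying in a terminal
    gap of either sequence are excluded from the denominator (USEARCH-like);
    ``"all-columns"`` counts every column.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 1.0
    aln = _aligner(matrix, gap_open, gap_extend).align(a, b)[0]
    ga, gb = aln[0], aln[1]
    n_cols = len(ga)
    if definition == "internal":
        start = max(_first_residue(ga), _first_residue(gb))
        end = min(_last_residue(ga), _last_residue(gb))
        if end < start:  # alignments of disjoint terminal blocks
            return 0.0
    else:
        start, end = 0, n_cols - 1
    matches = sum(1 for i in range(start, end + 1) if ga[i] == gb[i] and ga[i] != "-")
    return matches / (end - start + 1)


def _first_residue(gapped: str) -> int:
    return len(gapped) - len(gapped.lstrip("-"))


def _last_residue(gapped: str) -> int:
    return len(gapped.rstrip("-")) - 1


def kmer_set(sequence: str, k: int = WORD_SIZE) -> frozenset[str]:
    """All length-``k`` amino-acid words of a sequence (empty if shorter than k)."""
    return frozenset(sequence[i : i + k] for i in range(len(sequence) - k + 1))


@dataclass
class Cluster:
    """One greedy cluster: a centroid plus its (member, identity) hits."""

    index: int
    centroid: str
    centroid_sequence: str
    members: list[tuple[str, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return 1 + len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [self.centroid] + [m for m, _ in self.members]


@dataclass
class ClusterSet:
    """Greedy clustering result: an ordered partition of the pooled records."""

    clusters: list[Cluster]
    threshold: float
    lengths: dict[str, int] = field(default_factory=dict)

    @property
    def centroid_ids(self) -> list[str]:
        return [c.centroid for c in self.clusters]

    def membership(self) -> dict[str, str]:
        """Member tagged-id → centroid tagged-id map (the uc file's content)."""
        out: dict[str, str] = {}
        for cl in self.clusters:
            out[cl.centroid] = cl.centroid
            for member, _ in cl.members:
                out[member] = cl.centroid
        return out

    def __len__(self) -> int:
        return len(self.clusters)


def greedy_cluster(
    records: Sequence[ProteinRecord],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    exact: bool = False,
    match_mode: Literal["first", "best"] = "first",
    identity_def: IdentityDef = "internal",
) -> ClusterSet:
    """Cluster pooled records greedily at a fractional identity threshold.

    Records are sorted by decreasing length (ties: lexicographic tagged id)
    and compared against existing centroids in centroid-creation order.  With
    ``match_mode="first"`` a query joins the first centroid reaching the
    threshold (UCLUST's maxaccepts=1 default); ``"best"`` scans all centroids
    and joins the highest-identity one at or above the threshold.

    A length-5 k-mer prefilter skips centroids sharing no word with the query;
    pass ``exact=True`` to disable it (the result may then differ only for
    pairs whose identity straddles the threshold without sharing any word,
    which the oracle tests rule out).
    """
    if not records:
        raise ValueError("no records to cluster")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.tagged_id))
    clusters: list[Cluster] = []
    centroid_words: list[frozenset[str]] = []
    lengths = {r.tagged_id: len(r.sequence) for r in ordered}

    for rec in ordered:
        words = kmer_set(rec.sequence) if not exact else None
        chosen: tuple[int, float] | None = None
        for idx, cl in enumerate(clusters):
            if not exact and words is not None and not (words & centroid_words[idx]):
                continue
            ident = pairwise_identity(rec.sequence, cl.centroid_sequence, definition=identity_def)
            if ident >= threshold:
                if match_mode == "first":
                    chosen = (idx, ident)
                    break
                if chosen is None or ident > chosen[1]:
                    chosen = (idx, ident)
        if chosen is None:
            clusters.append(
                Cluster(index=len(clusters), centroid=rec.tagged_id, centroid_sequence=rec.sequence)
            )
            centroid_words.append(kmer_set(rec.sequence))
        else:
            clusters[chosen[0]].members.append((rec.tagged_id, chosen[1]))

    return ClusterSet(clusters=clusters, threshold=threshold, lengths=lengths)
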