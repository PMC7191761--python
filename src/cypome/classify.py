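"""Family/subfamily assignment of identified CYPs by best-identity search.

Follows the P450 nomenclature convention: a query sharing ≥40% identity with
a named reference CYP belongs to that reference's family, and ≥55% identity
places it in the same subfamily.  Queries below 40% to every reference found
new families.  Novel sequences are grouped among themselves with the same
40%/55% thresholds and receive run-scoped placeholder labels (NF<k> families,
NF<k>.<j> subfamilies; novel subfamilies inside a known family are
<family>-NS<j>).  These placeholders are not official nomenclature — real CYP
names are issued by the nomenclature committee.

Cluster members inherit their centroid's assignment, which is how per-genome
counts are recovered from the non-redundant centroid set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .cluster import ClusterSet, pairwise_identity
from .seqio import split_tag

logger = logging.getLogger(__name__)

FAMILY_THRESHOLD = 0.40
SUBFAMILY_THRESHOLD = 0.55
BOUNDARY_WARN_MARGIN = 0.05

_CYP_NAME = re.compile(r"^(CYP\d+)([A-Za-z]*)(\d*)$")


@dataclass(frozen=True)
class ReferenceCyp:
    """A named reference CYP; the name encodes family and subfamily."""

    cyp_name: str
    sequence: str

    @property
    def family(self) -> str:
        return parse_cyp_name(self.cyp_name)[0]

    @property
    def subfamily(self) -> str:
        return parse_cyp_name(self.cyp_name)[1]


@dataclass(frozen=True)
class CypAssignment:
    """Classification outcome for one (centroid) sequence."""

    query: str
    family: str
    subfamily: str
    best_hit: str | None
    best_identity: float
    family_is_new: bool
    subfamily_is_new: bool


def parse_cyp_name(name: str) -> tuple[str, str]:
    """Split a CYP name into (family, subfamily): CYP51F1 → (CYP51, CYP51F).

    A name without a subfamily letter uses the family as its subfamily.
    """
    m = _CYP_NAME.match(name)
    if not m:
        raise ValueError(f"not a CYP name: {name!r}")
    family = m.group(1)
    letters = m.group(2)
    return family, family + letters if letters else family


def best_hit_classify(
    query: str,
    sequence: str,
    refs: Sequence[ReferenceCyp],
    family_threshold: float = FAMILY_THRESHOLD,
    subfamily_threshold: float = SUBFAMILY_THRESHOLD,
) -> CypAssignment:
    """Classify one sequence by its best-identity reference hit.

    Identity ≥ subfamily threshold → same family and subfamily as the best
    hit; family threshold ≤ identity < subfamily threshold → same family, new
    subfamily; below the family threshold → new family and subfamily.
    Thresholds are inclusive.  Ties on identity break to the
    lexicographically smallest reference name.
    """
    if not refs:
        raise ValueError("empty reference set")
    best_name, best_ident = None, -1.0
    for ref in sorted(refs, key=lambda r: r.cyp_name):
        ident = pairwise_identity(sequence, ref.sequence)
        if ident > best_ident:
            best_name, best_ident = ref.cyp_name, ident
    family, subfamily = parse_cyp_name(best_name)
    if best_ident >= subfamily_threshold:
        return CypAssignment(query, family, subfamily, best_name, best_ident, False, False)
    if best_ident >= family_threshold:
        return CypAssignment(query, family, "", best_name, best_ident, False, True)
    return CypAssignment(query, "", "", best_name, best_ident, True, True)


def classify_centroids(
    centroid_sequences: Mapping[str, str],
    refs: Sequence[ReferenceCyp],
    family_threshold: float = FAMILY_THRESHOLD,
    subfamily_threshold: float = SUBFAMILY_THRESHOLD,
) -> list[CypAssignment]:
    """Classify every identified centroid and name the novel groups."""
    assignments = [
        best_hit_classify(q, s, refs, family_threshold, subfamily_threshold)
        for q, s in sorted(centroid_sequences.items())
    ]
    return name_novel_groups(assignments, centroid_sequences, family_threshold, subfamily_threshold)


def name_novel_groups(
    assignments: Sequence[CypAssignment],
    sequences: Mapping[str, str],
    family_threshold: float = FAMILY_THRESHOLD,
    subfamily_threshold: float = SUBFAMILY_THRESHOLD,
) -> list[CypAssignment]:
    """Label novel families/subfamilies by greedy co-clustering.

    Novel-family sequences are grouped greedily (deterministic tagged-id
    order, first match) at the family threshold; groups are labelled NF1,
    NF2, … in discovery order, with subfamilies NF<k>.<j> grouped at the
    subfamily threshold inside each new family.  Sequences novel only at the
    subfamily level are grouped per known family at the subfamily threshold
    and labelled <family>-NS<j>.
    """
    out: dict[str, CypAssignment] = {a.query: a for a in assignments}

    # New families: greedy first-match grouping at the family threshold.
    nf_founders: list[tuple[str, str]] = []  # (label, founder sequence)
    nf_sub_founders: dict[str, list[tuple[str, str]]] = {}
    for a in sorted(assignments, key=lambda a: a.query):
        if not a.family_is_new:
            continue
        seq = sequences[a.query]
        fam_label = None
        for label, founder_seq in nf_founders:
            if pairwise_identity(seq, founder_seq) >= family_threshold:
                fam_label = label
                break
        if fam_label is None:
            fam_label = f"NF{len(nf_founders) + 1}"
            nf_founders.append((fam_label, seq))
            nf_sub_founders[fam_label] = []
        sub_label = None
        for label, founder_seq in nf_sub_founders[fam_label]:
            if pairwise_identity(seq, founder_seq) >= subfamily_threshold:
                sub_label = label
                break
        if sub_label is None:
            sub_label = f"{fam_label}.{len(nf_sub_founders[fam_label]) + 1}"
            nf_sub_founders[fam_label].append((sub_label, seq))
        out[a.query] = replace(a, family=fam_label, subfamily=sub_label)

    # New subfamilies inside known families, grouped per family.
    ns_founders: dict[str, list[tuple[str, str]]] = {}
    for a in sorted(assignments, key=lambda a: a.query):
        if a.family_is_new or not a.subfamily_is_new:
            continue
        seq = sequences[a.query]
        founders = ns_founders.setdefault(a.family, [])
        sub_label = None
        for label, founder_seq in founders:
            if pairwise_identity(seq, founder_seq) >= subfamily_threshold:
                sub_label = label
                break
        if sub_label is None:
            sub_label = f"{a.family}-NS{len(founders) + 1}"
            founders.append((sub_label, seq))
        out[a.query] = replace(a, subfamily=sub_label)

    if nf_founders or ns_founders:
        logger.warning(
            "WARN %d new famil(ies) and %d known-family new subfamily group(s) received "
            "run-scoped placeholder labels; official naming requires the nomenclature committee",
            len(nf_founders),
            sum(len(v) for v in ns_founders.values()),
        )
    return [out[a.query] for a in assignments]


def propagate_to_members(
    assignments: Sequence[CypAssignment],
    clusters: ClusterSet,
) -> pd.DataFrame:
    """Broadcast centroid assignments to every member of their clusters.

    Returns a per-sequence table (query, genome, family, subfamily, best_hit,
    identity, novelty flags, near_boundary).  ``near_boundary`` flags members
    whose identity to their centroid sits within 0.05 of the 0.40/0.55 rule
    boundaries — their own best-hit identity could fall on the other side.
    Members of unassigned (non-CYP) centroids are omitted.
    """
    by_centroid = {a.query: a for a in assignments}
    unknown = set(by_centroid) - set(c.centroid for c in clusters.clusters)
    if unknown:
        raise ValueError(f"assignments for non-centroid ids: {sorted(unknown)}")
    rows = []
    for cl in clusters.clusters:
        a = by_centroid.get(cl.centroid)
        if a is None:
            continue
        for tagged, ident in [(cl.centroid, 1.0)] + list(cl.members):
            genome_id, _ = split_tag(tagged)
            near = any(
                abs(ident - b) <= BOUNDARY_WARN_MARGIN
                for b in (FAMILY_THRESHOLD, SUBFAMILY_THRESHOLD)
            )
            rows.append(
                {
                    "query": tagged,
                    "genome": genome_id,
                    "family": a.family,
                    "subfamily": a.subfamily,
                    "best_hit": a.best_hit or "",
                    "identity": a.best_identity,
                    "family_is_new": a.family_is_new,
                    "subfamily_is_new": a.subfamily_is_new,
                    "centroid": cl.centroid,
                    "identity_to_centroid": ident,
                    "near_boundary": near,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "query",
            "genome",
            "family",
            "subfamily",
            "best_hit",
            "identity",
            "family_is_new",
            "subfamily_is_new",
            "centroid",
            "identity_to_centroid",
            "near_boundary",
        ],
    )


def read_reference_fasta(path) -> list[ReferenceCyp]:
    """Load a reference CYP FASTA whose headers are CYP names (e.g. CYP51F1)."""
    from Bio import SeqIO

    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parse_cyp_name(rec.id)  # validates
        refs.append(ReferenceCyp(cyp_name=rec.id, sequence=str(rec.seq).upper()))
    if not refs:
        raise ValueError(f"no reference CYPs in {path}")
    return refs
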