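"""Protein FASTA ingest/export and the UCLUST-style cluster (uc) file format.

Each input genome is one protein FASTA file (``.fasta``/``.faa``); the file
stem becomes the genome identifier.  Sequences from all genomes are pooled for
clustering, with every record tagged ``genome_id|record_id`` so that cluster
membership can later be resolved back to its genome of origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus X (ambiguous residue).
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Separator between genome id and record id in pooled (tagged) headers.
TAG_SEPARATOR = "|"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tagged with its genome of origin.

    The composite key ``genome_id|id`` is unique across a run; sequences are
    uppercase strings over the 20 amino acids plus X.
    """

    id: str
    genome_id: str
    sequence: str

    @property
    def tagged_id(self) -> str:
        return f"{self.genome_id}{TAG_SEPARATOR}{self.id}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeProteome:
    """All protein records of one genome, in input-file order."""

    genome_id: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _clean_sequence(raw: str, label: str) -> str | None:
    """Normalise one sequence; return None (and warn) if it is unusable.

    Terminal ``*`` stop characters and gap dashes are stripped silently;
    an internal ``*`` or any other non-amino-acid character rejects the
    record with a warning.
    """
    seq = raw.strip().upper().replace("-", "")
    seq = seq.rstrip("*")
    if not seq:
        logger.warning("WARN empty sequence after cleanup: %s; skipped", label)
        return None
    bad = set(seq) - AMINO_ALPHABET
    if bad:
        logger.warning(
            "WARN record %s contains non-amino-acid characters %s; skipped",
            label,
            "".join(sorted(bad)),
        )
        return None
    return seq


def read_fasta(path: str | Path) -> GenomeProteome:
    """Read one genome's protein FASTA into a :class:`GenomeProteome`.

    The genome id is the filename stem.  Duplicate record ids within the file
    are disambiguated by appending an ordinal suffix (``x`` → ``x_2``) and
    logged.  Records containing characters outside the 20 amino acids plus X
    are skipped with a warning; terminal ``*`` is stripped.

    Raises ``ValueError`` if the file yields no usable sequence.
    """
    path = Path(path)
    genome_id = path.stem
    seen: dict[str, int] = {}
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(rec.seq), f"{genome_id}:{rec.id}")
        if seq is None:
            continue
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            logger.warning(
                "WARN duplicate record id %r in %s; renamed to %r", rid, path.name, new_id
            )
            rid = new_id
            seen.setdefault(rid, 1)
        else:
            seen[rid] = 1
        records.append(ProteinRecord(id=rid, genome_id=genome_id, sequence=seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return GenomeProteome(genome_id=genome_id, records=records)


def pool_and_tag(genomes: Sequence[GenomeProteome]) -> list[ProteinRecord]:
    """Pool all genomes' records for clustering, enforcing unique tags.

    A ``|`` occurring inside a record id would collide with the tag separator
    and is replaced by ``_`` (logged).  Duplicate genome ids are an error.
    """
    if not genomes:
        raise ValueError("no genomes to pool")
    seen_genomes: set[str] = set()
    pooled: list[ProteinRecord] = []
    for genome in genomes:
        if genome.genome_id in seen_genomes:
            raise ValueError(f"duplicate genome_id {genome.genome_id!r}")
        seen_genomes.add(genome.genome_id)
        for rec in genome.records:
            rid = rec.id
            if TAG_SEPARATOR in rid:
                new_id = rid.replace(TAG_SEPARATOR, "_")
                logger.warning(
                    "WARN record id %r contains %r; replaced with %r",
                    rid,
                    TAG_SEPARATOR,
                    new_id,
                )
                rec = ProteinRecord(id=new_id, genome_id=rec.genome_id, sequence=rec.sequence)
            pooled.append(rec)
    return pooled


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, tagged: bool = True) -> None:
    """Write records as protein FASTA; headers are tagged ids by default."""
    out = [
        SeqRecord(Seq(r.sequence), id=r.tagged_id if tagged else r.id, description="")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def split_tag(tagged_id: str) -> tuple[str, str]:
    """Recover (genome_id, record_id) from a pooled tagged id."""
    genome_id, _, rid = tagged_id.partition(TAG_SEPARATOR)
    return genome_id, rid


# ---------------------------------------------------------------------------
# uc cluster format (UCLUST's 10-column tab-separated record layout)
# ---------------------------------------------------------------------------

def write_uc(clusters, path: str | Path, lengths: Mapping[str, int] | None = None) -> None:
    """Write a :class:`~cypome.cluster.ClusterSet` in the 10-column uc format.

    Record types: ``S`` (centroid seed), ``H`` (member hit, with percent
    identity to its centroid), ``C`` (cluster summary with size).  The
    alignment column is emitted as ``*``; nothing downstream consumes it.
    """
    lengths = lengths if lengths is not None else getattr(clusters, "lengths", {})
    lines: list[str] = []
    for cl in clusters.clusters:
        clen = lengths.get(cl.centroid, "*")
        lines.append(
            "\t".join(["S", str(cl.index), str(clen), "*", "*", "*", "*", "*", cl.centroid, "*"])
        )
        for member, ident in cl.members:
            mlen = lengths.get(member, "*")
            lines.append(
                "\t".join(
                    [
                        "H",
                        str(cl.index),
                        str(mlen),
                        f"{100.0 * ident:.1f}",
                        "*",
                        "*",
                        "*",
                        "*",
                        member,
                        cl.centroid,
                    ]
                )
            )
    for cl in clusters.clusters:
        lines.append(
            "\t".join(
                ["C", str(cl.index), str(cl.size), "*", "*", "*", "*", "*", cl.centroid, "*"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_uc(path: str | Path) -> dict[str, str]:
    """Parse a uc file into a member → centroid map (centroids map to themselves)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        rtype = fields[0]
        if rtype == "S":
            mapping[fields[8]] = fields[8]
        elif rtype == "H":
            mapping[fields[8]] = fields[9]
    return mapping
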