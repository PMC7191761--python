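"""Deterministic synthetic data: reference CYPs, domain alignments, genomes.

The generator emulates the inputs the pipeline consumes, with ground truth:

* a set of protein *families* (named after real CYP families), each with one
  ancestor sequence; every CYP carries one conserved 60-residue core domain
  (the profile scan's target), which no decoy contains;
* *subfamily* ancestors derived from the family ancestor so that pairwise
  identity between subfamilies of one family falls inside the 0.45–0.54
  band — same family but different subfamily under the 40%/55% rules;
* named reference sequences (≥ 0.70 identity within a subfamily) standing in
  for a curated nomenclature database;
* genome proteomes whose CYP members derive from subfamily ancestors well
  inside the same-subfamily band, plus random decoy proteins.

The mutation model is substitution-only (positions uniform over the non-core
part, replacement residue drawn from a BLOSUM62-conditional distribution), so
realized identity tracks the mutated fraction closely; every identity band is
nevertheless *verified* by direct alignment and regenerated (bounded retries)
when violated.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .classify import ReferenceCyp
from .cluster import pairwise_identity
from .seqio import GenomeProteome, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Real CYP family numbers used for naming synthetic families.
FAMILY_NUMBERS = [51, 61, 102, 124, 135, 140, 144, 505, 509, 530]
SUBFAMILY_LETTERS = "ABCDEFGH"


@dataclass
class SynthConfig:
    """Study conditions for the synthetic population.

    Identity bands are disjoint and keep ≥ 0.05 margin from the 0.40/0.55
    nomenclature boundaries; divergence fractions are chosen so realized
    identities land mid-band (verified post hoc).
    """

    seed: int = 42
    n_families: int = 5
    subfamilies_per_family: int = 2
    refs_per_subfamily: int = 2
    n_genomes: int = 6
    cyps_per_genome: tuple[int, int] = (6, 10)  # inclusive uniform range
    decoys_per_genome: int = 5
    seq_len_range: tuple[int, int] = (420, 500)  # typical CYP length
    decoy_len_range: tuple[int, int] = (120, 300)
    core_len: int = 60
    within_subfamily_min: float = 0.70
    within_family_band: tuple[float, float] = (0.45, 0.54)
    between_family_max: float = 0.30
    subfamily_divergence: float = 0.355  # non-core fraction mutated per subfamily ancestor
    ref_divergence: float = 0.02
    member_divergence: float = 0.08
    max_retries: int = 40


@dataclass
class SyntheticReference:
    """Reference database plus the generator's internal ancestors."""

    core: str
    family_names: list[str]
    family_ancestors: dict[str, str]
    core_start: dict[str, int]  # 0-based core offset per family
    subfamily_ancestors: dict[str, str]  # subfamily name → sequence
    subfamily_family: dict[str, str]  # subfamily name → family name
    refs: list[ReferenceCyp]
    domain_alignment: list[str] = field(default_factory=list)


def _blosum_conditional() -> np.ndarray:
    """P(replacement b | original a) ∝ exp(BLOSUM62[a,b]/2), b ≠ a."""
    m = substitution_matrices.load("BLOSUM62")
    cond = np.zeros((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            if i != j:
                cond[i, j] = np.exp(m[a, b] / 2.0)
        cond[i] /= cond[i].sum()
    return cond

_COND = _blosum_conditional()
_AA_INDEX = {a: i for i, a in enumerate(AA)}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


def _mutate(
    seq: str, fraction: float, rng: np.random.Generator, protected: range | None = None
) -> str:
    """Substitute ``fraction`` of the mutable positions, sparing ``protected``."""
    mutable = [i for i in range(len(seq)) if protected is None or i not in protected]
    n_mut = int(round(fraction * len(mutable)))
    positions = rng.choice(len(mutable), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        i = mutable[p]
        orig = _AA_INDEX[out[i]]
        out[i] = AA[rng.choice(20, p=_COND[orig])]
    return "".join(out)


def generate_reference_db(config: SynthConfig) -> SyntheticReference:
    """Generate family/subfamily ancestors and the named reference set.

    All realized identity bands (within-subfamily, within-family across
    subfamilies, between families) are verified by direct global-alignment
    identity; a family whose subfamily set violates its band is regenerated
    with fresh draws, up to ``max_retries`` times.
    """
    if config.n_families > len(FAMILY_NUMBERS):
        raise ValueError(f"at most {len(FAMILY_NUMBERS)} families supported")
    rng = np.random.default_rng(config.seed)
    core = _random_seq(rng, config.core_len)
    lo_band, hi_band = config.within_family_band

    family_names: list[str] = []
    family_ancestors: dict[str, str] = {}
    core_start: dict[str, int] = {}
    subfam_ancestors: dict[str, str] = {}
    subfam_family: dict[str, str] = {}
    refs: list[ReferenceCyp] = []

    for fi in range(config.n_families):
        fam = f"CYP{FAMILY_NUMBERS[fi]}"
        for attempt in range(config.max_retries):
            length = int(rng.integers(config.seq_len_range[0], config.seq_len_range[1] + 1))
            start = (2 * (length - config.core_len)) // 3
            flank = _random_seq(rng, length - config.core_len)
            ancestor = flank[:start] + core + flank[start:]
            protected = range(start, start + config.core_len)
            # Between-family check against already-accepted ancestors.
            if any(
                pairwise_identity(ancestor, other) > config.between_family_max
                for other in family_ancestors.values()
            ):
                continue
            subs = {}
            for si in range(config.subfamilies_per_family):
                sub_name = fam + SUBFAMILY_LETTERS[si]
                subs[sub_name] = _mutate(
                    ancestor, config.subfamily_divergence, rng, protected
                )
            names = list(subs)
            ok = all(
                lo_band
                <= pairwise_identity(subs[names[i]], subs[names[j]])
                <= hi_band
                for i in range(len(names))
                for j in range(i + 1, len(names))
            )
            if not ok:
                continue
            fam_refs = []
            for sub_name, sub_anc in subs.items():
                for ri in range(config.refs_per_subfamily):
                    seq = _mutate(sub_anc, config.ref_divergence, rng, protected)
                    fam_refs.append(ReferenceCyp(cyp_name=f"{sub_name}{ri + 1}", sequence=seq))
            # Refs: same subfamily above the subfamily floor, different
            # subfamilies of the family inside the within-family band.
            ok = True
            for i in range(len(fam_refs)):
                for j in range(i + 1, len(fam_refs)):
                    ident = pairwise_identity(fam_refs[i].sequence, fam_refs[j].sequence)
                    if fam_refs[i].subfamily == fam_refs[j].subfamily:
                        ok = ok and ident >= config.within_subfamily_min
                    else:
                        ok = ok and lo_band <= ident <= hi_band
            if not ok:
                continue
            # Between-family band holds for every realized ref pair, not just
            # the ancestors the refs drift away from.
            if any(
                pairwise_identity(r.sequence, prev.sequence) > config.between_family_max
                for r in fam_refs
                for prev in refs
            ):
                continue
            family_names.append(fam)
            family_ancestors[fam] = ancestor
            core_start[fam] = start
            for sub_name, sub_anc in subs.items():
                subfam_ancestors[sub_name] = sub_anc
                subfam_family[sub_name] = fam
            refs.extend(fam_refs)
            break
        else:
            raise RuntimeError(
                f"could not realize identity bands for family {fam} "
                f"after {config.max_retries} attempts; loosen bands or divergences"
            )

    alignment = [
        r.sequence[core_start[subfam_family[r.subfamily]] :][: config.core_len] for r in refs
    ]
    return SyntheticReference(
        core=core,
        family_names=family_names,
        family_ancestors=family_ancestors,
        core_start=core_start,
        subfamily_ancestors=subfam_ancestors,
        subfamily_family=subfam_family,
        refs=refs,
        domain_alignment=alignment,
    )


def _shares_kmer(seq: str, core: str, k: int = 10) -> bool:
    core_kmers = {core[i : i + k] for i in range(len(core) - k + 1)}
    return any(seq[i : i + k] in core_kmers for i in range(len(seq) - k + 1))


def generate_genomes(
    config: SynthConfig,
    reference: SyntheticReference,
    family_pool: list[str] | None = None,
    genome_prefix: str = "genome",
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomeProteome], pd.DataFrame]:
    """Generate genome proteomes and the ground-truth manifest.

    Each genome draws its CYP count uniformly from the configured range, picks
    a subfamily (from ``family_pool``, default all families) for each CYP with
    replacement, and derives the member from the subfamily ancestor inside the
    same-subfamily identity band (verified against the subfamily's first
    reference, bounded retries).  Decoys are random sequences sharing no
    10-mer with the conserved core.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pool = family_pool if family_pool is not None else reference.family_names
    subfams = [s for s, f in reference.subfamily_family.items() if f in pool]
    if not subfams:
        raise ValueError("family_pool matches no reference family")
    ref_by_sub: dict[str, str] = {}
    for r in reference.refs:
        ref_by_sub.setdefault(r.subfamily, r.sequence)

    genomes: list[GenomeProteome] = []
    rows = []
    for gi in range(config.n_genomes):
        gid = f"{genome_prefix}{gi + 1:02d}"
        records: list[ProteinRecord] = []
        lo, hi = config.cyps_per_genome
        n_cyps = int(rng.integers(lo, hi + 1))
        for pi in range(n_cyps):
            sub = subfams[rng.integers(0, len(subfams))]
            fam = reference.subfamily_family[sub]
            protected = range(
                reference.core_start[fam], reference.core_start[fam] + config.core_len
            )
            for _ in range(config.max_retries):
                seq = _mutate(
                    reference.subfamily_ancestors[sub],
                    config.member_divergence,
                    rng,
                    protected,
                )
                if pairwise_identity(seq, ref_by_sub[sub]) >= config.within_subfamily_min:
                    break
            else:
                raise RuntimeError(f"could not realize member band for {sub}")
            rid = f"p{pi + 1:04d}"
            records.append(ProteinRecord(id=rid, genome_id=gid, sequence=seq))
            rows.append(
                {"genome": gid, "seq_id": rid, "is_cyp": True, "family": fam, "subfamily": sub}
            )
        for di in range(config.decoys_per_genome):
            for _ in range(config.max_retries):
                length = int(
                    rng.integers(config.decoy_len_range[0], config.decoy_len_range[1] + 1)
                )
                seq = _random_seq(rng, length)
                if not _shares_kmer(seq, reference.core):
                    break
            else:
                raise RuntimeError("could not generate a core-free decoy")
            rid = f"d{di + 1:04d}"
            records.append(ProteinRecord(id=rid, genome_id=gid, sequence=seq))
            rows.append(
                {"genome": gid, "seq_id": rid, "is_cyp": False, "family": "", "subfamily": ""}
            )
        genomes.append(GenomeProteome(genome_id=gid, records=records))
    manifest = pd.DataFrame(rows, columns=["genome", "seq_id", "is_cyp", "family", "subfamily"])
    return genomes, manifest


def expected_gcm(
    manifest: pd.DataFrame, level: str, genome_ids: list[str] | None = None
):
    """Derive the expected GCM by counting the truth manifest."""
    from .gcm import build_gcm

    cyps = manifest[manifest["is_cyp"]].copy()
    if genome_ids is None:
        genome_ids = sorted(manifest["genome"].unique())
    return build_gcm(cyps, level, genome_ids=genome_ids)


def make_family_sequences(
    n_families: int = 3,
    n_seqs: int = 10,
    seq_len: int = 120,
    member_divergence: float = 0.08,
    seed: int = 0,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Small clustering fixture: unrelated families, tight members.

    Returns pooled records (round-robin over families, one synthetic genome)
    and the true family index of each tagged id.  Within-family identity is
    ≥ ~0.8, between-family identity that of random sequences (≪ 0.3).
    """
    rng = np.random.default_rng(seed)
    ancestors = [_random_seq(rng, seq_len) for _ in range(n_families)]
    records, truth = [], {}
    for i in range(n_seqs):
        fam = i % n_families
        seq = _mutate(ancestors[fam], member_divergence, rng)
        rec = ProteinRecord(id=f"s{i:03d}", genome_id="fixture", sequence=seq)
        records.append(rec)
        truth[rec.tagged_id] = fam
    return records, truth


def write_dataset(out_dir: str | Path, config: SynthConfig) -> Path:
    """Generate and write a complete dataset: genomes/, reference files, manifest.

    Layout: ``genomes/<id>.faa``, ``ref_cyps.faa`` (headers are CYP names),
    ``domain_alignment.fasta`` and ``truth_manifest.tsv``.
    """
    from .seqio import write_fasta

    out_dir = Path(out_dir)
    (out_dir / "genomes").mkdir(parents=True, exist_ok=True)
    reference = generate_reference_db(config)
    genomes, manifest = generate_genomes(config, reference)
    for genome in genomes:
        write_fasta(genome.records, out_dir / "genomes" / f"{genome.genome_id}.faa", tagged=False)
    with open(out_dir / "ref_cyps.faa", "w") as fh:
        for r in reference.refs:
            fh.write(f">{r.cyp_name}\n{r.sequence}\n")
    with open(out_dir / "domain_alignment.fasta", "w") as fh:
        for i, seq in enumerate(reference.domain_alignment):
            fh.write(f">domain_{i + 1}\n{seq}\n")
    manifest.to_csv(out_dir / "truth_manifest.tsv", sep="\t", index=False)
    return out_dir
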