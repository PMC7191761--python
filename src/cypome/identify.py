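"""CYP identification by position-specific scoring matrix (PSSM) domain scan.

Centroid sequences are scanned against one or more CYP-domain profiles built
from a multiple alignment of known CYP domains.  A profile stores per-position
log-odds scores in half-bits; a query is scanned with an ungapped sliding
window and the best window score is converted to an E-value through a
Karlin–Altschul-shaped model E = K·m·n·exp(−λS), with λ and K calibrated once
per profile from the best-score distribution of shuffled decoy sequences
(Gumbel maximum-likelihood fit, fixed seed).  A centroid is called a CYP when
its best E-value across profiles is at or below the cutoff (default 1e-5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gumbel_r

from .seqio import ProteinRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

DEFAULT_EVALUE_CUTOFF = 1e-5
NO_HIT_SCORE = float("-inf")


@dataclass
class DomainProfile:
    """Ungapped log-odds profile over the 20 amino acids, in half-bit units."""

    name: str
    scores: np.ndarray  # shape (length, 20)
    background: np.ndarray  # shape (20,), sums to 1

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("profile scores must be (length, 20)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite")


@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel-tail parameters (λ, K) fitted from shuffled-decoy best scores."""

    profile: str
    lam: float
    k: float
    decoy_length: int
    n_decoys: int


@dataclass(frozen=True)
class DomainHit:
    """Best profile hit for one query: score, E-value and window coordinates."""

    query: str
    profile: str
    score: float
    evalue: float
    start: int  # 1-based inclusive
    end: int


def build_profile(
    aligned_sequences: Sequence[str],
    name: str,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> DomainProfile:
    """Build a half-bit log-odds profile from equal-length gapped sequences.

    Columns with more than ``max_gap_fraction`` gaps are dropped.  Per-column
    scores are ``2·log2((count_a + 1) / (n + 20) / background_a)`` — observed
    frequency with a +1 pseudocount against the background (uniform 0.05 by
    default).
    """
    if len(aligned_sequences) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(s) for s in aligned_sequences}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    bg = np.full(20, 0.05) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (20,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be 20 frequencies summing to 1")

    seqs = [s.upper() for s in aligned_sequences]
    n_cols = lengths.pop()
    columns: list[np.ndarray] = []
    for j in range(n_cols):
        residues = [s[j] for s in seqs]
        gaps = sum(1 for r in residues if r in "-.")
        if gaps / len(residues) > max_gap_fraction:
            continue
        counts = np.zeros(20)
        n_obs = 0
        for r in residues:
            if r in AA_INDEX:
                counts[AA_INDEX[r]] += 1
                n_obs += 1
        freqs = (counts + 1.0) / (n_obs + 20.0)
        columns.append(2.0 * np.log2(freqs / bg))
    if not columns:
        raise ValueError("no columns survive the gap filter")
    return DomainProfile(name=name, scores=np.vstack(columns), background=bg)


def consensus_sequence(profile: DomainProfile) -> str:
    """Residue with the maximal score at each profile position."""
    return "".join(AA_ORDER[i] for i in np.argmax(profile.scores, axis=1))


def scan_sequence(query: str, profile: DomainProfile) -> tuple[float, int, int]:
    """Best ungapped window score of a profile along a query.

    Returns ``(score, start, end)`` with 1-based inclusive coordinates; ties
    are broken by the smallest start.  X (or any non-standard residue) scores
    0 at every position, its background expectation.  A query shorter than the
    profile yields ``(-inf, 0, 0)`` — a no-hit sentinel, not an error.
    """
    L = profile.length
    m = len(query)
    if m < L:
        return NO_HIT_SCORE, 0, 0
    # Column-score lookup: index 20 is the neutral row for X/unknowns.
    lut = np.hstack([profile.scores, np.zeros((L, 1))])
    q = np.fromiter((AA_INDEX.get(c, 20) for c in query.upper()), dtype=np.intp, count=m)
    n_windows = m - L + 1
    window_scores = np.zeros(n_windows)
    for k in range(L):
        window_scores += lut[k, q[k : k + n_windows]]
    best = int(np.argmax(window_scores))  # argmax takes the first maximum
    return float(window_scores[best]), best + 1, best + L


def calibrate(
    profile: DomainProfile,
    n_decoys: int = 500,
    decoy_length: int = 400,
    seed: int = 0,
) -> EvalueCalibration:
    """Fit λ and K for a profile from shuffled decoy sequences.

    Decoys are random sequences drawn from the profile background (equivalent
    to shuffles of a background-composition sequence); the best window score
    of each decoy is collected and a Gumbel distribution is fitted by maximum
    likelihood.  With location μ and scale β, the expected-hit model
    E = K·m·n·exp(−λS) uses λ = 1/β and K = exp(μ/β)/(m_decoy·n_profile).
    """
    if n_decoys < 2:
        raise ValueError("need at least 2 decoys")
    rng = np.random.default_rng(seed)
    scores = decoy_scores(profile, n_decoys, decoy_length, rng)
    mu, beta = gumbel_r.fit(scores)
    lam = 1.0 / beta
    k = math.exp(mu / beta) / (decoy_length * profile.length)
    return EvalueCalibration(
        profile=profile.name, lam=lam, k=k, decoy_length=decoy_length, n_decoys=n_decoys
    )


def decoy_scores(
    profile: DomainProfile,
    n_decoys: int,
    decoy_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Best window scores of random background-composition decoy sequences."""
    out = np.empty(n_decoys)
    for i in range(n_decoys):
        seq_idx = rng.choice(20, size=decoy_length, p=profile.background)
        decoy = "".join(AA_ORDER[j] for j in seq_idx)
        out[i], _, _ = scan_sequence(decoy, profile)
    return out


def estimate_evalue(
    score: float,
    profile: DomainProfile,
    query_length: int,
    database_size: int,
    calibration: EvalueCalibration,
) -> float:
    """Expected chance hits at or above ``score``: E = K·m·n·exp(−λS).

    ``m`` is the query length and ``n`` the database size in residues (the
    summed length of all profiles scanned).  Monotonically decreasing in the
    score; clamped away from exact zero so downstream log-scale reports stay
    finite.
    """
    if calibration is None:
        raise ValueError(f"no E-value calibration for profile {profile.name!r}; run calibrate()")
    if score == NO_HIT_SCORE:
        return float("inf")
    e = calibration.k * query_length * database_size * math.exp(-calibration.lam * score)
    return max(e, 1e-300)


def identify_cyps(
    centroids: Iterable[ProteinRecord],
    profiles: Sequence[DomainProfile],
    calibrations: Mapping[str, EvalueCalibration],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    database_size: int | None = None,
) -> list[DomainHit]:
    """Call CYPs among centroid sequences: best hit per centroid at E ≤ cutoff.

    Each centroid keeps only its single best (lowest E-value) profile hit, so
    multi-domain proteins count once downstream.  Hits are returned in
    centroid input order.
    """
    if not profiles:
        raise ValueError("need at least 1 profile")
    n_db = database_size if database_size is not None else sum(p.length for p in profiles)
    hits: list[DomainHit] = []
    for rec in centroids:
        best: DomainHit | None = None
        for profile in profiles:
            score, start, end = scan_sequence(rec.sequence, profile)
            if score == NO_HIT_SCORE:
                continue
            ev = estimate_evalue(
                score, profile, len(rec.sequence), n_db, calibrations[profile.name]
            )
            if best is None or ev < best.evalue:
                best = DomainHit(
                    query=rec.tagged_id,
                    profile=profile.name,
                    score=score,
                    evalue=ev,
                    start=start,
                    end=end,
                )
        if best is not None and best.evalue <= evalue_cutoff:
            hits.append(best)
    return hits


# ---------------------------------------------------------------------------
# Profile text serialization: one header line, then length×20 half-bit scores
# ---------------------------------------------------------------------------

def save_profile(profile: DomainProfile, path: str | Path) -> None:
    lines = [f"#PROFILE\t{profile.name}\t{profile.length}"]
    lines.append("#BACKGROUND\t" + "\t".join(f"{x:.6g}" for x in profile.background))
    lines.append("#AA\t" + "\t".join(AA_ORDER))
    for row in profile.scores:
        lines.append("\t".join(f"{x:.4f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_profile(path: str | Path) -> DomainProfile:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header[0] != "#PROFILE":
        raise ValueError(f"not a profile file: {path}")
    name = header[1]
    background = np.array([float(x) for x in lines[1].split("\t")[1:]])
    rows = [
        [float(x) for x in ln.split("\t")]
        for ln in lines[2:]
        if ln and not ln.startswith("#")
    ]
    return DomainProfile(name=name, scores=np.array(rows), background=background)
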