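"""bHLH domain detection, region partition, binding classification and
intron-pattern typing.

The domain is located by aligning a frequency profile (built from a seed
alignment) against each protein with a semi-global affine-gap dynamic
program: every profile column must be consumed while the protein flanks
are free, so the reported hit is a local placement of the whole domain.
The located domain is partitioned into the basic region, helix 1, the
loop and helix 2; DNA-binding ability is then classified by a fixed
cascade on the basic region (basic-residue count, then the E-box
requirement E-2 + R-4, then the G-box requirement H/K-1 + E-2 + R-5).
Intron positions from the gene model are mapped into domain-CDS
coordinates and typed against twelve canonical distribution patterns.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from . import synthetic_seed_profile as seed

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
PROTEIN_ALPHABET = frozenset(AA_ORDER) | {"X"}
_BACKGROUND = 1.0 / 20.0
_PSEUDOCOUNT = 0.2

GAP_OPEN = 5.0
GAP_EXTEND = 1.0


# ---------------------------------------------------------------------------
# Records and profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise InputError(
                f"protein {self.id}: invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class DomainProfile:
    """Per-column residue frequencies with region layout and rule positions."""

    columns: tuple[Mapping[str, float], ...]  # frequencies over residues + '-'
    region_spec: Mapping[str, tuple[int, int]]
    named_positions: Mapping[str, int]
    score_threshold: float

    def __post_init__(self) -> None:
        length = len(self.columns)
        prev_end = 0
        for region, (start, end) in self.region_spec.items():
            if start != prev_end:
                raise ConfigurationError(
                    f"region_spec: region {region!r} does not start at {prev_end}"
                )
            if end <= start:
                raise ConfigurationError(f"region_spec: region {region!r} is empty")
            prev_end = end
        if prev_end != length:
            raise ConfigurationError(
                f"region_spec covers columns [0,{prev_end}) but profile has {length}"
            )
        for label, col in self.named_positions.items():
            if not 0 <= col < length:
                raise ConfigurationError(
                    f"named_positions: {label!r} -> column {col} outside profile"
                )

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def consensus(self) -> str:
        out = []
        for freqs in self.columns:
            best = max(
                (aa for aa in AA_ORDER),
                key=lambda aa: (freqs.get(aa, 0.0), -AA_INDEX[aa]),
            )
            out.append(best)
        return "".join(out)

    def region_of_column(self, col: int) -> str:
        for region, (start, end) in self.region_spec.items():
            if start <= col < end:
                return region
        raise InputError(f"column {col} outside profile")

    @property
    def score_matrix(self) -> np.ndarray:
        """(L, 21) log2-odds: 20 residues in AA_ORDER order plus X (score 0)."""
        cached = getattr(self, "_score_matrix", None)
        if cached is not None:
            return cached
        length = len(self)
        mat = np.zeros((length, 21))
        for i, freqs in enumerate(self.columns):
            occupancy = 1.0 - freqs.get("-", 0.0)
            denom = occupancy + _PSEUDOCOUNT
            for aa in AA_ORDER:
                q = (freqs.get(aa, 0.0) + _PSEUDOCOUNT * _BACKGROUND) / denom
                mat[i, AA_INDEX[aa]] = np.log2(q / _BACKGROUND)
        mat[:, 20] = 0.0  # X: uninformative
        object.__setattr__(self, "_score_matrix", mat)
        return mat


def build_domain_profile(
    seed_alignment: Sequence[str],
    region_spec: Mapping[str, tuple[int, int]],
    named_positions: Mapping[str, int],
    score_threshold: float | None = None,
    *,
    n_shuffles: int = 1000,
    quantile: float = 0.99,
    calibration_seed: int = 0,
) -> DomainProfile:
    """Build a frequency profile from an aligned set of domain sequences.

    Per-column frequencies (residues plus gap) sum to one.  If no
    ``score_threshold`` is given it is calibrated as the ``quantile`` of
    profile scores over ``n_shuffles`` residue shuffles of the consensus.
    """
    if len(seed_alignment) < 2:
        raise InputError("seed alignment needs at least 2 rows")
    ncol = len(seed_alignment[0])
    if any(len(row) != ncol for row in seed_alignment):
        raise InputError("seed alignment rows have unequal lengths (ragged alignment)")
    columns = []
    nrow = len(seed_alignment)
    for c in range(ncol):
        counts: dict[str, float] = {}
        for row in seed_alignment:
            ch = row[c]
            if ch != "-" and ch not in AA_INDEX:
                raise InputError(f"seed alignment: invalid residue {ch!r} in column {c}")
            counts[ch] = counts.get(ch, 0.0) + 1.0
        columns.append({k: v / nrow for k, v in counts.items()})
    profile = DomainProfile(
        tuple(columns), dict(region_spec), dict(named_positions),
        score_threshold if score_threshold is not None else 0.0,
    )
    if score_threshold is None:
        threshold = calibrate_score_threshold(
            profile, n_shuffles=n_shuffles, quantile=quantile, seed=calibration_seed
        )
        profile = DomainProfile(
            profile.columns, dict(region_spec), dict(named_positions), threshold
        )
    return profile


@lru_cache(maxsize=1)
def default_profile() -> DomainProfile:
    """The packaged profile built from the synthetic seed alignment."""
    return build_domain_profile(
        seed.SEED_ALIGNMENT,
        seed.REGION_SPEC,
        seed.NAMED_POSITIONS,
        score_threshold=seed.DEFAULT_SCORE_THRESHOLD,
    )


def calibrate_score_threshold(
    profile: DomainProfile,
    *,
    n_shuffles: int = 1000,
    quantile: float = 0.99,
    seed: int = 0,
) -> float:
    """Null-score threshold: quantile of scores of shuffled consensus copies."""
    rng = np.random.default_rng(seed)
    consensus = list(profile.consensus)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = "".join(rng.permutation(consensus))
        scores[i] = _best_alignment(profile, shuffled)[0]
    return float(np.quantile(scores, quantile))


# ---------------------------------------------------------------------------
# Semi-global profile-to-sequence alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainAnnotation:
    """A located domain: protein coordinates plus the profile column map."""

    protein_id: str
    start: int  # 0-based half-open, protein coordinates
    end: int
    column_map: tuple[Optional[int], ...]  # profile column -> protein index or None
    score: float
    sequence: str  # full protein sequence the annotation refers to

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= len(self.sequence)):
            raise InputError(
                f"domain coordinates [{self.start},{self.end}) invalid for "
                f"protein of length {len(self.sequence)}"
            )
        last = -1
        for pos in self.column_map:
            if pos is None:
                continue
            if pos <= last:
                raise InputError("column_map is not monotone")
            last = pos

    def residue_at_column(self, col: int) -> str | None:
        pos = self.column_map[col]
        return None if pos is None else self.sequence[pos]


_NEG = -1e30


def _encode(sequence: str) -> np.ndarray:
    return np.array([AA_INDEX.get(ch, 20) for ch in sequence], dtype=np.intp)


def _best_alignment(profile: DomainProfile, sequence: str):
    """Semi-global DP.  Returns (score, end_j, M, Ix, Iy) matrices.

    States: M — column matched to a residue; Ix — column deleted (gap in
    the protein); Iy — protein residue inserted between columns.  The
    whole profile must be consumed; protein flanks are free.
    """
    smat = profile.score_matrix
    enc = _encode(sequence)
    L, n = len(profile), len(sequence)
    M = np.full((L + 1, n + 1), _NEG)
    Ix = np.full((L + 1, n + 1), _NEG)
    Iy = np.full((L + 1, n + 1), _NEG)
    M[0, :] = 0.0
    idx = np.arange(n + 1)
    for i in range(1, L + 1):
        col_scores = smat[i - 1][enc]  # length n
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + col_scores
        Ix[i] = np.maximum(M[i - 1] - GAP_OPEN, Ix[i - 1] - GAP_EXTEND)
        # Iy[i, j] = max_{j' < j} M[i, j'] - GAP_OPEN - (j - 1 - j') * GAP_EXTEND
        running = np.maximum.accumulate(M[i] + idx * GAP_EXTEND)
        Iy[i, 1:] = running[:-1] - GAP_OPEN - (idx[1:] - 1) * GAP_EXTEND
    finals = np.maximum(M[L], Ix[L])
    end_j = int(np.argmax(finals))  # first maximum on ties -> first copy wins
    return float(finals[end_j]), end_j, M, Ix, Iy


def find_bhlh_domain(
    protein: ProteinRecord, profile: DomainProfile
) -> DomainAnnotation | None:
    """Best-scoring placement of the profile in the protein, or None.

    Returns an annotation only if the alignment score reaches the
    profile's score threshold; absence is a value, not an error.
    """
    score, end_j, M, Ix, Iy = _best_alignment(profile, protein.sequence)
    if score < profile.score_threshold:
        return None
    L = len(profile)
    tol = 1e-9
    column_map: list[Optional[int]] = [None] * L
    i, j = L, end_j
    state = "M" if M[L, end_j] >= Ix[L, end_j] else "Ix"
    while i > 0:
        if state == "M":
            column_map[i - 1] = j - 1
            target = M[i, j] - profile.score_matrix[i - 1][_encode(protein.sequence[j - 1])[0]]
            i, j = i - 1, j - 1
            for cand in ("M", "Ix", "Iy"):
                val = {"M": M, "Ix": Ix, "Iy": Iy}[cand][i, j]
                if abs(val - target) <= tol * max(1.0, abs(target)):
                    state = cand
                    break
        elif state == "Ix":
            if abs(M[i - 1, j] - GAP_OPEN - Ix[i, j]) <= tol * max(1.0, abs(Ix[i, j])):
                state = "M"
            i -= 1
        else:  # Iy: inserted protein residue
            if abs(M[i, j - 1] - GAP_OPEN - Iy[i, j]) <= tol * max(1.0, abs(Iy[i, j])):
                state = "M"
            j -= 1
    mapped = [p for p in column_map if p is not None]
    if not mapped:
        return None
    return DomainAnnotation(
        protein_id=protein.id,
        start=mapped[0],
        end=mapped[-1] + 1,
        column_map=tuple(column_map),
        score=score,
        sequence=protein.sequence,
    )


def partition_regions(
    annotation: DomainAnnotation, profile: DomainProfile
) -> dict[str, tuple[int, int] | None]:
    """Map each profile region through the column map to protein coordinates.

    A region whose columns are all gapped in the protein is flagged empty
    (None), not an error.
    """
    regions: dict[str, tuple[int, int] | None] = {}
    for region, (c0, c1) in profile.region_spec.items():
        mapped = [
            annotation.column_map[c]
            for c in range(c0, c1)
            if annotation.column_map[c] is not None
        ]
        regions[region] = (mapped[0], mapped[-1] + 1) if mapped else None
    return regions


# ---------------------------------------------------------------------------
# Binding classification
# ---------------------------------------------------------------------------


class BindingCategory(enum.Enum):
    NON_BINDING = "non-binding"
    NON_EBOX = "non-E-box"
    GBOX = "G-box"
    EBOX_NON_GBOX = "E-box-non-G-box"


@dataclass(frozen=True)
class BindingRuleSet:
    """Residue rules for the DNA-binding cascade.

    ``basic_min_count`` defaults to 6 — the literal reading of
    "more than five basic residues" in the basic region.
    """

    basic_residues: frozenset[str] = frozenset("KRH")
    basic_min_count: int = 6
    ebox_required: Mapping[str, frozenset[str]] = None  # type: ignore[assignment]
    gbox_required: Mapping[str, frozenset[str]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.basic_min_count < 1:
            raise ConfigurationError("basic_min_count must be >= 1")
        if self.ebox_required is None:
            object.__setattr__(
                self, "ebox_required",
                {"E-2": frozenset("E"), "R-4": frozenset("R")},
            )
        if self.gbox_required is None:
            object.__setattr__(
                self, "gbox_required",
                {"H/K-1": frozenset("HK"), "E-2": frozenset("E"), "R-5": frozenset("R")},
            )


def classify_binding(
    annotation: DomainAnnotation,
    profile: DomainProfile,
    rules: BindingRuleSet | None = None,
) -> BindingCategory:
    """Deterministic binding cascade.

    (1) fewer than ``basic_min_count`` basic residues in the basic region
    -> NON_BINDING; (2) otherwise the E-box positions must hold their
    required residues, else NON_EBOX; (3) an E-box binder with the G-box
    positions satisfied -> GBOX, else EBOX_NON_GBOX.  A gapped named
    position fails its requirement.
    """
    rules = rules or BindingRuleSet()
    for label in {**rules.ebox_required, **rules.gbox_required}:
        if label not in profile.named_positions:
            raise ConfigurationError(f"profile lacks named position {label!r}")
    c0, c1 = profile.region_spec["basic"]
    basic_count = 0
    for c in range(c0, c1):
        res = annotation.residue_at_column(c)
        if res is not None and res in rules.basic_residues:
            basic_count += 1
    if basic_count < rules.basic_min_count:
        return BindingCategory.NON_BINDING

    def satisfied(required: Mapping[str, frozenset[str]]) -> bool:
        for label, allowed in required.items():
            res = annotation.residue_at_column(profile.named_positions[label])
            if res is None or res not in allowed:
                return False
        return True

    if not satisfied(rules.ebox_required):
        return BindingCategory.NON_EBOX
    if satisfied(rules.gbox_required):
        return BindingCategory.GBOX
    return BindingCategory.EBOX_NON_GBOX


def count_basic_residues(
    annotation: DomainAnnotation,
    profile: DomainProfile,
    rules: BindingRuleSet | None = None,
) -> int:
    rules = rules or BindingRuleSet()
    c0, c1 = profile.region_spec["basic"]
    return sum(
        1
        for c in range(c0, c1)
        if (res := annotation.residue_at_column(c)) is not None
        and res in rules.basic_residues
    )


# ---------------------------------------------------------------------------
# Gene models and intron patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one representative transcript.

    Coordinates are 0-based half-open genomic; exons and CDS segments are
    ordered 5'->3' along the transcript.  Intron positions are derived in
    CDS coordinate space (nucleotides from the CDS start).
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: invalid strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise InputError(f"{self.gene_id}: overlapping exons")
        if self.cds_length % 3:
            raise InputError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def intron_cds_positions(self) -> tuple[int, ...]:
        """Positions of introns interrupting the CDS, in CDS nucleotides."""
        positions = []
        running = 0
        for s, e in self.cds_segments[:-1]:
            running += e - s
            positions.append(running)
        return tuple(positions)

    @property
    def phases(self) -> tuple[int, ...]:
        """GFF3 phase of each CDS segment."""
        out = []
        running = 0
        for s, e in self.cds_segments:
            out.append((3 - running % 3) % 3)
            running += e - s
        return tuple(out)


@dataclass(frozen=True)
class IntronEvent:
    cds_position: int  # nucleotides from CDS start
    domain_offset: int  # nucleotides from domain-CDS start
    phase: int


def map_introns_to_domain(
    gene: GeneModel,
    annotation: DomainAnnotation,
    cds: str | Sequence[str],
) -> list[IntronEvent]:
    """Introns whose CDS position falls inside the domain-encoding region.

    The domain's protein coordinates convert to CDS nucleotides by *3;
    the half-open convention keeps an intron exactly at the domain start
    inside and one at the end outside.  Phase is position mod 3.
    """
    cds_len = len(cds) if isinstance(cds, str) else 3 * len(cds)
    if cds_len != gene.cds_length:
        raise InputError(
            f"{gene.gene_id}: CDS sequence length {cds_len} does not match "
            f"gene model CDS length {gene.cds_length}"
        )
    lo, hi = annotation.start * 3, annotation.end * 3
    return [
        IntronEvent(pos, pos - lo, pos % 3)
        for pos in gene.intron_cds_positions
        if lo <= pos < hi
    ]


class IntronPatternCode(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"
    X = "X"
    XI = "XI"
    O = "O"


# signature: (frozenset of occupied canonical positions in {1,2,3},
#             whether any non-canonical intron is present)
# I ({1,2,3}), IX ({2}) and XI (empty) are fixed; the remaining codes are
# assigned to the other occupancy signatures by a packaged, editable table.
DEFAULT_PATTERN_TABLE: dict[tuple[frozenset[int], bool], IntronPatternCode] = {
    (frozenset({1, 2, 3}), False): IntronPatternCode.I,
    (frozenset({1, 2}), False): IntronPatternCode.II,
    (frozenset({1, 3}), False): IntronPatternCode.III,
    (frozenset({2, 3}), False): IntronPatternCode.IV,
    (frozenset({1}), False): IntronPatternCode.V,
    (frozenset({3}), False): IntronPatternCode.VI,
    (frozenset({1, 2, 3}), True): IntronPatternCode.VII,
    (frozenset({2}), True): IntronPatternCode.VIII,
    (frozenset({2}), False): IntronPatternCode.IX,
    (frozenset(), True): IntronPatternCode.X,
    (frozenset(), False): IntronPatternCode.XI,
}


def type_intron_pattern(
    events: Iterable[IntronEvent],
    canonical_positions: Sequence[int] = seed.CANONICAL_INTRON_OFFSETS,
    tolerance: int = 6,
    pattern_table: Mapping[tuple[frozenset[int], bool], IntronPatternCode] = None,  # type: ignore[assignment]
) -> IntronPatternCode:
    """Type an intron configuration against the canonical patterns.

    Each event is assigned to the nearest canonical position within the
    tolerance window, otherwise it counts as non-canonical.  Two events
    landing on the same canonical position demote that position to
    non-canonical occupancy.  Signatures missing from the table fall back
    to pattern O.
    """
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    if list(canonical_positions) != sorted(canonical_positions):
        raise ConfigurationError("canonical positions must be ordered")
    table = pattern_table if pattern_table is not None else DEFAULT_PATTERN_TABLE
    hits: dict[int, int] = {}
    noncanonical = 0
    for event in events:
        best = None
        for idx, canon in enumerate(canonical_positions, start=1):
            dist = abs(event.domain_offset - canon)
            if dist <= tolerance and (best is None or dist < best[0]):
                best = (dist, idx)
        if best is None:
            noncanonical += 1
        else:
            hits[best[1]] = hits.get(best[1], 0) + 1
    occupied = set()
    for idx, count in hits.items():
        if count == 1:
            occupied.add(idx)
        else:  # doubly-hit canonical position: treated as non-canonical
            noncanonical += count
    signature = (frozenset(occupied), noncanonical > 0)
    return table.get(signature, IntronPatternCode.O)
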