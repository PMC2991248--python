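"""AG-exclusion-zone delimitation and canonical branch-point candidate search.

The AG exclusion zone (AGEZ) is the 3'-terminal intron region devoid of AG
dinucleotides in which the branch point normally resides.  AGs very close to
the 3SS (within the ``grace`` region, default 12 nt) compete with the actual
acceptor rather than terminating the zone, so they are ignored when the zone
is delimited; the first AG beyond the grace region is the AGEZ-defining AG.

Canonical branch-point candidates are 9-mers with T at position 4 and the
branch adenosine A at position 6 (1-based), the minimal TNA signature with
one extra constrained position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .seqio import IntronRecord


@dataclass(frozen=True)
class AGEZ:
    """An AG exclusion zone in 3SS-anchored coordinates.

    ``start`` is the first (5'-most) nucleotide inside the zone; ``end`` the
    last.  For the first AGEZ (rank 0) ``end`` is -3, i.e. the zone excludes
    the 3SS AG itself.  ``defining_ag`` is the position of the A of the
    AGEZ-defining AG (just upstream of ``start``); it is None when no AG was
    found within the scanned extent.
    """

    start: int
    end: int
    defining_ag: Optional[int] = None
    rank: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos3ss: int) -> bool:
        return self.start <= pos3ss <= self.end


@dataclass
class BPCandidate:
    """A branch-point candidate 9-mer with the adenosine at position 6.

    ``bp_pos`` is the 3SS-anchored position of the branch adenosine.  Score
    fields are filled by downstream modules.  Canonical candidates also have
    T at position 4 (``is_canonical``); the consensus-based baselines may
    rank non-canonical 9-mers.
    """

    ninemer: str
    bp_pos: int
    motif_score: Optional[float] = None
    ppt_distance: Optional[float] = None
    ppt_score: Optional[float] = None
    py_content: Optional[float] = None
    svm_score: Optional[float] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.ninemer) != 9:
            raise ValueError(f"candidate 9-mer has length {len(self.ninemer)}")
        if self.ninemer[5] != "A":
            raise ValueError(f"{self.ninemer}: position 6 must be the branch A")

    @property
    def is_canonical(self) -> bool:
        return self.ninemer[3] == "T"


def _sequence_of(intron: Union[IntronRecord, str]) -> str:
    return intron.sequence if isinstance(intron, IntronRecord) else str(intron)


def ag_positions(seq: str) -> list[int]:
    """3SS-anchored positions of the A of every AG dinucleotide, ascending."""
    L = len(seq)
    return [i - L for i in range(L - 1) if seq[i : i + 2] == "AG"]


def find_agez(
    intron: Union[IntronRecord, str],
    grace: int = 12,
    rank: int = 0,
    max_extent: int = 500,
) -> AGEZ:
    """Delimit the AG exclusion zone of rank ``rank``.

    Scanning 5'-ward from the 3SS, AGs whose A lies at position >= -grace
    are ignored (they compete with the 3SS rather than delimit the zone);
    the first AG beyond that is the defining AG and the zone spans from it
    (exclusive of its A) down to -3.  When no defining AG exists within
    ``max_extent`` nt (or the intron start), the zone is truncated there and
    ``defining_ag`` is None.

    ``rank`` k > 0 returns the k-th zone upstream, applying the same rule
    anchored at the previous defining AG.
    """
    seq = _sequence_of(intron)
    L = len(seq)
    if L < grace + 2:
        raise ValueError(f"intron of length {L} shorter than grace+2 = {grace + 2}")
    if rank < 0:
        raise ValueError("rank must be >= 0")
    ags = ag_positions(seq)

    anchor_a = -2  # A of the 3SS AG
    zone = None
    for k in range(rank + 1):
        end = anchor_a - 1
        cutoff = anchor_a - grace + 2  # AGs with A >= cutoff are in the grace region
        floor = max(-L, end - max_extent + 1)  # 5'-most nt the zone may reach
        eligible = [p for p in ags if floor - 1 <= p < cutoff]
        if eligible:
            defining = max(eligible)
            zone = AGEZ(start=defining + 1, end=end, defining_ag=defining, rank=k)
        else:
            zone = AGEZ(start=floor, end=end, defining_ag=None, rank=k)
        if k < rank:
            if zone.defining_ag is None:
                raise ValueError(
                    f"no defining AG for AGEZ rank {k}; rank {rank} does not exist"
                )
            anchor_a = zone.defining_ag
    return zone


def enumerate_candidates(
    intron: Union[IntronRecord, str],
    region: Union[AGEZ, tuple, None] = None,
    min_dist: int = 15,
    grace: int = 12,
) -> list[BPCandidate]:
    """All canonical BP candidate 9-mers whose adenosine lies in ``region``.

    ``region`` may be an :class:`AGEZ`, an inclusive ``(from, to)`` pair of
    3SS-anchored positions, or None (the first AGEZ is computed).  The
    adenosine must additionally lie at or upstream of ``-min_dist``.
    Windows containing N are skipped; candidates are returned 5'->3'.
    """
    seq = _sequence_of(intron)
    L = len(seq)
    if min_dist < 3:
        raise ValueError("min_dist must be >= 3")
    if region is None:
        region = find_agez(seq, grace=grace)
    if isinstance(region, AGEZ):
        lo, hi = region.start, region.end
    else:
        lo, hi = region
        if lo > hi:
            raise ValueError(f"empty region ({lo}, {hi})")
    hi = min(hi, -min_dist)

    out = []
    for pos in range(max(lo, -L + 5), hi + 1):
        i = L + pos  # 0-based index of the candidate adenosine
        if i + 4 > L or i < 5:
            continue
        if seq[i] != "A" or seq[i - 2] != "T":
            continue
        window = seq[i - 5 : i + 4]
        if "N" in window:
            continue
        out.append(BPCandidate(ninemer=window, bp_pos=pos))
    return out


_TNA_PATTERNS = ("TNANN", "NTNAN", "NNTNA")


def tna_pentamer_patterns() -> tuple[str, ...]:
    """All distinct pentamers matching TNANN, NTNAN or NNTNA (sorted).

    These are the pentamers that can carry the minimal TNA branch-point
    signature (branch A preceded by a T two bases upstream); there are 184.
    """
    hits = set()
    for pent in itertools.product("ACGT", repeat=5):
        word = "".join(pent)
        for pat in _TNA_PATTERNS:
            if all(p == "N" or p == c for p, c in zip(pat, word)):
                hits.add(word)
                break
    return tuple(sorted(hits))
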