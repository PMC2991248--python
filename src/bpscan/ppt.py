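"""Heuristic polypyrimidine-tract (PPT) detection and scoring.

A PPT is a maximal subsequence satisfying five rules:

1. both the 5' and 3' end are pyrimidines (C/T);
2. no more than two contiguous purines occur inside;
3. every purine segment of length L (< 3) is surrounded by at least 4L
   pyrimidines in total, with both the upstream and the downstream
   pyrimidine segment of length >= L (this forces a pyrimidine content
   above 2/3 around interruptions);
4. T(GT)n stretches are allowed: a G flanked by T on both sides is treated
   as pyrimidine-like for rules 2-3 (it still counts as G in composition
   and score);
5. the tract is at least 9 nt long or contains at least 5 T.

Tracts are scored linearly in composition, score = sum_n w_n f_n with
default weights w_T=3, w_C=2, w_G=-1, w_A=-2 (a documented stand-in that
preserves the qualitative ordering: T-richness dominates, purine
interruptions are penalized).  Coordinates are 3SS-anchored, treating the
end of the supplied sequence as the intron end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .agez import BPCandidate

DEFAULT_WEIGHTS = {"T": 3.0, "C": 2.0, "G": -1.0, "A": -2.0}

#: Distance reported when no PPT lies downstream of a candidate (the length
#: of the default genome-wide scan window); the associated score is 0.
NO_PPT_SENTINEL = 500


@dataclass
class PPTTract:
    """A maximal polypyrimidine tract in 3SS-anchored coordinates."""

    start: int
    end: int
    sequence: str
    counts: dict
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def ppt_score(tract_or_seq, weights: Optional[dict] = None) -> float:
    """Length-and-composition score: sum of per-nucleotide weights."""
    w = DEFAULT_WEIGHTS if weights is None else weights
    if isinstance(tract_or_seq, PPTTract):
        counts = tract_or_seq.counts
    else:
        counts = Counter(tract_or_seq)
    return float(sum(w.get(n, 0.0) * c for n, c in counts.items()))


def _classify(seq: str) -> list[str]:
    """Per-position classes: Y pyrimidine, X exempt G (T on both sides),
    R purine, N anything else."""
    cls = []
    n = len(seq)
    for i, c in enumerate(seq):
        if c in "CT":
            cls.append("Y")
        elif c == "G" and 0 < i < n - 1 and seq[i - 1] == "T" and seq[i + 1] == "T":
            cls.append("X")
        elif c in "AG":
            cls.append("R")
        else:
            cls.append("N")
    return cls


def _blocks(cls: list[str], max_run: int) -> list[tuple[int, int]]:
    """Maximal [lo, hi] stretches free of N and of purine runs > max_run.

    Any valid tract lies entirely inside one block: a tract can neither
    contain an over-long purine run nor start/end on a purine.
    """
    blocks = []
    n = len(cls)
    i = 0
    while i < n:
        if cls[i] == "N":
            i += 1
            continue
        j = i
        run = 0
        last_ok = i - 1
        while j < n and cls[j] != "N":
            if cls[j] == "R":
                run += 1
                if run > max_run:
                    break
            else:
                run = 0
            j += 1
        # j stopped at N, end, or inside an over-long purine run
        if j < n and cls[j] == "R":
            # trim the offending run: block ends just before it starts
            blocks.append((i, j - run))
            # resume after the purine run
            k = j
            while k < n and cls[k] == "R":
                k += 1
            i = k
        else:
            blocks.append((i, j - 1))
            i = j + 1
    return [(lo, hi) for lo, hi in blocks if hi >= lo]


def _scan_block(
    seq: str,
    cls: list[str],
    lo: int,
    hi: int,
    max_run: int,
    surround: int,
    min_len: int,
    min_t: int,
) -> dict[int, set[int]]:
    """valid[i] = set of j such that seq[i..j] satisfies all tract rules."""
    valid: dict[int, set[int]] = {}
    for i in range(lo, hi + 1):
        if cls[i] != "Y":
            continue
        ends: set[int] = set()
        cur_run = 0  # length of the open purine run
        run_u = 0  # upstream pyrimidine segment of the open/last run
        last_py = 0  # length of the current pyrimidine-like segment
        pend = None  # (L, U) of the most recent closed purine run
        tcount = 0
        dead = False
        for j in range(i, hi + 1):
            c = cls[j]
            if c == "R":
                if cur_run:
                    cur_run += 1
                    if cur_run > max_run:
                        break
                else:
                    if pend is not None:
                        # previous run's downstream segment is now frozen
                        L0, U0 = pend
                        if last_py < L0 or U0 + last_py < surround * L0:
                            dead = True
                            break
                        pend = None
                    cur_run = 1
                    run_u = last_py
                    last_py = 0
            else:
                if cur_run:
                    if run_u < cur_run:
                        # upstream segment can never grow for this start
                        dead = True
                        break
                    pend = (cur_run, run_u)
                    cur_run = 0
                    last_py = 1
                else:
                    last_py += 1
                if seq[j] == "T":
                    tcount += 1
                if c == "Y":
                    ok = True
                    if pend is not None:
                        L0, U0 = pend
                        ok = last_py >= L0 and U0 + last_py >= surround * L0
                    if ok and (j - i + 1 >= min_len or tcount >= min_t):
                        ends.add(j)
            if dead:
                break
        if ends:
            valid[i] = ends
    return valid


def find_ppts(
    seq: Union[str, "object"],
    weights: Optional[dict] = None,
    min_len: int = 9,
    min_t: int = 5,
    max_purine_run: int = 2,
    surround_factor: int = 4,
) -> list[PPTTract]:
    """Find maximal, non-overlapping polypyrimidine tracts.

    Maximal means no emitted tract can be extended by one nucleotide on
    either side and still satisfy every rule.  Overlaps among maximal
    tracts are resolved greedily: longest first, ties to the 3'-most.
    Output is sorted 5'->3'.  N breaks tracts.
    """
    s = seq.sequence if hasattr(seq, "sequence") else str(seq)
    n = len(s)
    cls = _classify(s)
    empty: set[int] = set()
    candidates: list[tuple[int, int]] = []
    for lo, hi in _blocks(cls, max_purine_run):
        valid = _scan_block(s, cls, lo, hi, max_purine_run, surround_factor, min_len, min_t)
        for i, ends in valid.items():
            left = valid.get(i - 1, empty)
            for j in ends:
                if j + 1 in ends:  # extendable 3'
                    continue
                if j in left:  # extendable 5'
                    continue
                candidates.append((i, j))
    # greedy overlap resolution: longest first, ties to the 3'-most
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0] + 1), -ij[0]))
    kept: list[tuple[int, int]] = []
    for i, j in candidates:
        if all(j < ki or i > kj for ki, kj in kept):
            kept.append((i, j))
    kept.sort()
    tracts = []
    for i, j in kept:
        sub = s[i : j + 1]
        counts = dict(Counter(sub))
        tracts.append(
            PPTTract(
                start=i - n,
                end=j - n,
                sequence=sub,
                counts=counts,
                score=ppt_score(sub, weights),
            )
        )
    return tracts


def closest_downstream_ppt(
    bp: Union[BPCandidate, int],
    tracts: Sequence[PPTTract],
    sentinel: int = NO_PPT_SENTINEL,
) -> tuple[float, float]:
    """Distance and score of the nearest PPT extending downstream of the BP.

    Distance counts the nucleotides strictly between the branch adenosine
    and the tract's 5' end: 0 when the tract starts immediately after the
    adenosine, and also 0 when a maximal tract overlaps it (a tract that
    absorbed flanking pyrimidines still supports the branch point).
    Returns ``(sentinel, 0.0)`` when no tract reaches downstream of the BP.
    """
    bp_pos = bp.bp_pos if isinstance(bp, BPCandidate) else int(bp)
    best: Optional[PPTTract] = None
    best_d = None
    for t in tracts:
        if t.end > bp_pos:
            d = max(0, t.start - bp_pos - 1)
            if best is None or (d, t.start) < (best_d, best.start):
                best, best_d = t, d
    if best is None:
        return float(sentinel), 0.0
    return float(best_d), float(best.score)
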