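"""Baseline branch-point predictors and benchmark evaluation.

The consensus baselines rank candidate 9-mers by Hamming distance to the
strict U2-complementary consensus TACTAACAC inside a fixed window upstream
of the 3SS (100 nt and 200 nt in the two published variants), optionally
preferring the hit closest to the 3SS among equal-distance candidates.
The PWM baseline scores candidates with the position-independent log-odds
inside the AGEZ.  Benchmark metrics follow the convention that an intron
with several mapped branch points counts as a hit if any of them is
recovered; sensitivity is TP over the number of introns and PPV is TP over
the number of introns for which the method made a prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .seqio import IntronRecord

U2_CONSENSUS = "TACTAACAC"


@dataclass
class HammingHit:
    """A consensus-method candidate: 9-mer, branch-A position, distance."""

    ninemer: str
    bp_pos: int
    distance: int
    rank: Optional[int] = None


def hamming_rank(
    intron: Union[IntronRecord, str],
    consensus: str = U2_CONSENSUS,
    window: int = 100,
    max_distance: Optional[int] = 2,
    proximal_preference: bool = False,
    min_dist: int = 15,
) -> list[HammingHit]:
    """Rank 9-mers with an A at position 6 by Hamming distance to a consensus.

    Only candidates whose branch adenosine lies within ``window`` nt of the
    3SS (and at least ``min_dist`` nt upstream) are considered; candidates
    farther than ``max_distance`` mismatches are discarded (None disables
    the cutoff).  With ``proximal_preference`` equal-distance hits are
    ranked 3'-most first, emulating methods that select the candidate
    closest to the 3SS.
    """
    if len(consensus) != 9:
        raise ValueError("consensus must be a 9-mer")
    seq = intron.sequence if isinstance(intron, IntronRecord) else str(intron)
    L = len(seq)
    hits = []
    for pos in range(max(-window, -L + 5), -min_dist + 1):
        i = L + pos
        if seq[i] != "A" or i + 4 > L or i < 5:
            continue
        window9 = seq[i - 5 : i + 4]
        if "N" in window9:
            continue
        d = sum(1 for a, b in zip(window9, consensus) if a != b)
        if max_distance is not None and d > max_distance:
            continue
        hits.append(HammingHit(window9, pos, d))
    if proximal_preference:
        hits.sort(key=lambda h: (h.distance, -h.bp_pos))
    else:
        hits.sort(key=lambda h: (h.distance, h.bp_pos))
    for r, h in enumerate(hits, 1):
        h.rank = r
    return hits


@dataclass
class BenchmarkResult:
    """Per-intron hits plus aggregate sensitivity/PPV with standard errors."""

    table: pd.DataFrame
    sensitivity: float
    ppv: float
    sensitivity_se: float
    ppv_se: float
    n_introns: int
    n_predictions: int


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n) if n else float("nan")


def evaluate(
    predictions: Mapping[str, Sequence[int]],
    truth: Mapping[str, Sequence[int]],
    top_k: int = 1,
) -> BenchmarkResult:
    """Score ranked per-intron predictions against mapped branch points.

    ``predictions`` maps intron id to a ranked list of predicted branch-A
    positions (may be empty); an intron is a hit when any mapped position
    appears among its top ``top_k`` predictions.
    """
    unknown = set(predictions) - set(truth)
    if unknown:
        raise ValueError(f"predictions for introns absent from truth: {sorted(unknown)}")
    rows = []
    for iid, true_pos in truth.items():
        pred = list(predictions.get(iid, []))[:top_k]
        hit = any(p in true_pos for p in pred)
        rows.append(
            {
                "intron_id": iid,
                "predicted": pred,
                "truth": list(true_pos),
                "has_prediction": bool(pred),
                "hit": hit,
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    n_pred = int(table["has_prediction"].sum())
    tp = int(table["hit"].sum())
    sens = tp / n if n else float("nan")
    ppv = tp / n_pred if n_pred else float("nan")
    return BenchmarkResult(
        table=table,
        sensitivity=sens,
        ppv=ppv,
        sensitivity_se=_binomial_se(sens, n),
        ppv_se=_binomial_se(ppv, n_pred) if n_pred else float("nan"),
        n_introns=n,
        n_predictions=n_pred,
    )


def est_inclusion(n_incl: int, n_skip: int) -> float:
    """EST inclusion level of an exon, 100 * I / (I + S), in percent."""
    if n_incl < 0 or n_skip < 0:
        raise ValueError("EST counts must be non-negative")
    total = n_incl + n_skip
    if total == 0:
        raise ValueError("no ESTs cover the exon")
    return 100.0 * n_incl / total


def passes_coverage(n_incl: int, n_skip: int, min_total: int = 10) -> bool:
    """Coverage filter applied before inclusion levels enter analyses."""
    return n_incl + n_skip >= min_total
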