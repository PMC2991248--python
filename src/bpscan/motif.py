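"""Statistical models of the branch-point 9-mer signal.

The branch-point motif is described over a 9-nt window with the branch
adenosine at position 6 and a T at position 4 (1-based); those two positions
are invariant in canonical candidates.  Two models are provided:

* a position-specific frequency model (PWM), used for information content,
  logo counts and the PWM log-odds baseline;
* a position-dependent Markov model of order 1 (MM1) over the chain of free
  positions 1->2->3->5->7->8->9.  Because positions 4 and 6 are fixed, the
  positions immediately downstream of them condition on the nearest free
  upstream position (5 on 3, 7 on 5), i.e. second-order dependencies across
  the fixed positions.

Scores are log-odds (log base 2) of a positive against a negative model.
An optional backend computes the duplex free energy of a candidate against
the U2 snRNA branch-point-recognition sequence.
"""

from __future__ import annotations

import json
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

NUCS = "ACGT"
_IDX = {c: i for i, c in enumerate(NUCS)}

#: 1-based motif positions of the MM1 chain (fixed positions 4 and 6 skipped).
DEFAULT_CHAIN: tuple[int, ...] = (1, 2, 3, 5, 7, 8, 9)

MOTIF_LENGTH = 9
FIXED_POSITIONS = {4: "T", 6: "A"}  # 1-based: the TNA signature

_FORMAT = "bpscan-model"
_VERSION = 1


def _check_ninemer(seq: str, canonical: bool = True) -> None:
    if len(seq) != MOTIF_LENGTH:
        raise ValueError(f"{seq!r}: expected a 9-mer")
    if any(c not in _IDX for c in seq):
        raise ValueError(f"{seq!r}: sequence must be over ACGT")
    if canonical:
        for pos, nuc in FIXED_POSITIONS.items():
            if seq[pos - 1] != nuc:
                raise ValueError(
                    f"{seq!r}: non-canonical 9-mer (position {pos} must be {nuc})"
                )


def _encode(seqs: Sequence[str], canonical: bool) -> np.ndarray:
    mat = np.empty((len(seqs), MOTIF_LENGTH), dtype=np.int8)
    for r, s in enumerate(seqs):
        _check_ninemer(s, canonical=canonical)
        for c, ch in enumerate(s):
            mat[r, c] = _IDX[ch]
    return mat


@dataclass
class FrequencyModel:
    """Position-specific nucleotide counts/probabilities over the 9-mer."""

    counts: np.ndarray  # (9, 4) raw counts
    pseudocount: float
    n_seqs: int

    @property
    def probs(self) -> np.ndarray:
        return (self.counts + self.pseudocount) / (
            self.n_seqs + 4.0 * self.pseudocount
        )

    def sample(self, rng: np.random.Generator) -> str:
        p = self.probs
        return "".join(NUCS[rng.choice(4, p=p[i] / p[i].sum())] for i in range(9))

    def to_dict(self) -> dict:
        return {
            "format": _FORMAT,
            "version": _VERSION,
            "type": "frequency",
            "counts": self.counts.tolist(),
            "pseudocount": self.pseudocount,
            "n_seqs": self.n_seqs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencyModel":
        _check_header(d, "frequency")
        return cls(
            counts=np.asarray(d["counts"], dtype=float),
            pseudocount=float(d["pseudocount"]),
            n_seqs=int(d["n_seqs"]),
        )


def _check_header(d: dict, expected_type: str) -> None:
    if d.get("format") != _FORMAT or d.get("version") != _VERSION:
        raise ValueError(
            f"unsupported model file (format={d.get('format')!r}, "
            f"version={d.get('version')!r})"
        )
    if d.get("type") != expected_type:
        raise ValueError(f"expected a {expected_type} model, got {d.get('type')!r}")


def fit_frequency_model(
    seqs: Sequence[str], pseudocount: float = 1.0, canonical: bool = False
) -> FrequencyModel:
    """Tally per-position nucleotide counts with a Laplace pseudocount."""
    if len(seqs) == 0:
        raise ValueError("cannot fit a frequency model on an empty set")
    mat = _encode(seqs, canonical=canonical)
    counts = np.zeros((MOTIF_LENGTH, 4), dtype=float)
    for i in range(MOTIF_LENGTH):
        counts[i] = np.bincount(mat[:, i], minlength=4)
    return FrequencyModel(counts=counts, pseudocount=pseudocount, n_seqs=len(seqs))


def information_content(model: FrequencyModel) -> tuple[np.ndarray, float]:
    """Per-position and total information content in bits.

    IC_i = 2 + sum_n p_{n,i} log2 p_{n,i} (with 0 log 0 := 0); a uniform
    column carries 0 bits, an invariant column 2 bits.
    """
    p = model.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    per_pos = 2.0 + plogp.sum(axis=1)
    return per_pos, float(per_pos.sum())


def mutual_information(
    seqs: Sequence[str], fixed: Sequence[int] = (4, 6)
) -> np.ndarray:
    """Mutual information (bits) between all 9-mer position pairs.

    Plug-in estimate from joint nucleotide frequencies.  Pairs involving the
    invariant positions (1-based ``fixed``) are reported as NaN, matching
    the blank cells of the motif's dependency map.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for mutual information")
    mat = _encode(seqs, canonical=False)
    n = len(seqs)
    mi = np.zeros((MOTIF_LENGTH, MOTIF_LENGTH))
    for i in range(MOTIF_LENGTH):
        for j in range(i, MOTIF_LENGTH):
            joint = np.zeros((4, 4))
            for r in range(n):
                joint[mat[r, i], mat[r, j]] += 1
            joint /= n
            pi = joint.sum(axis=1)
            pj = joint.sum(axis=0)
            outer = np.outer(pi, pj)
            mask = joint > 0
            val = float(np.sum(joint[mask] * np.log2(joint[mask] / outer[mask])))
            mi[i, j] = mi[j, i] = val
    fixed0 = [p - 1 for p in fixed]
    mi[fixed0, :] = np.nan
    mi[:, fixed0] = np.nan
    return mi


@dataclass
class MM1Model:
    """Position-dependent order-1 Markov model over the free 9-mer positions.

    ``initial`` is the distribution of the first chain position; for every
    subsequent chain position ``transitions[pos]`` is a (4, 4) matrix of
    P(nucleotide at pos | nucleotide at the previous chain position).
    """

    chain: tuple[int, ...]
    initial: np.ndarray  # (4,)
    transitions: dict[int, np.ndarray]  # 1-based position -> (4, 4) [from, to]
    pseudocount: float
    n_seqs: int

    def log2_prob(self, ninemer: str) -> float:
        _check_ninemer(ninemer, canonical=True)
        idx = [_IDX[c] for c in ninemer]
        first = self.chain[0]
        logp = np.log2(self.initial[idx[first - 1]])
        prev = first
        for pos in self.chain[1:]:
            logp += np.log2(self.transitions[pos][idx[prev - 1], idx[pos - 1]])
            prev = pos
        return float(logp)

    def prob(self, ninemer: str) -> float:
        return float(2.0 ** self.log2_prob(ninemer))

    def sample(self, rng: np.random.Generator) -> str:
        out = {pos: nuc for pos, nuc in FIXED_POSITIONS.items()}
        first = self.chain[0]
        p = self.initial / self.initial.sum()
        out[first] = NUCS[rng.choice(4, p=p)]
        prev = first
        for pos in self.chain[1:]:
            row = self.transitions[pos][_IDX[out[prev]]]
            out[pos] = NUCS[rng.choice(4, p=row / row.sum())]
            prev = pos
        return "".join(out[i] for i in range(1, MOTIF_LENGTH + 1))

    def to_dict(self) -> dict:
        return {
            "format": _FORMAT,
            "version": _VERSION,
            "type": "mm1",
            "chain": list(self.chain),
            "initial": self.initial.tolist(),
            "transitions": {str(k): v.tolist() for k, v in self.transitions.items()},
            "pseudocount": self.pseudocount,
            "n_seqs": self.n_seqs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MM1Model":
        _check_header(d, "mm1")
        return cls(
            chain=tuple(d["chain"]),
            initial=np.asarray(d["initial"], dtype=float),
            transitions={
                int(k): np.asarray(v, dtype=float)
                for k, v in d["transitions"].items()
            },
            pseudocount=float(d["pseudocount"]),
            n_seqs=int(d["n_seqs"]),
        )


def fit_mm1(
    seqs: Sequence[str],
    pseudocount: float = 1.0,
    chain: tuple[int, ...] = DEFAULT_CHAIN,
) -> MM1Model:
    """Estimate MM1 initial and transition probabilities with pseudocounts.

    Every training 9-mer must be canonical (T at position 4, A at 6).
    Alternative ``chain`` orderings over the free positions are accepted for
    sensitivity analyses.
    """
    if len(seqs) == 0:
        raise ValueError("cannot fit an MM1 model on an empty set")
    free = sorted(set(range(1, MOTIF_LENGTH + 1)) - set(FIXED_POSITIONS))
    if sorted(chain) != free:
        raise ValueError(f"chain must cover the free positions {free}, got {chain}")
    mat = _encode(seqs, canonical=True)
    n = len(seqs)
    first = chain[0]
    init_counts = np.bincount(mat[:, first - 1], minlength=4).astype(float)
    initial = (init_counts + pseudocount) / (n + 4.0 * pseudocount)
    transitions = {}
    prev = first
    for pos in chain[1:]:
        counts = np.zeros((4, 4), dtype=float)
        for r in range(n):
            counts[mat[r, prev - 1], mat[r, pos - 1]] += 1
        row_tot = counts.sum(axis=1, keepdims=True)
        denom = row_tot + 4.0 * pseudocount
        trans = np.where(denom > 0, (counts + pseudocount) / np.where(denom > 0, denom, 1.0), 0.25)
        transitions[pos] = trans
        prev = pos
    return MM1Model(
        chain=tuple(chain),
        initial=initial,
        transitions=transitions,
        pseudocount=pseudocount,
        n_seqs=n,
    )


def mm1_score(pos: MM1Model, neg: MM1Model, ninemer: str) -> float:
    """Log2-odds of the 9-mer under the positive vs the negative MM1."""
    return pos.log2_prob(ninemer) - neg.log2_prob(ninemer)


def pwm_score(pos: FrequencyModel, neg: FrequencyModel, ninemer: str) -> float:
    """Position-independent log2-odds over the 7 free positions.

    The fixed positions 4 and 6 are omitted (for canonical candidates they
    carry the same letter under both models), which makes the PWM score the
    exact independence limit of the MM1 score.
    """
    _check_ninemer(ninemer, canonical=True)
    pp, pn = pos.probs, neg.probs
    score = 0.0
    for posn in range(1, MOTIF_LENGTH + 1):
        if posn in FIXED_POSITIONS:
            continue
        k = _IDX[ninemer[posn - 1]]
        score += float(np.log2(pp[posn - 1, k]) - np.log2(pn[posn - 1, k]))
    return score


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    if d.get("type") == "mm1":
        return MM1Model.from_dict(d)
    return FrequencyModel.from_dict(d)


# ---------------------------------------------------------------------------
# U2 duplex energy (optional backend)
# ---------------------------------------------------------------------------

#: Reverse complement (as RNA) of the U2-pairing branch-point consensus
#: TACTAACAC; the branch adenosine bulges out of the duplex.
U2_RECOGNITION_RNA = "GUGUUAGUA"

#: Hard constraint applied to the candidate strand: every nucleotide must
#: pair except the branch adenosine (position 6), which is forced unpaired.
#: The U2 strand is left unconstrained.
U2_CONSTRAINT = "|||||x|||" + "&" + "." * len(U2_RECOGNITION_RNA)


class FeatureUnavailableError(RuntimeError):
    """Raised when an optional backend is requested but not configured."""


class RNAcofoldBackend:
    """Duplex free energy via the ViennaRNA ``RNAcofold`` executable."""

    def __init__(
        self,
        u2: str = U2_RECOGNITION_RNA,
        executable: str = "RNAcofold",
    ):
        self.u2 = u2
        self.executable = executable

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def energy(self, ninemer: str) -> float:
        _check_ninemer(ninemer, canonical=True)
        rna = ninemer.replace("T", "U")
        payload = f"{rna}&{self.u2}\n{U2_CONSTRAINT}\n"
        proc = subprocess.run(
            [self.executable, "--noPS", "-C"],
            input=payload,
            capture_output=True,
            text=True,
            check=True,
        )
        for line in reversed(proc.stdout.strip().splitlines()):
            m = re.search(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$", line)
            if m:
                return float(m.group(1))
        raise RuntimeError(f"could not parse RNAcofold output:\n{proc.stdout}")


def u2_duplex_energy(ninemer: str, backend=None) -> float:
    """Constrained duplex free energy (kcal/mol) of a candidate against U2.

    Lower (more negative) energies mean a more stable branch-site/U2 helix.
    Raises :class:`FeatureUnavailableError` if no backend is configured or
    the configured backend is not available; there is no silent fallback.
    """
    if backend is None or not backend.available():
        raise FeatureUnavailableError(
            "U2 duplex energy requires an RNA-folding backend "
            "(e.g. RNAcofoldBackend with ViennaRNA installed)"
        )
    return backend.energy(ninemer)


def cluster_energies(
    ninemers: Iterable[str], backend=None
) -> dict[str, float]:
    """Mean duplex energy per central-pentamer cluster of 9-mers."""
    groups: dict[str, list[float]] = {}
    for nm in ninemers:
        groups.setdefault(nm[2:7], []).append(u2_duplex_energy(nm, backend))
    return {k: float(np.mean(v)) for k, v in groups.items()}
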