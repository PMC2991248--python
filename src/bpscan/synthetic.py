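"""Synthetic introns and alignment blocks with known branch-point truth.

The generator emulates the 3'-end architecture of a mammalian intron:

* a planted canonical branch-point 9-mer whose adenosine position is drawn
  from a peaked distribution centred 24 nt upstream of the 3SS and
  restricted to the canonical -55..-15 window;
* a downstream polypyrimidine tract (pure C/T, T-rich) a few nucleotides
  3' of the planted 9-mer;
* a controlled AG exclusion zone: an AG dinucleotide is planted just
  upstream of the zone and all AGs inside it (beyond the grace region) are
  scrubbed, while the sequence upstream of the defining AG and within the
  grace region keeps its natural AG content;
* uniform background nucleotide composition typical of 3' intron ends
  elsewhere.

The default planted 9-mer model is an order-1 Markov model whose marginals
follow the degenerate YTNAY-style consensus (pyrimidine-rich positions 3
and 7, a central position depleted of T) and whose transitions favour
keeping the purine/pyrimidine class of the previous position, so that
adjacent positions carry genuine first-order dependencies.

Alignment blocks add 6 further species by per-site substitution (and
optional deletion) of the human sequence, with the planted 9-mer copied
intact at a configurable per-species rate, mimicking the elevated
conservation of functional branch points.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .motif import MM1Model, FrequencyModel, DEFAULT_CHAIN, NUCS, _IDX
from .seqio import IntronRecord
from .trainset import ALIGN_LENGTH, AlignmentBlock, DEFAULT_SPECIES

_NUC_ARR = np.array(list(NUCS))


def default_bp_model(class_boost: float = 3.0) -> MM1Model:
    """The default planted branch-point 9-mer model.

    Marginal frequencies follow the degenerate YTNAY-style consensus;
    transitions multiply the target marginal by ``class_boost`` when the
    nucleotide keeps the purine/pyrimidine class of its predecessor,
    creating the adjacent-position dependencies seen in real signals.
    """
    marg = {
        1: (0.24, 0.24, 0.16, 0.36),
        2: (0.12, 0.28, 0.08, 0.52),
        3: (0.05, 0.26, 0.07, 0.62),
        5: (0.38, 0.30, 0.27, 0.05),
        7: (0.08, 0.28, 0.06, 0.58),
        8: (0.16, 0.26, 0.10, 0.48),
        9: (0.22, 0.26, 0.16, 0.36),
    }
    is_pyr = np.array([0, 1, 0, 1], dtype=bool)  # A C G T
    initial = np.asarray(marg[1], dtype=float)
    transitions = {}
    prev = DEFAULT_CHAIN[0]
    for pos in DEFAULT_CHAIN[1:]:
        m = np.asarray(marg[pos], dtype=float)
        t = np.empty((4, 4))
        for a in range(4):
            row = m * np.where(is_pyr == is_pyr[a], class_boost, 1.0)
            t[a] = row / row.sum()
        transitions[pos] = t
        prev = pos
    return MM1Model(
        chain=DEFAULT_CHAIN,
        initial=initial,
        transitions=transitions,
        pseudocount=0.0,
        n_seqs=0,
    )


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic intron/alignment generator."""

    seed: int
    n_introns: int = 5000
    # intron length: lognormal, clipped
    length_log_mean: float = 6.55  # median ~700 nt
    length_log_sigma: float = 0.35
    min_length: int = 300
    max_length: int = 1500
    # background composition (A, C, G, T) of 3' intron ends
    background: tuple = (0.27, 0.21, 0.21, 0.31)
    # planted branch point position: rounded normal truncated to a window
    bp_center: float = -24.0
    bp_sd: float = 5.0
    bp_min: int = -55
    bp_max: int = -15
    bp_model: Optional[Union[MM1Model, FrequencyModel]] = None
    # downstream polypyrimidine tract
    ppt_gap: tuple = (3, 7)  # nt between 9-mer end and tract start
    ppt_length: tuple = (10, 20)
    ppt_t_frac: float = 0.7
    # AGEZ: margin between zone start and the planted 9-mer
    agez_margin: tuple = (5, 20)
    grace: int = 12
    # alignment blocks
    species: tuple = DEFAULT_SPECIES
    conservation_rate: float = 0.9  # per-site per-species identity
    bp_conservation: float = 0.95  # P(planted 9-mer copied intact per species)
    gap_rate: float = 0.0

    def model(self) -> Union[MM1Model, FrequencyModel]:
        return self.bp_model if self.bp_model is not None else default_bp_model()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("bp_model")
        d["bp_model"] = None if self.bp_model is None else self.bp_model.to_dict()
        return json.dumps(d, indent=1)


def _sample_length(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    L = int(round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sigma)))
    return int(np.clip(L, cfg.min_length, cfg.max_length))


def _sample_bp_pos(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    while True:
        v = int(round(rng.normal(cfg.bp_center, cfg.bp_sd)))
        if cfg.bp_min <= v <= cfg.bp_max:
            return v


def _sample_ninemer(cfg: GeneratorConfig, rng: np.random.Generator) -> str:
    model = cfg.model()
    # reject 9-mers containing AG so the planted BP stays inside its AGEZ
    while True:
        nm = model.sample(rng)
        if "AG" not in nm:
            return nm


def generate_intron(
    cfg: GeneratorConfig, rng: np.random.Generator, index: int = 0
) -> tuple[IntronRecord, dict]:
    """One synthetic intron plus its truth record.

    The truth record carries the planted branch position and 9-mer, the
    AGEZ start and the defining AG position.
    """
    L = _sample_length(cfg, rng)
    bp = _sample_bp_pos(cfg, rng)
    if L + bp - 5 - cfg.agez_margin[1] - 2 < 0:
        raise ValueError(f"intron of length {L} cannot hold a BP at {bp}")
    ninemer = _sample_ninemer(cfg, rng)

    arr = rng.choice(4, size=L, p=np.asarray(cfg.background))
    seq = list(_NUC_ARR[arr])

    a_idx = L + bp
    seq[a_idx - 5 : a_idx + 4] = list(ninemer)
    nine_span = range(a_idx - 5, a_idx + 4)

    gap = int(rng.integers(cfg.ppt_gap[0], cfg.ppt_gap[1] + 1))
    # keep the tract long enough to satisfy the PPT rules even for
    # proximal branch points squeezed against the 3SS
    ppt_start = max(a_idx + 4, min(a_idx + 1 + gap, L - 4 - 7))
    ppt_len = int(rng.integers(cfg.ppt_length[0], cfg.ppt_length[1] + 1))
    ppt_end = min(ppt_start + ppt_len - 1, L - 4)
    tract = [
        "T" if rng.random() < cfg.ppt_t_frac else "C"
        for _ in range(ppt_start, ppt_end + 1)
    ]
    # rule 5 guarantee: short tracts must still hold >= 5 T
    need = 5 - tract.count("T")
    if need > 0 and len(tract) < 9:
        for i in [i for i, c in enumerate(tract) if c == "C"][:need]:
            tract[i] = "T"
    seq[ppt_start : ppt_end + 1] = tract

    margin = int(rng.integers(cfg.agez_margin[0], cfg.agez_margin[1] + 1))
    zone_start = bp - 5 - margin  # 3SS position of the first zone nt
    def_idx = L + zone_start - 1  # index of the defining AG's A
    seq[def_idx] = "A"
    seq[def_idx + 1] = "G"

    # scrub AGs inside the zone (beyond the grace region); the planted
    # 9-mer is AG-free, so only background letters are ever mutated
    for q in range(def_idx + 1, L - cfg.grace):
        if seq[q] == "A" and seq[q + 1] == "G":
            if q + 1 in nine_span:
                seq[q] = "CT"[rng.integers(2)]
            else:
                seq[q + 1] = "CT"[rng.integers(2)]

    seq[L - 2 : L] = ["A", "G"]
    record = IntronRecord(
        id=f"syn{index:05d}", sequence="".join(seq), source="synthetic"
    )
    truth = {
        "intron_id": record.id,
        "bp_pos": bp,
        "ninemer": ninemer,
        "agez_start": zone_start,
        "defining_ag": zone_start - 1,
        "length": L,
    }
    return record, truth


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[IntronRecord], pd.DataFrame]:
    """``n_introns`` introns with truth, fully reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed)
    records, truths = [], []
    for i in range(cfg.n_introns):
        rec, truth = generate_intron(cfg, rng, index=i)
        records.append(rec)
        truths.append(truth)
    return records, pd.DataFrame(truths)


def write_dataset(cfg: GeneratorConfig, fasta_path, truth_path, config_path=None):
    from .seqio import write_fasta

    records, truth = generate_dataset(cfg)
    write_fasta(records, fasta_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    if config_path is not None:
        Path(config_path).write_text(cfg.to_json() + "\n")
    return records, truth


def _planted_pentamers(ninemer: str, bp: int) -> list[tuple[str, int]]:
    """The three TNA-containing sub-pentamers of a planted 9-mer with their
    3SS start positions (patterns NNTNA, NTNAN, TNANN)."""
    return [
        (ninemer[1:6], bp - 4),
        (ninemer[2:7], bp - 3),
        (ninemer[3:8], bp - 2),
    ]


def generate_alignment_block(
    cfg: GeneratorConfig, rng: np.random.Generator, index: int = 0
) -> tuple[AlignmentBlock, dict]:
    """A 7-species alignment of the last 300 intron nt plus truth.

    Non-human rows substitute each site independently at rate
    ``1 - conservation_rate`` (and delete at ``gap_rate``); with probability
    ``bp_conservation`` per species the planted 9-mer columns are copied
    intact instead.
    """
    rec, truth = generate_intron(cfg, rng, index=index)
    human = rec.sequence[-ALIGN_LENGTH:]
    n = ALIGN_LENGTH
    harr = np.array([_IDX[c] for c in human], dtype=np.int8)
    a9 = n + truth["bp_pos"] - 5  # planted 9-mer start in the 300-nt frame
    rows = {cfg.species[0]: human}
    for sp in cfg.species[1:]:
        arr = harr.copy()
        mut = rng.random(n) < (1.0 - cfg.conservation_rate)
        shift = rng.integers(1, 4, size=n)
        arr[mut] = (arr[mut] + shift[mut]) % 4
        chars = _NUC_ARR[arr].copy()
        if cfg.gap_rate > 0:
            gaps = rng.random(n) < cfg.gap_rate
            chars[gaps] = "-"
        if rng.random() < cfg.bp_conservation:
            chars[a9 : a9 + 9] = list(truth["ninemer"])
        rows[sp] = "".join(chars)
    block = AlignmentBlock(
        intron_id=truth["intron_id"], species=cfg.species, rows=rows
    )
    truth = dict(truth)
    truth["pentamers"] = _planted_pentamers(truth["ninemer"], truth["bp_pos"])
    return block, truth


def generate_alignment_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[AlignmentBlock], list[dict]]:
    rng = np.random.default_rng(cfg.seed)
    blocks, truths = [], []
    for i in range(cfg.n_introns):
        b, t = generate_alignment_block(cfg, rng, index=i)
        blocks.append(b)
        truths.append(t)
    return blocks, truths


def planted_pentamer_counts(truths: list[dict]) -> dict[str, int]:
    """How often each pentamer was planted across a block dataset."""
    counts: dict[str, int] = {}
    for t in truths:
        for pent, _pos in t["pentamers"]:
            counts[pent] = counts.get(pent, 0) + 1
    return counts
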