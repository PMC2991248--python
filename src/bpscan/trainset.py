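"""Conservation-based construction of the branch-point positive set.

Starting from per-intron multi-species alignments of the last 300 intronic
nucleotides (human first), the pipeline

1. records all pentamer instances exactly conserved across the species
   (:func:`conserved_instances`),
2. classifies each TNA-containing pentamer by the positional bias of its
   conserved instances into branch-point-associated, PPT-associated or
   unassociated (:func:`classify_pentamer`),
3. collects introns with a single conserved TNA in the window 15-55 nt
   upstream of the 3SS and takes the human 9-mer centred on it
   (:func:`build_consTNA`), and
4. keeps only instances overlapped by at least one BP-associated pentamer
   in every species (:func:`filter_bp5`) - the positive training set.

Positions are 3SS-anchored start coordinates in the human sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .agez import tna_pentamer_patterns

#: The 7 mammals used for the conservation screen.
DEFAULT_SPECIES = ("hg", "panTro", "rheMac", "mm", "rn", "canFam", "bosTau")

ALIGN_LENGTH = 300
DEFAULT_WINDOW = (-55, -15)
DEFAULT_SCAN = (-300, -1)


@dataclass
class AlignmentBlock:
    """Aligned last-300-nt intron ends across species (human row first)."""

    intron_id: str
    species: tuple[str, ...]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.intron_id}: rows have unequal gapped lengths")
        if self.species[0] not in self.rows:
            raise ValueError(f"{self.intron_id}: missing human row {self.species[0]!r}")

    @property
    def human(self) -> str:
        return self.rows[self.species[0]]

    @property
    def human_ungapped(self) -> str:
        return self.human.replace("-", "")


@dataclass
class PentamerProfile:
    """Positional profile of one pentamer's instances (all vs conserved)."""

    pentamer: str
    positions_all: list[int] = field(default_factory=list)
    positions_conserved: list[int] = field(default_factory=list)
    label: Optional[str] = None
    ks_p: Optional[float] = None
    enrich_p: Optional[float] = None
    peak: Optional[float] = None


@dataclass(frozen=True)
class ConsTNARecord:
    """One putative branch point: intron, branch-A position, human 9-mer."""

    intron_id: str
    bp_pos: int
    ninemer: str


def _human_columns(block: AlignmentBlock) -> list[int]:
    return [c for c, ch in enumerate(block.human) if ch != "-"]


def conserved_instances(block: AlignmentBlock, k: int = 5) -> dict[str, list[int]]:
    """Exactly conserved k-mer instances, keyed by human k-mer.

    An instance is conserved iff its k human columns are consecutive in the
    alignment (no insertions in any species) and every species carries the
    identical, gap-free k nucleotides.  Positions are 3SS-anchored starts in
    the human ungapped sequence.
    """
    hcols = _human_columns(block)
    n = len(hcols)
    others = [block.rows[s] for s in block.species[1:]]
    human = block.human
    out: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        c0, c1 = hcols[i], hcols[i + k - 1]
        if c1 - c0 != k - 1:
            continue  # insertion columns interleaved
        word = human[c0 : c1 + 1]
        if "N" in word or "-" in word:
            continue
        if all(row[c0 : c1 + 1] == word for row in others):
            out.setdefault(word, []).append(i - n)
    return out


def all_instances(block: AlignmentBlock, k: int = 5) -> dict[str, list[int]]:
    """All k-mer instances in the human ungapped sequence (3SS starts)."""
    seq = block.human_ungapped
    n = len(seq)
    out: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        word = seq[i : i + k]
        if "N" not in word:
            out.setdefault(word, []).append(i - n)
    return out


def classify_pentamer(
    profile: PentamerProfile,
    alpha: float = 0.001,
    window: tuple[int, int] = DEFAULT_WINDOW,
    scan: tuple[int, int] = DEFAULT_SCAN,
    bin_width: int = 5,
    smooth_bins: int = 3,
) -> str:
    """Label a pentamer ``bp``, ``ppt`` or ``none`` from its conserved positions.

    Test 1: Kolmogorov-Smirnov against a uniform distribution over the
    scanned region.  Test 2: one-sided binomial test that the proportion of
    conserved instances inside ``window`` exceeds the window's share of the
    scanned region.  A pentamer failing either test is unassociated
    (``none``); passing both, it is ``bp`` if the smoothed histogram peak
    lies inside the window and ``ppt`` otherwise.  The test statistics and
    label are stored on the profile.
    """
    pos = np.asarray(profile.positions_conserved, dtype=float)
    if pos.size == 0:
        profile.label = "none"
        return "none"
    lo, hi = scan
    span = hi - lo + 1
    ks = stats.kstest(pos, stats.uniform(loc=lo, scale=span).cdf)
    profile.ks_p = float(ks.pvalue)

    k_in = int(np.sum((pos >= window[0]) & (pos <= window[1])))
    p0 = (window[1] - window[0] + 1) / span
    enrich = stats.binomtest(k_in, pos.size, p0, alternative="greater")
    profile.enrich_p = float(enrich.pvalue)

    edges = np.arange(lo, hi + 2, bin_width)
    hist, _ = np.histogram(pos, bins=edges)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        hist = np.convolve(hist, kernel, mode="same")
    peak_bin = int(np.argmax(hist))
    profile.peak = float(edges[peak_bin] + bin_width / 2.0)

    if profile.ks_p >= alpha or profile.enrich_p >= alpha:
        profile.label = "none"
    elif window[0] <= profile.peak <= window[1]:
        profile.label = "bp"
    else:
        profile.label = "ppt"
    return profile.label


def collect_profiles(
    blocks: Iterable[AlignmentBlock],
    pentamers: Optional[Sequence[str]] = None,
    k: int = 5,
) -> dict[str, PentamerProfile]:
    """Aggregate all/conserved instance positions for a pentamer set.

    By default the 184 TNA-containing pentamers are profiled.
    """
    wanted = set(tna_pentamer_patterns() if pentamers is None else pentamers)
    profiles = {p: PentamerProfile(pentamer=p) for p in sorted(wanted)}
    for block in blocks:
        for word, positions in all_instances(block, k).items():
            if word in wanted:
                profiles[word].positions_all.extend(positions)
        for word, positions in conserved_instances(block, k).items():
            if word in wanted:
                profiles[word].positions_conserved.extend(positions)
    return profiles


def classify_all(
    profiles: dict[str, PentamerProfile], alpha: float = 0.001, **kwargs
) -> dict[str, str]:
    return {p: classify_pentamer(prof, alpha=alpha, **kwargs) for p, prof in profiles.items()}


def _is_tna(word: str) -> bool:
    return len(word) == 3 and word[0] == "T" and word[2] == "A"


def build_consTNA(
    blocks: Iterable[AlignmentBlock],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[ConsTNARecord]:
    """Introns with a single conserved TNA, as human 9-mers around it.

    The TNA trinucleotide must be the only one conserved across all species
    in the block, with the branch adenosine inside ``window``; the returned
    9-mer has the TNA at positions 4-6.
    """
    out = []
    for block in blocks:
        cons3 = conserved_instances(block, k=3)
        tna_positions = [
            p for word, ps in cons3.items() if _is_tna(word) for p in ps
        ]
        if len(tna_positions) != 1:
            continue
        start = tna_positions[0]  # 3SS start of the TNA
        a_pos = start + 2
        if not window[0] <= a_pos <= window[1]:
            continue
        seq = block.human_ungapped
        n = len(seq)
        i = n + start  # 0-based TNA start
        if i - 3 < 0 or i + 6 > n:
            continue
        ninemer = seq[i - 3 : i + 6]
        if "N" in ninemer:
            continue
        out.append(ConsTNARecord(block.intron_id, a_pos, ninemer))
    return out


def filter_bp5(
    cons_records: Sequence[ConsTNARecord],
    bp_pentamers: Iterable[str],
    blocks: Iterable[AlignmentBlock],
    overlap: str = "tna",
) -> list[ConsTNARecord]:
    """Keep instances overlapped by a BP-associated pentamer in every species.

    ``overlap`` controls what the pentamer must intersect: the conserved TNA
    trinucleotide (default) or the full 9-mer (``"ninemer"``).  The overlap
    is evaluated on each species' own ungapped sequence, so sequence
    variation is tolerated as long as every species retains some
    BP-associated word across the site.
    """
    if overlap not in ("tna", "ninemer"):
        raise ValueError(f"unknown overlap mode {overlap!r}")
    bp_set = set(bp_pentamers)
    if not bp_set:
        raise ValueError("bp_pentamers must be non-empty")
    by_id = {b.intron_id: b for b in blocks}
    kept = []
    for rec in cons_records:
        block = by_id[rec.intron_id]
        hcols = _human_columns(block)
        n = len(hcols)
        i = n + rec.bp_pos - 2  # human ungapped index of the TNA start
        tna_cols = hcols[i : i + 3]
        ok_all = True
        for sp in block.species:
            row = block.rows[sp]
            sp_seq = row.replace("-", "")
            # species-local index of the TNA start
            sp_i = sum(1 for c in range(tna_cols[0]) if row[c] != "-")
            if overlap == "tna":
                lo, hi = sp_i - 4, sp_i + 2
            else:
                lo, hi = sp_i - 3 - 4, sp_i - 3 + 8
            found = False
            for s in range(max(0, lo), min(len(sp_seq) - 5, hi) + 1):
                if sp_seq[s : s + 5] in bp_set:
                    found = True
                    break
            if not found:
                ok_all = False
                break
        if ok_all:
            kept.append(rec)
    return kept
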