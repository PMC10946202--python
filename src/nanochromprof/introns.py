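"""Intron size spectrum, splice-site motif and branch-point profiling.

Ciliate introns are tiny (tens of bp) with a narrow, often bimodal size
distribution.  Because nearly all introns of the modal size class share
one exact length, positional base frequencies can be computed by stacking
those introns without alignment, indexing positions from the 3' end
(-1 = last nucleotide).  A position in the second half of the intron whose
A frequency exceeds 50% is called as a putative branch-point adenosine;
the 3' acceptor dinucleotide positions (-1, -2) are excluded from calling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from nanochromprof.genome_io import Contig, GeneModel, gene_introns

BASES = "ACGT"


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    index: int  # 0-based position within the gene, transcript order
    seq: str  # strand-oriented, 5' splice site first

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def donor2(self) -> str:
        return self.seq[:2]

    @property
    def acceptor2(self) -> str:
        return self.seq[-2:]


def extract_introns(
    genes: Sequence[GeneModel], contigs: Sequence[Contig] | Mapping[str, Contig]
) -> list[IntronRecord]:
    """Strand-oriented intron records for all multi-exon genes."""
    if not isinstance(contigs, Mapping):
        contigs = {c.id: c for c in contigs}
    out = []
    for g in genes:
        for i, seq in enumerate(gene_introns(g, contigs[g.contig_id])):
            out.append(IntronRecord(g.gene_id, i, seq))
    return out


@dataclass
class IntronSpectrum:
    histogram: Counter
    fraction_in_range: float
    size_range: tuple[int, int]
    peaks: list[int]  # strict local maxima, descending count order
    n_introns: int


def _lengths(introns: Iterable[IntronRecord | int]) -> list[int]:
    return [i if isinstance(i, int) else i.length for i in introns]


def intron_spectrum(
    introns: Sequence[IntronRecord | int], size_range: tuple[int, int] = (28, 40)
) -> IntronSpectrum:
    """Integer-length histogram, mass inside ``size_range`` and modal peaks.

    Peaks are lengths within ``size_range`` whose count strictly exceeds
    both neighbouring bins of the dense integer histogram; a plateau of
    equal counts flanked by strictly smaller neighbours is reported once,
    at its smallest length.  Peaks are listed in descending count order.
    """
    lengths = _lengths(introns)
    if not lengths:
        raise ValueError("no introns")
    hist = Counter(lengths)
    lo, hi = min(hist), max(hist)
    dense = np.zeros(hi - lo + 3, dtype=int)  # zero-padded on both sides
    for length, n in hist.items():
        dense[length - lo + 1] = n
    peaks = []
    i = 1
    while i <= hi - lo + 1:
        j = i
        while j + 1 <= hi - lo + 1 and dense[j + 1] == dense[i]:
            j += 1
        if dense[i] > dense[i - 1] and dense[i] > dense[j + 1] and dense[i] > 0:
            length = i + lo - 1
            if size_range[0] <= length <= size_range[1]:
                peaks.append(length)
        i = j + 1
    peaks.sort(key=lambda p: (-hist[p], p))
    in_range = sum(n for length, n in hist.items() if size_range[0] <= length <= size_range[1])
    return IntronSpectrum(
        histogram=hist,
        fraction_in_range=in_range / len(lengths),
        size_range=size_range,
        peaks=peaks,
        n_introns=len(lengths),
    )


@dataclass
class SpliceMotif:
    donor_counts: Counter
    acceptor_counts: Counter
    gt_ag_fraction: float
    n_introns: int


def splice_motif(introns: Sequence[IntronRecord]) -> SpliceMotif:
    """Donor/acceptor dinucleotide usage and the canonical GT-AG fraction."""
    if not introns:
        raise ValueError("no introns")
    donors = Counter(i.donor2 for i in introns)
    acceptors = Counter(i.acceptor2 for i in introns)
    canonical = sum(1 for i in introns if i.donor2 == "GT" and i.acceptor2 == "AG")
    return SpliceMotif(donors, acceptors, canonical / len(introns), len(introns))


@dataclass
class BranchPointProfile:
    """Base frequencies of stacked same-length introns, 3'-anchored.

    ``freq`` is indexed by positions -L..-1 with columns A/C/G/T summing
    to 1 per row; ``called_positions`` are second-half positions (excluding
    the acceptor -1/-2) where freq(A) > ``threshold``.
    """

    modal_length: int
    n_introns: int
    freq: pd.DataFrame
    called_positions: list[int]
    threshold: float = 0.5

    @property
    def a_frequency(self) -> pd.Series:
        return self.freq["A"]


def positional_profile(
    introns: Sequence[IntronRecord],
    length_class: int | None = None,
    min_introns: int = 50,
    threshold: float = 0.5,
    window: int = 0,
) -> BranchPointProfile | None:
    """Stack introns of one exact length and call conserved-A positions.

    ``length_class`` defaults to the most abundant intron length (ties:
    smallest).  With fewer than ``min_introns`` members the profile is
    withheld (None): below ~50 sequences a 50% frequency threshold is
    dominated by sampling noise.  ``window`` widens the class to lengths
    within +/-window bp, stacked right-anchored (aligned at the 3' end);
    positions missing from shorter members are averaged over the introns
    that reach them.
    """
    if not introns:
        return None
    if length_class is None:
        hist = Counter(i.length for i in introns)
        length_class = min(hist, key=lambda L: (-hist[L], L))
    members = [
        i.seq for i in introns if abs(i.length - length_class) <= window
    ]
    if len(members) < min_introns:
        return None
    L = max(len(s) for s in members)
    counts = np.zeros((L, 4), dtype=float)
    totals = np.zeros(L, dtype=float)
    base_idx = {b: j for j, b in enumerate(BASES)}
    for s in members:
        for k, ch in enumerate(reversed(s)):  # k: 0 = position -1
            if ch in base_idx:
                counts[L - 1 - k, base_idx[ch]] += 1
                totals[L - 1 - k] += 1
    positions = list(range(-L, 0))
    with np.errstate(invalid="ignore"):
        freq = pd.DataFrame(
            counts / totals[:, None], index=positions, columns=list(BASES)
        )
    L = length_class
    second_half = [p for p in range(-(L // 2), -2)]
    called = [p for p in second_half if freq.loc[p, "A"] > threshold]
    return BranchPointProfile(
        modal_length=L,
        n_introns=len(members),
        freq=freq,
        called_positions=called,
        threshold=threshold,
    )


def branch_point_compare(
    intron_sets: Mapping[str, Sequence[IntronRecord]],
    min_introns: int = 50,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-genome branch-point summary table.

    One row per input genome: modal intron length, called branch-point
    positions ('none' when nothing is called, missing when the intron set
    is empty or too small to profile), and median intron length.
    """
    rows = []
    for label, introns in intron_sets.items():
        lengths = [i.length for i in introns]
        if not lengths:
            rows.append(
                {
                    "species": label,
                    "n_introns": 0,
                    "modal_length": pd.NA,
                    "median_length": pd.NA,
                    "branch_points": pd.NA,
                }
            )
            continue
        profile = positional_profile(introns, min_introns=min_introns, threshold=threshold)
        hist = Counter(lengths)
        modal = min(hist, key=lambda L: (-hist[L], L))
        if profile is None:
            bp = pd.NA
        elif not profile.called_positions:
            bp = "none"
        else:
            bp = ",".join(str(p) for p in profile.called_positions)
        rows.append(
            {
                "species": label,
                "n_introns": len(lengths),
                "modal_length": modal,
                "median_length": float(np.median(lengths)),
                "branch_points": bp,
            }
        )
    return pd.DataFrame(rows)
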