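"""Per-contig and per-genome descriptive statistics.

Covers assembly metrics (N50, GC), gene architecture (gene/CDS lengths,
exon counts, genes per chromosome), the chromosome-length vs feature
Spearman correlation table, and the decomposition of contig GC into CDS
and non-CDS compartments.  Genes-per-chromosome and the correlation table
are computed on complete (2-telomere) chromosomes only, since those are
the only contigs whose full extent is known; a flag widens them to the
whole assembly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nanochromprof.genome_io import Contig, GeneModel
from nanochromprof.telomere import (
    AssemblyClassification,
    SubtelomereRecord,
    round_half_up,
    subtelomere_lengths,
)

#: per-contig features correlated against chromosome length
CORRELATION_FEATURES = [
    "n_genes",
    "gene_bp",
    "subtel5",
    "subtel3",
    "intergenic_bp",
    "gc",
    "telomere_bp",
    "cds_bp",
    "intron_bp",
]


def gc_content(seq: str) -> float:
    """GC fraction over A/C/G/T bases; N is excluded from both numerator
    and denominator; an empty or all-N sequence is missing (NaN)."""
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    if denom == 0:
        return math.nan
    return gc / denom


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L cover half the assembly."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length set")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, half))
    return int(arr[idx])


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of the rank vectors,
    with average ranks for ties (exactly +/-1 on monotone data)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors, n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(abs(rho) - 1.0) < 1e-14:  # perfect monotone up to fp rounding
        rho = math.copysign(1.0, rho)
    return rho


@dataclass
class GenesPerChromosome:
    counts: Counter
    percentages: dict[str, float]  # keys "1","2","3+" -> percent, 1 decimal
    n_chromosomes: int


def genes_per_chromosome(gene_counts: Sequence[int]) -> GenesPerChromosome:
    """Distribution of gene number over complete chromosomes.

    ``gene_counts`` is the per-contig gene count of 2-telomere contigs;
    contigs with no annotated gene are excluded.
    """
    counts = Counter(int(c) for c in gene_counts if c >= 1)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no complete chromosome carries a gene")
    buckets = {
        "1": counts.get(1, 0),
        "2": counts.get(2, 0),
        "3+": sum(v for k, v in counts.items() if k >= 3),
    }
    pct = {k: round_half_up(100.0 * v / n, 1) for k, v in buckets.items()}
    return GenesPerChromosome(counts=counts, percentages=pct, n_chromosomes=n)


def multi_exon_ratio(n_multi: int, n_total: int) -> float:
    """Share of genes with >= 2 exons, rounded half-up to 2 decimals."""
    if n_total == 0:
        raise ValueError("no genes")
    return round_half_up(n_multi / n_total, 2)


@dataclass
class ExonCountStats:
    histogram: Counter
    single_exon_fraction: float
    multi_exon_ratio: float  # rounded to 2 decimals
    n_genes: int


def exon_count_stats(genes: Iterable[GeneModel]) -> ExonCountStats:
    hist = Counter(g.exon_count for g in genes)
    n = sum(hist.values())
    if n == 0:
        raise ValueError("no genes")
    n_multi = sum(v for k, v in hist.items() if k >= 2)
    return ExonCountStats(
        histogram=hist,
        single_exon_fraction=hist.get(1, 0) / n,
        multi_exon_ratio=multi_exon_ratio(n_multi, n),
        n_genes=n,
    )


def _interval_union_bp(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last = -1
    for s, e in sorted(intervals):
        s = max(s, last)
        if e > s:
            total += e - s
            last = e
    return total


@dataclass
class GCDecomposition:
    contig_id: str
    gc_cds: float
    gc_noncds: float
    covered_fraction: float
    gc_overall: float


def gc_decomposition(contig: Contig, genes: Sequence[GeneModel]) -> GCDecomposition:
    """Split a contig's GC into CDS-covered and uncovered compartments.

    The overall GC equals the (non-N base count)-weighted mean of the two
    compartment GCs by construction.
    """
    mask = np.zeros(contig.length, dtype=bool)
    for g in genes:
        if g.contig_id != contig.id:
            continue
        for s, e in g.cds:
            mask[s:e] = True
    arr = np.frombuffer(contig.seq.encode(), dtype="S1")
    cds_seq = arr[mask].tobytes().decode()
    non_seq = arr[~mask].tobytes().decode()
    return GCDecomposition(
        contig_id=contig.id,
        gc_cds=gc_content(cds_seq),
        gc_noncds=gc_content(non_seq),
        covered_fraction=float(mask.mean()) if contig.length else math.nan,
        gc_overall=gc_content(contig.seq),
    )


@dataclass
class GenomeProfile:
    """The full per-genome summary used for reports and comparison."""

    label: str
    assembly_size: int
    n_contigs: int
    n50: int
    gc_overall: float
    per_contig: pd.DataFrame
    gene_lengths: np.ndarray
    cds_lengths: np.ndarray
    genes_per_chrom: GenesPerChromosome | None
    exon_stats: ExonCountStats | None
    telomere_counts: dict[int, int]
    telomere_percentages: dict[int, float]
    mean_telomere_length: float | None

    @property
    def single_gene_fraction(self) -> float | None:
        if self.genes_per_chrom is None:
            return None
        gpc = self.genes_per_chrom
        return gpc.counts.get(1, 0) / gpc.n_chromosomes

    def to_dict(self) -> dict:
        """JSON-ready summary; percentages at 1 decimal, ratios at 2."""
        d = {
            "label": self.label,
            "assembly_size": self.assembly_size,
            "n_contigs": self.n_contigs,
            "n50": self.n50,
            "gc_overall": round_half_up(self.gc_overall, 4),
            "telomere_counts": {str(k): v for k, v in self.telomere_counts.items()},
            "telomere_percentages": {
                str(k): v for k, v in self.telomere_percentages.items()
            },
            "mean_telomere_length": (
                round_half_up(self.mean_telomere_length, 1)
                if self.mean_telomere_length is not None
                else None
            ),
            "mean_gene_length": (
                round_half_up(float(np.mean(self.gene_lengths)), 1)
                if self.gene_lengths.size
                else None
            ),
            "mean_cds_length": (
                round_half_up(float(np.mean(self.cds_lengths)), 1)
                if self.cds_lengths.size
                else None
            ),
        }
        if self.genes_per_chrom is not None:
            d["genes_per_chromosome_pct"] = self.genes_per_chrom.percentages
            d["single_gene_fraction"] = round_half_up(self.single_gene_fraction, 3)
        if self.exon_stats is not None:
            d["single_exon_fraction"] = round_half_up(
                self.exon_stats.single_exon_fraction, 3
            )
            d["multi_exon_ratio"] = self.exon_stats.multi_exon_ratio
        return d


def build_profile(
    contigs: Sequence[Contig],
    genes: Sequence[GeneModel],
    classification: AssemblyClassification,
    label: str = "genome",
) -> GenomeProfile:
    """Assemble the per-genome profile from contigs, gene models and the
    telomere classification."""
    if not contigs:
        raise ValueError("empty assembly")
    by_contig = classification.by_contig()
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)

    rows = []
    for c in contigs:
        cc = by_contig[c.id]
        gs = genes_by_contig.get(c.id, [])
        tel_bp = sum(call.tract_length for call in cc.calls)
        sub5 = sub3 = None
        if gs and cc.tel_class >= 1:
            rec = subtelomere_lengths(c, cc, gs)
            sub5, sub3 = rec.len5, rec.len3
        gene_bp = sum(g.span for g in gs)
        cds_bp = sum(g.cds_bp for g in gs)
        intron_bp = sum(g.span - g.exon_bp for g in gs)
        # intergenic: inside the gene-bearing region, between consecutive genes
        inter = 0
        if len(gs) > 1:
            ordered = sorted(gs, key=lambda g: g.start)
            inter = sum(
                max(0, b.start - a.end) for a, b in zip(ordered, ordered[1:])
            )
        rows.append(
            {
                "contig_id": c.id,
                "length": c.length,
                "gc": gc_content(c.seq),
                "n_genes": len(gs),
                "tel_class": cc.tel_class,
                "telomere_bp": tel_bp,
                "subtel5": sub5,
                "subtel3": sub3,
                "gene_bp": gene_bp,
                "cds_bp": cds_bp,
                "intron_bp": intron_bp,
                "intergenic_bp": inter,
            }
        )
    per_contig = pd.DataFrame(rows)

    whole = "".join(c.seq for c in contigs)
    two_tel = per_contig[per_contig.tel_class == 2]
    gpc = None
    with_genes = two_tel[two_tel.n_genes >= 1]
    if len(with_genes):
        gpc = genes_per_chromosome(with_genes.n_genes.tolist())
    exon_stats = exon_count_stats(genes) if genes else None

    return GenomeProfile(
        label=label,
        assembly_size=sum(c.length for c in contigs),
        n_contigs=len(contigs),
        n50=n50([c.length for c in contigs]),
        gc_overall=gc_content(whole),
        per_contig=per_contig,
        gene_lengths=np.array([g.span for g in genes], dtype=int),
        cds_lengths=np.array([g.cds_bp for g in genes if g.cds], dtype=int),
        genes_per_chrom=gpc,
        exon_stats=exon_stats,
        telomere_counts=classification.counts,
        telomere_percentages=classification.percentages,
        mean_telomere_length=classification.mean_telomere_length,
    )


def feature_correlations(
    profile: GenomeProfile, complete_only: bool = True
) -> pd.DataFrame:
    """Spearman correlations of chromosome length against per-contig
    features, over 2-telomere contigs (default) or the whole assembly.

    Features with fewer than 3 observed values yield a missing rho.
    """
    tab = profile.per_contig
    if complete_only:
        tab = tab[tab.tel_class == 2]
    rows = []
    for feat in CORRELATION_FEATURES:
        col = pd.to_numeric(tab[feat], errors="coerce")
        ok = col.notna() & tab.length.notna()
        n = int(ok.sum())
        if n < 3 or col[ok].nunique() < 2:
            rho = math.nan
        else:
            rho = spearman(tab.length[ok].to_numpy(), col[ok].to_numpy())
        rows.append({"feature": feat, "rho": rho, "n": n})
    return pd.DataFrame(rows)
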