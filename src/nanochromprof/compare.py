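"""Multi-genome comparison of nanochromosome profiles.

Builds the per-species table of chromosome/gene length, GC, single-gene
chromosome fraction, exon-count make-up and subtelomere asymmetry.  The
5'-vs-3' subtelomere comparison uses a two-sided Mann-Whitney U test on
the per-contig length populations (exact null distribution when the
smaller sample has <= 20 values and no ties are present, otherwise the
tie-corrected normal approximation); direction is assigned by the medians
when p < 0.05.  The six-or-so tests across species are reported as raw
p-values without multiplicity correction.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from nanochromprof.chromstats import GenomeProfile
from nanochromprof.telomere import round_half_up

DIRECTION_5 = "5'>3'"
DIRECTION_3 = "3'>5'"
DIRECTION_NONE = "none"


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; returns (U of x, p).

    Exact distribution when min(n) <= ``exact_max_n`` and there are no
    ties; tie-corrected normal approximation with continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def subtelomere_asymmetry(
    len5: Sequence[float], len3: Sequence[float], alpha: float = 0.05
) -> dict:
    """Compare 5' and 3' subtelomere length populations of one genome."""
    len5 = np.asarray([v for v in len5 if v is not None and not math.isnan(v)])
    len3 = np.asarray([v for v in len3 if v is not None and not math.isnan(v)])
    if len5.size == 0 or len3.size == 0:
        return {
            "median5": math.nan,
            "median3": math.nan,
            "p_value": math.nan,
            "direction": DIRECTION_NONE,
        }
    _, p = mann_whitney_u(len5, len3)
    m5 = float(np.median(len5))
    m3 = float(np.median(len3))
    if p < alpha and m5 != m3:
        direction = DIRECTION_5 if m5 > m3 else DIRECTION_3
    else:
        direction = DIRECTION_NONE
    return {"median5": m5, "median3": m3, "p_value": p, "direction": direction}


def compare_profiles(profiles: Sequence[GenomeProfile], alpha: float = 0.05) -> pd.DataFrame:
    """One row per genome with the cross-species comparison panels.

    Row order follows the input order; results are invariant to contig
    order within a genome.  Genomes lacking 2-telomere contigs get missing
    chromosome-restricted fields.
    """
    if len(profiles) < 2:
        raise ValueError("comparison needs at least two genomes")
    rows = []
    for prof in profiles:
        tab = prof.per_contig
        two = tab[tab.tel_class == 2]
        row: dict = {"species": prof.label, "n_contigs": prof.n_contigs,
                     "n_chromosomes": int(len(two))}
        if len(two):
            row["mean_chrom_length"] = float(two.length.mean())
            row["median_chrom_length"] = float(two.length.median())
            row["mean_gc"] = float(two.gc.mean())
            row["median_gc"] = float(two.gc.median())
        else:
            row["mean_chrom_length"] = row["median_chrom_length"] = math.nan
            row["mean_gc"] = row["median_gc"] = math.nan
        row["mean_gene_length"] = (
            float(prof.gene_lengths.mean()) if prof.gene_lengths.size else math.nan
        )
        sgf = prof.single_gene_fraction
        row["single_gene_fraction"] = sgf if sgf is not None else math.nan
        if prof.exon_stats is not None:
            hist = prof.exon_stats.histogram
            n = prof.exon_stats.n_genes
            row["exon1_fraction"] = hist.get(1, 0) / n
            row["exon2_fraction"] = hist.get(2, 0) / n
            row["exon3plus_fraction"] = sum(v for k, v in hist.items() if k >= 3) / n
            row["multi_exon_ratio"] = prof.exon_stats.multi_exon_ratio
        else:
            row["exon1_fraction"] = row["exon2_fraction"] = math.nan
            row["exon3plus_fraction"] = row["multi_exon_ratio"] = math.nan
        asym = subtelomere_asymmetry(
            pd.to_numeric(two.subtel5, errors="coerce").dropna().to_numpy()
            if len(two)
            else [],
            pd.to_numeric(two.subtel3, errors="coerce").dropna().to_numpy()
            if len(two)
            else [],
            alpha=alpha,
        )
        row["subtel5_median"] = asym["median5"]
        row["subtel3_median"] = asym["median3"]
        row["subtel_p_value"] = asym["p_value"]
        row["subtel_direction"] = asym["direction"]
        rows.append(row)
    return pd.DataFrame(rows)


def single_gene_fraction_table(profiles: Sequence[GenomeProfile]) -> pd.Series:
    """Fraction of complete chromosomes bearing exactly one gene, per species."""
    vals = {}
    for prof in profiles:
        sgf = prof.single_gene_fraction
        vals[prof.label] = math.nan if sgf is None else sgf
    return pd.Series(vals, name="single_gene_fraction")


def mean_percent(fractions: Sequence[float]) -> float:
    """Average of fractions expressed as a percentage at 1 decimal."""
    return round_half_up(100.0 * float(np.mean(fractions)), 1)
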