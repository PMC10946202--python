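"""Stop-codon usage and genetic-code reassignment detection.

Hypotrich ciliates use a variant nuclear code in which UAA and UAG encode
glutamine and only UGA terminates translation.  Under the standard code,
TAA/TAG/TGA essentially never occur in-frame inside a CDS; under the
reassigned code, TAA/TAG appear at ordinary sense-codon frequencies.  The
detector therefore compares, per codon, its in-frame internal rate (per kb
of CDS) with its share of gene-terminal codons, which separates the two
regimes by orders of magnitude at even modest gene counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from nanochromprof.genome_io import Contig, GeneModel, spliced_cds

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class StopCodonUsage:
    terminal_counts: dict[str, int]
    internal_counts: dict[str, int]
    internal_rate_per_kb: dict[str, float]
    terminal_share: dict[str, float]
    n_genes: int
    cds_bp: int
    n_skipped: int = 0


@dataclass(frozen=True)
class CodeParams:
    """Thresholds separating sense-reassigned codons from true stops.

    A codon read as sense appears internally at tens of occurrences per kb
    while a true stop stays near zero, so 1/kb with a near-zero band of
    0.05/kb splits the regimes with a wide margin; min_genes guards the
    call against small-sample noise.
    """

    min_internal_rate: float = 1.0  # per kb CDS, to call sense
    near_zero_rate: float = 0.05  # per kb CDS, to call stop
    max_terminal_share: float = 0.1
    min_stop_terminal_share: float = 0.1
    min_genes: int = 50


def stop_usage(
    genes: Sequence[GeneModel], contigs: Sequence[Contig] | Mapping[str, Contig]
) -> StopCodonUsage:
    """Count terminal and in-frame internal TAA/TAG/TGA over all CDSs.

    Genes without CDS rows, or whose CDS length is not divisible by 3, are
    skipped (logged).  Codons containing N are ignored.
    """
    if not isinstance(contigs, Mapping):
        contigs = {c.id: c for c in contigs}
    terminal = {c: 0 for c in STOP_CODONS}
    internal = {c: 0 for c in STOP_CODONS}
    n_genes = 0
    cds_bp = 0
    skipped = 0
    for g in genes:
        if not g.cds:
            continue
        seq = spliced_cds(g, contigs[g.contig_id])
        if len(seq) % 3 != 0:
            logger.warning("gene %s: CDS length %d not divisible by 3; skipped", g.gene_id, len(seq))
            skipped += 1
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        n_genes += 1
        cds_bp += len(seq)
        for codon in codons[:-1]:
            if codon in internal:
                internal[codon] += 1
        if codons and codons[-1] in terminal:
            terminal[codons[-1]] += 1
    kb = cds_bp / 1000.0
    term_total = sum(terminal.values())
    return StopCodonUsage(
        terminal_counts=terminal,
        internal_counts=internal,
        internal_rate_per_kb={
            c: (internal[c] / kb if kb > 0 else 0.0) for c in STOP_CODONS
        },
        terminal_share={
            c: (terminal[c] / term_total if term_total else 0.0) for c in STOP_CODONS
        },
        n_genes=n_genes,
        cds_bp=cds_bp,
        n_skipped=skipped,
    )


def infer_reassignment(
    usage: StopCodonUsage, params: CodeParams = CodeParams()
) -> dict[str, str]:
    """Call each of TAA/TAG/TGA as 'Q', 'stop' or 'ambiguous'.

    A codon is sense (labelled Q, the hypotrich reassignment target) when
    its internal rate is high and it rarely terminates genes; a stop when
    its internal rate is near zero and it terminates a meaningful share of
    genes.  With fewer than ``min_genes`` CDS genes everything is
    ambiguous.
    """
    out: dict[str, str] = {}
    if usage.n_genes < params.min_genes:
        return {c: "ambiguous" for c in STOP_CODONS}
    for c in STOP_CODONS:
        rate = usage.internal_rate_per_kb[c]
        share = usage.terminal_share[c]
        if rate >= params.min_internal_rate and share < params.max_terminal_share:
            out[c] = "Q"
        elif rate < params.near_zero_rate and share >= params.min_stop_terminal_share:
            out[c] = "stop"
        else:
            out[c] = "ambiguous"
    return out
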