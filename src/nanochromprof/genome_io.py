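"""Reading, writing and slicing of assemblies and gene annotations.

All internal coordinates are 0-based half-open ``[start, end)``; GFF3 is
read and written in its native 1-based inclusive convention.  Each gene is
reduced to one primary transcript (the mRNA with the longest summed CDS;
ties broken by lexicographically smallest transcript id), because all
downstream statistics are per-gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Malformed input that cannot be repaired by dropping a record."""


@dataclass(frozen=True)
class Contig:
    """One assembled sequence (a putative nanochromosome or fragment)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene reduced to its primary transcript.

    ``exons`` and ``cds`` are sorted, non-overlapping 0-based half-open
    intervals in genomic order regardless of strand.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    transcript_id: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def exon_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_bp(self) -> int:
        return sum(e - s for s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic-order gaps between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


def _clean_seq(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise GenomeIOError(
            f"record {rec_id!r}: invalid characters {sorted(bad)} (allowed: A,C,G,T,N,U)"
        )
    return seq


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a multi-FASTA assembly.

    Sequences are uppercased and U is mapped to T; any other character
    outside {A,C,G,T,N} is a hard error, as are duplicate ids and empty
    records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeIOError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = _clean_seq(str(rec.seq), rec.id)
        if not seq:
            raise GenomeIOError(f"empty FASTA record {rec.id!r}")
        contigs.append(Contig(id=rec.id, seq=seq))
    if not contigs:
        raise GenomeIOError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _validate_model(
    model: GeneModel, contig_len: int | None
) -> str | None:
    """Return a reason code if the model violates an invariant, else None."""
    if model.strand not in {"+", "-"}:
        return "bad_strand"
    if not model.exons:
        return "no_exons"
    for ivs in (model.exons, model.cds):
        for s, e in ivs:
            if e <= s:
                return "empty_interval"
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                return "overlapping_intervals"
    if contig_len is not None and (model.start < 0 or model.end > contig_len):
        return "outside_contig"
    # every CDS interval must lie inside the exon union
    for cs, ce in model.cds:
        if not any(es <= cs and ce <= ee for es, ee in model.exons):
            return "cds_outside_exons"
    return None


def read_gff3(
    path: str | Path,
    contigs: Sequence[Contig] | None = None,
    return_dropped: bool = False,
):
    """Read gene models from GFF3 (gene -> mRNA -> exon/CDS Parent chains).

    Coordinates are converted to 0-based half-open.  Models violating the
    structural invariants are dropped and logged with a reason code.  When
    a gene has several mRNAs, the one with the longest summed CDS is kept
    (tie: lexicographically smallest transcript id).

    Returns the accepted models; with ``return_dropped=True`` also a list
    of ``(gene_id, reason_code)`` pairs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contig_lens = {c.id: c.length for c in contigs} if contigs is not None else None

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=True,
    )

    models: list[GeneModel] = []
    dropped: list[tuple[str, str]] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = gene.id
        if contig_lens is not None and gene.seqid not in contig_lens:
            dropped.append((gid, "unknown_contig"))
            logger.warning("gene %s dropped: unknown_contig (%s)", gid, gene.seqid)
            continue
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            dropped.append((gid, "no_mrna"))
            logger.warning("gene %s dropped: no_mrna", gid)
            continue

        def _cds_total(m) -> int:
            return sum(c.end - c.start + 1 for c in db.children(m, featuretype="CDS"))

        primary = sorted(mrnas, key=lambda m: (-_cds_total(m), m.id))[0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(primary, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end) for f in db.children(primary, featuretype="CDS")
        )
        model = GeneModel(
            gene_id=gid,
            contig_id=gene.seqid,
            strand=primary.strand,
            exons=exons,
            cds=cds,
            transcript_id=primary.id,
        )
        reason = _validate_model(
            model, contig_lens.get(gene.seqid) if contig_lens else None
        )
        if reason is not None:
            dropped.append((gid, reason))
            logger.warning("gene %s dropped: %s", gid, reason)
            continue
        models.append(model)
    if return_dropped:
        return models, dropped
    return models


def _cds_phases(cds: Sequence[tuple[int, int]], strand: str) -> list[int]:
    order = list(cds) if strand == "+" else list(cds)[::-1]
    phases_t: list[int] = []
    acc = 0
    for s, e in order:
        phases_t.append((3 - acc % 3) % 3)
        acc += e - s
    return phases_t if strand == "+" else phases_t[::-1]


def write_gff3(models: Iterable[GeneModel], path: str | Path, source: str = "nanochromprof") -> None:
    """Write gene models as GFF3 (1-based inclusive, gene/mRNA/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            tid = m.transcript_id or f"{m.gene_id}.t1"
            row = "{}\t{}\t{}\t{}\t{}\t.\t{}\t{}\t{}\n"
            fh.write(
                row.format(m.contig_id, source, "gene", m.start + 1, m.end, m.strand,
                           ".", f"ID={m.gene_id}")
            )
            fh.write(
                row.format(m.contig_id, source, "mRNA", m.start + 1, m.end, m.strand,
                           ".", f"ID={tid};Parent={m.gene_id}")
            )
            for s, e in m.exons:
                fh.write(
                    row.format(m.contig_id, source, "exon", s + 1, e, m.strand,
                               ".", f"Parent={tid}")
                )
            phases = _cds_phases(m.cds, m.strand)
            for (s, e), ph in zip(m.cds, phases):
                fh.write(
                    row.format(m.contig_id, source, "CDS", s + 1, e, m.strand,
                               ph, f"Parent={tid}")
                )


def gene_introns(model: GeneModel, contig: Contig) -> list[str]:
    """Strand-oriented intron sequences of a gene, 5' splice site first.

    Introns are the gaps between consecutive exons in genomic order; on the
    minus strand each gap is reverse-complemented and the list is returned
    in transcript (5'->3') order.
    """
    if model.contig_id != contig.id:
        raise ValueError(
            f"gene {model.gene_id} annotated on {model.contig_id}, got contig {contig.id}"
        )
    gaps = model.introns()
    seqs = [contig.seq[s:e] for s, e in gaps]
    if model.strand == "-":
        seqs = [revcomp(s) for s in reversed(seqs)]
    return seqs


def spliced_cds(model: GeneModel, contig: Contig) -> str:
    """Concatenated CDS sequence in reading orientation (5'->3')."""
    parts = [contig.seq[s:e] for s, e in model.cds]
    seq = "".join(parts)
    return revcomp(seq) if model.strand == "-" else seq
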