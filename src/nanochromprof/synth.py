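"""Synthetic MAC nanochromosome genome generator with ground truth.

Emits a FASTA assembly, a GFF3 annotation and per-contig/gene/intron
truth tables with the statistical structure the analyses assume:

* a configurable mixture of 0/1/2-telomere contigs with C4A4/T4G4 repeat
  tracts (geometric number of full units plus a uniform partial unit,
  mean ~21 bp by default);
* 1-3 genes per chromosome separated by subtelomeric and intergenic
  spacers, on random strands, in randomly flipped contig orientation;
* CDSs written under the standard or the ciliate (UAA/UAG = glutamine,
  UGA = stop) genetic code, with in-frame Q codons planted at a known
  rate and a valid terminal stop;
* introns with a bimodal small-size spectrum (peaks at 31 and 34 bp,
  ~72% of mass in 28-40 bp by default), GT-AG termini, and an optional
  over-represented A at a fixed 3'-anchored position.

The seed fully determines the output; every planted feature is recorded
in the truth tables so recovery tests can compare exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
import numpy as np
import pandas as pd

from nanochromprof.genome_io import Contig, GeneModel, revcomp, write_fasta, write_gff3

_BASES = np.array(list("ACGT"))
_CODONS = ["".join(t) for t in product("ACGT", repeat=3)]
_STOP_IDX = np.array(
    [_CODONS.index("TAA"), _CODONS.index("TAG"), _CODONS.index("TGA")]
)


class SynthesisError(ValueError):
    """The requested spec cannot produce a valid genome."""


def _default_intron_pmf() -> dict[int, float]:
    """Bimodal small-intron length distribution.

    72.43% of mass inside 28-40 bp with strict peaks at 31 and 34 bp, a
    small rising shoulder at 20-27 bp and a geometrically decaying tail
    at 41-100 bp.
    """
    core = {
        28: 0.04, 29: 0.06, 30: 0.09, 31: 0.16, 32: 0.08, 33: 0.10,
        34: 0.14, 35: 0.09, 36: 0.07, 37: 0.06, 38: 0.05, 39: 0.03, 40: 0.03,
    }
    pmf = {k: v * 0.7243 for k, v in core.items()}
    short = {k: 0.05 / 8 for k in range(20, 28)}
    r = 0.95
    tail_lengths = list(range(41, 101))
    weights = np.array([r**i for i in range(len(tail_lengths))])
    weights = weights / weights.sum() * (1.0 - 0.7243 - 0.05)
    pmf.update(short)
    pmf.update({k: float(w) for k, w in zip(tail_lengths, weights)})
    return pmf


@dataclass
class SyntheticSpec:
    """All generator knobs; defaults emulate a hypotrich MAC assembly."""

    seed: int = 0
    n_contigs: int = 1000
    class_mix: dict[int, float] = field(
        default_factory=lambda: {0: 0.302, 1: 0.351, 2: 0.347}
    )
    unit5: str = "CCCCAAAA"
    unit3: str = "TTTTGGGG"
    tel_min_units: int = 2
    tel_extra_unit_p: float = 0.8421  # geometric success prob; mean tract ~21 bp
    genes_per_chrom_mix: dict[int, float] = field(
        default_factory=lambda: {1: 0.823, 2: 0.137, 3: 0.040}
    )
    cds_codons_mean: float = 510.0
    cds_codons_shape: float = 3.0
    cds_codons_min: int = 60
    gc_cds: float = 0.30
    gc_background: float = 0.2839
    p_intronless: float = 0.5
    introns_per_gene_p: float = 0.6  # geometric over counts >= 1
    max_introns_per_gene: int = 4
    intron_length_pmf: dict[int, float] = field(default_factory=_default_intron_pmf)
    donor: str = "GT"
    acceptor: str = "AG"
    noncanonical_donor_rate: float = 0.0
    branchpoint_position: int = -5  # 3'-anchored
    branchpoint_enrichment: float = 0.0  # fraction of introns carrying the A
    code: str = "ciliate"  # or "standard"
    q_codon_rate: float = 0.05  # in-frame TAA/TAG rate under the ciliate code
    spacer5_mean: float = 150.0
    spacer5_sd: float = 40.0
    spacer3_mean: float = 100.0
    spacer3_sd: float = 30.0
    intergenic_mean: float = 120.0
    intergenic_sd: float = 40.0
    spacer_min: int = 20
    # contigs are emitted in the chromosome's conventional orientation
    # (5' C4A4 cap on the left); raise this to emulate assemblers that
    # strand contigs arbitrarily
    orientation_flip_prob: float = 0.0
    telomere_error_rate: float = 0.0

    def validate(self) -> None:
        for name, mix in (
            ("class_mix", self.class_mix),
            ("genes_per_chrom_mix", self.genes_per_chrom_mix),
            ("intron_length_pmf", self.intron_length_pmf),
        ):
            vals = np.array(list(mix.values()), dtype=float)
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise SynthesisError(f"{name} must be a probability distribution")
        for name in (
            "tel_extra_unit_p", "gc_cds", "gc_background", "p_intronless",
            "introns_per_gene_p", "noncanonical_donor_rate",
            "branchpoint_enrichment", "q_codon_rate",
            "orientation_flip_prob", "telomere_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthesisError(f"{name} must be in [0,1], got {v}")
        if self.code not in ("standard", "ciliate"):
            raise SynthesisError(f"unknown code {self.code!r}")
        if self.n_contigs < 1:
            raise SynthesisError("n_contigs must be >= 1")
        if self.cds_codons_min * 3 < 9:
            raise SynthesisError("CDS must hold at least three codons")
        if min(self.intron_length_pmf) < 7:
            raise SynthesisError("introns shorter than 7 bp cannot hold GT..A..AG")
        if self.spacer_min < 1:
            raise SynthesisError("spacer_min must be >= 1 so genes never touch telomere tracts")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["intron_length_pmf"] = {str(k): v for k, v in d["intron_length_pmf"].items()}
        d["class_mix"] = {str(k): v for k, v in d["class_mix"].items()}
        d["genes_per_chrom_mix"] = {
            str(k): v for k, v in d["genes_per_chrom_mix"].items()
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground-truth tables consistent with the emitted FASTA/GFF3."""

    contigs: pd.DataFrame
    genes: pd.DataFrame
    introns: pd.DataFrame


@dataclass
class SyntheticGenome:
    contigs: list[Contig]
    genes: list[GeneModel]
    truth: SyntheticTruth
    spec: SyntheticSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "truth_contigs": outdir / "truth_contigs.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "truth_introns": outdir / "truth_introns.tsv",
            "spec": outdir / "spec_resolved.json",
        }
        write_fasta(self.contigs, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        self.truth.contigs.to_csv(paths["truth_contigs"], sep="\t", index=False)
        self.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        self.truth.introns.to_csv(paths["truth_introns"], sep="\t", index=False)
        paths["spec"].write_text(self.spec.to_json())
        return paths


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    idx = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join(_BASES[idx])


def _sense_codons(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Indices into the 64-codon table, excluding TAA/TAG/TGA."""
    p = _base_probs(gc)
    idx = rng.choice(4, size=(n, 3), p=p)
    codes = idx[:, 0] * 16 + idx[:, 1] * 4 + idx[:, 2]
    bad = np.isin(codes, _STOP_IDX)
    while bad.any():
        redraw = rng.choice(4, size=(int(bad.sum()), 3), p=p)
        codes[bad] = redraw[:, 0] * 16 + redraw[:, 1] * 4 + redraw[:, 2]
        bad = np.isin(codes, _STOP_IDX)
    return codes


def _make_cds(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[str, int, str]:
    """One spliced CDS: (sequence, planted Q count, terminal stop codon)."""
    n_body = max(
        spec.cds_codons_min,
        int(round(rng.gamma(spec.cds_codons_shape,
                            spec.cds_codons_mean / spec.cds_codons_shape))),
    )
    codes = _sense_codons(rng, n_body, spec.gc_cds)
    n_q = 0
    if spec.code == "ciliate" and spec.q_codon_rate > 0:
        mask = rng.random(n_body) < spec.q_codon_rate
        n_q = int(mask.sum())
        if n_q:
            q_choices = rng.choice(
                [_CODONS.index("TAA"), _CODONS.index("TAG")], size=n_q
            )
            codes[mask] = q_choices
    if spec.code == "ciliate":
        stop = "TGA"
    else:
        stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    seq = "".join(_CODONS[c] for c in codes) + stop
    return seq, n_q, stop


def _make_intron(
    rng: np.random.Generator, spec: SyntheticSpec, length: int
) -> tuple[str, bool]:
    donor = spec.donor
    if spec.noncanonical_donor_rate > 0 and rng.random() < spec.noncanonical_donor_rate:
        donor = "GC"
    middle = list(_random_dna(rng, length - len(donor) - len(spec.acceptor),
                              spec.gc_background))
    carrier = False
    pos = length + spec.branchpoint_position  # index from intron 5' end
    mid_idx = pos - len(donor)
    if 0 <= mid_idx < len(middle):
        carrier = bool(rng.random() < spec.branchpoint_enrichment)
        if carrier:
            middle[mid_idx] = "A"
    return donor + "".join(middle) + spec.acceptor, carrier


def _telomere_tract(
    rng: np.random.Generator, spec: SyntheticSpec, unit: str, end: str
) -> str:
    """A tract of ``tel_min_units`` + Geom extra full units plus a uniform
    partial unit; the partial sits at the tract's inner (gene-side) edge."""
    k = spec.tel_min_units + int(rng.geometric(spec.tel_extra_unit_p)) - 1
    partial = int(rng.integers(0, len(unit)))
    if end == "five_prime":
        return unit * k + unit[:partial]
    return unit[len(unit) - partial :] + unit * k


def _spacer_len(rng: np.random.Generator, mean: float, sd: float, floor: int) -> int:
    return max(floor, int(round(rng.normal(mean, sd))))


def generate(spec: SyntheticSpec) -> SyntheticGenome:
    """Generate a synthetic assembly, annotation and truth tables.

    Deterministic under ``spec.seed``; two calls with equal specs produce
    byte-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    class_vals = np.array(sorted(spec.class_mix))
    class_p = np.array([spec.class_mix[v] for v in class_vals], dtype=float)
    gpc_vals = np.array(sorted(spec.genes_per_chrom_mix))
    gpc_p = np.array([spec.genes_per_chrom_mix[v] for v in gpc_vals], dtype=float)
    il_vals = np.array(sorted(spec.intron_length_pmf))
    il_p = np.array([spec.intron_length_pmf[v] for v in il_vals], dtype=float)
    il_p = il_p / il_p.sum()

    contigs: list[Contig] = []
    genes: list[GeneModel] = []
    t_contigs, t_genes, t_introns = [], [], []

    for ci in range(spec.n_contigs):
        contig_id = f"ctg{ci:05d}"
        tel_class = int(rng.choice(class_vals, p=class_p))
        if tel_class == 2:
            has5 = has3 = True
        elif tel_class == 1:
            has5 = bool(rng.random() < 0.5)
            has3 = not has5
        else:
            has5 = has3 = False
        n_genes = int(rng.choice(gpc_vals, p=gpc_p))

        parts: list[str] = []
        offset = 0
        tel5_len = tel3_len = 0
        if has5:
            tract = _telomere_tract(rng, spec, spec.unit5, "five_prime")
            tel5_len = len(tract)
            parts.append(tract)
            offset += tel5_len
        spacer5 = _spacer_len(rng, spec.spacer5_mean, spec.spacer5_sd, spec.spacer_min)
        parts.append(_random_dna(rng, spacer5, spec.gc_background))
        offset += spacer5

        gene_infos = []
        for gi in range(n_genes):
            gene_id = f"g{ci:05d}_{gi}"
            cds_seq, n_q, stop = _make_cds(rng, spec)
            C = len(cds_seq)
            if rng.random() < spec.p_intronless:
                n_introns = 0
            else:
                n_introns = min(
                    spec.max_introns_per_gene, int(rng.geometric(spec.introns_per_gene_p))
                )
            n_introns = min(n_introns, C - 1)
            cuts = (
                sorted(rng.choice(np.arange(1, C), size=n_introns, replace=False))
                if n_introns
                else []
            )
            intron_seqs, carriers = [], []
            for _ in range(n_introns):
                length = int(rng.choice(il_vals, p=il_p))
                iseq, carrier = _make_intron(rng, spec, length)
                intron_seqs.append(iseq)
                carriers.append(carrier)
            # assemble gene block and relative exon intervals
            block_parts, exon_rel = [], []
            prev = 0
            pos = 0
            for cut, iseq in zip(cuts, intron_seqs):
                block_parts.append(cds_seq[prev:cut])
                exon_rel.append((pos, pos + (cut - prev)))
                pos += cut - prev
                block_parts.append(iseq)
                pos += len(iseq)
                prev = cut
            block_parts.append(cds_seq[prev:])
            exon_rel.append((pos, pos + (C - prev)))
            block = "".join(block_parts)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                block = revcomp(block)
                glen = len(block)
                exon_rel = sorted((glen - e, glen - s) for s, e in exon_rel)
            exons_abs = [(offset + s, offset + e) for s, e in exon_rel]
            gene_infos.append(
                {
                    "gene_id": gene_id,
                    "strand": strand,
                    "exons": exons_abs,
                    "n_q": n_q,
                    "stop": stop,
                    "cds_len": C,
                    "intron_lengths": [len(s) for s in intron_seqs],
                    "carriers": carriers,
                }
            )
            parts.append(block)
            offset += len(block)
            if gi < n_genes - 1:
                inter = _spacer_len(
                    rng, spec.intergenic_mean, spec.intergenic_sd, spec.spacer_min
                )
                parts.append(_random_dna(rng, inter, spec.gc_background))
                offset += inter

        spacer3 = _spacer_len(rng, spec.spacer3_mean, spec.spacer3_sd, spec.spacer_min)
        parts.append(_random_dna(rng, spacer3, spec.gc_background))
        offset += spacer3
        if has3:
            tract = _telomere_tract(rng, spec, spec.unit3, "three_prime")
            tel3_len = len(tract)
            parts.append(tract)
            offset += tel3_len

        seq = "".join(parts)
        L = len(seq)
        # Break the repeat period for two bases just past each tract's
        # inner edge, so the planted tract is exactly the maximal periodic
        # run in the emitted sequence and a substitution-tolerant scanner
        # cannot walk past the true edge.
        fixes: list[tuple[int, str]] = []
        if has5:
            u5 = spec.unit5
            for d in (0, 1):
                cont = u5[(tel5_len + d) % len(u5)]
                if seq[tel5_len + d] == cont:
                    fixes.append((tel5_len + d, cont))
        if has3:
            u3 = spec.unit3
            partial3 = tel3_len % len(u3)
            for d in (1, 2):
                pred = u3[(len(u3) - partial3 - d) % len(u3)]
                p_idx = L - tel3_len - d
                if seq[p_idx] == pred:
                    fixes.append((p_idx, pred))
        if fixes:
            chars = list(seq)
            for p_idx, banned in fixes:
                chars[p_idx] = str(rng.choice([b for b in "ACGT" if b != banned]))
            seq = "".join(chars)
        if spec.telomere_error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            for lo, hi in ((0, tel5_len), (L - tel3_len, L)):
                if hi <= lo:
                    continue
                for p in range(lo, hi):
                    if rng.random() < spec.telomere_error_rate:
                        cur = arr[p].decode()
                        others = [b for b in "ACGT" if b != cur]
                        arr[p] = rng.choice(others).encode()
            seq = arr.tobytes().decode()

        flipped = bool(rng.random() < spec.orientation_flip_prob)
        if flipped:
            seq = revcomp(seq)
            tel5_len, tel3_len = tel3_len, tel5_len
            spacer5, spacer3 = spacer3, spacer5
            has5, has3 = has3, has5
            for info in gene_infos:
                info["strand"] = "+" if info["strand"] == "-" else "-"
                info["exons"] = sorted((L - e, L - s) for s, e in info["exons"])
            gene_infos = gene_infos[::-1]

        contigs.append(Contig(id=contig_id, seq=seq))
        t_contigs.append(
            {
                "contig_id": contig_id,
                "length": L,
                "tel_class": tel_class,
                "tel5_len": tel5_len if has5 else 0,
                "tel3_len": tel3_len if has3 else 0,
                "has_tel5": has5,
                "has_tel3": has3,
                "spacer5": spacer5,
                "spacer3": spacer3,
                "orientation": "-" if flipped else "+",
                "n_genes": n_genes,
            }
        )
        for info in gene_infos:
            model = GeneModel(
                gene_id=info["gene_id"],
                contig_id=contig_id,
                strand=info["strand"],
                exons=info["exons"],
                cds=list(info["exons"]),
                transcript_id=info["gene_id"] + ".t1",
            )
            genes.append(model)
            t_genes.append(
                {
                    "gene_id": info["gene_id"],
                    "contig_id": contig_id,
                    "strand": info["strand"],
                    "n_exons": len(info["exons"]),
                    "cds_len": info["cds_len"],
                    "gene_span": model.span,
                    "n_planted_q": info["n_q"],
                    "terminal_stop": info["stop"],
                }
            )
            for k, (ilen, carrier) in enumerate(
                zip(info["intron_lengths"], info["carriers"])
            ):
                t_introns.append(
                    {
                        "gene_id": info["gene_id"],
                        "intron_index": k,
                        "length": ilen,
                        "branchpoint_carrier": carrier,
                    }
                )

    truth = SyntheticTruth(
        contigs=pd.DataFrame(t_contigs),
        genes=pd.DataFrame(t_genes),
        introns=pd.DataFrame(
            t_introns,
            columns=["gene_id", "intron_index", "length", "branchpoint_carrier"],
        ),
    )
    return SyntheticGenome(contigs=contigs, genes=genes, truth=truth, spec=spec)


def sample_intron_set(spec: SyntheticSpec, n: int, seed: int | None = None):
    """Draw ``n`` intron records from the spec's intron model alone.

    Convenience for calibration studies (branch-point detection power and
    false-call rates) that do not need whole chromosomes around the
    introns.  Uses ``spec.seed`` unless ``seed`` is given.
    """
    from nanochromprof.introns import IntronRecord

    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    il_vals = np.array(sorted(spec.intron_length_pmf))
    il_p = np.array([spec.intron_length_pmf[v] for v in il_vals], dtype=float)
    il_p = il_p / il_p.sum()
    records = []
    carriers = []
    for i in range(n):
        length = int(rng.choice(il_vals, p=il_p))
        seq, carrier = _make_intron(rng, spec, length)
        records.append(IntronRecord(gene_id=f"sim{i}", index=0, seq=seq))
        carriers.append(carrier)
    return records, carriers


def corrupt(
    contigs: list[Contig],
    error_rate: float,
    seed: int,
) -> tuple[list[Contig], pd.DataFrame]:
    """Apply i.i.d. per-base substitutions (never the identity base).

    Returns the mutated contigs and a log of substituted positions; truth
    tables of the source genome are deliberately left untouched.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    out: list[Contig] = []
    logs = []
    others = {b: [o for o in "ACGT" if o != b] for b in "ACGTN"}
    for c in contigs:
        if error_rate == 0.0:
            out.append(c)
            continue
        arr = list(c.seq)
        hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for p in hits:
            old = arr[p]
            new = str(rng.choice(others[old]))
            arr[p] = new
            logs.append({"contig_id": c.id, "pos": int(p), "old": old, "new": new})
        out.append(Contig(id=c.id, seq="".join(arr)))
    return out, pd.DataFrame(logs, columns=["contig_id", "pos", "old", "new"])
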