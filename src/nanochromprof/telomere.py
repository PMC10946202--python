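"""Telomeric repeat detection and contig classification.

Spirotrich MAC telomeres are tandem arrays of an 8-mer unit (C4A4 on the
5' strand, T4G4 on the 3' strand), ~21 bp on average, so only two or three
unit copies cap each chromosome end.  The scanner finds the maximal tandem
run of the unit whose outermost edge lies within ``max_offset`` of the
contig end.  The repeat phase is free (assembly breakpoints do not respect
it), partial units extend a tract when ``allow_partial``, and up to
``max_mismatches`` isolated substitutions inside a tract are tolerated —
each substituted base is accepted only when followed by a clean full unit,
so error-free tracts are never over-extended into flanking sequence.

A contig's class (0/1/2) is the number of ends carrying a call; both
orientations are scanned and the one yielding more total repeat units is
kept (ties keep the input orientation), with calls always reported in
input-orientation coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from nanochromprof.genome_io import Contig, GeneModel, VALID_BASES, revcomp

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class TelomereParams:
    """Scanner configuration.

    min_units=2 reproduces "repeated" units while rejecting single chance
    octamers; max_offset=5 bp allows a few junk bases beyond the cap;
    max_mismatches=2 absorbs isolated base-call/assembly errors.
    """

    unit5: str = "CCCCAAAA"
    unit3: str = "TTTTGGGG"
    min_units: int = 2
    max_offset: int = 5
    allow_partial: bool = True
    max_mismatches: int = 2


@dataclass(frozen=True)
class TelomereCall:
    contig_id: str
    end: str  # five_prime | three_prime
    tract_start: int
    tract_end: int
    unit: str
    n_full_units: int
    offset_from_end: int

    @property
    def tract_length(self) -> int:
        return self.tract_end - self.tract_start


@dataclass
class ContigClass:
    contig_id: str
    tel_class: int
    orientation: str  # '+' input orientation kept, '-' reverse complement
    call5: TelomereCall | None
    call3: TelomereCall | None

    @property
    def calls(self) -> list[TelomereCall]:
        return [c for c in (self.call5, self.call3) if c is not None]


@dataclass
class AssemblyClassification:
    per_contig: list[ContigClass]
    counts: dict[int, int]
    percentages: dict[int, float]
    mean_telomere_length: float | None
    mean_two_telomere_length: float | None

    def by_contig(self) -> dict[str, ContigClass]:
        return {c.contig_id: c for c in self.per_contig}


@dataclass
class SubtelomereRecord:
    """Distance from the inner telomere edge to the nearest gene boundary.

    A side without a telomere is ``None`` (missing, not zero); a gene
    overlapping the tract clamps the length to 0 and sets the flag.
    """

    contig_id: str
    len5: int | None
    len3: int | None
    clamped5: bool = False
    clamped3: bool = False


def _check_unit(unit: str) -> None:
    if not unit or set(unit) - (VALID_BASES - {"N"}):
        raise ValueError(f"telomere unit must be non-empty DNA over A/C/G/T, got {unit!r}")


def _periodic_run(seq: str, unit: str, start: int, phase: int, max_mismatches: int) -> int:
    """Length of the run of ``seq[start:]`` matching the periodic extension
    of ``unit`` beginning at rotation ``phase``, tolerating up to
    ``max_mismatches`` isolated substitutions.  A substitution is crossed
    only after at least half a unit has already matched (so a run never
    starts on junk) and only when the next base continues the period (so
    two consecutive period breaks always terminate the run)."""
    L = len(unit)
    anchor = max(1, L // 2)
    n = len(seq)
    i = start
    k = phase
    mm = 0
    end = start
    while i < n:
        if seq[i] == unit[k]:
            i += 1
            k = (k + 1) % L
            end = i
        else:
            if (
                mm >= max_mismatches
                or i - start < anchor
                or i + 1 >= n
                or seq[i + 1] != unit[(k + 1) % L]
            ):
                break
            mm += 1
            i += 1
            k = (k + 1) % L
    return end - start


def _scan_start(seq: str, unit: str, params: TelomereParams) -> tuple[int, int, int] | None:
    """Best tract anchored near position 0: (start, end, n_full_units)."""
    L = len(unit)
    best: tuple[int, int, int] | None = None  # (run, -start, phase) ordering
    best_key = None
    for o in range(min(params.max_offset, len(seq) - 1) + 1):
        for phase in range(L):
            run = _periodic_run(seq, unit, o, phase, params.max_mismatches)
            if run == 0:
                continue
            key = (run, -o)
            if best_key is None or key > best_key:
                best_key = key
                best = (o, o + run, phase)
    if best is None:
        return None
    start, end, phase = best
    if params.allow_partial:
        n_full = (end - start) // L
    else:
        lead = (L - phase) % L
        run = end - start
        if run < lead:
            return None
        n_full = (run - lead) // L
        start = start + lead
        end = start + n_full * L
        if start > params.max_offset:
            return None
    if n_full < params.min_units:
        return None
    return start, end, n_full


def scan_end(
    seq: str,
    unit: str,
    end: str,
    params: TelomereParams = TelomereParams(),
    contig_id: str = "",
) -> TelomereCall | None:
    """Scan one contig end for a tandem telomeric repeat tract.

    Returns the maximal tract whose outermost edge lies within
    ``params.max_offset`` of the contig end, or None if fewer than
    ``params.min_units`` full unit copies are present.
    """
    _check_unit(unit)
    if end not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"end must be {FIVE_PRIME} or {THREE_PRIME}")
    if end == FIVE_PRIME:
        hit = _scan_start(seq, unit, params)
        if hit is None:
            return None
        s, e, n_full = hit
        return TelomereCall(contig_id, end, s, e, unit, n_full, offset_from_end=s)
    # 3' end: scan the reversed sequence with the reversed unit, then mirror
    hit = _scan_start(seq[::-1], unit[::-1], params)
    if hit is None:
        return None
    s, e, n_full = hit
    n = len(seq)
    return TelomereCall(contig_id, end, n - e, n - s, unit, n_full, offset_from_end=s)


def _mirror_call(call: TelomereCall, n: int) -> TelomereCall:
    """Map a call on the reverse complement back to input coordinates."""
    end = THREE_PRIME if call.end == FIVE_PRIME else FIVE_PRIME
    return TelomereCall(
        contig_id=call.contig_id,
        end=end,
        tract_start=n - call.tract_end,
        tract_end=n - call.tract_start,
        unit=revcomp(call.unit),
        n_full_units=call.n_full_units,
        offset_from_end=call.offset_from_end,
    )


def classify_contig(contig: Contig, params: TelomereParams = TelomereParams()) -> ContigClass:
    """Classify a contig by the number of telomere-capped ends (0/1/2).

    Both orientations are scanned; the orientation with more total detected
    repeat units wins (tie keeps the input orientation).  Calls are always
    reported in input-orientation coordinates.
    """

    def _both(seq: str) -> tuple[TelomereCall | None, TelomereCall | None]:
        c5 = scan_end(seq, params.unit5, FIVE_PRIME, params, contig.id)
        c3 = scan_end(seq, params.unit3, THREE_PRIME, params, contig.id)
        return c5, c3

    fwd = _both(contig.seq)
    rev = _both(revcomp(contig.seq))

    def _units(pair) -> int:
        return sum(c.n_full_units for c in pair if c is not None)

    if _units(rev) > _units(fwd):
        n = contig.length
        c5r, c3r = rev
        call5 = _mirror_call(c3r, n) if c3r is not None else None
        call3 = _mirror_call(c5r, n) if c5r is not None else None
        orientation = "-"
    else:
        call5, call3 = fwd
        orientation = "+"
    tel_class = int(call5 is not None) + int(call3 is not None)
    return ContigClass(contig.id, tel_class, orientation, call5, call3)


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def class_percentages(counts: dict[int, int]) -> dict[int, float]:
    """Per-class percentages, rounded half-up to one decimal place."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty assembly")
    out = {}
    for cls in (0, 1, 2):
        frac = Decimal(100) * Decimal(counts.get(cls, 0)) / Decimal(total)
        out[cls] = float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out


def classify_assembly(
    contigs: Sequence[Contig], params: TelomereParams = TelomereParams()
) -> AssemblyClassification:
    """Classify every contig and summarise the telomere-class mixture."""
    if not contigs:
        raise ValueError("empty assembly")
    per = [classify_contig(c, params) for c in contigs]
    counts = {cls: 0 for cls in (0, 1, 2)}
    for p in per:
        counts[p.tel_class] += 1
    lengths = {c.id: c.length for c in contigs}
    tel_lens = [call.tract_length for p in per for call in p.calls]
    two_lens = [lengths[p.contig_id] for p in per if p.tel_class == 2]
    return AssemblyClassification(
        per_contig=per,
        counts=counts,
        percentages=class_percentages(counts),
        mean_telomere_length=(sum(tel_lens) / len(tel_lens)) if tel_lens else None,
        mean_two_telomere_length=(sum(two_lens) / len(two_lens)) if two_lens else None,
    )


def subtelomere_lengths(
    contig: Contig,
    calls: ContigClass | Iterable[TelomereCall],
    genes: Sequence[GeneModel],
) -> SubtelomereRecord:
    """Measure 5'/3' subtelomeric spacer lengths to the nearest gene bound.

    Requires at least one telomere call and one gene on the contig.  Sides
    lacking a telomere are missing (None).  Genes overlapping a tract clamp
    the corresponding length to 0 and set the flag.
    """
    if isinstance(calls, ContigClass):
        call5, call3 = calls.call5, calls.call3
    else:
        call5 = next((c for c in calls if c.end == FIVE_PRIME), None)
        call3 = next((c for c in calls if c.end == THREE_PRIME), None)
    genes_here = [g for g in genes if g.contig_id == contig.id]
    if not genes_here:
        raise ValueError(f"no genes on contig {contig.id}")
    if call5 is None and call3 is None:
        raise ValueError(f"no telomere call on contig {contig.id}")
    gmin = min(g.start for g in genes_here)
    gmax = max(g.end for g in genes_here)
    len5 = len3 = None
    clamped5 = clamped3 = False
    if call5 is not None:
        len5 = gmin - call5.tract_end
        if len5 < 0:
            len5, clamped5 = 0, True
    if call3 is not None:
        len3 = call3.tract_start - gmax
        if len3 < 0:
            len3, clamped3 = 0, True
    return SubtelomereRecord(contig.id, len5, len3, clamped5, clamped3)
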