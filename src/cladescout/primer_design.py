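"""Taxon-specific primer design in the variable ITS region.

Candidates are exhaustively enumerated (all 16-21-mers of the annotated
ITS2 window, both orientations) and filtered by five criteria:

(i)   melting temperature 54-58 degC,
(ii)  GC content 33-62%,
(iii) length 16-21 bases,
(iv)  the 3'-terminal decamer exactly matches fewer than 20 OTUs in the
      whole data set (searched on both strands),
(v)   distance from both flanking conserved rRNA-gene boundaries > 20 bases
      (so unspecific amplification remains detectable by product size).

Specific reverse primers are paired with the 18S universal primers
(NS5a, NS7a); specific forward primers with the 28S universal primers
(TW13, LR5).  All bounds, the Tm method/conditions and the universal
primer sequences are configuration, not hard-coded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import IUPACData
from Bio.SeqUtils import MeltingTemp

from .io_formats import OperonAnnotation, OtuRecord, ValidationError

__all__ = [
    "PrimerCandidate",
    "PrimerPair",
    "CriteriaReport",
    "PrimerConfig",
    "UniversalPrimer",
    "DEFAULT_UNIVERSAL_PRIMERS",
    "Amplicon",
    "reverse_complement",
    "gc_fraction",
    "melting_temperature",
    "three_prime_specificity",
    "evaluate_criteria",
    "design_primers",
    "pair_with_universal",
    "insilico_pcr",
]

_COMPLEMENT = {
    k: v
    for k, v in IUPACData.ambiguous_dna_complement.items()
    if k in "ACGTRYSWKMBDHVN"  # Biopython's table also maps non-IUPAC 'X'
}


def reverse_complement(seq: str) -> str:
    """Reverse complement with full IUPAC ambiguity support (involution)."""
    try:
        return "".join(_COMPLEMENT[base] for base in reversed(seq.upper()))
    except KeyError as exc:
        raise ValidationError(f"reverse_complement: non-IUPAC base {exc}") from None


def gc_fraction(seq: str) -> float:
    """(G+C)/length; rejects ambiguity codes (excluded upstream anyway)."""
    seq = seq.upper()
    if not seq:
        raise ValidationError("gc_fraction: empty sequence")
    if set(seq) - set("ACGT"):
        raise ValidationError(f"gc_fraction: ambiguous bases in {seq!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str,
    method: str = "nearest_neighbor",
    dnac1: float = 250.0,
    dnac2: float = 250.0,
    Na: float = 50.0,
) -> float:
    """Primer melting temperature in degC.

    ``wallace``: the 2(A+T) + 4(G+C) rule.  ``nearest_neighbor``: unified
    nearest-neighbor thermodynamics (SantaLucia 1998 parameter set as
    shipped with Biopython) with the SantaLucia entropy salt correction;
    defaults correspond to 0.5 uM total oligo and 50 mM monovalent salt.
    """
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValidationError(f"melting_temperature: ambiguous bases in {seq!r}")
    if method == "wallace":
        return float(MeltingTemp.Tm_Wallace(seq))
    if method == "nearest_neighbor":
        if len(seq) < 2:
            raise ValidationError("nearest_neighbor Tm needs length >= 2")
        return float(
            MeltingTemp.Tm_NN(
                seq,
                nn_table=MeltingTemp.DNA_NN3,
                dnac1=dnac1,
                dnac2=dnac2,
                Na=Na,
                saltcorr=5,
            )
        )
    raise ValidationError(f"unknown Tm method {method!r}")


@dataclass
class PrimerCandidate:
    """An oriented primer candidate cut from an annotated template.

    ``sequence`` is the oligo 5'->3' as synthesized: for reverse candidates
    it is the reverse complement of the template slice
    ``[template_start, template_end)``.
    """

    target_id: str
    direction: str  # "forward" | "reverse"
    sequence: str
    template_start: int
    template_end: int
    tm: float
    gc_pct: float
    three_prime_hits: int
    flank_distance: int


@dataclass
class CriteriaReport:
    tm_ok: bool
    gc_ok: bool
    length_ok: bool
    specificity_ok: bool
    flank_ok: bool
    tm: float
    gc_pct: float
    length: int
    three_prime_hits: int
    flank_distance: int

    @property
    def overall(self) -> bool:
        return (
            self.tm_ok
            and self.gc_ok
            and self.length_ok
            and self.specificity_ok
            and self.flank_ok
        )


@dataclass(frozen=True)
class UniversalPrimer:
    """A broad-range eukaryote primer annealing in a conserved gene."""

    name: str
    sequence: str
    gene: str  # SSU18S | LSU28S
    orientation: str  # forward: sequence on plus strand; reverse: revcomp on plus


# Editable defaults: classic eukaryote rRNA primers for the same conserved
# sites the taxon-specific primers are meant to pair with.  ITS2/fITS7R/LR0R
# are sequencing primers carried for completeness, never used for pairing.
DEFAULT_UNIVERSAL_PRIMERS: dict[str, UniversalPrimer] = {
    "NS5a": UniversalPrimer("NS5a", "AACTTAAAGGAATTGACGGA", "SSU18S", "forward"),
    "NS7a": UniversalPrimer("NS7a", "GAGGCAATAACAGGTCTGTG", "SSU18S", "forward"),
    "TW13": UniversalPrimer("TW13", "GGTCCGTGTTTCAAGACG", "LSU28S", "reverse"),
    "LR5": UniversalPrimer("LR5", "TCCTGAGGGAAACTTCG", "LSU28S", "reverse"),
    "ITS2seq": UniversalPrimer("ITS2seq", "GCTGCGTTCTTCATCGATGC", "SSU18S", "reverse"),
    "fITS7R": UniversalPrimer("fITS7R", "CAAAGATTCGATGAYTCAC", "ITS2", "forward"),
    "LR0R": UniversalPrimer("LR0R", "ACCCGCTGAACTTAAGC", "LSU28S", "forward"),
}

#: Universal partners per specific-primer direction.
PAIRING = {
    "reverse": ("NS5a", "NS7a"),  # amplify the 18S gene
    "forward": ("TW13", "LR5"),  # amplify the 28S gene
}


@dataclass
class PrimerConfig:
    """Criterion bounds, Tm conditions and universal primer table."""

    tm_min: float = 54.0
    tm_max: float = 58.0
    gc_min: float = 0.33
    gc_max: float = 0.62
    length_min: int = 16
    length_max: int = 21
    max_three_prime_hits: int = 20  # pass iff hits < this
    min_flank_distance: int = 20  # pass iff distance > this
    tm_method: str = "nearest_neighbor"
    dnac1: float = 250.0
    dnac2: float = 250.0
    Na: float = 50.0
    universal_primers: dict[str, UniversalPrimer] = field(
        default_factory=lambda: dict(DEFAULT_UNIVERSAL_PRIMERS)
    )

    def tm(self, seq: str) -> float:
        return melting_temperature(
            seq, self.tm_method, dnac1=self.dnac1, dnac2=self.dnac2, Na=self.Na
        )


@dataclass(frozen=True)
class PrimerPair:
    specific: PrimerCandidate
    universal_name: str
    universal_seq: str
    amplified_gene: str


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def three_prime_specificity(
    candidate: PrimerCandidate | str, otus: Sequence[OtuRecord]
) -> int:
    """Number of OTUs exactly containing the 3'-terminal decamer (either strand)."""
    seq = candidate if isinstance(candidate, str) else candidate.sequence
    if len(seq) < 10:
        raise ValidationError("three_prime_specificity: candidate shorter than 10")
    decamer = seq[-10:].upper()
    rc = reverse_complement(decamer)
    return sum(1 for otu in otus if decamer in otu.sequence or rc in otu.sequence)


def evaluate_criteria(
    candidate: PrimerCandidate,
    otus: Sequence[OtuRecord],
    annotation: OperonAnnotation,
    config: PrimerConfig | None = None,
    variable_region: str = "ITS2",
) -> CriteriaReport:
    """Apply the five primer criteria to one candidate.

    The candidate footprint must lie inside the annotated variable region;
    the flank criterion measures its distance to both boundaries of that
    region (the ends of the flanking conserved genes).
    """
    config = config or PrimerConfig()
    var_start, var_end = annotation.region(variable_region)
    if candidate.template_start < var_start or candidate.template_end > var_end:
        raise ValidationError(
            f"candidate [{candidate.template_start},{candidate.template_end}) "
            f"outside the annotated variable region [{var_start},{var_end})"
        )
    length = len(candidate.sequence)
    tm = config.tm(candidate.sequence)
    gc_pct = 100.0 * gc_fraction(candidate.sequence)
    hits = three_prime_specificity(candidate, otus)
    flank = min(candidate.template_start - var_start, var_end - candidate.template_end)
    report = CriteriaReport(
        tm_ok=config.tm_min <= tm <= config.tm_max,
        gc_ok=100.0 * config.gc_min <= gc_pct <= 100.0 * config.gc_max,
        length_ok=config.length_min <= length <= config.length_max,
        specificity_ok=hits < config.max_three_prime_hits,
        flank_ok=flank > config.min_flank_distance,
        tm=tm,
        gc_pct=gc_pct,
        length=length,
        three_prime_hits=hits,
        flank_distance=flank,
    )
    candidate.tm = tm
    candidate.gc_pct = gc_pct
    candidate.three_prime_hits = hits
    candidate.flank_distance = flank
    return report


def _rank_key(candidate: PrimerCandidate) -> tuple:
    # fewest 3' hits, Tm closest to 56, longer primer, 5'-most position
    return (
        candidate.three_prime_hits,
        abs(candidate.tm - 56.0),
        -len(candidate.sequence),
        candidate.template_start,
    )


def design_primers(
    target_id: str,
    annotation: OperonAnnotation,
    otus: Sequence[OtuRecord],
    config: PrimerConfig | None = None,
    variable_region: str = "ITS2",
    group_member_windows: Sequence[str] | None = None,
) -> tuple[list[PrimerCandidate], list[PrimerCandidate]]:
    """Enumerate, filter and rank candidates in the variable window.

    Returns (forward candidates, reverse candidates), each ranked.  For a
    grouped target, pass the variable-window sequences of all members as
    ``group_member_windows``: a candidate is only reported when its
    template-strand slice occurs verbatim in every member window, so one
    oligo serves the whole group.
    """
    config = config or PrimerConfig()
    var_start, var_end = annotation.region(variable_region)
    window = annotation.sequence[var_start:var_end]
    if len(window) < config.length_min:
        raise ValidationError(
            f"{target_id}: variable window of {len(window)} bases is shorter "
            f"than the minimum primer length {config.length_min}"
        )
    forward: list[PrimerCandidate] = []
    reverse: list[PrimerCandidate] = []
    for length in range(config.length_min, config.length_max + 1):
        for offset in range(0, len(window) - length + 1):
            slice_ = window[offset : offset + length]
            if set(slice_) - set("ACGT"):
                continue  # degenerate 3' decamer breaks exact-match specificity
            if group_member_windows is not None and not all(
                slice_ in member for member in group_member_windows
            ):
                continue
            start = var_start + offset
            for direction, oligo in (
                ("forward", slice_),
                ("reverse", reverse_complement(slice_)),
            ):
                candidate = PrimerCandidate(
                    target_id=target_id,
                    direction=direction,
                    sequence=oligo,
                    template_start=start,
                    template_end=start + length,
                    tm=0.0,
                    gc_pct=0.0,
                    three_prime_hits=0,
                    flank_distance=0,
                )
                report = evaluate_criteria(
                    candidate, otus, annotation, config, variable_region
                )
                if report.overall:
                    (forward if direction == "forward" else reverse).append(candidate)
    forward.sort(key=_rank_key)
    reverse.sort(key=_rank_key)
    return forward, reverse


def pair_with_universal(
    candidate: PrimerCandidate,
    universal_primers: Mapping[str, UniversalPrimer] | None = None,
) -> list[PrimerPair]:
    """Pair a criteria-compliant specific primer with its universal partners.

    Reverse specifics pair with the 18S universals (amplifying SSU18S);
    forward specifics with the 28S universals (amplifying LSU28S).
    """
    if universal_primers is None:
        universal_primers = DEFAULT_UNIVERSAL_PRIMERS
    if candidate.direction not in PAIRING:
        raise ValidationError(f"unknown primer direction {candidate.direction!r}")
    pairs = []
    for name in PAIRING[candidate.direction]:
        if name not in universal_primers:
            raise ValidationError(f"universal primer {name!r} missing from config")
        universal = universal_primers[name]
        expected_gene = "SSU18S" if candidate.direction == "reverse" else "LSU28S"
        if universal.gene != expected_gene:
            raise ValidationError(
                f"{candidate.direction} specific primers pair only with "
                f"{expected_gene} universals; {name} targets {universal.gene}"
            )
        pairs.append(
            PrimerPair(
                specific=candidate,
                universal_name=name,
                universal_seq=universal.sequence,
                amplified_gene=universal.gene,
            )
        )
    return pairs


def _binding_sites(
    template: str, primer: str, strand: str, max_mismatch: int
) -> list[int]:
    """Start positions (plus strand) where the primer binds.

    ``strand`` 'plus': the primer sequence itself matches the template;
    'minus': its reverse complement matches.  Mismatches (up to
    ``max_mismatch``) are never tolerated in the 3'-terminal decamer, which
    maps to the last 10 matched bases for plus-strand binding and the first
    10 for minus-strand binding.
    """
    probe = primer if strand == "plus" else reverse_complement(primer)
    k = len(probe)
    protected = range(k - 10, k) if strand == "plus" else range(0, 10)
    protected = set(p for p in protected if 0 <= p < k)
    sites = []
    for start in range(0, len(template) - k + 1):
        mismatches = 0
        ok = True
        for i in range(k):
            if template[start + i] != probe[i]:
                if i in protected:
                    ok = False
                    break
                mismatches += 1
                if mismatches > max_mismatch:
                    ok = False
                    break
        if ok:
            sites.append(start)
    return sites


def insilico_pcr(
    pair: PrimerPair,
    operon_db: Mapping[str, str] | Iterable[OperonAnnotation],
    max_mismatch: int = 0,
    max_product_length: int = 4000,
) -> list[Amplicon]:
    """Predict amplicons for a primer pair against full-operon templates.

    An amplicon is reported wherever the forward and reverse primers bind
    convergently within ``max_product_length``.  More than one amplicon on
    a template indicates unspecific amplification.
    """
    if not isinstance(operon_db, Mapping):
        operon_db = {ann.template_id: ann.sequence for ann in operon_db}
    if pair.specific.direction == "reverse":
        fwd_seq, rev_seq = pair.universal_seq, pair.specific.sequence
    else:
        fwd_seq, rev_seq = pair.specific.sequence, pair.universal_seq
    amplicons: list[Amplicon] = []
    for template_id, template in operon_db.items():
        fwd_sites = _binding_sites(template, fwd_seq, "plus", max_mismatch)
        rev_sites = _binding_sites(template, rev_seq, "minus", max_mismatch)
        for p in fwd_sites:
            for q in rev_sites:
                end = q + len(rev_seq)
                if end > p and (end - p) <= max_product_length:
                    amplicons.append(Amplicon(template_id, p, end))
    return amplicons
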