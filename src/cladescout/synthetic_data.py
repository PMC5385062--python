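"""Synthetic rRNA-operon communities with planted clades and niches.

The generator emulates the data the pipeline consumes in the field:

* a root 18S-ITS1-5.8S-ITS2-28S operon with universal-primer binding
  sites embedded in the conserved genes (those footprints never mutate --
  that invariance is what makes the primers "universal");
* order-level clades drawn by mutating the root (spacers fast, genes
  slow), then OTUs drawn by mutating their clade ancestor;
* site metadata with six environmental predictors plus biome/region
  labels, and a site x OTU occurrence matrix in which each clade follows a
  Gaussian occurrence response to one focal variable,
  ``P(present) = p_max * exp(-(v - mu)^2 / (2 sigma^2))``;
* chimeric constructs and multi-read segment sets for the QC stage.

Mutation model: independent per-site substitutions, uniform over the three
alternative bases, no indels.  Two successive substitution rounds with
probabilities ``m1``, ``m2`` compose into a single round with
``q = m1 + m2 - (4/3) m1 m2``, and two lineages at ``qA``, ``qB`` from a
common ancestor disagree per site with probability
``qA + qB - (4/3) qA qB``; :func:`expected_divergence` exposes this closed
form so realized divergences can be checked analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contig_qc import ReadSegment
from .io_formats import (
    OccurrenceMatrix,
    OperonAnnotation,
    OtuRecord,
    ReferenceRecord,
    SiteMetadata,
    GENE_REGIONS,
    REGION_ORDER,
    ValidationError,
)
from .primer_design import (
    DEFAULT_UNIVERSAL_PRIMERS,
    UniversalPrimer,
    reverse_complement,
)

import pandas as pd

__all__ = [
    "NicheModel",
    "SimulationConfig",
    "OperonFamily",
    "generate_operon_family",
    "generate_references",
    "generate_chimera",
    "generate_occurrences",
    "simulate_read_segments",
    "substitution_q",
    "compose_q",
    "expected_divergence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class NicheModel:
    """Gaussian occurrence response of one clade to one focal variable.

    ``niche_sd=None`` means a flat (no-preference) niche where presence
    probability equals ``max_occurrence_prob`` everywhere.
    """

    variable: str
    niche_mean: float
    niche_sd: float | None
    max_occurrence_prob: float

    def __post_init__(self) -> None:
        if self.niche_sd is not None and self.niche_sd <= 0:
            raise ValidationError("niche_sd must be positive (or None for flat)")
        if not 0.0 <= self.max_occurrence_prob <= 1.0:
            raise ValidationError("max_occurrence_prob must be in [0, 1]")

    def presence_probability(self, values: np.ndarray) -> np.ndarray:
        if self.niche_sd is None:
            return np.full(values.shape, self.max_occurrence_prob)
        z = (values - self.niche_mean) / self.niche_sd
        return self.max_occurrence_prob * np.exp(-0.5 * z * z)


def default_env_model(n_clades: int) -> dict[str, NicheModel]:
    """One niche per clade, cycling over realistic pH / MAT / MAP optima."""
    cycle = [
        NicheModel("pH", 4.5, 0.4, 0.8),
        NicheModel("MAT", 20.0, 3.0, 0.7),
        NicheModel("pH", 7.5, 0.5, 0.6),
        NicheModel("MAT", 0.0, 4.0, 0.6),
        NicheModel("MAP", 2800.0, 400.0, 0.6),
        NicheModel("pH", 5.8, 0.6, 0.5),
    ]
    return {
        f"clade_{i:02d}": cycle[i % len(cycle)] for i in range(n_clades)
    }


#: Uniform sampling ranges for the numeric environmental predictors,
#: spanning tundra-to-tropics global soil surveys.
DEFAULT_ENV_RANGES: dict[str, tuple[float, float]] = {
    "MAT": (-5.0, 28.0),  # degC
    "MAP": (100.0, 4000.0),  # mm/yr
    "pH": (3.0, 8.5),
    "soil_C": (0.3, 45.0),  # %
    "soil_P": (20.0, 1200.0),  # mg/kg
    "fire_time": (1.0, 200.0),  # yr
}

DEFAULT_BIOMES = (
    "tundra",
    "boreal_forest",
    "temperate_forest",
    "grassland",
    "savanna",
    "tropical_forest",
)
DEFAULT_REGIONS = (
    "Europe",
    "North_America",
    "South_America",
    "Africa",
    "Asia",
    "Australasia",
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic community, with field-realistic defaults."""

    seed: int = 0
    n_clades: int = 4
    otus_per_clade: int = 8
    #: per-base substitution probability, clade ancestor -> OTU
    gene_mut_rate: float = 0.005
    its_mut_rate: float = 0.015
    #: per-base substitution probability, root -> clade ancestor
    clade_gene_mut_rate: float = 0.02
    clade_its_mut_rate: float = 0.16
    region_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "SSU18S": 1800,
            "ITS1": 200,
            "r5_8S": 160,
            "ITS2": 280,
            "LSU28S": 900,
        }
    )
    n_sites: int = 200
    env_model: dict[str, NicheModel] | None = None
    env_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENV_RANGES)
    )
    biomes: tuple[str, ...] = DEFAULT_BIOMES
    regions: tuple[str, ...] = DEFAULT_REGIONS
    universal_primers: dict[str, UniversalPrimer] = field(
        default_factory=lambda: dict(DEFAULT_UNIVERSAL_PRIMERS)
    )

    def __post_init__(self) -> None:
        for rate in (
            self.gene_mut_rate,
            self.its_mut_rate,
            self.clade_gene_mut_rate,
            self.clade_its_mut_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"mutation rate {rate} outside [0, 1]")
        if self.its_mut_rate < self.gene_mut_rate:
            raise ValidationError("spacers must mutate at least as fast as genes")
        if sum(self.region_lengths.values()) <= 0:
            raise ValidationError("region lengths sum to 0")
        if self.env_model is None:
            self.env_model = default_env_model(self.n_clades)

    def clade_ids(self) -> list[str]:
        return [f"clade_{i:02d}" for i in range(self.n_clades)]


# ---------------------------------------------------------------------------
# Mutation arithmetic (closed forms for calibration checks)
# ---------------------------------------------------------------------------


def substitution_q(rate: float) -> float:
    """P(site differs from its ancestor) after one substitution round."""
    return rate


def compose_q(q1: float, q2: float) -> float:
    """Compose two uniform-substitution rounds into one equivalent round."""
    return q1 + q2 - (4.0 / 3.0) * q1 * q2


def expected_divergence(path_a: Sequence[float], path_b: Sequence[float]) -> float:
    """Expected per-site difference between two lineages from one ancestor.

    Each path is the sequence of per-branch substitution probabilities from
    the common ancestor to the tip.
    """
    qa = 0.0
    for rate in path_a:
        qa = compose_q(qa, rate)
    qb = 0.0
    for rate in path_b:
        qb = compose_q(qb, rate)
    return qa + qb - (4.0 / 3.0) * qa * qb


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def _mutate(
    codes: np.ndarray, rate: float, rng: np.random.Generator, mask: np.ndarray
) -> np.ndarray:
    """One substitution round; ``mask`` marks protected (invariant) sites."""
    out = codes.copy()
    hit = (rng.random(codes.size) < rate) & ~mask
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lookup = np.full(256, 255, dtype=np.uint8)
    for i, base in enumerate("ACGT"):
        lookup[ord(base)] = i
    codes = lookup[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValidationError("only A/C/G/T sequences can be encoded")
    return codes


#: Fractional positions (within their region) of the planted universal
#: primer sites, approximating where these primers anneal on real genes.
_UNIVERSAL_SITE_FRACTIONS = {
    "NS5a": ("SSU18S", 0.33),
    "NS7a": ("SSU18S", 0.80),
    "TW13": ("LSU28S", 0.45),
    "LR5": ("LSU28S", 0.90),
}


@dataclass
class OperonFamily:
    """Everything :func:`generate_operon_family` produces."""

    root: OperonAnnotation
    otus: list[OtuRecord]
    labels: dict[str, str]
    operons: dict[str, OperonAnnotation]
    clade_ancestors: dict[str, OperonAnnotation]


def _build_regions(region_lengths: Mapping[str, int]) -> list[tuple[str, int, int]]:
    regions = []
    pos = 0
    for name in REGION_ORDER:
        length = int(region_lengths.get(name, 0))
        if length < 0:
            raise ValidationError(f"negative length for region {name}")
        if length:
            regions.append((name, pos, pos + length))
            pos += length
    if pos == 0:
        raise ValidationError("region lengths sum to 0")
    return regions


def generate_operon_family(config: SimulationConfig) -> OperonFamily:
    """Simulate root, clade-ancestor and per-OTU operons.

    Conserved genes mutate at the gene rates, spacers at the ITS rates;
    universal-primer footprints are invariant.  OTU records carry the ITS2
    region as their representative sequence (counts are filled later by
    :func:`generate_occurrences`).  Same config (incl. seed) => identical
    output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    regions = _build_regions(config.region_lengths)
    total = regions[-1][2]
    root_codes = rng.integers(0, 4, size=total).astype(np.uint8)

    region_span = {name: (start, end) for name, start, end in regions}
    mask = np.zeros(total, dtype=bool)
    for name, (region, fraction) in _UNIVERSAL_SITE_FRACTIONS.items():
        primer = config.universal_primers.get(name)
        if primer is None or region not in region_span:
            continue
        start, end = region_span[region]
        site = (
            primer.sequence
            if primer.orientation == "forward"
            else reverse_complement(primer.sequence)
        )
        if set(site) - set("ACGT"):
            continue  # degenerate universal primers are never planted
        if end - start < len(site):
            raise ValidationError(
                f"universal site {name} does not fit inside region {region}"
            )
        pos = min(start + int(fraction * (end - start)), end - len(site))
        root_codes[pos : pos + len(site)] = _encode(site)
        mask[pos : pos + len(site)] = True

    gene_sites = np.zeros(total, dtype=bool)
    for name, start, end in regions:
        if name in GENE_REGIONS:
            gene_sites[start:end] = True

    def mutate_operon(codes: np.ndarray, gene_rate: float, its_rate: float) -> np.ndarray:
        out = _mutate(codes, gene_rate, rng, mask | ~gene_sites)
        return _mutate(out, its_rate, rng, mask | gene_sites)

    root = OperonAnnotation("root", _decode(root_codes), list(regions))
    otus: list[OtuRecord] = []
    labels: dict[str, str] = {}
    operons: dict[str, OperonAnnotation] = {}
    ancestors: dict[str, OperonAnnotation] = {}
    its2_span = region_span.get("ITS2")
    for clade_index, clade_id in enumerate(config.clade_ids()):
        ancestor_codes = mutate_operon(
            root_codes, config.clade_gene_mut_rate, config.clade_its_mut_rate
        )
        ancestors[clade_id] = OperonAnnotation(
            clade_id, _decode(ancestor_codes), list(regions)
        )
        for otu_index in range(config.otus_per_clade):
            otu_codes = mutate_operon(
                ancestor_codes, config.gene_mut_rate, config.its_mut_rate
            )
            otu_id = f"otu_{clade_index:02d}_{otu_index:02d}"
            sequence = _decode(otu_codes)
            if its2_span is not None:
                rep = sequence[its2_span[0] : its2_span[1]]
            else:
                rep = sequence
            otus.append(OtuRecord(otu_id, rep))
            labels[otu_id] = clade_id
            operons[otu_id] = OperonAnnotation(otu_id, sequence, list(regions))
    return OperonFamily(
        root=root, otus=otus, labels=labels, operons=operons, clade_ancestors=ancestors
    )


def generate_references(
    config: SimulationConfig, n_references: int = 6, length: int | None = None
) -> list[ReferenceRecord]:
    """Named reference sequences unrelated to the planted clades."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    if length is None:
        length = config.region_lengths.get("ITS2", 280)
    references = []
    for i in range(n_references):
        codes = rng.integers(0, 4, size=length).astype(np.uint8)
        references.append(
            ReferenceRecord(
                ref_id=f"ref_{i:02d}",
                binomial=f"Synthomyces exemplaris{i}",
                sequence=_decode(codes),
            )
        )
    return references


def generate_chimera(seq_a: str, seq_b: str, breakpoint: int) -> str:
    """A[0:breakpoint] + B[breakpoint:] -- an artificial two-parent joint."""
    if not 0 < breakpoint < min(len(seq_a), len(seq_b)):
        raise ValidationError(
            f"breakpoint {breakpoint} outside (0, {min(len(seq_a), len(seq_b))})"
        )
    return seq_a[:breakpoint] + seq_b[breakpoint:]


# ---------------------------------------------------------------------------
# Sites and occurrences
# ---------------------------------------------------------------------------


def generate_occurrences(
    config: SimulationConfig, labels: Mapping[str, str]
) -> tuple[OccurrenceMatrix, list[SiteMetadata]]:
    """Draw site environments and clade-conditioned OTU occurrences.

    Environments are uniform over ``config.env_ranges``; each OTU is
    present at a site with its clade's Gaussian response probability
    evaluated at the site's focal variable.  Seed-reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    n = config.n_sites
    env = {
        var: rng.uniform(lo, hi, size=n) for var, (lo, hi) in config.env_ranges.items()
    }
    biome = rng.choice(config.biomes, size=n)
    region = rng.choice(config.regions, size=n)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    sites = [
        SiteMetadata(
            sample_id=sample_ids[i],
            MAT=float(env["MAT"][i]),
            MAP=float(env["MAP"][i]),
            pH=float(env["pH"][i]),
            soil_C=float(env["soil_C"][i]),
            soil_P=float(env["soil_P"][i]),
            fire_time=float(env["fire_time"][i]),
            biome=str(biome[i]),
            region=str(region[i]),
        )
        for i in range(n)
    ]
    otu_ids = sorted(labels)
    columns = {}
    for otu_id in otu_ids:
        clade = labels[otu_id]
        model = config.env_model.get(clade)
        if model is None:
            raise ValidationError(f"env_model does not cover clade {clade!r}")
        prob = model.presence_probability(env[model.variable])
        columns[otu_id] = (rng.random(n) < prob).astype(int)
    table = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    return OccurrenceMatrix(table), sites


# ---------------------------------------------------------------------------
# Read sets for the QC stage
# ---------------------------------------------------------------------------


def simulate_read_segments(
    annotation: OperonAnnotation,
    flank: int = 700,
    tail: int = 800,
    overlap: int = 60,
    chimera_source: OperonAnnotation | None = None,
) -> list[ReadSegment]:
    """Three overlapping reads (18S Sanger, ITS2 pyro, 28S Sanger).

    With ``chimera_source`` set, the 28S read is cut from that template
    instead, emulating a cross-organism chimera whose joint lies inside the
    read overlap.
    """
    its2_start, its2_end = annotation.region("ITS2")
    seq = annotation.sequence
    lo = max(0, its2_start - flank)
    hi = min(len(seq), its2_end + tail)
    reads = [
        ReadSegment(
            f"{annotation.template_id}_18S",
            seq[lo : its2_start + overlap],
            "SSU18S",
            source="sanger",
        ),
        ReadSegment(
            f"{annotation.template_id}_ITS2",
            seq[its2_start:its2_end],
            "ITS",
            source="pyrosequencing",
        ),
    ]
    source_28s = chimera_source.sequence if chimera_source is not None else seq
    suffix = "_28S_chimeric" if chimera_source is not None else "_28S"
    reads.append(
        ReadSegment(
            f"{annotation.template_id}{suffix}",
            source_28s[its2_end - overlap : hi],
            "LSU28S",
            source="sanger",
        )
    )
    return reads
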