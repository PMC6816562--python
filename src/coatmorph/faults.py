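"""Breed-standard fault detection and random-mating fault-phenotype probability.

A "fault" is an allele capable of producing a phenotype a registry's written
standard disallows (tolerance N) or dispreferes (n.p.).  The probability of
the fault phenotype under random mating multiplies one Hardy-Weinberg factor
per participating gene; each factor's expression mode reflects how the
required genotype class expresses:

    dominant_or_better    p^2 + sum(2*p*q) over listed same-gene recessives
    homozygous_recessive  (p + sum(q))^2   (compound heterozygotes included)
    heterozygous_only     2*p*(1 - p)      (e.g. homozygous-lethal harlequin)
    het_or_hom            p^2 + 2*p*(1-p)  (co-dominant: one copy suffices)

An optional live-birth correction renormalizes by the viable fraction
1 - p_lethal^2 per lethal locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .frequencies import BreedFrequencyTable

__all__ = [
    "ExpressionMode",
    "FaultFactor",
    "FaultProbabilityInputs",
    "RegistryStandard",
    "TraitDefinition",
    "StandardsConfig",
    "FaultFinding",
    "factor_probability",
    "fault_probability",
    "live_birth_correction",
    "detect_fault_alleles",
    "compute_fault_probabilities",
    "load_standards",
    "default_standards",
]

MODES = ("dominant_or_better", "homozygous_recessive", "heterozygous_only", "het_or_hom")
TOLERANCES = ("N", "n.p.", "Y", "amb.", "not_recognized")
REGISTRIES = ("AKC", "UKC", "KC", "FCI")

ExpressionMode = str


def _check_freq(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} = {value!r} outside [0, 1]")
    return float(value)


@dataclass(frozen=True)
class FaultFactor:
    """One gene's contribution: required-allele frequency p, the frequencies
    of up to three same-gene alleles recessive to it, and the expression mode."""

    p: float
    recessives: tuple[float, ...] = ()
    mode: ExpressionMode = "dominant_or_better"

    def __post_init__(self) -> None:
        _check_freq(self.p, "p")
        if len(self.recessives) > 3:
            raise ValueError("at most 3 same-gene recessive alleles are supported")
        for q in self.recessives:
            _check_freq(q, "recessive frequency")
        if self.mode not in MODES:
            raise ValueError(f"unknown expression mode {self.mode!r}")


@dataclass(frozen=True)
class FaultProbabilityInputs:
    """Up to three multiplied factors (the fault gene plus at most two
    interacting genes) and the lethal-allele frequencies for the optional
    live-birth renormalization."""

    factors: tuple[FaultFactor, ...]
    lethal_frequencies: tuple[float, ...] = ()
    live_birth: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.factors) <= 3:
            raise ValueError("between 1 and 3 factors are supported")
        for p in self.lethal_frequencies:
            _check_freq(p, "lethal allele frequency")


def factor_probability(factor: FaultFactor) -> float:
    p = factor.p
    if factor.mode == "dominant_or_better":
        return p * p + sum(2 * p * q for q in factor.recessives)
    if factor.mode == "homozygous_recessive":
        s = p + sum(factor.recessives)
        _check_freq(s, "recessive-class total frequency")
        return s * s
    if factor.mode == "heterozygous_only":
        return 2 * p * (1 - p)
    # het_or_hom
    return p * p + 2 * p * (1 - p)


def live_birth_correction(
    raw: float, lethal_frequencies: Sequence[float]
) -> float:
    """Renormalize a conception-scale probability to live births."""
    divisor = math.prod(1 - _check_freq(p, "lethal allele frequency") ** 2
                        for p in lethal_frequencies)
    return raw / divisor


def fault_probability(inputs: FaultProbabilityInputs) -> float:
    """Random-mating probability of the fault phenotype."""
    prob = math.prod(factor_probability(f) for f in inputs.factors)
    if inputs.live_birth and inputs.lethal_frequencies:
        prob = live_birth_correction(prob, inputs.lethal_frequencies)
    return prob


# ---------------------------------------------------------------------------
# standards configuration and fault detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistryStandard:
    breed: str
    registry: str
    trait: str
    tolerance: str

    def __post_init__(self) -> None:
        if self.registry not in REGISTRIES:
            raise ValueError(f"unknown registry {self.registry!r}")
        if self.tolerance not in TOLERANCES:
            raise ValueError(f"unknown tolerance code {self.tolerance!r}")


@dataclass(frozen=True)
class TraitDefinition:
    """How a named fault trait maps onto genes: which alleles signal carrier
    status, the inheritance class (D/R/CH), and the probability recipe."""

    name: str
    gene: str
    fault_alleles: tuple[str, ...]
    inheritance: str  # D, R, or CH
    #: probability recipe: (gene, allele symbols pooled into the class, mode)
    factors: tuple[tuple[str, tuple[str, ...], ExpressionMode], ...]
    live_birth: bool = False
    lethal_alleles: tuple[tuple[str, str], ...] = ()  # (gene, allele)


@dataclass
class StandardsConfig:
    traits: dict[str, TraitDefinition]
    standards: list[RegistryStandard]

    def for_breed(self, breed: str) -> list[RegistryStandard]:
        return [s for s in self.standards if s.breed == breed]


@dataclass
class FaultFinding:
    breed: str
    registry: str
    trait: str
    gene: str
    fault_alleles: tuple[str, ...]
    inheritance: str
    tolerance: str
    carrier_frequency: float
    ambiguous: bool = False
    probability: Optional[float] = None
    population: str = ""
    notes: list[str] = field(default_factory=list)


_DATA_DIR = Path(__file__).parent / "data"


def load_standards(path: str | Path) -> StandardsConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    traits = {}
    for name, t in raw["traits"].items():
        traits[name] = TraitDefinition(
            name=name,
            gene=t["gene"],
            fault_alleles=tuple(t["fault_alleles"]),
            inheritance=t["inheritance"],
            factors=tuple(
                (f["gene"], tuple(f["alleles"]), f["mode"]) for f in t["factors"]
            ),
            live_birth=t.get("live_birth", False),
            lethal_alleles=tuple(
                (l["gene"], l["allele"]) for l in t.get("lethal_alleles", [])
            ),
        )
    standards = [
        RegistryStandard(
            breed=s["breed"],
            registry=s["registry"],
            trait=s["trait"],
            tolerance=s["tolerance"],
        )
        for s in raw["standards"]
    ]
    return StandardsConfig(traits=traits, standards=standards)


_default: Optional[StandardsConfig] = None


def default_standards() -> StandardsConfig:
    """Curated standards for the breeds discussed in the worked examples."""
    global _default
    if _default is None:
        _default = load_standards(_DATA_DIR / "standards.yaml")
    return _default


def detect_fault_alleles(
    freqs: Mapping[tuple[str, str], BreedFrequencyTable] | BreedFrequencyTable,
    config: Optional[StandardsConfig] = None,
) -> list[FaultFinding]:
    """One finding per (breed, registry, trait) whose fault allele is present
    and whose tolerance is N or n.p.; amb. entries are kept but flagged."""
    config = config or default_standards()
    if isinstance(freqs, BreedFrequencyTable):
        tables: Iterable[BreedFrequencyTable] = [freqs]
    else:
        tables = list(freqs.values())
    findings: list[FaultFinding] = []
    for table in tables:
        standards = config.for_breed(table.breed)
        if not standards:
            continue
        for std in standards:
            if std.tolerance not in ("N", "n.p.", "amb."):
                continue
            trait = config.traits[std.trait]
            gf = table.genes.get(trait.gene)
            if gf is None or not gf.available:
                continue
            carrier = sum(gf.frequencies.get(a, 0.0) for a in trait.fault_alleles)
            if carrier <= 0.0:
                continue
            findings.append(
                FaultFinding(
                    breed=table.breed,
                    registry=std.registry,
                    trait=std.trait,
                    gene=trait.gene,
                    fault_alleles=trait.fault_alleles,
                    inheritance=trait.inheritance,
                    tolerance=std.tolerance,
                    carrier_frequency=carrier,
                    ambiguous=std.tolerance == "amb.",
                    population=table.population,
                )
            )
    return findings


def _inputs_from_table(
    trait: TraitDefinition, table: BreedFrequencyTable
) -> Optional[FaultProbabilityInputs]:
    factors = []
    for gene, alleles, mode in trait.factors:
        gf = table.genes.get(gene)
        if gf is None or not gf.available:
            return None
        freqs = [gf.frequencies.get(a, 0.0) for a in alleles]
        factors.append(FaultFactor(p=freqs[0], recessives=tuple(freqs[1:]), mode=mode))
    lethal = []
    for gene, allele in trait.lethal_alleles:
        gf = table.genes.get(gene)
        if gf is not None and gf.available:
            lethal.append(gf.frequencies.get(allele, 0.0))
    return FaultProbabilityInputs(
        factors=tuple(factors),
        lethal_frequencies=tuple(lethal),
        live_birth=trait.live_birth,
    )


def compute_fault_probabilities(
    findings: Iterable[FaultFinding],
    freqs: Mapping[tuple[str, str], BreedFrequencyTable],
    config: Optional[StandardsConfig] = None,
) -> list[FaultFinding]:
    """Fill in the random-mating fault probability for each finding."""
    config = config or default_standards()
    out = []
    for finding in findings:
        table = freqs.get((finding.breed, finding.population))
        trait = config.traits[finding.trait]
        if table is not None:
            inputs = _inputs_from_table(trait, table)
            if inputs is not None:
                finding.probability = fault_probability(inputs)
            else:
                finding.notes.append("interacting-gene frequencies unavailable")
        out.append(finding)
    return out
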