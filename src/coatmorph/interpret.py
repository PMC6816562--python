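"""Assembly of diploid genotypes from per-variant marker copy counts.

Markers report 0, 1, or 2 copies of each assayed derived variant.  Wild-type
alleles (ASIP aw, MC1R E, TYRP1 B, ...) carry no marker and are called by
exclusion: chromosomes not accounted for by derived copies are assigned the
wild type.  Dogs whose ASIP markers report three or more derived copies are
re-phased through the cis ay+at combination allele (ayt) where a unique
phasing exists; anything else is flagged unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .trait_model import Ambiguity, GeneCatalog, GeneModel, GenotypeCall, default_catalog

__all__ = [
    "MarkerCall",
    "DogRecord",
    "InterpretationError",
    "interpret_asip",
    "interpret_mc1r",
    "interpret_biallelic",
    "interpret_gene",
    "interpret_dog",
]


class InterpretationError(ValueError):
    """Raised on marker copy counts outside the valid 0-2 range."""


@dataclass(frozen=True)
class MarkerCall:
    marker_id: str
    copies: Optional[int]  # 0, 1, 2, or None for a failed assay

    def __post_init__(self) -> None:
        if self.copies is not None and self.copies not in (0, 1, 2):
            raise InterpretationError(
                f"{self.marker_id}: copy count {self.copies!r} outside 0-2"
            )


@dataclass
class DogRecord:
    """One dog's identity labels plus its raw marker calls."""

    dog_id: str
    breed: str
    population: str = ""
    marker_calls: dict[str, Optional[int]] = field(default_factory=dict)
    #: retained only by the simulator: gene_id -> (haplotype, haplotype)
    true_haplotypes: Optional[dict[str, tuple[str, str]]] = None
    genotypes: Optional[dict[str, GenotypeCall]] = None

    def copies(self, marker_id: str) -> Optional[int]:
        return self.marker_calls.get(marker_id)


def _missing(gene_id: str) -> GenotypeCall:
    return GenotypeCall(gene_id, (), missing=True)


def _unresolved(gene_id: str) -> GenotypeCall:
    return GenotypeCall(gene_id, (), ambiguity=Ambiguity.UNRESOLVED, missing=True)


def _check(gene_id: str, copies: Mapping[str, Optional[int]]) -> bool:
    """Validate copy ranges; return True when all constituent calls are present."""
    for marker, c in copies.items():
        if c is not None and c not in (0, 1, 2):
            raise InterpretationError(f"{gene_id}/{marker}: copies {c!r} outside 0-2")
    return all(c is not None for c in copies.values())


def interpret_asip(
    ay: Optional[int], at: Optional[int], a: Optional[int]
) -> GenotypeCall:
    """Assemble the ASIP genotype from the ay, at, and a marker copy counts.

    Up to two derived copies are padded with the by-exclusion aw allele.
    Three or four derived copies are explained, where possible, by the cis
    ay+at haplotype (ayt); the ay=1/at=1/a=1 case has two consistent
    phasings and is flagged ``ayt_vs_trans``.
    """
    if not _check("ASIP", {"asip_ay": ay, "asip_at": at, "asip_a": a}):
        return _missing("ASIP")
    total = ay + at + a
    if total <= 2:
        pair = ["ay"] * ay + ["at"] * at + ["a"] * a + ["aw"] * (2 - total)
        return GenotypeCall("ASIP", tuple(pair))
    if total == 3 and ay >= 1 and at >= 1:
        if (ay, at, a) == (2, 1, 0):
            return GenotypeCall("ASIP", ("ayt", "ay"))
        if (ay, at, a) == (1, 2, 0):
            return GenotypeCall("ASIP", ("ayt", "at"))
        # ay=1, at=1, a=1: either ayt/a or the trans ay/at with a third
        # chromosome is impossible, but ay+a or at+a cis pairs are unreported;
        # the only described phasing is ayt/a, kept with an ambiguity flag.
        return GenotypeCall("ASIP", ("ayt", "a"), ambiguity=Ambiguity.AYT_VS_TRANS)
    if (ay, at, a) == (2, 2, 0):
        return GenotypeCall("ASIP", ("ayt", "ayt"))
    return _unresolved("ASIP")


def interpret_mc1r(
    em: Optional[int], eg: Optional[int], e: Optional[int]
) -> GenotypeCall:
    """Assemble the MC1R genotype; E is the by-exclusion allele.

    No cis combination is described for MC1R, so more than two derived
    copies is always unresolved.
    """
    if not _check("MC1R", {"mc1r_em": em, "mc1r_eg": eg, "mc1r_e": e}):
        return _missing("MC1R")
    total = em + eg + e
    if total <= 2:
        pair = ["EM"] * em + ["EG"] * eg + ["e"] * e + ["E"] * (2 - total)
        return GenotypeCall("MC1R", tuple(pair))
    return _unresolved("MC1R")


def interpret_biallelic(
    model: GeneModel, copies: Mapping[str, Optional[int]]
) -> GenotypeCall:
    """Interpret a gene whose derived alleles each carry one marker.

    Handles plain two-allele genes (copies 0/1/2 -> wt/wt, wt/var, var/var)
    and TYRP1-style multi-recessive genes by summing derived copies; a total
    above two chromosomes is a data error.
    """
    if not _check(model.gene_id, copies):
        return _missing(model.gene_id)
    derived: list[str] = []
    for allele in model.alleles:
        if len(allele.markers) == 1:
            derived.extend([allele.symbol] * copies[allele.markers[0]])
    if len(derived) > 2:
        raise InterpretationError(
            f"{model.gene_id}: {len(derived)} derived copies exceed two chromosomes"
        )
    wt = model.wild_type.symbol
    pair = derived + [wt] * (2 - len(derived))
    return GenotypeCall(model.gene_id, tuple(pair))


def interpret_gene(model: GeneModel, dog: DogRecord) -> GenotypeCall:
    if model.gene_id == "ASIP":
        return interpret_asip(
            dog.copies("asip_ay"), dog.copies("asip_at"), dog.copies("asip_a")
        )
    if model.gene_id == "MC1R":
        return interpret_mc1r(
            dog.copies("mc1r_em"), dog.copies("mc1r_eg"), dog.copies("mc1r_e")
        )
    return interpret_biallelic(model, {m: dog.copies(m) for m in model.marker_ids})


def interpret_dog(
    dog: DogRecord, catalog: Optional[GeneCatalog] = None
) -> dict[str, GenotypeCall]:
    """Interpret every catalogued gene for one dog; result cached on the record."""
    catalog = catalog or default_catalog()
    genotypes = {model.gene_id: interpret_gene(model, dog) for model in catalog}
    dog.genotypes = genotypes
    return genotypes
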