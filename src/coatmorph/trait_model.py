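"""Allele catalogue, dominance hierarchies, and the epistatic phenotype engine.

Twelve genes control the modelled coat-colour and morphology traits.  Each
gene carries an ordered allele hierarchy (lower rank = more dominant); the
phenotype engine applies the cross-gene epistasis rules in a fixed decision
order (recessive-red first, then dominant-black, then the agouti pattern,
then the overlay modifiers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

__all__ = [
    "Allele",
    "GeneModel",
    "GenotypeCall",
    "PhenotypeReport",
    "Ambiguity",
    "GeneCatalog",
    "default_catalog",
    "load_catalog",
    "resolve_expressed_allele",
    "predict_phenotype",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a gene-model configuration is internally inconsistent."""


class Ambiguity(str, Enum):
    NONE = "none"
    KB_VS_KBR = "kb_vs_kbr"
    AYT_VS_TRANS = "ayt_vs_trans"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Allele:
    gene_id: str
    symbol: str
    rank: int
    is_wild_type: bool = False
    lethal_homozygous: bool = False
    #: marker ids whose presence on a haplotype indicates this allele;
    #: empty for by-exclusion (wild-type) alleles.
    markers: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    alleles: tuple[Allele, ...]
    #: hierarchy — strict dominance ordering; compound_recessive — the
    #: recessive class expresses only when both alleles are recessive
    #: members; overlay — effect applied by the phenotype engine, not a
    #: standalone colour pattern.
    mode: str = "hierarchy"
    breed_overrides: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = [a.rank for a in self.alleles]
        if len(set(ranks)) != len(ranks):
            raise ConfigError(f"{self.gene_id}: duplicate dominance ranks")
        symbols = [a.symbol for a in self.alleles]
        if len(set(symbols)) != len(symbols):
            raise ConfigError(f"{self.gene_id}: duplicate allele symbols")

    def allele(self, symbol: str) -> Allele:
        for a in self.alleles:
            if a.symbol == symbol:
                return a
        raise ConfigError(f"unknown allele {symbol!r} for gene {self.gene_id}")

    @property
    def marker_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for a in self.alleles:
            for m in a.markers:
                if m not in seen:
                    seen.append(m)
        return tuple(seen)

    @property
    def wild_type(self) -> Allele:
        for a in self.alleles:
            if a.is_wild_type:
                return a
        raise ConfigError(f"{self.gene_id}: no wild-type allele")


@dataclass(frozen=True)
class GenotypeCall:
    """Unordered diploid allele pair for one gene, or a missing/ambiguous call."""

    gene_id: str
    allele_pair: tuple[str, ...] = ()
    ambiguity: Ambiguity = Ambiguity.NONE
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing != (len(self.allele_pair) == 0):
            raise ValueError("allele_pair must be empty iff the call is missing")
        if not self.missing and len(self.allele_pair) != 2:
            raise ValueError("a non-missing call carries exactly two alleles")
        object.__setattr__(self, "allele_pair", tuple(sorted(self.allele_pair)))

    def count(self, symbol: str) -> int:
        return sum(1 for s in self.allele_pair if s == symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.allele_pair


class GeneCatalog:
    """The full set of gene models, indexed by gene id."""

    def __init__(self, models: Iterable[GeneModel]):
        self._models = {m.gene_id: m for m in models}

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._models[gene_id]
        except KeyError:
            raise ConfigError(f"unknown gene {gene_id!r}") from None

    def __iter__(self):
        return iter(self._models.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self._models)


_DATA_DIR = Path(__file__).parent / "data"


def load_catalog(path: str | Path) -> GeneCatalog:
    """Load a gene-model catalogue from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    models = []
    for gene_id, g in raw["genes"].items():
        alleles = tuple(
            Allele(
                gene_id=gene_id,
                symbol=a["symbol"],
                rank=a["rank"],
                is_wild_type=a.get("wild_type", False),
                lethal_homozygous=a.get("lethal_homozygous", False),
                markers=tuple(a.get("markers", [])),
            )
            for a in g["alleles"]
        )
        models.append(
            GeneModel(
                gene_id=gene_id,
                alleles=alleles,
                mode=g.get("mode", "hierarchy"),
                breed_overrides=g.get("breed_overrides", {}),
            )
        )
    return GeneCatalog(models)


_default: Optional[GeneCatalog] = None


def default_catalog() -> GeneCatalog:
    """The shipped 12-gene catalogue (ASIP … ear-set marker)."""
    global _default
    if _default is None:
        _default = load_catalog(_DATA_DIR / "gene_models.yaml")
    return _default


def resolve_expressed_allele(genotype: GenotypeCall, model: GeneModel) -> Allele:
    """Return the expressed (most dominant) allele of a diploid genotype.

    For ``compound_recessive`` genes the returned allele is wild type unless
    both alleles are recessive members, in which case the highest-ranked
    recessive of the pair stands for the recessive phenotype class.
    """
    if genotype.missing:
        raise ValueError(f"{model.gene_id}: cannot resolve a missing genotype")
    pair = [model.allele(s) for s in genotype.allele_pair]
    return min(pair, key=lambda a: a.rank)


# phenotype field vocabulary
_PHAEO_BEARING = {"fawn_sable", "wolf_sable", "tan_points", "ayt_uncharacterized"}

_ASIP_PATTERN = {
    "ayt": "ayt_uncharacterized",
    "ay": "fawn_sable",
    "aw": "wolf_sable",
    "at": "tan_points",
    "a": "recessive_black",
}


@dataclass
class PhenotypeReport:
    pigment_pattern: str = "unknown"
    eumelanin_shade: str = "unknown"
    nose_shade: str = "unknown"
    mask: str = "unknown"
    grizzle: str = "unknown"
    saddle: str = "unknown"
    white_spotting: str = "unknown"
    harlequin: str = "unknown"
    coat_length: str = "unknown"
    curl: str = "unknown"
    tail: str = "unknown"
    muzzle_genotype: str = "unknown"
    ear_genotype: str = "unknown"
    viability: bool = True
    notes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _usable(call: Optional[GenotypeCall]) -> bool:
    return (
        call is not None
        and not call.missing
        and call.ambiguity in (Ambiguity.NONE, Ambiguity.KB_VS_KBR)
    )


def predict_phenotype(
    genotypes: Mapping[str, GenotypeCall],
    breed_config: Optional[Mapping[str, str]] = None,
    catalog: Optional[GeneCatalog] = None,
) -> PhenotypeReport:
    """Predict the expressed phenotype from per-gene genotype calls.

    ``breed_config`` may set ``mitf_mode`` to ``co_dominant`` or
    ``recessive``; without it a heterozygous white-spotting genotype is
    reported ``breed_dependent``.  Genes other than MC1R, CBD103 and ASIP
    are optional; their report fields stay ``unknown`` when absent.
    """
    catalog = catalog or default_catalog()
    breed_config = breed_config or {}
    rep = PhenotypeReport()

    mc1r = genotypes.get("MC1R")
    cbd = genotypes.get("CBD103")
    asip = genotypes.get("ASIP")

    # -- base pigment pattern: e/e, then dominant black, then agouti --------
    if not _usable(mc1r) or not _usable(cbd):
        rep.pigment_pattern = "unknown"
        rep.warnings.append("MC1R or CBD103 genotype unavailable; pattern unknown")
    elif mc1r.count("e") == 2:
        rep.pigment_pattern = "solid_phaeomelanin"
    elif "KB_kbr" in cbd:
        rep.pigment_pattern = "solid_eumelanin_or_brindle"
        rep.notes.append("KB indistinguishable from kbr: solid or brindle")
        if asip is not None and not asip.missing:
            rep.notes.append("ASIP pattern masked by CBD103 epistasis")
    elif not _usable(asip):
        rep.pigment_pattern = "unknown"
        rep.warnings.append("ASIP genotype unavailable; pattern unknown")
    else:
        expressed = resolve_expressed_allele(asip, catalog["ASIP"])
        rep.pigment_pattern = _ASIP_PATTERN[expressed.symbol]
        if expressed.symbol == "ayt":
            rep.notes.append("ayt phenotype uncharacterized; dominance unverified")

    # -- mask and grizzle overlays on the MC1R hierarchy --------------------
    if _usable(mc1r):
        if "EM" in mc1r:
            if rep.pigment_pattern in _PHAEO_BEARING:
                rep.mask = "present"
            elif rep.pigment_pattern == "unknown":
                rep.mask = "unknown"
            else:
                rep.mask = "masked_by_epistasis"
        else:
            rep.mask = "masked_by_epistasis" if mc1r.count("e") == 2 else "absent"
        if "EG" in mc1r:
            grizzle_bg = rep.pigment_pattern == "tan_points" and "EM" not in mc1r
            rep.grizzle = "expressed" if grizzle_bg else "carried_unexpressed"
        else:
            rep.grizzle = "absent"

    # -- saddle modifier: requires an expressed tan-point background --------
    raly = genotypes.get("RALY")
    if _usable(raly):
        if "saddle_dup" in raly and rep.pigment_pattern == "tan_points":
            rep.saddle = "capable"  # an unidentified extra modifier is required
        else:
            rep.saddle = "not_capable"

    # -- eumelanin shade (TYRP1 compound recessive); nose browns even e/e ---
    tyrp1 = genotypes.get("TYRP1")
    if _usable(tyrp1):
        expressed = resolve_expressed_allele(tyrp1, catalog["TYRP1"])
        shade = "black" if expressed.is_wild_type else "brown"
        rep.eumelanin_shade = shade
        rep.nose_shade = shade

    # -- white spotting: breed-dependent dominance --------------------------
    mitf = genotypes.get("MITF")
    if _usable(mitf):
        copies = mitf.count("sp")
        if copies == 2:
            rep.white_spotting = "expressed"
        elif copies == 1:
            mode = breed_config.get("mitf_mode")
            if mode == "co_dominant":
                rep.white_spotting = "expressed"
            elif mode == "recessive":
                rep.white_spotting = "absent"
            else:
                rep.white_spotting = "breed_dependent"
        else:
            rep.white_spotting = "absent"

    # -- harlequin: heterozygous-only, homozygous lethal --------------------
    psmb7 = genotypes.get("PSMB7")
    if _usable(psmb7):
        copies = psmb7.count("h")
        rep.harlequin = "capable_if_merle" if copies == 1 else "absent"
        if copies == 2:
            rep.viability = False
            rep.notes.append("h/h is homozygous lethal")

    # -- coat length, then curl gating on length ----------------------------
    fgf5 = genotypes.get("FGF5")
    if _usable(fgf5):
        rep.coat_length = "long" if fgf5.count("long") == 2 else "short"
    krt71 = genotypes.get("KRT71")
    if _usable(krt71):
        if "curl" in krt71:
            rep.curl = "expressed" if rep.coat_length == "long" else "carried_masked"
        else:
            rep.curl = "absent"

    # -- natural bobtail: heterozygous-only, homozygous lethal --------------
    t = genotypes.get("T")
    if _usable(t):
        copies = t.count("tailless")
        rep.tail = "natural_bobtail" if copies >= 1 else "normal"
        if copies == 2:
            rep.viability = False
            rep.notes.append("tailless/tailless is homozygous lethal")

    # -- polygenic-context genotypes (no deterministic phenotype claim) -----
    bmp3 = genotypes.get("BMP3")
    if _usable(bmp3):
        rep.muzzle_genotype = "/".join(bmp3.allele_pair) + " (polygenic context)"
    ear = genotypes.get("EAR")
    if _usable(ear):
        rep.ear_genotype = "/".join(ear.allele_pair) + " (polygenic context)"

    return rep
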