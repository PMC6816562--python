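"""Synthetic cohort generation under Hardy-Weinberg equilibrium.

Cohorts are drawn haplotype-wise at specified per-gene allele frequencies.
At homozygous-lethal loci the draws are rejected and redrawn while lethal
(live-cohort sampling), so the observed genotype distribution follows the
viability-conditioned HWE distribution.  Cis ayt haplotypes emit both the
ay and the at marker variant on one chromosome.  Marker calls can be masked
missing independently at a per-marker rate.  Generation is fully
deterministic for a fixed spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .interpret import DogRecord
from .trait_model import GeneCatalog, default_catalog

__all__ = [
    "PopulationSpec",
    "BreedSpec",
    "CohortSpec",
    "SpecError",
    "generate_cohort",
    "generate_null_and_alternative",
    "shift_frequencies",
    "load_cohort_spec",
]


class SpecError(ValueError):
    """Raised when a cohort spec is invalid."""


@dataclass
class PopulationSpec:
    label: str
    n: int
    #: gene_id -> {allele symbol -> frequency}; genes omitted here are not
    #: simulated and interpret as missing.
    frequencies: dict[str, dict[str, float]]

    def validate(self) -> None:
        if self.n < 1:
            raise SpecError(f"population {self.label!r}: n must be >= 1")
        for gene, freqs in self.frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise SpecError(
                    f"population {self.label!r}, gene {gene}: frequencies sum to {total}"
                )
            for allele, f in freqs.items():
                if not 0.0 <= f <= 1.0:
                    raise SpecError(f"{gene}/{allele}: frequency {f} outside [0, 1]")


@dataclass
class BreedSpec:
    breed: str
    populations: list[PopulationSpec]


@dataclass
class CohortSpec:
    breeds: list[BreedSpec]
    seed: int
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.seed is None:
            raise SpecError("a random seed is mandatory")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecError("missing rate must be in [0, 1)")
        for b in self.breeds:
            for pop in b.populations:
                pop.validate()


def _draw_haplotypes(
    rng: np.random.Generator,
    n: int,
    alleles: list[str],
    probs: np.ndarray,
    lethal: set[str],
) -> np.ndarray:
    """n x 2 array of haplotype allele indices, rejecting lethal homozygotes."""
    if lethal:
        viable = 1.0 - sum(
            probs[i] ** 2 for i, a in enumerate(alleles) if a in lethal
        )
        if viable <= 0.0:
            raise SpecError("no viable genotype exists at a lethal locus")
    idx = rng.choice(len(alleles), size=(n, 2), p=probs)
    if lethal:
        lethal_idx = {i for i, a in enumerate(alleles) if a in lethal}
        while True:
            bad = np.array(
                [h0 == h1 and h0 in lethal_idx for h0, h1 in idx], dtype=bool
            )
            if not bad.any():
                break
            idx[bad] = rng.choice(len(alleles), size=(int(bad.sum()), 2), p=probs)
    return idx


def generate_cohort(
    spec: CohortSpec, catalog: Optional[GeneCatalog] = None
) -> list[DogRecord]:
    """Generate the cohort; true haplotypes are retained on each record."""
    spec.validate()
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(spec.seed)
    dogs: list[DogRecord] = []
    counter = 0
    for breed_spec in spec.breeds:
        for pop in breed_spec.populations:
            n = pop.n
            haplotypes: dict[str, list[tuple[str, str]]] = {}
            for gene_id in sorted(pop.frequencies):
                model = catalog[gene_id]
                freqs = pop.frequencies[gene_id]
                alleles = sorted(freqs)
                for a in alleles:
                    model.allele(a)  # validate symbols against the catalogue
                probs = np.array([freqs[a] for a in alleles], dtype=float)
                probs = probs / probs.sum()
                lethal = {a.symbol for a in model.alleles if a.lethal_homozygous}
                idx = _draw_haplotypes(rng, n, alleles, probs, lethal)
                haplotypes[gene_id] = [
                    (alleles[i], alleles[j]) for i, j in idx
                ]
            # marker columns for the simulated genes only
            markers: list[str] = []
            for gene_id in sorted(pop.frequencies):
                markers.extend(
                    m for m in catalog[gene_id].marker_ids if m not in markers
                )
            allele_markers = {
                (g, a.symbol): a.markers
                for g in sorted(pop.frequencies)
                for a in catalog[g].alleles
            }
            mask = (
                rng.random((n, len(markers))) < spec.missing_rate
                if spec.missing_rate > 0
                else np.zeros((n, len(markers)), dtype=bool)
            )
            for i in range(n):
                counter += 1
                calls: dict[str, Optional[int]] = {m: 0 for m in markers}
                true: dict[str, tuple[str, str]] = {}
                for gene_id in sorted(pop.frequencies):
                    pair = haplotypes[gene_id][i]
                    true[gene_id] = tuple(sorted(pair))
                    for hap in pair:
                        for m in allele_markers[(gene_id, hap)]:
                            calls[m] += 1
                for j, m in enumerate(markers):
                    if mask[i, j]:
                        calls[m] = None
                dogs.append(
                    DogRecord(
                        dog_id=f"{breed_spec.breed}_{pop.label}_{counter:06d}",
                        breed=breed_spec.breed,
                        population=pop.label,
                        marker_calls=calls,
                        true_haplotypes=true,
                    )
                )
    return dogs


def shift_frequencies(
    frequencies: dict[str, dict[str, float]], divergence: float
) -> dict[str, dict[str, float]]:
    """Shift each gene's distribution by moving `divergence` mass onto the
    first allele (sorted order), rescaling the rest."""
    shifted = {}
    for gene, freqs in frequencies.items():
        alleles = sorted(freqs)
        first = alleles[0]
        new_first = min(freqs[first] + divergence, 1.0)
        rest_total = sum(freqs[a] for a in alleles[1:])
        out = {first: new_first}
        remaining = 1.0 - new_first
        for a in alleles[1:]:
            out[a] = remaining * (freqs[a] / rest_total) if rest_total > 0 else 0.0
        shifted[gene] = out
    return shifted


def generate_null_and_alternative(
    breed: str,
    n_per_population: int,
    frequencies: dict[str, dict[str, float]],
    divergence: float,
    seed: int,
    missing_rate: float = 0.0,
    catalog: Optional[GeneCatalog] = None,
) -> list[DogRecord]:
    """Two same-breed populations: "A" at the base frequencies, "B" shifted
    by `divergence` (identical distributions when divergence is 0)."""
    spec = CohortSpec(
        breeds=[
            BreedSpec(
                breed=breed,
                populations=[
                    PopulationSpec("A", n_per_population, frequencies),
                    PopulationSpec(
                        "B",
                        n_per_population,
                        shift_frequencies(frequencies, divergence),
                    ),
                ],
            )
        ],
        seed=seed,
        missing_rate=missing_rate,
    )
    return generate_cohort(spec, catalog)


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a cohort spec from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    breeds = [
        BreedSpec(
            breed=b["breed"],
            populations=[
                PopulationSpec(
                    label=p["label"],
                    n=p["n"],
                    frequencies={g: dict(f) for g, f in p["frequencies"].items()},
                )
                for p in b["populations"]
            ],
        )
        for b in raw["breeds"]
    ]
    spec = CohortSpec(
        breeds=breeds,
        seed=raw["seed"],
        missing_rate=raw.get("missing_rate", 0.0),
    )
    spec.validate()
    return spec
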