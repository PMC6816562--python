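"""Allele-frequency and chromosome-count estimation per breed or subpopulation.

Each non-missing, resolved genotype contributes two chromosomes to its
gene's counts.  Dogs with an unresolved ambiguity at a gene are excluded
from that gene only; the pooled KB/kbr class counts as a single allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .interpret import DogRecord, interpret_dog
from .trait_model import Ambiguity, GeneCatalog, default_catalog

__all__ = [
    "GeneFrequency",
    "BreedFrequencyTable",
    "estimate_frequencies",
    "frequency_frame",
    "tables_from_frame",
]


@dataclass
class GeneFrequency:
    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)
    genotype_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_genotyped: int = 0
    n_missing: int = 0
    n_excluded: int = 0  # unresolved-ambiguity dogs

    @property
    def available(self) -> bool:
        return self.n_genotyped > 0

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_genotyped

    @property
    def frequencies(self) -> dict[str, float]:
        total = self.n_chromosomes
        if total == 0:
            return {}
        return {allele: c / total for allele, c in self.counts.items()}

    def frequency(self, allele: str) -> float:
        if not self.available:
            raise ValueError(f"{self.gene_id}: no genotyped dogs")
        return self.counts.get(allele, 0) / self.n_chromosomes

    @property
    def fixed(self) -> Optional[str]:
        """The single allele at frequency 1, or None if the gene segregates."""
        for allele, f in self.frequencies.items():
            if f == 1.0:
                return allele
        return None


@dataclass
class BreedFrequencyTable:
    breed: str
    population: str = ""
    genes: dict[str, GeneFrequency] = field(default_factory=dict)

    def frequency(self, gene_id: str, allele: str) -> float:
        return self.genes[gene_id].frequency(allele)


def estimate_frequencies(
    dogs: Iterable[DogRecord],
    by_population: bool = False,
    catalog: Optional[GeneCatalog] = None,
) -> dict[tuple[str, str], BreedFrequencyTable]:
    """Tally allele chromosome counts per breed (and optionally population).

    Returns a mapping from (breed, population) — population is "" when
    pooling across populations — to the breed's frequency table.
    """
    catalog = catalog or default_catalog()
    tables: dict[tuple[str, str], BreedFrequencyTable] = {}
    for dog in dogs:
        if dog.genotypes is None:
            interpret_dog(dog, catalog)
        pop = dog.population if by_population else ""
        key = (dog.breed, pop)
        table = tables.setdefault(key, BreedFrequencyTable(dog.breed, pop))
        for gene_id, call in dog.genotypes.items():
            gf = table.genes.setdefault(gene_id, GeneFrequency(gene_id))
            if call.ambiguity is Ambiguity.UNRESOLVED:
                gf.n_excluded += 1
            elif call.missing:
                gf.n_missing += 1
            else:
                gf.n_genotyped += 1
                for allele in call.allele_pair:
                    gf.counts[allele] = gf.counts.get(allele, 0) + 1
                pair = tuple(call.allele_pair)
                gf.genotype_counts[pair] = gf.genotype_counts.get(pair, 0) + 1
    return tables


def frequency_frame(
    tables: dict[tuple[str, str], BreedFrequencyTable]
) -> pd.DataFrame:
    """Flatten frequency tables to breed x gene x allele rows for export."""
    rows = []
    for (breed, pop), table in sorted(tables.items()):
        for gene_id, gf in table.genes.items():
            if not gf.available:
                rows.append(
                    {
                        "breed": breed,
                        "population": pop,
                        "gene": gene_id,
                        "allele": "",
                        "count": 0,
                        "frequency": float("nan"),
                        "n_genotyped": 0,
                        "n_missing": gf.n_missing,
                        "status": "unavailable",
                    }
                )
                continue
            for allele, count in sorted(gf.counts.items()):
                rows.append(
                    {
                        "breed": breed,
                        "population": pop,
                        "gene": gene_id,
                        "allele": allele,
                        "count": count,
                        "frequency": count / gf.n_chromosomes,
                        "n_genotyped": gf.n_genotyped,
                        "n_missing": gf.n_missing,
                        "status": "fixed" if gf.fixed == allele else "segregating",
                    }
                )
    return pd.DataFrame(rows)


def tables_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], BreedFrequencyTable]:
    """Rebuild frequency tables from an exported breed x gene x allele frame.

    Requires ``breed``, ``gene``, ``allele``, ``count`` and ``n_genotyped``
    columns; ``population`` is optional.  Inverse of :func:`frequency_frame`
    up to row ordering.
    """
    required = {"breed", "gene", "allele", "count", "n_genotyped"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"frequency table lacks columns: {sorted(missing)}")
    tables: dict[tuple[str, str], BreedFrequencyTable] = {}
    for _, row in frame.iterrows():
        pop = str(row["population"]) if "population" in frame.columns and pd.notna(row["population"]) else ""
        key = (str(row["breed"]), pop)
        table = tables.setdefault(key, BreedFrequencyTable(key[0], pop))
        gene = str(row["gene"])
        gf = table.genes.setdefault(gene, GeneFrequency(gene))
        allele = str(row["allele"])
        if allele:
            gf.counts[allele] = int(row["count"])
            gf.n_genotyped = int(row["n_genotyped"])
    for table in tables.values():
        for gf in table.genes.values():
            if gf.available and sum(gf.counts.values()) != gf.n_chromosomes:
                raise ValueError(
                    f"{table.breed}/{gf.gene_id}: allele counts do not sum to "
                    f"2 x n_genotyped"
                )
    return tables
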