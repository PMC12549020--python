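"""Cross-species matrisome-complexity comparison via orthogroup sharing.

For an in-silico matrisome to be comparable to curated published matrisomes,
only proteins from orthogroups shared with at least one published (reference)
matrisome are counted; the filtered matrisome size is then plotted against the
number of distinct orthogroups those proteins occupy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import OrthogroupTable

__all__ = [
    "MatrisomeComplexityRecord",
    "shared_orthogroup_filter",
    "complexity_table",
    "write_complexity_table",
]


@dataclass(frozen=True)
class MatrisomeComplexityRecord:
    species: str
    filtered_matrisome_size: int
    orthogroup_count: int
    gene_count: Optional[int] = None  # after id mapping, when supplied

    def __post_init__(self) -> None:
        if self.filtered_matrisome_size < 0 or self.orthogroup_count < 0:
            raise ValueError("counts must be nonnegative")
        if self.orthogroup_count > self.filtered_matrisome_size:
            raise ValueError("orthogroup_count cannot exceed matrisome size")


def shared_orthogroup_filter(
    target_species: str,
    target_matrisome: set[str],
    table: OrthogroupTable,
    reference_sets: Mapping[str, set[str]],
) -> set[str]:
    """Keep target-matrisome genes whose orthogroup is shared with a reference.

    A gene survives iff its orthogroup contains at least one gene belonging to
    at least one reference species' matrisome set.  Genes without an
    orthogroup are excluded.  Idempotent, and monotone in the reference sets.
    """
    if target_species not in table.species:
        raise KeyError(f"unknown target species {target_species!r}")
    gene_to_og = table.gene_to_group(target_species)
    # orthogroups containing >=1 reference-matrisome gene
    shared_ogs: set[str] = set()
    for og, by_sp in table.groups.items():
        for sp, ref in reference_sets.items():
            if sp == target_species:
                continue
            if ref & set(by_sp.get(sp, ())):
                shared_ogs.add(og)
                break
    return {g for g in target_matrisome
            if g in gene_to_og and gene_to_og[g] in shared_ogs}


def complexity_table(
    entries: Sequence[tuple[str, set[str]]],
    table: OrthogroupTable,
    reference_sets: Mapping[str, set[str]],
    gene_map: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[MatrisomeComplexityRecord]:
    """One complexity record per species, ordered by species name.

    ``gene_map`` optionally maps protein ids to gene ids per species (isoform
    collapse happens upstream; the mapping is 1:1); when supplied the record
    also reports the distinct mapped gene count.
    """
    records = []
    for species, matrisome in sorted(entries, key=lambda e: e[0]):
        filtered = shared_orthogroup_filter(
            species, matrisome, table, reference_sets)
        gene_to_og = table.gene_to_group(species)
        ogs = {gene_to_og[g] for g in filtered}
        gene_count = None
        if gene_map is not None and species in gene_map:
            mapping = gene_map[species]
            gene_count = len({mapping.get(p, p) for p in filtered})
        records.append(MatrisomeComplexityRecord(
            species, len(filtered), len(ogs), gene_count))
    return records


def write_complexity_table(
    records: Sequence[MatrisomeComplexityRecord], path: str | Path
) -> None:
    pd.DataFrame([{
        "species": r.species,
        "filtered_matrisome_size": r.filtered_matrisome_size,
        "orthogroup_count": r.orthogroup_count,
        "gene_count": "" if r.gene_count is None else r.gene_count,
    } for r in records]).to_csv(path, sep="\t", index=False)
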