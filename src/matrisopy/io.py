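"""Readers and writers for the external formats the pipeline consumes.

All tabular formats are plain TSV; every reader has a matching writer and the
pair round-trips (``read(write(x)) == x``).  Coordinates in domain-annotation
tables are 1-based inclusive, following the common annotation-export
convention; this is the single place where that convention is enforced.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "SignalPrediction",
    "LocalizationPrediction",
    "OrthogroupTable",
    "DomainTableDialect",
    "read_fasta",
    "write_fasta",
    "read_domain_annotations",
    "write_domain_annotations",
    "read_signal_predictions",
    "write_signal_predictions",
    "read_localization_predictions",
    "write_localization_predictions",
    "read_orthogroups",
    "write_orthogroups",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: an identifier plus an optional amino-acid sequence."""

    protein_id: str
    sequence: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.sequence is not None:
            bad = set(self.sequence.upper()) - _AA_ALPHABET
            if bad:
                raise ValueError(
                    f"{self.protein_id}: non-amino-acid characters {sorted(bad)}"
                )


@dataclass(frozen=True)
class DomainHit:
    """A single domain annotation on a protein.

    ``start``/``end`` are 1-based inclusive residue coordinates.  ``source_db``
    names the member database (Pfam, SMART, ...) or ``InterPro`` for the
    integrated accession.  Missing e-values stay missing (``None``), never 0.
    """

    protein_id: str
    source_db: str
    domain_id: str
    domain_name: str = ""
    start: int = 1
    end: int = 1
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.domain_id:
            raise ValueError("domain_id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.domain_id}: invalid coordinates "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("e-value must be nonnegative")


@dataclass(frozen=True)
class SignalPrediction:
    protein_id: str
    has_signal: bool
    probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("signal probability must lie in [0, 1]")


@dataclass(frozen=True)
class LocalizationPrediction:
    protein_id: str
    compartment: str
    membrane_flag: bool = False
    probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("localization probability must lie in [0, 1]")


@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup id -> species -> gene-id list."""

    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for og, by_sp in self.groups.items():
            for sp, genes in by_sp.items():
                for g in genes:
                    key = (sp, g)
                    if key in seen and seen[key] != og:
                        raise ValueError(
                            f"gene {g} of {sp} appears in both {seen[key]} and {og}"
                        )
                    seen[key] = og

    def group_of(self, species: str, gene: str) -> Optional[str]:
        for og, by_sp in self.groups.items():
            if gene in by_sp.get(species, ()):  # pragma: no branch
                return og
        return None

    def gene_to_group(self, species: str) -> dict[str, str]:
        """Fast lookup map gene -> orthogroup for one species."""
        out: dict[str, str] = {}
        for og, by_sp in self.groups.items():
            for g in by_sp.get(species, ()):
                out[g] = og
        return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` entries.

    Sequences are uppercased.  Duplicate identifiers are an error because the
    classification cascade keys everything by protein id.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA id: {rec.id}")
            seen.add(rec.id)
            desc = (rec.description[len(rec.id):].strip()
                    if rec.description else "")
            records.append(ProteinRecord(rec.id, str(rec.seq).upper(), desc))
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: not valid FASTA: {exc}") from None
    if not records and Path(path).stat().st_size > 0:
        raise FormatError(f"{path}: no FASTA records found in non-empty file")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence or ""), id=r.protein_id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain annotation table (InterProScan-style TSV)

@dataclass(frozen=True)
class DomainTableDialect:
    """Column layout of a tab-separated domain-annotation export.

    Indices are 0-based column positions.  ``interpro_col`` may be ``None``
    when the export carries no integrated InterPro accession; unknown extra
    columns are ignored.  The shipped default mirrors the standard 11+ column
    InterProScan TSV layout.
    """

    protein_col: int = 0
    source_db_col: int = 3
    accession_col: int = 4
    name_col: int = 5
    start_col: int = 6
    end_col: int = 7
    evalue_col: int = 8
    interpro_col: Optional[int] = 11
    interpro_name_col: Optional[int] = 12

    @property
    def min_columns(self) -> int:
        cols = [self.protein_col, self.source_db_col, self.accession_col,
                self.name_col, self.start_col, self.end_col, self.evalue_col]
        return max(cols) + 1


DEFAULT_DIALECT = DomainTableDialect()


def _parse_evalue(text: str) -> Optional[float]:
    text = text.strip()
    if text in ("", "-", "NA", "nan"):
        return None
    value = float(text)
    if math.isnan(value):
        return None
    return value


def read_domain_annotations(
    path: str | Path, dialect: DomainTableDialect = DEFAULT_DIALECT
) -> list[DomainHit]:
    """Read a tab-separated domain-annotation export.

    Each row yields one :class:`DomainHit` for the member-database accession;
    rows carrying an integrated InterPro accession yield a second hit with
    ``source_db="InterPro"`` on the same coordinates, so downstream rule sets
    can match either accession space.  Rows for one protein keep file order.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < dialect.min_columns:
                raise FormatError(
                    f"{path}:{lineno}: expected at least {dialect.min_columns} "
                    f"columns, found {len(cells)}"
                )
            try:
                start = int(cells[dialect.start_col])
                end = int(cells[dialect.end_col])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: malformed coordinates: {exc}"
                ) from None
            evalue = _parse_evalue(cells[dialect.evalue_col])
            try:
                hits.append(DomainHit(
                    protein_id=cells[dialect.protein_col].strip(),
                    source_db=cells[dialect.source_db_col].strip(),
                    domain_id=cells[dialect.accession_col].strip(),
                    domain_name=cells[dialect.name_col].strip(),
                    start=start, end=end, evalue=evalue,
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if dialect.interpro_col is not None and len(cells) > dialect.interpro_col:
                ipr = cells[dialect.interpro_col].strip()
                if ipr and ipr != "-":
                    name = ""
                    if (dialect.interpro_name_col is not None
                            and len(cells) > dialect.interpro_name_col):
                        name = cells[dialect.interpro_name_col].strip()
                    hits.append(DomainHit(
                        protein_id=cells[dialect.protein_col].strip(),
                        source_db="InterPro", domain_id=ipr, domain_name=name,
                        start=start, end=end, evalue=evalue,
                    ))
    return hits


def write_domain_annotations(
    hits: list[DomainHit], path: str | Path,
    dialect: DomainTableDialect = DEFAULT_DIALECT,
) -> None:
    """Write hits in the dialect's layout (InterPro hits as extra columns).

    Hits with ``source_db == "InterPro"`` that share protein/coordinates with
    the immediately preceding member-database hit are folded back into that
    row's InterPro columns, mirroring how :func:`read_domain_annotations`
    expands them.
    """
    ncols = dialect.min_columns
    if dialect.interpro_col is not None:
        ncols = max(ncols, (dialect.interpro_name_col or dialect.interpro_col) + 1)
    rows: list[list[str]] = []
    for hit in hits:
        if (hit.source_db == "InterPro" and dialect.interpro_col is not None and rows):
            prev = rows[-1]
            same_locus = (
                prev[dialect.protein_col] == hit.protein_id
                and prev[dialect.start_col] == str(hit.start)
                and prev[dialect.end_col] == str(hit.end)
                and prev[dialect.interpro_col] == "-"
            )
            if same_locus:
                prev[dialect.interpro_col] = hit.domain_id
                if dialect.interpro_name_col is not None:
                    prev[dialect.interpro_name_col] = hit.domain_name
                continue
        row = ["-"] * ncols
        row[dialect.protein_col] = hit.protein_id
        row[dialect.source_db_col] = hit.source_db
        row[dialect.accession_col] = hit.domain_id
        row[dialect.name_col] = hit.domain_name
        row[dialect.start_col] = str(hit.start)
        row[dialect.end_col] = str(hit.end)
        row[dialect.evalue_col] = "" if hit.evalue is None else repr(hit.evalue)
        rows.append(row)
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Signal-peptide / localization tables

def read_signal_predictions(path: str | Path) -> dict[str, SignalPrediction]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out = {}
    for row in df.itertuples(index=False):
        out[row.protein_id] = SignalPrediction(
            row.protein_id, bool(row.has_signal), float(row.probability))
    return out


def write_signal_predictions(
    preds: dict[str, SignalPrediction], path: str | Path
) -> None:
    pd.DataFrame(
        [dataclasses.asdict(p) for p in preds.values()]
    ).to_csv(path, sep="\t", index=False)


def read_localization_predictions(
    path: str | Path,
) -> dict[str, LocalizationPrediction]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out = {}
    for row in df.itertuples(index=False):
        out[row.protein_id] = LocalizationPrediction(
            row.protein_id, str(row.compartment), bool(row.membrane_flag),
            float(row.probability))
    return out


def write_localization_predictions(
    preds: dict[str, LocalizationPrediction], path: str | Path
) -> None:
    pd.DataFrame(
        [dataclasses.asdict(p) for p in preds.values()]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Orthogroup membership table (wide TSV, one species per column)

_GENE_SEP = ", "


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Read a wide orthogroup table: first column orthogroup id, one column
    per species, cells are ", "-separated gene lists (whitespace tolerated)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise FormatError(f"{path}: missing header line")
    header = lines[0].split("\t")
    species = [s.strip() for s in header[1:]]
    groups: dict[str, dict[str, list[str]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                f"header has {len(header)})"
            )
        og = cells[0].strip().rstrip(":")
        if og in groups:
            raise FormatError(f"{path}:{lineno}: duplicate orthogroup id {og}")
        groups[og] = {
            sp: [g.strip() for g in cell.split(",") if g.strip()]
            for sp, cell in zip(species, cells[1:])
        }
    return OrthogroupTable(groups=groups, species=species)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["Orthogroup"] + table.species) + "\n")
        for og, by_sp in table.groups.items():
            cells = [_GENE_SEP.join(by_sp.get(sp, [])) for sp in table.species]
            fh.write("\t".join([og] + cells) + "\n")


# The intensity-matrix reader/writer lives with the TMT container it builds;
# re-exported here so this module covers every external format.
from .tmt import (TMTExperiment, read_intensity_table,  # noqa: E402,F401
                  write_intensity_table)

__all__ += ["TMTExperiment", "read_intensity_table", "write_intensity_table"]
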