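"""Readers and writers for the pipeline's file formats.

Sequences travel as FASTA with ``gene_id|species`` headers; tabular data
(ortholog pairs, paralogs, SNP counts, gene groups) as TSV with a header
row, ``NA`` for missing values and ``.`` decimals, mirroring HomoloGene /
BioMart export style.  The dataclasses here are the shared vocabulary of
every downstream stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("imprintdiv")

DEFAULT_SPECIES = ("human", "mouse", "rat", "cow", "chimpanzee", "dog", "chicken")

GROUPS = ("maternal", "paternal", "background")

_VALID_DNA = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file (bad header, bad characters, bad row)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass(frozen=True)
class CodingSequence:
    """A coding DNA sequence for one gene in one species."""

    gene_id: str
    species: str
    dna: str
    frame_validated: bool = False

    def __post_init__(self) -> None:
        if self.frame_validated:
            if len(self.dna) == 0 or len(self.dna) % 3 != 0:
                raise ValidationError(
                    f"{self.gene_id}|{self.species}: frame-validated CDS length "
                    f"{len(self.dna)} is not a positive multiple of 3"
                )

    def __len__(self) -> int:
        return len(self.dna)


@dataclass
class GenePairRecord:
    """One HomoloGene-style ortholog pair row.

    ``ks`` carries three states: a float (usable), None (missing / NA), or the
    string flag on ``ks_discarded`` for the database sentinel -1, which is
    never used numerically.
    """

    gene_id: str
    species_a: str
    species_b: str
    protein_identity: float
    cdna_identity: float
    gap_count: int = 0
    ka: float | None = None
    ks: float | None = None
    ks_discarded: bool = False

    def __post_init__(self) -> None:
        for name in ("protein_identity", "cdna_identity"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValidationError(f"{self.gene_id}: {name}={v} outside [0, 100]")
        if self.ks is not None and self.ks == -1:
            # sentinel must be mapped at read time, never stored numerically
            object.__setattr__(self, "ks", None)
            self.ks_discarded = True

    @property
    def ka_ks(self) -> float | None:
        """Ka/Ks ratio; defined only when Ks is present, usable and > 0."""
        if self.ks_discarded or self.ks is None or self.ka is None or self.ks <= 0:
            return None
        return self.ka / self.ks


@dataclass(frozen=True)
class ParalogRecord:
    """One Ensembl/BioMart-style paralog row; rank 1 = most recent duplicate."""

    gene_id: str
    paralog_id: str
    rank: int
    paralog_chromosome: str
    protein_identity: float
    n_paralogs: int = 1

    @property
    def on_x(self) -> bool:
        return self.paralog_chromosome.upper() == "X"


@dataclass(frozen=True)
class SnpRecord:
    gene_id: str
    coding_length_bp: int
    snp_count: int

    def __post_init__(self) -> None:
        if self.coding_length_bp <= 0:
            raise ValidationError(f"{self.gene_id}: coding length must be positive")
        if self.snp_count < 0:
            raise ValidationError(f"{self.gene_id}: negative SNP count")

    @property
    def density_per_kb(self) -> float:
        return self.snp_count / (self.coding_length_bp / 1000.0)


@dataclass(frozen=True)
class GeneGroupAssignment:
    gene_id: str
    group: str
    has_paralog: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.gene_id}: unknown group {self.group!r}; expected one of {GROUPS}"
            )

    @property
    def imprinted(self) -> bool:
        return self.group in ("maternal", "paternal")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path,
    species: Iterable[str] = DEFAULT_SPECIES,
    separator: str = "|",
) -> list[CodingSequence]:
    """Read coding sequences from FASTA with ``gene_id|species`` headers.

    Sequences are upper-cased; characters outside {A, C, G, T, N} are
    rejected.  Order of records is preserved.
    """
    path = Path(path)
    known = set(species)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty FASTA (no records)")
    out: list[CodingSequence] = []
    for rec in records:
        parts = rec.id.split(separator)
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(
                f"{path}: header {rec.id!r} does not follow 'gene_id{separator}species'"
            )
        gene_id, sp = parts
        if known and sp not in known:
            raise FormatError(f"{path}: record {rec.id!r} has unknown species {sp!r}")
        dna = str(rec.seq).upper()
        bad = set(dna) - _VALID_DNA
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        out.append(CodingSequence(gene_id=gene_id, species=sp, dna=dna))
    return out


def write_fasta(
    sequences: Iterable[CodingSequence], path: str | Path, separator: str = "|"
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in sequences:
            fh.write(f">{s.gene_id}{separator}{s.species}\n{s.dna}\n")


# ---------------------------------------------------------------------------
# TSV tables


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return str(v)


def _parse_float(v: str) -> float | None:
    return None if v in ("NA", "", None) else float(v)


def read_gene_pair_table(path: str | Path) -> list[GenePairRecord]:
    """Read a HomoloGene-style ortholog pair TSV.

    Rows with the Ks sentinel -1 are retained but flagged discarded so they
    still serve identity analyses while never entering Ks or Ka/Ks ones.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "species_a", "species_b", "protein_identity", "cdna_identity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: list[GenePairRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            ks_raw = _parse_float(d.get("ks"))
            discarded = ks_raw is not None and ks_raw == -1
            records.append(
                GenePairRecord(
                    gene_id=d["gene_id"],
                    species_a=d["species_a"],
                    species_b=d["species_b"],
                    protein_identity=_parse_float(d["protein_identity"]),
                    cdna_identity=_parse_float(d["cdna_identity"]),
                    gap_count=int(d.get("gap_count") or 0),
                    ka=_parse_float(d.get("ka")),
                    ks=None if discarded else ks_raw,
                    ks_discarded=discarded,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_gene_pair_table(records: Iterable[GenePairRecord], path: str | Path) -> None:
    cols = ["gene_id", "species_a", "species_b", "protein_identity", "cdna_identity",
            "gap_count", "ka", "ks"]
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            ks = "-1" if r.ks_discarded else _fmt(r.ks)
            fh.write("\t".join([
                r.gene_id, r.species_a, r.species_b,
                _fmt(r.protein_identity), _fmt(r.cdna_identity),
                str(r.gap_count), _fmt(r.ka), ks,
            ]) + "\n")


def read_paralog_table(path: str | Path) -> list[ParalogRecord]:
    """Read a BioMart-style paralog TSV; rows re-sorted by rank within gene."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "paralog_id", "rank", "paralog_chromosome", "protein_identity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: list[ParalogRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            records.append(
                ParalogRecord(
                    gene_id=d["gene_id"],
                    paralog_id=d["paralog_id"],
                    rank=int(d["rank"]),
                    paralog_chromosome=d["paralog_chromosome"],
                    protein_identity=_parse_float(d["protein_identity"]),
                    n_paralogs=int(d.get("n_paralogs") or 1),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    records.sort(key=lambda r: (r.gene_id, r.rank))
    seen: dict[tuple[str, int], int] = {}
    for r in records:
        key = (r.gene_id, r.rank)
        if key in seen:
            raise ValidationError(f"{path}: duplicate rank {r.rank} for gene {r.gene_id}")
        seen[key] = 1
    return records


def write_paralog_table(records: Iterable[ParalogRecord], path: str | Path) -> None:
    cols = ["gene_id", "paralog_id", "rank", "paralog_chromosome",
            "protein_identity", "n_paralogs"]
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.gene_id, r.paralog_id, str(r.rank), r.paralog_chromosome,
                _fmt(r.protein_identity), str(r.n_paralogs),
            ]) + "\n")


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "coding_length_bp", "snp_count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            records.append(SnpRecord(d["gene_id"], int(d["coding_length_bp"]), int(d["snp_count"])))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_snp_table(records: Iterable[SnpRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tcoding_length_bp\tsnp_count\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.coding_length_bp}\t{r.snp_count}\n")


def read_group_file(path: str | Path) -> list[GeneGroupAssignment]:
    """Read the gene-group TSV; a gene may appear in exactly one group."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    seen: set[str] = set()
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        if d["gene_id"] in seen:
            raise ValidationError(f"{path}: row {i}: gene {d['gene_id']} assigned twice")
        seen.add(d["gene_id"])
        has_paralog = str(d.get("has_paralog", "")).lower() in ("1", "true", "yes")
        records.append(GeneGroupAssignment(d["gene_id"], d["group"], has_paralog))
    return records


def write_group_file(records: Iterable[GeneGroupAssignment], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tgroup\thas_paralog\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.group}\t{str(r.has_paralog).lower()}\n")


# ---------------------------------------------------------------------------
# JSON config


@dataclass
class PipelineConfig:
    """Run-wide settings: species list, genetic code, thresholds."""

    species: tuple[str, ...] = DEFAULT_SPECIES
    genetic_code_id: int = 1
    ks_saturation_threshold: float = 2.5
    lrt_threshold: float = 2.71
    identity_denominator: str = "all_columns"  # or "ungapped_columns"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "species" in data:
            data["species"] = tuple(data["species"])
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["species"] = list(d["species"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")
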