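"""Reading and writing the pipeline's file formats.

The pipeline works at the protein level: every entry is one protein isoform
carrying its gene and species identity in the FASTA header as ``key=value``
tokens (``>AT4G17570.1 gene=AT4G17570 species=ath``).  Species metadata
(taxonomic group, order, genus) travels in a separate tab-delimited table.
An optional gene→isoform map can override the header-derived gene ids.

All coordinates in this package are 0-based, half-open ``[start, end)``;
1-based positions appear only in report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: The 20 standard amino-acid one-letter codes plus X for an unknown residue.
#: B/Z/U/* and lower case are rejected at parse time rather than remapped.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: The nine taxonomic groups of the cohort, in canonical reporting order.
TAXON_GROUPS = (
    "eudicots",
    "monocots",
    "basal_angiosperm",
    "gymnosperm",
    "marchantiophyta",
    "bryophyta",
    "lycopodiophyta",
    "charophyta",
    "chlorophytae",
)

FASTA_WRAP = 60


@dataclass(frozen=True)
class ProteinRecord:
    """One protein isoform with its gene and species identity."""

    protein_id: str
    gene_id: str
    species_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpeciesInfo:
    """Species metadata: display name, taxonomic group, order and genus.

    ``order`` is empty for non-angiosperms; ``genus`` defaults to the first
    whitespace-delimited token of ``name`` when not supplied explicitly.
    """

    species_id: str
    name: str
    group: str
    order: str = ""
    genus: str = ""

    def __post_init__(self):
        if self.group not in TAXON_GROUPS:
            raise ValueError(
                f"unknown taxonomic group {self.group!r} for species "
                f"{self.species_id!r}; legal values: {', '.join(TAXON_GROUPS)}"
            )
        if not self.genus:
            object.__setattr__(self, "genus", self.name.split()[0] if self.name else "")


@dataclass
class IsoformGroup:
    """All isoforms of one gene, with alternative-splicing annotations.

    ``utr_only`` and ``change_event`` are filled in by
    :mod:`gatascan.isoforms`; they stay ``None`` until computed.
    """

    gene_id: str
    species_id: str
    isoform_ids: list[str] = field(default_factory=list)
    utr_only: bool | None = None
    change_event: str | None = None

    @property
    def n_forms(self) -> int:
        return len(self.isoform_ids)


def _parse_header(line: str) -> tuple[str, str | None, str | None]:
    tokens = line[1:].split()
    if not tokens:
        raise ValueError("FASTA header with no protein id")
    protein_id = tokens[0]
    gene = species = None
    for tok in tokens[1:]:
        if tok.startswith("gene="):
            gene = tok[5:]
        elif tok.startswith("species="):
            species = tok[8:]
    return protein_id, gene, species


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA file into a list of :class:`ProteinRecord`.

    Headers carry the protein id first, then optional ``gene=`` and
    ``species=`` tokens.  A missing ``gene=`` defaults the gene id to the
    protein id; a missing ``species=`` defaults to ``"NA"``.

    Raises
    ------
    ValueError
        On a duplicate protein id, a character outside the 21-letter
        alphabet (reported with its line number), or an empty sequence.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()

    header: tuple[str, str | None, str | None] | None = None
    chunks: list[str] = []
    header_line = 0

    def flush():
        if header is None:
            return
        protein_id, gene, species = header
        seq = "".join(chunks)
        if not seq:
            raise ValueError(
                f"{path}: empty sequence for {protein_id!r} (header at line {header_line})"
            )
        if protein_id in seen:
            raise ValueError(f"{path}: duplicate protein id {protein_id!r}")
        seen.add(protein_id)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                gene_id=gene if gene is not None else protein_id,
                species_id=species if species is not None else "NA",
                sequence=seq,
            )
        )

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = _parse_header(line)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header at line {lineno}")
                body = line.strip()
                bad = set(body) - AMINO_ALPHABET
                if bad:
                    raise ValueError(
                        f"{path}: illegal residue character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(body)
        flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapping sequences at 60 columns.

    ``read_fasta`` inverts this exactly (identity on protein_id, gene_id,
    species_id and sequence).
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id} gene={rec.gene_id} species={rec.species_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def read_species_table(path: str | Path) -> dict[str, SpeciesInfo]:
    """Read the species metadata TSV (species_id, name, group, order, genus).

    ``order`` and ``genus`` may be empty; an empty genus falls back to the
    first token of the species name.  Unknown group strings and duplicate
    species ids are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"species_id", "name", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: species table missing column(s) {sorted(missing)}")
    out: dict[str, SpeciesInfo] = {}
    for row in df.itertuples(index=False):
        sid = row.species_id
        if sid in out:
            raise ValueError(f"{path}: duplicate species_id {sid!r}")
        out[sid] = SpeciesInfo(
            species_id=sid,
            name=row.name,
            group=row.group,
            order=getattr(row, "order", "") or "",
            genus=getattr(row, "genus", "") or "",
        )
    return out


def write_species_table(species: Mapping[str, SpeciesInfo], path: str | Path) -> None:
    rows = [
        {
            "species_id": s.species_id,
            "name": s.name,
            "group": s.group,
            "order": s.order,
            "genus": s.genus,
        }
        for s in species.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_isoform_map(path: str | Path) -> dict[str, str]:
    """Read a gene→isoform TSV (columns gene_id, protein_id).

    Returns a protein_id → gene_id mapping used to override header-derived
    gene ids via :func:`apply_isoform_map`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"gene_id", "protein_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: isoform map missing column(s) {sorted(missing)}")
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.protein_id in mapping:
            raise ValueError(f"{path}: protein {row.protein_id!r} mapped to two genes")
        mapping[row.protein_id] = row.gene_id
    return mapping


def apply_isoform_map(
    records: Iterable[ProteinRecord], mapping: Mapping[str, str]
) -> list[ProteinRecord]:
    """Return records with gene ids overridden where the map supplies one."""
    return [
        replace(rec, gene_id=mapping[rec.protein_id]) if rec.protein_id in mapping else rec
        for rec in records
    ]


def build_isoform_groups(records: Iterable[ProteinRecord]) -> list[IsoformGroup]:
    """Group records into one :class:`IsoformGroup` per (species, gene).

    Groups are ordered by (species_id, gene_id) and isoform ids within a
    group are sorted, so the output is deterministic regardless of input
    order.  The total of ``n_forms`` over groups equals the number of
    records (conservation of isoforms).
    """
    buckets: dict[tuple[str, str], list[str]] = {}
    for rec in records:
        buckets.setdefault((rec.species_id, rec.gene_id), []).append(rec.protein_id)
    return [
        IsoformGroup(gene_id=gene, species_id=species, isoform_ids=sorted(ids))
        for (species, gene), ids in sorted(buckets.items())
    ]
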