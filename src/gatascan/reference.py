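"""Published reference census of plant GATA transcription factors.

The package ships three small tab-delimited tables transcribed from a
genome-wide census of GATA TFs in 165 plant species (the cohort this
pipeline is designed to reproduce):

* ``species_census.tsv`` — per species: taxonomic group, order, genus,
  number of GATA genes, number of GATA TF isoforms, and how many genes
  have alternative-splicing forms (grand totals: 4,762 genes, 5,335 TFs,
  329 AS genes, 902 AS isoforms);
* ``domain_type_census.tsv`` — domain-type × group counts of the 5,536
  zinc-finger domains found on those TFs;
* ``as_form_census.tsv`` — AS genes by number of isoforms (2–12) × group.

These serve as realistic parameterizations for the synthetic generator and
as arithmetic fixtures for the summary operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import SpeciesInfo
from .summaries import GroupDomainTable


def _read(name: str) -> pd.DataFrame:
    with resources.files("gatascan.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_species_census() -> pd.DataFrame:
    """Per-species census, indexed by species_id, with columns name, group,
    order, genus, n_genes, n_tfs, n_as_genes, n_as_tfs."""
    return _read("species_census.tsv").set_index("species_id")


def census_species_info() -> dict[str, SpeciesInfo]:
    """The census species as a species_id → :class:`SpeciesInfo` mapping."""
    df = load_species_census()
    return {
        sid: SpeciesInfo(
            species_id=sid,
            name=row["name"],
            group=row["group"],
            order=row["order"],
            genus=row["genus"],
        )
        for sid, row in df.iterrows()
    }


def load_domain_type_census() -> GroupDomainTable:
    """Domain-type × group counts wrapped for ratio computation."""
    df = _read("domain_type_census.tsv").set_index("dtype")
    return GroupDomainTable(counts=df.astype(int))


def load_as_form_census() -> pd.DataFrame:
    """AS genes by number of forms (index) × group (columns)."""
    return _read("as_form_census.tsv").set_index("n_forms").astype(int)
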