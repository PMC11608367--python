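"""Cohort-level summary tables.

Produces the per-species census (genes, TF isoforms, alternative-splicing
genes), the domain-type × taxonomic-group count table with its percentage
ratio column, descriptive statistics of gene counts and sequence lengths
over a chosen set of groups, and genus/order aggregations.

Conventions: domain totals count every isoform's hits separately (a gene
with three isoforms each carrying one IVb contributes three IVb domains) —
the census tallies domains over TF isoforms, not genes.  Count/length
bands are closed intervals.  Reported means and ratios are rounded
half-up to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import IsoformGroup, ProteinRecord, SpeciesInfo, TAXON_GROUPS, build_isoform_groups
from .scanner import DOMAIN_TYPES, DomainHit
from .utils import pct, round_half_up

#: Reporting order of domain types in the group-domain table.
DTYPE_ORDER = ("IVb", "IVc", "IVp", "IV4", "IVa", "IVe")


def species_summary(
    records: Iterable[ProteinRecord],
    groups: Iterable[IsoformGroup] | None = None,
) -> pd.DataFrame:
    """One row per species: n_genes, n_tfs, n_as_genes (genes with ≥2
    isoforms) and n_as_tfs (isoforms of those genes).  Sorted by
    species_id."""
    records = list(records)
    if groups is None:
        groups = build_isoform_groups(records)
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        row = rows.setdefault(
            rec.species_id, {"n_genes": 0, "n_tfs": 0, "n_as_genes": 0, "n_as_tfs": 0}
        )
        row["n_tfs"] += 1
    for g in groups:
        row = rows[g.species_id]
        row["n_genes"] += 1
        if g.n_forms >= 2:
            row["n_as_genes"] += 1
            row["n_as_tfs"] += g.n_forms
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "species_id"
    return df


@dataclass
class GroupDomainTable:
    """Domain-type × taxonomic-group counts with totals and a percentage
    ratio per type (type total / grand total × 100, half-up, 2 decimals)."""

    counts: pd.DataFrame  # index: dtype, columns: the nine groups

    @property
    def dtype_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def group_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def ratios(self) -> pd.Series:
        """Percent of the grand total per domain type."""
        grand = self.grand_total
        if grand == 0:
            return pd.Series(0.0, index=self.counts.index)
        return pd.Series(
            [pct(int(t), grand) for t in self.dtype_totals],
            index=self.counts.index,
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["total"] = self.dtype_totals
        out["ratio_pct"] = self.ratios
        out.index.name = "dtype"
        return out

    @classmethod
    def from_counts(cls, counts: Mapping[str, Sequence[int]]) -> "GroupDomainTable":
        """Build directly from per-type count vectors over the nine groups
        (canonical group order)."""
        df = pd.DataFrame(
            {g: [counts[t][i] for t in counts] for i, g in enumerate(TAXON_GROUPS)},
            index=list(counts),
        )
        return cls(counts=df.astype(int))


def group_domain_table(
    hits_by_isoform: Mapping[str, Sequence[DomainHit]],
    records: Iterable[ProteinRecord],
    species: Mapping[str, SpeciesInfo],
) -> GroupDomainTable:
    """Count every resolved hit once in its (domain type, group) cell."""
    species_of = {r.protein_id: r.species_id for r in records}
    counts = pd.DataFrame(0, index=list(DTYPE_ORDER), columns=list(TAXON_GROUPS), dtype=int)
    for pid, hits in hits_by_isoform.items():
        if not hits:
            continue
        sid = species_of.get(pid, pid)
        info = species.get(sid)
        if info is None:
            raise KeyError(
                f"hit on protein {pid!r} references species {sid!r} absent "
                f"from the species table"
            )
        for h in hits:
            counts.loc[h.dtype, info.group] += 1
    return GroupDomainTable(counts=counts)


def _band_stats(values: Sequence[int | float], band: tuple[float, float]) -> dict:
    lo, hi = band
    if lo > hi:
        raise ValueError(f"band lower bound {lo} exceeds upper bound {hi}")
    n = len(values)
    n_in = sum(1 for v in values if lo <= v <= hi)
    total = sum(values)
    return {
        "min": min(values),
        "max": max(values),
        "mean": float(round_half_up(Decimal(int(total)) / Decimal(n), 2)),
        "n_in_band": n_in,
        "fraction_in_band": n_in / n,
    }


def _species_in_groups(
    species: Mapping[str, SpeciesInfo], group_set: Iterable[str]
) -> set[str]:
    wanted = set(group_set)
    unknown = wanted - set(TAXON_GROUPS)
    if unknown:
        raise ValueError(f"unknown group(s) {sorted(unknown)}")
    return {sid for sid, info in species.items() if info.group in wanted}


def gene_count_stats(
    summaries: pd.DataFrame,
    species: Mapping[str, SpeciesInfo],
    group_set: Iterable[str],
    band: tuple[int, int],
) -> dict:
    """min/max/mean gene count over the species of ``group_set`` plus how
    many fall inside the closed ``band`` (e.g. the common 15–40 range)."""
    keep = _species_in_groups(species, group_set)
    sel = summaries.loc[summaries.index.isin(keep), "n_genes"]
    if sel.empty:
        raise ValueError(f"no species in groups {sorted(set(group_set))}")
    return _band_stats([int(v) for v in sel], band)


def length_stats(
    records: Iterable[ProteinRecord],
    species: Mapping[str, SpeciesInfo],
    group_set: Iterable[str],
    band: tuple[int, int],
) -> dict:
    """As :func:`gene_count_stats` but over TF sequence lengths (the
    canonical angiosperm band is 100–400 residues)."""
    keep = _species_in_groups(species, group_set)
    lengths = [rec.length for rec in records if rec.species_id in keep]
    if not lengths:
        raise ValueError(f"no records in groups {sorted(set(group_set))}")
    return _band_stats(lengths, band)


def genus_aggregation(
    summaries: pd.DataFrame, species: Mapping[str, SpeciesInfo]
) -> pd.DataFrame:
    """Per-genus row: n_species and min/max/mean gene counts, genus order
    lexicographic."""
    rows: dict[str, list[int]] = {}
    for sid, row in summaries.iterrows():
        info = species.get(sid)
        if info is None:
            raise KeyError(f"species {sid!r} absent from species table")
        rows.setdefault(info.genus, []).append(int(row["n_genes"]))
    out = pd.DataFrame(
        [
            {
                "genus": genus,
                "n_species": len(vals),
                "min_genes": min(vals),
                "max_genes": max(vals),
                "mean_genes": float(round_half_up(Decimal(sum(vals)) / Decimal(len(vals)), 2)),
            }
            for genus, vals in sorted(rows.items())
        ]
    ).set_index("genus")
    return out


def order_aggregation(
    summaries: pd.DataFrame,
    hits_by_isoform: Mapping[str, Sequence[DomainHit]],
    records: Iterable[ProteinRecord],
    species: Mapping[str, SpeciesInfo],
) -> pd.DataFrame:
    """Per-order row: n_species, mean gene count, and the set of domain
    types present (≥1 hit among the order's species).

    Angiosperm species aggregate under their taxonomic order;
    non-angiosperm groups have no order assignment and aggregate under
    their group name.
    """
    def label_of(info: SpeciesInfo) -> str:
        return info.order if info.order else info.group

    species_of = {r.protein_id: r.species_id for r in records}
    gene_counts: dict[str, list[int]] = {}
    for sid, row in summaries.iterrows():
        info = species.get(sid)
        if info is None:
            raise KeyError(f"species {sid!r} absent from species table")
        gene_counts.setdefault(label_of(info), []).append(int(row["n_genes"]))
    dtypes: dict[str, set[str]] = {label: set() for label in gene_counts}
    for pid, hits in hits_by_isoform.items():
        if not hits:
            continue
        info = species[species_of[pid]]
        dtypes.setdefault(label_of(info), set()).update(h.dtype for h in hits)
    out = pd.DataFrame(
        [
            {
                "order": label,
                "n_species": len(vals),
                "mean_genes": float(round_half_up(Decimal(sum(vals)) / Decimal(len(vals)), 2)),
                "dtypes_present": ",".join(
                    sorted(dtypes.get(label, set()), key=DOMAIN_TYPES.index)
                ),
            }
            for label, vals in sorted(gene_counts.items())
        ]
    ).set_index("order")
    return out
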