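"""Alternative-splicing (AS) structure of gene isoform groups.

A gene with two or more protein isoforms is an "AS gene".  Three questions
are asked of each AS gene:

* How many isoforms does it have (the AS-form distribution)?
* Is the splicing UTR-only — i.e. do all isoforms encode byte-identical
  protein sequences?  (A protein-level proxy: transcript models are not
  available from protein FASTA.)
* Does splicing change the zinc-finger domain complement — converting a
  complete domain type to a partial one (IVp), dropping a domain entirely,
  or otherwise altering the per-isoform domain-type multiset?
"""

from __future__ import annotations

from collections import Counter
from decimal import Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import IsoformGroup, ProteinRecord, SpeciesInfo, TAXON_GROUPS
from .scanner import COMPLETE_TYPES, DomainHit
from .utils import round_half_up

CHANGE_EVENTS = ("none", "partial_conversion", "domain_loss", "other_change")


def as_form_distribution(
    groups: Iterable[IsoformGroup], species: Mapping[str, SpeciesInfo]
) -> pd.DataFrame:
    """Tabulate AS genes by number of isoforms and taxonomic group.

    Rows are n_forms values from 2 up to the observed maximum; columns are
    the nine taxonomic groups plus ``total`` and ``ratio_pct`` (row total
    over total AS genes, percent, half-up to 2 decimals).  Genes with a
    single form are not counted.  Empty when there are no AS genes.
    """
    as_groups = [g for g in groups if g.n_forms >= 2]
    columns = list(TAXON_GROUPS) + ["total", "ratio_pct"]
    if not as_groups:
        return pd.DataFrame(columns=columns)
    max_forms = max(g.n_forms for g in as_groups)
    counts = pd.DataFrame(
        0, index=range(2, max_forms + 1), columns=list(TAXON_GROUPS), dtype=int
    )
    for g in as_groups:
        info = species.get(g.species_id)
        if info is None:
            raise KeyError(f"species {g.species_id!r} absent from species table")
        counts.loc[g.n_forms, info.group] += 1
    total_as = len(as_groups)
    counts["total"] = counts[list(TAXON_GROUPS)].sum(axis=1)
    counts["ratio_pct"] = [
        float(round_half_up(Decimal(int(t)) * 100 / Decimal(total_as), 2))
        for t in counts["total"]
    ]
    counts.index.name = "n_forms"
    return counts


def detect_utr_only(
    group: IsoformGroup, records: Mapping[str, ProteinRecord]
) -> bool:
    """True iff all isoform protein sequences of an AS gene are identical.

    Identical proteins across isoforms indicate splicing confined to
    untranslated regions.  Undefined (ValueError) for single-form genes.
    """
    if group.n_forms < 2:
        raise ValueError(
            f"UTR-only detection undefined for single-isoform gene {group.gene_id!r}"
        )
    seqs = {records[pid].sequence for pid in group.isoform_ids}
    return len(seqs) == 1


def _is_strict_submultiset(a: Counter, b: Counter) -> bool:
    return a != b and all(a[k] <= b[k] for k in a)


def domain_change_events(
    group: IsoformGroup, hits_by_isoform: Mapping[str, Sequence[DomainHit]]
) -> str:
    """Classify the domain-type change across one AS gene's isoforms.

    Compares per-isoform multisets of domain types:

    * ``partial_conversion`` — one isoform carries a partial (IVp) domain
      while another carries a complete type, and the multisets differ;
    * ``domain_loss`` — some isoform's multiset is a strict sub-multiset of
      another's (a domain disappears entirely);
    * ``other_change`` — multisets differ in any other way;
    * ``none`` — all multisets equal.

    Precedence when several apply: partial_conversion > domain_loss >
    other_change.  Multiset comparison deliberately avoids isoform-to-
    isoform coordinate projection, which would need genome alignment.
    """
    if group.n_forms < 2:
        raise ValueError(
            f"domain-change classification undefined for single-isoform gene "
            f"{group.gene_id!r}"
        )
    multisets = [
        Counter(h.dtype for h in hits_by_isoform.get(pid, ()))
        for pid in group.isoform_ids
    ]
    if all(ms == multisets[0] for ms in multisets[1:]):
        return "none"
    has_partial = any(ms["IVp"] > 0 for ms in multisets)
    has_complete = any(
        any(ms[t] > 0 for t in COMPLETE_TYPES) for ms in multisets
    )
    if has_partial and has_complete:
        return "partial_conversion"
    for a in multisets:
        for b in multisets:
            if _is_strict_submultiset(a, b):
                return "domain_loss"
    return "other_change"


def annotate_groups(
    groups: Iterable[IsoformGroup],
    records: Mapping[str, ProteinRecord],
    hits_by_isoform: Mapping[str, Sequence[DomainHit]],
) -> list[IsoformGroup]:
    """Fill in utr_only and change_event for every multi-isoform group.

    Single-form genes get ``utr_only=False`` and ``change_event="none"``.
    """
    out = []
    for g in groups:
        if g.n_forms >= 2:
            g.utr_only = detect_utr_only(g, records)
            g.change_event = domain_change_events(g, hits_by_isoform)
        else:
            g.utr_only = False
            g.change_event = "none"
        out.append(g)
    return out


def domain_change_table(
    groups: Iterable[IsoformGroup],
    hits_by_isoform: Mapping[str, Sequence[DomainHit]],
) -> pd.DataFrame:
    """Per-AS-gene domain accounting: gene_id, species_id, n_forms, counts
    of IVb/IVc/IVp across all isoforms, and the change event."""
    rows = []
    for g in groups:
        if g.n_forms < 2:
            continue
        tally = Counter()
        for pid in g.isoform_ids:
            tally.update(h.dtype for h in hits_by_isoform.get(pid, ()))
        rows.append(
            {
                "gene_id": g.gene_id,
                "species_id": g.species_id,
                "n_forms": g.n_forms,
                "n_IVb": tally["IVb"],
                "n_IVc": tally["IVc"],
                "n_IVp": tally["IVp"],
                "change_event": domain_change_events(g, hits_by_isoform),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "species_id", "n_forms", "n_IVb", "n_IVc", "n_IVp",
                 "change_event"],
    )
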