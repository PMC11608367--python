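"""Class-IV zinc-finger GATA domain scanning and typing.

The GATA DNA-binding domain is a four-cysteine zinc finger written
CX\\ :sub:`2`\\ CX\\ :sub:`n`\\ CX\\ :sub:`2`\\ C, where the spacer *n* between
the second and third cysteines defines the domain type:

=========  ==============  =============
type       spacer1 (C1-C2)  spacer2 (C2-C3)
=========  ==============  =============
IVa        2               17
IVb        2               18
IVc        2               20
IV4        4               18
IVe        2               16, 19 or 21
IVp        partial motif (one or more anchor cysteines missing)
=========  ==============  =============

Spacers count residues *strictly between* consecutive anchor cysteines, so
the canonical IVb domain spans 26 residues with cysteines at internal
1-based positions 1, 4, 23 and 26.  Complete candidates are enumerated over
all cysteine quadruples, partial (IVp) candidates are matched against three
truncation templates and filtered on the IVb consensus, and overlaps are
resolved by an explicit deterministic priority.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import ProteinRecord

COMPLETE_TYPES = ("IVa", "IVb", "IVc", "IV4", "IVe")
DOMAIN_TYPES = COMPLETE_TYPES + ("IVp",)

#: (spacer1, spacer2) → domain type for complete four-cysteine motifs.
#: IVe covers the odd inner spacers 16/19/21 that no named type claims;
#: spacer1 = 4 is legal only with spacer2 = 18 (the one known IV4 form).
SPACER_TABLE = {
    (2, 17): "IVa",
    (2, 18): "IVb",
    (2, 20): "IVc",
    (4, 18): "IV4",
    (2, 16): "IVe",
    (2, 19): "IVe",
    (2, 21): "IVe",
}

#: Overlap-resolution priority: complete before partial, then the two
#: dominant biological types first, then the rarities.
TYPE_PRIORITY = {"IVb": 0, "IVc": 1, "IVa": 2, "IV4": 3, "IVe": 4, "IVp": 5}

#: Fixed total lengths of the fixed-length complete types
#: (4 cysteines + spacer1 + spacer2 + 2).
FIXED_LENGTH = {"IVa": 25, "IVb": 26, "IVc": 28, "IV4": 28}

#: Highly conserved residues of the IVb domain at 1-based internal
#: positions (cysteines at 1, 4, 23, 26 excluded).  Used as the consensus
#: filter when vetting partial-domain candidates.
IVB_CONSENSUS = {9: "T", 10: "P", 12: "W", 13: "R", 15: "G", 16: "P", 18: "G",
                 22: "L", 24: "N", 25: "A"}

#: IVb anchor cysteines, 1-based internal positions.
_IVB_CYS = (1, 4, 23, 26)

DEFAULT_IVP_WINDOW = (12, 21)
DEFAULT_IVP_MIN_CONSENSUS = 4

SPACER2_RANGE = (16, 21)


@dataclass(frozen=True)
class DomainHit:
    """One detected zinc-finger region on a protein sequence.

    ``start``/``end`` are 0-based half-open; ``cys_positions`` are absolute
    0-based positions of the anchor cysteines (4 for complete types, 2–3
    for partials).  ``spacer1``/``spacer2`` are the residue counts strictly
    between the 1st–2nd and 2nd–3rd cysteines, ``None`` when the relevant
    cysteines are missing.
    """

    protein_id: str
    start: int
    end: int
    cys_positions: tuple[int, ...]
    dtype: str
    domain_seq: str
    spacer1: int | None = None
    spacer2: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_complete(self) -> bool:
        return self.dtype != "IVp"


def classify_spacers(spacer1: int, spacer2: int) -> str | None:
    """Map a (spacer1, spacer2) pair to a complete domain type, or None."""
    return SPACER_TABLE.get((spacer1, spacer2))


def _cys_positions(sequence: str) -> list[int]:
    return [i for i, ch in enumerate(sequence) if ch == "C"]


def enumerate_complete_candidates(
    sequence: str, protein_id: str = ""
) -> list[DomainHit]:
    """Enumerate every complete four-cysteine candidate in a sequence.

    Every cysteine quadruple i<j<k<l with j-i-1 ∈ {2,4}, k-j-1 ∈ [16,21]
    and l-k-1 == 2 whose spacers classify to a named type is emitted.
    Candidates may overlap; the list is sorted by (start, end).
    """
    cys = _cys_positions(sequence)
    lo2, hi2 = SPACER2_RANGE
    hits: list[DomainHit] = []
    for a, i in enumerate(cys):
        for b in range(a + 1, len(cys)):
            j = cys[b]
            s1 = j - i - 1
            if s1 > 4:
                break
            if s1 not in (2, 4):
                continue
            for c in range(b + 1, len(cys)):
                k = cys[c]
                s2 = k - j - 1
                if s2 > hi2:
                    break
                if s2 < lo2:
                    continue
                dtype = classify_spacers(s1, s2)
                if dtype is None:
                    continue
                for d in range(c + 1, len(cys)):
                    l = cys[d]
                    if l - k - 1 > 2:
                        break
                    if l - k - 1 == 2:
                        hits.append(
                            DomainHit(
                                protein_id=protein_id,
                                start=i,
                                end=l + 1,
                                cys_positions=(i, j, k, l),
                                dtype=dtype,
                                domain_seq=sequence[i : l + 1],
                                spacer1=s1,
                                spacer2=s2,
                            )
                        )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _consensus_matches(sequence: str, cys_map: dict[int, int], m: int) -> int:
    """Count IVb high-conservation residues present in a partial candidate.

    ``cys_map`` maps the IVb anchor cysteine positions (1-based internal)
    present in the template to their absolute 0-based sequence positions.
    Spacer positions are aligned by anchoring at the left cysteine of their
    spacer; ``m`` is the template's long-spacer length, so consensus
    positions whose left-anchored offset exceeds ``m`` are unmatched.
    X never counts as a match.
    """
    n = 0
    for pos, want in IVB_CONSENSUS.items():
        if 4 < pos < 23:
            # inside the long spacer, left-anchored at C-4
            if 4 not in cys_map:
                continue
            off = pos - 4
            if off > m:
                continue
            abs_pos = cys_map[4] + off
        else:
            # N-24 / A-25 sit between C-23 and C-26
            if 23 not in cys_map:
                continue
            abs_pos = cys_map[23] + (pos - 23)
        if 0 <= abs_pos < len(sequence) and sequence[abs_pos] == want:
            n += 1
    return n


def _intersects(start: int, end: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def find_partial_candidates(
    sequence: str,
    exclusion: Sequence[tuple[int, int]] = (),
    protein_id: str = "",
    *,
    spacer_window: tuple[int, int] = DEFAULT_IVP_WINDOW,
    min_consensus: int = DEFAULT_IVP_MIN_CONSENSUS,
) -> list[DomainHit]:
    """Find partial (type IVp) zinc-finger candidates.

    Three truncation templates of the canonical motif are matched, with the
    long spacer m constrained to ``spacer_window``:

    a. ``C X{m} C X{2} C``  — missing the N-terminal cysteine pair
       (cysteines anchor to IVb C-4, C-23, C-26);
    b. ``C X{2} C X{m}``    — missing the C-terminal pair, with no cysteine
       inside the m-window (anchors C-1, C-4); the window is taken maximal;
    c. ``C X{2} C X{m} C``  — missing only the final cysteine
       (anchors C-1, C-4, C-23).

    A candidate is reported only if its span avoids every ``exclusion``
    interval (the spans of retained complete hits) and at least
    ``min_consensus`` of the IVb high-conservation residues are present at
    their anchored positions.
    """
    lo, hi = spacer_window
    cys = _cys_positions(sequence)
    cys_set = set(cys)
    raw: list[tuple[int, DomainHit]] = []  # (n_cys, hit) for ranking/dedup

    # template (a): C X{m} C X{2} C
    for a, c1 in enumerate(cys):
        for b in range(a + 1, len(cys)):
            c2 = cys[b]
            m = c2 - c1 - 1
            if m > hi:
                break
            if m < lo:
                continue
            c3 = c2 + 3
            if c3 < len(sequence) and c3 in cys_set:
                start, end = c1, c3 + 1
                if _intersects(start, end, exclusion):
                    continue
                if _consensus_matches(sequence, {4: c1, 23: c2, 26: c3}, m) >= min_consensus:
                    raw.append(
                        (3, DomainHit(protein_id, start, end, (c1, c2, c3), "IVp",
                                      sequence[start:end], spacer1=m, spacer2=2))
                    )

    for a, c1 in enumerate(cys):
        c2 = c1 + 3
        if c2 not in cys_set:
            continue

        # template (c): C X{2} C X{m} C
        for c3 in cys:
            if c3 <= c2:
                continue
            m = c3 - c2 - 1
            if m > hi:
                break
            if m < lo:
                continue
            start, end = c1, c3 + 1
            if _intersects(start, end, exclusion):
                continue
            if _consensus_matches(sequence, {1: c1, 4: c2, 23: c3}, m) >= min_consensus:
                raw.append(
                    (3, DomainHit(protein_id, start, end, (c1, c2, c3), "IVp",
                                  sequence[start:end], spacer1=2, spacer2=m))
                )

        # template (b): C X{2} C X{m}, cysteine-free maximal window
        m = 0
        while m < hi and c2 + m + 1 < len(sequence) and (c2 + m + 1) not in cys_set:
            m += 1
        if m >= lo:
            start, end = c1, c2 + m + 1
            if not _intersects(start, end, exclusion):
                if _consensus_matches(sequence, {1: c1, 4: c2}, m) >= min_consensus:
                    raw.append(
                        (2, DomainHit(protein_id, start, end, (c1, c2), "IVp",
                                      sequence[start:end], spacer1=2, spacer2=m))
                    )

    # Dedup identical spans, preferring the template with more cysteines;
    # the final pairwise-disjoint selection happens in resolve_overlaps.
    best: dict[tuple[int, int], tuple[int, DomainHit]] = {}
    for ncys, hit in raw:
        key = (hit.start, hit.end)
        if key not in best or ncys > best[key][0]:
            best[key] = (ncys, hit)
    out = [hit for _, hit in best.values()]
    out.sort(key=lambda h: (h.start, h.end, -len(h.cys_positions)))
    return out


def resolve_overlaps(candidates: Iterable[DomainHit]) -> list[DomainHit]:
    """Greedy non-overlapping selection with an explicit priority.

    Candidates are ranked complete-before-partial, then by type priority
    (IVb > IVc > IVa > IV4 > IVe > IVp), then by smaller start, then
    smaller end; a candidate is accepted iff it shares no residue with any
    already-accepted hit.  Output is sorted by start and pairwise disjoint.
    """
    ranked = sorted(
        candidates,
        key=lambda h: (0 if h.is_complete else 1, TYPE_PRIORITY[h.dtype], h.start, h.end),
    )
    accepted: list[DomainHit] = []
    spans: list[tuple[int, int]] = []
    for hit in ranked:
        if not _intersects(hit.start, hit.end, spans):
            accepted.append(hit)
            spans.append((hit.start, hit.end))
    accepted.sort(key=lambda h: (h.start, h.end))
    return accepted


def scan_protein(
    record: ProteinRecord,
    *,
    spacer_window: tuple[int, int] = DEFAULT_IVP_WINDOW,
    min_consensus: int = DEFAULT_IVP_MIN_CONSENSUS,
) -> list[DomainHit]:
    """Scan one protein: complete candidates, overlap resolution, then
    partial candidates on the remainder.  Deterministic; sorted by start."""
    complete = enumerate_complete_candidates(record.sequence, record.protein_id)
    kept = resolve_overlaps(complete)
    exclusion = [(h.start, h.end) for h in kept]
    partial = find_partial_candidates(
        record.sequence,
        exclusion,
        record.protein_id,
        spacer_window=spacer_window,
        min_consensus=min_consensus,
    )
    return resolve_overlaps(kept + partial)


def scan_dataset(
    records: Iterable[ProteinRecord],
    *,
    spacer_window: tuple[int, int] = DEFAULT_IVP_WINDOW,
    min_consensus: int = DEFAULT_IVP_MIN_CONSENSUS,
) -> dict[str, list[DomainHit]]:
    """Scan every record; returns protein_id → hit list (possibly empty)."""
    return {
        rec.protein_id: scan_protein(
            rec, spacer_window=spacer_window, min_consensus=min_consensus
        )
        for rec in records
    }


def hits_to_frame(hits_by_protein, records: Iterable[ProteinRecord]):
    """Flatten scan results to the hit-table layout used by the TSV output:
    protein_id, gene_id, species_id, start, end, dtype, spacer1, spacer2,
    cys_positions (comma-joined), domain_seq."""
    import pandas as pd

    by_id = {r.protein_id: r for r in records}
    rows = []
    for pid in sorted(hits_by_protein):
        rec = by_id.get(pid)
        for h in hits_by_protein[pid]:
            rows.append(
                {
                    "protein_id": pid,
                    "gene_id": rec.gene_id if rec else "",
                    "species_id": rec.species_id if rec else "",
                    "start": h.start,
                    "end": h.end,
                    "dtype": h.dtype,
                    "spacer1": "" if h.spacer1 is None else h.spacer1,
                    "spacer2": "" if h.spacer2 is None else h.spacer2,
                    "cys_positions": ",".join(str(p) for p in h.cys_positions),
                    "domain_seq": h.domain_seq,
                }
            )
    columns = ["protein_id", "gene_id", "species_id", "start", "end", "dtype",
               "spacer1", "spacer2", "cys_positions", "domain_seq"]
    return pd.DataFrame(rows, columns=columns)
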