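"""Per-position amino-acid frequency profiles of fixed-length domain types.

Domains of one fixed-length type (IVa 25, IVb 26, IVc/IV4 28 residues) are
stacked positionally — no alignment is needed because same-type domains
share their exact length — and per-position residue counts are normalized
into frequencies.  Profiles are stratified into three taxon strata
("eudicots", "monocots", "non-angiosperms") plus the merged "all";
the basal angiosperm is kept out of "non-angiosperms" and contributes only
to "all".  A position is called conserved when its modal residue exceeds a
frequency threshold (0.90 by convention for "highly conserved").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord, SpeciesInfo
from .scanner import FIXED_LENGTH, DomainHit

#: Column order of the count/frequency matrices: 20 standard residues then
#: X.  X occupies its own column and counts in the denominator but can
#: never be the reported modal residue — unknowns depress conservation,
#: they never inflate it.
PROFILE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + "X"
_COL = {ch: i for i, ch in enumerate(PROFILE_ALPHABET)}

STRATA = ("eudicots", "monocots", "non-angiosperms")

#: taxonomic group → profile stratum (basal angiosperm maps to no stratum).
GROUP_TO_STRATUM = {
    "eudicots": "eudicots",
    "monocots": "monocots",
    "basal_angiosperm": None,
    "gymnosperm": "non-angiosperms",
    "marchantiophyta": "non-angiosperms",
    "bryophyta": "non-angiosperms",
    "lycopodiophyta": "non-angiosperms",
    "charophyta": "non-angiosperms",
    "chlorophytae": "non-angiosperms",
}


@dataclass
class FrequencyProfile:
    """Per-position residue counts for one (domain type, stratum) pair."""

    dtype: str
    group_label: str
    length: int
    counts: np.ndarray  # (length, 21) non-negative ints
    n_domains: int

    @property
    def frequencies(self) -> np.ndarray:
        """Row-normalized counts; every row sums to 1 when n_domains > 0."""
        if self.n_domains == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / float(self.n_domains)


def stack_domains(hits: Sequence[DomainHit], dtype: str) -> np.ndarray:
    """Stack same-type domain sequences into an (n_domains, length) char
    matrix.  Only the fixed-length complete types are stackable; IVe and
    IVp vary in length and are rejected."""
    if dtype not in FIXED_LENGTH:
        raise ValueError(
            f"domain type {dtype!r} has variable length and cannot be stacked "
            f"positionally; fixed-length types: {sorted(FIXED_LENGTH)}"
        )
    length = FIXED_LENGTH[dtype]
    rows = []
    for h in hits:
        if h.dtype != dtype:
            raise ValueError(
                f"mixed domain types in stack: expected {dtype}, got {h.dtype}"
            )
        if len(h.domain_seq) != length:
            raise ValueError(
                f"{dtype} hit of length {len(h.domain_seq)} != {length}"
            )
        rows.append(list(h.domain_seq))
    if not rows:
        return np.empty((0, length), dtype="<U1")
    return np.array(rows, dtype="<U1")


def build_profile(stack: np.ndarray, dtype: str, group_label: str) -> FrequencyProfile:
    """Count residues per position over a stacked domain matrix."""
    n, length = stack.shape
    if n == 0:
        raise ValueError("cannot build a profile from an empty stack")
    counts = np.zeros((length, len(PROFILE_ALPHABET)), dtype=int)
    for j in range(length):
        col, cnt = np.unique(stack[:, j], return_counts=True)
        for ch, c in zip(col, cnt):
            counts[j, _COL[ch]] += int(c)
    return FrequencyProfile(
        dtype=dtype, group_label=group_label, length=length, counts=counts, n_domains=n
    )


def conserved_positions(
    profile: FrequencyProfile, threshold: float = 0.90
) -> list[tuple[int, str, float]]:
    """Positions whose modal residue frequency strictly exceeds ``threshold``.

    Returns (1-based position, residue, frequency) sorted by position.  The
    modal residue is chosen among the 20 standard residues (X is excluded);
    ties break alphabetically.
    """
    if profile.n_domains == 0:
        raise ValueError("profile has no domains")
    freqs = profile.frequencies
    out = []
    for i in range(profile.length):
        row = freqs[i, :20]  # exclude the X column from the mode
        j = int(np.argmax(row))  # argmax takes the first = alphabetical tie-break
        if row[j] > threshold:
            out.append((i + 1, PROFILE_ALPHABET[j], float(row[j])))
    return out


def merge_profiles(profiles: Sequence[FrequencyProfile], group_label: str = "all") -> FrequencyProfile:
    """Elementwise-sum stratum profiles into a merged profile."""
    if not profiles:
        raise ValueError("nothing to merge")
    first = profiles[0]
    counts = np.zeros_like(first.counts)
    n = 0
    for p in profiles:
        if p.dtype != first.dtype or p.length != first.length:
            raise ValueError("cannot merge profiles of different domain types")
        counts += p.counts
        n += p.n_domains
    return FrequencyProfile(first.dtype, group_label, first.length, counts, n)


def build_group_profiles(
    hits_by_isoform: Mapping[str, Sequence[DomainHit]],
    records: Iterable[ProteinRecord],
    species: Mapping[str, SpeciesInfo],
    dtype: str,
) -> dict[str, FrequencyProfile]:
    """Build stratified profiles for one fixed-length type.

    Returns stratum → profile for every stratum with at least one domain,
    plus "all" (which additionally includes basal-angiosperm domains).
    "all" counts equal the elementwise sum of the strata counts plus any
    basal-angiosperm contribution.
    """
    if dtype not in FIXED_LENGTH:
        raise ValueError(f"cannot profile variable-length type {dtype!r}")
    species_of = {r.protein_id: r.species_id for r in records}
    per_stratum: dict[str, list[DomainHit]] = {s: [] for s in STRATA}
    all_hits: list[DomainHit] = []
    for pid, hits in hits_by_isoform.items():
        sid = species_of.get(pid)
        if sid is None:
            raise KeyError(f"protein {pid!r} has hits but no record")
        info = species.get(sid)
        if info is None:
            raise KeyError(f"species {sid!r} absent from species table")
        stratum = GROUP_TO_STRATUM[info.group]
        for h in hits:
            if h.dtype != dtype:
                continue
            all_hits.append(h)
            if stratum is not None:
                per_stratum[stratum].append(h)
    out: dict[str, FrequencyProfile] = {}
    for stratum, hits in per_stratum.items():
        if hits:
            out[stratum] = build_profile(stack_domains(hits, dtype), dtype, stratum)
    if all_hits:
        out["all"] = build_profile(stack_domains(all_hits, dtype), dtype, "all")
    return out


def profile_to_frame(profile: FrequencyProfile) -> pd.DataFrame:
    """Long-format table: dtype, group_label, position (1-based), residue,
    count, frequency.  Zero-count cells are included so the matrix is
    reconstructible."""
    freqs = profile.frequencies
    rows = []
    for i in range(profile.length):
        for j, ch in enumerate(PROFILE_ALPHABET):
            rows.append(
                {
                    "dtype": profile.dtype,
                    "group_label": profile.group_label,
                    "position": i + 1,
                    "residue": ch,
                    "count": int(profile.counts[i, j]),
                    "frequency": float(freqs[i, j]),
                }
            )
    return pd.DataFrame(rows)
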