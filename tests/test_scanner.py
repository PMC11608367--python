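"""Zinc-finger grammar scanning: spacer typing, brute-force equivalence,
partial-domain templates and deterministic overlap resolution."""

from itertools import combinations

import numpy as np
import pytest

from gatascan import (
    DomainHit,
    ProteinRecord,
    classify_spacers,
    enumerate_complete_candidates,
    find_partial_candidates,
    resolve_overlaps,
    scan_protein,
)

BG = "K"  # cysteine-free background filler


# ---------------------------------------------------------------- oracles

# Independent re-statement of the spacer grammar for the brute-force oracle.
_ORACLE_TYPES = {(2, 17): "IVa", (2, 18): "IVb", (2, 20): "IVc", (4, 18): "IV4",
                 (2, 16): "IVe", (2, 19): "IVe", (2, 21): "IVe"}


def brute_force_complete(seq):
    """Exhaustive enumeration over all cysteine quadruples."""
    cys = [i for i, c in enumerate(seq) if c == "C"]
    out = set()
    for i, j, k, l in combinations(cys, 4):
        t = _ORACLE_TYPES.get((j - i - 1, k - j - 1))
        if t is not None and l - k - 1 == 2:
            out.add((i, j, k, l, t))
    return out


def reference_resolution(candidates):
    """Independent restatement of the greedy priority selection."""
    prio = {"IVb": 0, "IVc": 1, "IVa": 2, "IV4": 3, "IVe": 4, "IVp": 5}
    order = sorted(
        candidates,
        key=lambda h: (h.dtype == "IVp", prio[h.dtype], h.start, h.end),
    )
    taken = []
    for h in order:
        if all(h.end <= t.start or t.end <= h.start for t in taken):
            taken.append(h)
    return sorted(taken, key=lambda h: (h.start, h.end))


def random_sequences(n, rng, max_len=300, c_freq=0.07):
    letters = np.array(list("ADEFGHIKLMNPQRSTVWYCX"))
    probs = np.full(21, (1 - c_freq - 0.01) / 19)
    probs[-2] = c_freq  # elevated cysteine frequency
    probs[-1] = 0.01    # occasional unknown residue
    for _ in range(n):
        ln = int(rng.integers(30, max_len + 1))
        yield "".join(rng.choice(letters, size=ln, p=probs))


# ---------------------------------------------------------- spacer typing

@pytest.mark.parametrize(
    "s1, s2, expected",
    [
        (2, 17, "IVa"), (2, 18, "IVb"), (2, 20, "IVc"), (4, 18, "IV4"),
        (2, 16, "IVe"), (2, 19, "IVe"), (2, 21, "IVe"),
        (4, 20, None), (2, 22, None), (2, 15, None), (3, 18, None), (0, 18, None),
    ],
)
def test_classify_spacers(s1, s2, expected):
    assert classify_spacers(s1, s2) == expected


# ------------------------------------------------------ complete scanning

def _motif(s1, s2):
    return "C" + BG * s1 + "C" + BG * s2 + "C" + BG * 2 + "C"


def test_forced_ivb_parse():
    seq = _motif(2, 18)
    assert len(seq) == 26
    hits = enumerate_complete_candidates(seq)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.dtype) == (0, 26, "IVb")
    assert h.cys_positions == (0, 3, 22, 25)
    assert (h.spacer1, h.spacer2) == (2, 18)


def test_no_cysteines_empty():
    assert enumerate_complete_candidates("MKTAYIAKQR" * 10) == []
    rec = ProteinRecord("p", "g", "s", "MKTAYIAKQR" * 10)
    assert scan_protein(rec) == []


def test_length_identity_of_complete_hits():
    for s1, s2 in [(2, 17), (2, 18), (2, 20), (4, 18), (2, 16), (2, 19), (2, 21)]:
        seq = BG * 5 + _motif(s1, s2) + BG * 5
        (h,) = enumerate_complete_candidates(seq)
        assert h.length == 4 + h.spacer1 + h.spacer2 + 2
        assert h.domain_seq == seq[h.start : h.end]


def test_x_never_matches_cysteine():
    seq = _motif(2, 18).replace("C", "X", 1)  # corrupt the first anchor
    assert enumerate_complete_candidates(seq) == []


def test_scanner_equals_brute_force_on_random_sequences():
    rng = np.random.default_rng(20240917)
    for seq in random_sequences(200, rng):
        got = {
            (*h.cys_positions, h.dtype) for h in enumerate_complete_candidates(seq)
        }
        assert got == brute_force_complete(seq)


# ------------------------------------------------------- partial scanning

def _seq_with(positions, length):
    chars = [BG] * length
    for pos, ch in positions.items():
        chars[pos] = ch
    return "".join(chars)


def test_partial_template_missing_n_terminal_pair():
    # C X15 C X2 C with the consensus residues anchored at the IVb C-4
    seq = _seq_with(
        {0: "C", 16: "C", 19: "C", 5: "T", 6: "P", 8: "W", 9: "R", 11: "G",
         12: "P", 14: "G", 17: "N", 18: "A"},
        25,
    )
    hits = find_partial_candidates(seq)
    assert [(h.start, h.end, h.dtype) for h in resolve_overlaps(hits)] == [(0, 20, "IVp")]


def test_partial_template_missing_c_terminal_pair():
    # C X2 C X12 at the very end of the sequence
    seq = _seq_with({0: "C", 3: "C", 8: "T", 9: "P", 11: "W", 12: "R", 14: "G", 15: "P"}, 16)
    hits = find_partial_candidates(seq)
    assert [(h.start, h.end, h.dtype) for h in hits] == [(0, 16, "IVp")]


def test_partial_requires_consensus_matches():
    # same cysteine skeleton but featureless background: filtered out
    seq = _seq_with({0: "C", 16: "C", 19: "C"}, 25)
    assert find_partial_candidates(seq) == []


def test_partial_respects_exclusion():
    seq = _motif(2, 18) + BG * 10
    complete = resolve_overlaps(enumerate_complete_candidates(seq))
    spans = [(h.start, h.end) for h in complete]
    assert spans == [(0, 26)]
    assert find_partial_candidates(seq, spans) == []


def test_planted_iv4_scan():
    rec = ProteinRecord("p", "g", "s", BG * 30 + _motif(4, 18) + BG * 30)
    (h,) = scan_protein(rec)
    assert (h.dtype, h.start, h.end) == ("IV4", 30, 58)


# ------------------------------------------------------ overlap resolution

def _hit(start, end, dtype, pid="p"):
    return DomainHit(pid, start, end, (start,), dtype, BG * (end - start))


def test_disjoint_hits_all_kept():
    a, b = _hit(0, 26, "IVb"), _hit(40, 66, "IVb")
    assert resolve_overlaps([a, b]) == [a, b]


def test_priority_ivb_beats_ive_on_overlap():
    ive = _hit(0, 24, "IVe")
    ivb = _hit(10, 36, "IVb")
    assert resolve_overlaps([ive, ivb]) == [ivb]


def test_complete_beats_partial_on_overlap():
    ivp = _hit(0, 20, "IVp")
    ive = _hit(5, 29, "IVe")
    assert resolve_overlaps([ivp, ive]) == [ive]


def test_resolution_matches_reference_on_random_candidates():
    rng = np.random.default_rng(11)
    dtypes = ["IVa", "IVb", "IVc", "IV4", "IVe", "IVp"]
    for _ in range(200):
        n = int(rng.integers(1, 12))
        cands = []
        for _ in range(n):
            start = int(rng.integers(0, 150))
            length = int(rng.integers(15, 30))
            cands.append(_hit(start, start + length, dtypes[int(rng.integers(6))]))
        assert resolve_overlaps(cands) == reference_resolution(cands)
        spans = [(h.start, h.end) for h in resolve_overlaps(cands)]
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


def test_scan_is_deterministic():
    rng = np.random.default_rng(5)
    for seq in random_sequences(25, rng, max_len=200):
        rec = ProteinRecord("p", "g", "s", seq)
        assert scan_protein(rec) == scan_protein(rec)
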