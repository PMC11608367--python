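"""Positional frequency profiles: stacking, normalization, conservation
calls and stratum additivity."""

import numpy as np
import pytest

from gatascan import (
    DomainHit,
    build_group_profiles,
    build_profile,
    conserved_positions,
    generate_dataset,
    merge_profiles,
    plant_domain,
    scan_dataset,
    stack_domains,
)
from tests.conftest import small_config

IVB_CONSENSUS_POSITIONS = {1: "C", 4: "C", 23: "C", 26: "C", 9: "T", 10: "P",
                           12: "W", 13: "R", 15: "G", 16: "P", 18: "G",
                           22: "L", 24: "N", 25: "A"}
IVC_ANCHORS = {1: "C", 4: "C", 18: "P", 20: "G", 25: "C", 28: "C"}


def _hits(seqs, dtype):
    return [DomainHit("p", 0, len(s), (0,), dtype, s) for s in seqs]


def _planted_stack(dtype, n, conservation, seed):
    rng = np.random.default_rng(seed)
    seqs = [plant_domain(dtype, conservation, rng) for _ in range(n)]
    return stack_domains(_hits(seqs, dtype), dtype)


def test_stack_shape_and_errors():
    seqs = ["C" * 26] * 3
    assert stack_domains(_hits(seqs, "IVb"), "IVb").shape == (3, 26)
    with pytest.raises(ValueError, match="variable length"):
        stack_domains([], "IVe")
    with pytest.raises(ValueError, match="mixed"):
        stack_domains(_hits(["C" * 26], "IVc"), "IVb")
    with pytest.raises(ValueError, match="empty"):
        build_profile(np.empty((0, 26), dtype="<U1"), "IVb", "all")


def test_identical_sequences_give_unit_frequencies():
    stack = stack_domains(_hits(["ACDEFGHIKLMNPQRSTVWYACDEFG"] * 5, "IVb"), "IVb")
    prof = build_profile(stack, "IVb", "all")
    assert prof.n_domains == 5
    freqs = prof.frequencies
    assert np.allclose(freqs.max(axis=1), 1.0)
    assert len(conserved_positions(prof, 0.9)) == 26


def test_single_position_split():
    a = "ACDEFGHIKLMNPQRSTVWYACDEFG"
    b = a[:7] + "W" + a[8:]
    prof = build_profile(stack_domains(_hits([a, b], "IVb"), "IVb"), "IVb", "all")
    assert sorted(prof.frequencies[7][prof.frequencies[7] > 0]) == [0.5, 0.5]
    # a 0.5/0.5 split is not conserved at 0.9, and threshold 1.0 with any
    # variation reports nothing at that position
    assert all(pos != 8 for pos, _, _ in conserved_positions(prof, 0.9))


def test_normalization_invariant(small_dataset):
    hits = scan_dataset(small_dataset.records)
    profiles = build_group_profiles(
        hits, small_dataset.records, small_dataset.species, "IVb"
    )
    for prof in profiles.values():
        assert prof.counts.sum(axis=1).tolist() == [prof.n_domains] * prof.length
        assert np.allclose(prof.frequencies.sum(axis=1), 1.0, atol=1e-9)


def test_stratum_additivity(small_dataset):
    hits = scan_dataset(small_dataset.records)
    profiles = build_group_profiles(
        hits, small_dataset.records, small_dataset.species, "IVb"
    )
    strata = [p for label, p in profiles.items() if label != "all"]
    merged = merge_profiles(strata)
    # the small cohort has no basal-angiosperm species, so "all" is exactly
    # the elementwise sum of the strata
    assert np.array_equal(profiles["all"].counts, merged.counts)
    assert profiles["all"].n_domains == merged.n_domains


def test_threshold_monotonicity(small_dataset):
    hits = scan_dataset(small_dataset.records)
    prof = build_group_profiles(
        hits, small_dataset.records, small_dataset.species, "IVb"
    )["all"]
    previous = None
    for thr in (0.5, 0.7, 0.9, 0.95, 1.0):
        positions = {pos for pos, _, _ in conserved_positions(prof, thr)}
        if previous is not None:
            assert positions <= previous
        previous = positions


def test_fully_conserved_ivb_cohort_reports_consensus():
    stack = _planted_stack("IVb", 300, 1.0, seed=42)
    prof = build_profile(stack, "IVb", "all")
    called = {(pos, res) for pos, res, f in conserved_positions(prof, 0.9) if f == 1.0}
    assert called == set(IVB_CONSENSUS_POSITIONS.items())


def test_fully_conserved_ivc_cohort_reports_anchor_residues():
    stack = _planted_stack("IVc", 300, 1.0, seed=43)
    prof = build_profile(stack, "IVc", "all")
    at_one = {(pos, res) for pos, res, f in conserved_positions(prof, 0.9) if f == 1.0}
    assert set(IVC_ANCHORS.items()) <= at_one


def test_sampling_bound_on_consensus_frequency():
    """At conservation p the observed consensus frequency stays within a
    3-sigma binomial envelope (the uniform fallback can re-draw the
    consensus residue, so the effective rate is p + (1-p)/19)."""
    p, n = 0.9, 500
    stack = _planted_stack("IVb", n, p, seed=44)
    prof = build_profile(stack, "IVb", "all")
    eff = p + (1 - p) / 19
    bound = 3 * np.sqrt(eff * (1 - eff) / n)
    freqs = prof.frequencies
    from gatascan.profiles import PROFILE_ALPHABET

    for pos, res in {9: "T", 10: "P", 12: "W", 13: "R"}.items():
        observed = freqs[pos - 1, PROFILE_ALPHABET.index(res)]
        assert abs(observed - eff) <= bound
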