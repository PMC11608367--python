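"""Synthetic plant-proteome generator with planted zinc-finger domains.

Emulates a PlantTFDB-like protein cohort in which every GATA domain is
planted with fully known coordinates and type, so every pipeline stage can
be checked against ground truth:

* species are sampled per taxonomic group with realistic gene counts;
* each gene carries 1–5 planted domains (mostly 1) whose types follow the
  census mixture (IVb ≈ 74.6%, IVc ≈ 17.2%, …);
* anchor cysteines are planted with probability 1, consensus residues with
  a configurable conservation level, all other positions uniformly from
  the 19 non-cysteine residues;
* alternative-splicing scenarios rewrite extra isoforms: UTR-only
  (identical protein), truncation of a complete IVb domain to a partial
  (IVp), whole-domain loss, or a benign background substitution;
* planted domains are separated by at least :data:`MIN_DOMAIN_GAP`
  background residues so that no spurious cross-domain cysteine spacing
  can imitate a motif — with a cysteine-free background, recovery of the
  planted truth is then exact rather than probabilistic.

The random stream is split hierarchically per (group, species, gene), so
changing one species' count does not perturb any other species' sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ProteinRecord, SpeciesInfo, TAXON_GROUPS, write_fasta, write_species_table

NON_CYS = "ADEFGHIKLMNPQRSTVWY"  # the 19 standard residues other than C

#: Minimum background residues between two planted domains (and implied by
#: construction between a domain and any other cysteine).  22 exceeds the
#: largest legal spacer (21), so cysteines of neighbouring domains can
#: never combine into a legal quadruple or partial template.
MIN_DOMAIN_GAP = 22

#: Anchor residues planted with probability 1 (1-based internal positions).
#: For IVc the fully conserved P-18 and G-20 are anchors alongside the four
#: cysteines, matching their complete conservation in the real cohort.
ANCHORS = {
    "IVa": {1: "C", 4: "C", 22: "C", 25: "C"},
    "IVb": {1: "C", 4: "C", 23: "C", 26: "C"},
    "IVc": {1: "C", 4: "C", 18: "P", 20: "G", 25: "C", 28: "C"},
    "IV4": {1: "C", 6: "C", 25: "C", 28: "C"},
}

#: Consensus residues planted with probability ``conservation``.
CONSENSUS = {
    "IVa": {},
    "IVb": {9: "T", 10: "P", 12: "W", 13: "R", 15: "G", 16: "P", 18: "G",
            22: "L", 24: "N", 25: "A"},
    "IVc": {5: "G", 11: "T", 12: "P", 14: "M", 15: "R", 16: "R", 17: "G",
            22: "R", 24: "L", 26: "N", 27: "A"},
    "IV4": {},
}

PLANT_LENGTH = {"IVa": 25, "IVb": 26, "IVc": 28, "IV4": 28}

IVE_SPACERS = (16, 19, 21)

AS_SCENARIOS = ("utr_only", "truncation_to_IVp", "domain_loss", "benign")

_ANGIOSPERM = ("eudicots", "monocots", "basal_angiosperm")

_ORDER_POOL = {
    "eudicots": ("Brassicales", "Fabales", "Rosales", "Solanales", "Malpighiales"),
    "monocots": ("Poales", "Alismatales", "Arecales"),
    "basal_angiosperm": ("Amborellales",),
}

# Census-derived defaults (counts over the 165-species reference cohort).
_DEFAULT_SPECIES = {
    "eudicots": 100, "monocots": 39, "basal_angiosperm": 1, "gymnosperm": 5,
    "marchantiophyta": 1, "bryophyta": 2, "lycopodiophyta": 1,
    "charophyta": 1, "chlorophytae": 15,
}
_DEFAULT_GENES = {
    "eudicots": (2, 125, 33.82), "monocots": (6, 73, 29.28),
    "basal_angiosperm": (20, 20, 20.0), "gymnosperm": (4, 19, 8.6),
    "marchantiophyta": (6, 6, 6.0), "bryophyta": (15, 15, 15.0),
    "lycopodiophyta": (8, 8, 8.0), "charophyta": (10, 10, 10.0),
    "chlorophytae": (5, 15, 8.07),
}
# p(n isoforms) for n = 1..12: 329 of 4,762 genes have ≥2 forms, split by
# the census AS-form histogram.
_AS_COUNTS = (0, 216, 58, 33, 6, 5, 2, 2, 0, 5, 0, 2)
_DEFAULT_AS = tuple(
    float(Fraction(4762 - 329, 4762)) if n == 0 else float(Fraction(_AS_COUNTS[n], 4762))
    for n in range(12)
)
_DEFAULT_DOMAINS = (0.9717, 0.0208, 0.0060, 0.0011, 0.0004)
# exact census fractions over 5,536 domains
_DEFAULT_MIXTURE = {
    "IVb": 4131 / 5536, "IVc": 950 / 5536, "IVp": 323 / 5536,
    "IVe": 66 / 5536, "IV4": 40 / 5536, "IVa": 26 / 5536,
}
_DEFAULT_SCENARIOS = {
    "utr_only": 0.32, "truncation_to_IVp": 0.06, "domain_loss": 0.03, "benign": 0.59,
}


def _check_probs(vec, label: str):
    total = float(np.sum(vec))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{label} probabilities sum to {total}, not 1")


@dataclass
class SyntheticConfig:
    """Full parameterization of the planted-motif proteome generator.

    Defaults are the reference-cohort conditions: per-group species counts,
    gene-count bands with the census means, the census AS-form and
    domains-per-TF distributions, and the census domain-type mixture.
    """

    seed: int = 0
    species_per_group: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SPECIES))
    #: group → (min, max, mean) GATA genes per species
    gene_count_params: dict[str, tuple[int, int, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GENES))
    #: probability of 1..12 isoforms per gene
    as_form_probs: tuple[float, ...] = _DEFAULT_AS
    #: probability of 1..5 planted domains per gene
    domains_per_gene_probs: tuple[float, ...] = _DEFAULT_DOMAINS
    dtype_mixture: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIXTURE))
    #: conservation level of consensus positions (anchors are always 1.0)
    conservation: float = 0.95
    #: protein length band (uniform) for angiosperm species
    angiosperm_length: tuple[int, int] = (100, 400)
    #: protein length band for non-angiosperms (longer, mean ≈ 525)
    non_angiosperm_length: tuple[int, int] = (200, 850)
    #: "cys_free" (no background cysteines) or "natural"
    background_cysteine: str = "cys_free"
    #: background C probability under the "natural" policy
    natural_cys_prob: float = 0.014
    as_scenario_probs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SCENARIOS))

    def __post_init__(self):
        _check_probs(self.as_form_probs, "AS-form")
        _check_probs(self.domains_per_gene_probs, "domains-per-gene")
        _check_probs(list(self.dtype_mixture.values()), "domain-type mixture")
        _check_probs(list(self.as_scenario_probs.values()), "AS-scenario")
        if self.background_cysteine not in ("cys_free", "natural"):
            raise ValueError(f"unknown background policy {self.background_cysteine!r}")
        for g in self.species_per_group:
            if g not in TAXON_GROUPS:
                raise ValueError(f"unknown group {g!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("as_form_probs", "domains_per_gene_probs", "angiosperm_length",
                    "non_angiosperm_length"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "gene_count_params" in raw:
            raw["gene_count_params"] = {
                g: tuple(v) for g, v in raw["gene_count_params"].items()
            }
        return cls(**raw)


@dataclass
class SyntheticDataset:
    """Generator output: records plus the planted ground truth."""

    records: list[ProteinRecord]
    species: dict[str, SpeciesInfo]
    #: one row per planted domain per isoform: protein_id, gene_id,
    #: species_id, start, dtype
    truth_domains: pd.DataFrame
    #: one row per gene: gene_id, species_id, n_forms, scenario
    truth_genes: pd.DataFrame
    #: one row per species: species_id, group, n_genes
    truth_species: pd.DataFrame

    def write(self, out_dir: str | Path, stem: str = "synthetic") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / f"{stem}.fasta",
            "species": out / f"{stem}.species.tsv",
            "truth_domains": out / f"{stem}.truth_domains.tsv",
            "truth_genes": out / f"{stem}.truth_genes.tsv",
            "truth_species": out / f"{stem}.truth_species.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        write_species_table(self.species, paths["species"])
        self.truth_domains.to_csv(paths["truth_domains"], sep="\t", index=False)
        self.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        self.truth_species.to_csv(paths["truth_species"], sep="\t", index=False)
        return paths


def _rng(*entropy) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy))


def plant_domain(dtype: str, conservation: float, rng: np.random.Generator) -> str:
    """Build one planted domain string of the given complete type.

    Anchor positions (cysteines; for IVc also P-18/G-20) get their residue
    with probability 1; consensus positions get theirs with probability
    ``conservation``, otherwise a uniform non-cysteine residue; all other
    positions are uniform non-cysteine.  IVe draws its inner spacer from
    {16, 19, 21}.
    """
    if dtype == "IVe":
        s2 = int(rng.choice(IVE_SPACERS))
        length = 4 + 2 + s2 + 2
        anchors = {1: "C", 4: "C", 4 + s2 + 1: "C", 4 + s2 + 4: "C"}
        consensus: dict[int, str] = {}
    elif dtype in PLANT_LENGTH:
        length = PLANT_LENGTH[dtype]
        anchors = ANCHORS[dtype]
        consensus = CONSENSUS[dtype]
    else:
        raise ValueError(f"cannot plant domain type {dtype!r} directly")
    chars = []
    for pos in range(1, length + 1):
        if pos in anchors:
            chars.append(anchors[pos])
        elif pos in consensus and rng.random() < conservation:
            chars.append(consensus[pos])
        else:
            chars.append(NON_CYS[rng.integers(len(NON_CYS))])
    return "".join(chars)


def plant_partial(conservation: float, rng: np.random.Generator) -> str:
    """Plant a partial (IVp) domain by truncating a complete IVb domain:
    drop the N-terminal cysteine pair (C X2), the C-terminal pair (X2 C
    tail), or only the final cysteine."""
    full = plant_domain("IVb", conservation, rng)
    mode = int(rng.integers(3))
    if mode == 0:
        return full[3:]   # C X{18} C X{2} C
    if mode == 1:
        return full[:-4]  # C X{2} C X{18}
    return full[:-1]      # C X{2} C X{18} C

def _background(rng: np.random.Generator, n: int, policy: str, cys_prob: float) -> str:
    if n <= 0:
        return ""
    if policy == "cys_free":
        idx = rng.integers(len(NON_CYS), size=n)
        return "".join(NON_CYS[i] for i in idx)
    out = []
    for _ in range(n):
        if rng.random() < cys_prob:
            out.append("C")
        else:
            out.append(NON_CYS[rng.integers(len(NON_CYS))])
    return "".join(out)


def _gene_count(rng: np.random.Generator, lo: int, hi: int, mean: float) -> int:
    if lo == hi:
        return lo
    return int(np.clip(rng.poisson(mean), lo, hi))


def _place_domains(
    rng: np.random.Generator, lengths: Sequence[int], total_len: int
) -> tuple[list[int], int]:
    """Choose non-overlapping start offsets with ≥ MIN_DOMAIN_GAP spacing.

    Returns (starts, actual_length).  The drawn background length is
    stretched to the minimum feasible when too short; infeasibility against
    the configured maximum is the caller's error.
    """
    need = sum(lengths) + MIN_DOMAIN_GAP * (len(lengths) - 1)
    total_len = max(total_len, need)
    free = total_len - need
    shares = rng.multinomial(free, [1.0 / (len(lengths) + 1)] * (len(lengths) + 1))
    starts = []
    pos = int(shares[0])
    for i, ln in enumerate(lengths):
        starts.append(pos)
        pos += ln
        if i < len(lengths) - 1:
            pos += MIN_DOMAIN_GAP + int(shares[i + 1])
    return starts, total_len


def _choice(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    return items[int(rng.choice(len(items), p=np.asarray(probs) / np.sum(probs)))]


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic cohort with its truth tables.

    Deterministic given ``config`` (byte-identical FASTA for equal seeds).
    Raises ValueError naming the gene if the configured maximum background
    length cannot accommodate the drawn domain complement.
    """
    records: list[ProteinRecord] = []
    species: dict[str, SpeciesInfo] = {}
    truth_domains: list[dict] = []
    truth_genes: list[dict] = []
    truth_species: list[dict] = []

    dtypes = list(config.dtype_mixture)
    dtype_probs = [config.dtype_mixture[t] for t in dtypes]

    for gi, group in enumerate(TAXON_GROUPS):
        n_species = config.species_per_group.get(group, 0)
        lo, hi, mean = config.gene_count_params.get(group, (5, 30, 15.0))
        length_band = (
            config.angiosperm_length if group in _ANGIOSPERM else config.non_angiosperm_length
        )
        orders = _ORDER_POOL.get(group, ())
        for si in range(n_species):
            sp_rng = _rng(config.seed, gi, si)
            sid = f"{group[:4]}{si:03d}"
            genus = f"{group[:4].capitalize()}genus{si // 3}"
            species[sid] = SpeciesInfo(
                species_id=sid,
                name=f"{genus} synthetica{si}",
                group=group,
                order=orders[si % len(orders)] if orders else "",
                genus=genus,
            )
            n_genes = _gene_count(sp_rng, lo, hi, mean)
            truth_species.append({"species_id": sid, "group": group, "n_genes": n_genes})
            for g in range(n_genes):
                gene_rng = _rng(config.seed, gi, si, g)
                gene_id = f"{sid}_g{g:03d}"
                _generate_gene(
                    config, gene_rng, gene_id, sid, length_band, dtypes, dtype_probs,
                    records, truth_domains, truth_genes,
                )

    return SyntheticDataset(
        records=records,
        species=species,
        truth_domains=pd.DataFrame(
            truth_domains, columns=["protein_id", "gene_id", "species_id", "start", "dtype"]
        ),
        truth_genes=pd.DataFrame(
            truth_genes, columns=["gene_id", "species_id", "n_forms", "scenario"]
        ),
        truth_species=pd.DataFrame(truth_species, columns=["species_id", "group", "n_genes"]),
    )


def _generate_gene(
    config: SyntheticConfig,
    rng: np.random.Generator,
    gene_id: str,
    sid: str,
    length_band: tuple[int, int],
    dtypes: Sequence[str],
    dtype_probs: Sequence[float],
    records: list,
    truth_domains: list,
    truth_genes: list,
) -> None:
    n_domains = 1 + int(rng.choice(len(config.domains_per_gene_probs),
                                   p=config.domains_per_gene_probs))
    domain_types = [_choice(rng, dtypes, dtype_probs) for _ in range(n_domains)]
    domain_seqs = []
    for t in domain_types:
        if t == "IVp":
            domain_seqs.append(plant_partial(config.conservation, rng))
        else:
            domain_seqs.append(plant_domain(t, config.conservation, rng))
    lengths = [len(s) for s in domain_seqs]
    need = sum(lengths) + MIN_DOMAIN_GAP * (n_domains - 1)
    if need > length_band[1]:
        raise ValueError(
            f"gene {gene_id}: cannot place {n_domains} domains "
            f"({need} residues needed) within the configured maximum "
            f"background length {length_band[1]}"
        )
    total_len = int(rng.integers(length_band[0], length_band[1] + 1))
    starts, total_len = _place_domains(rng, lengths, total_len)

    # assemble the base isoform
    chars = list(
        _background(rng, total_len, config.background_cysteine, config.natural_cys_prob)
    )
    for s, seq in zip(starts, domain_seqs):
        chars[s : s + len(seq)] = list(seq)
    base_seq = "".join(chars)
    base_truth = list(zip(starts, domain_types))

    n_forms = 1 + int(rng.choice(len(config.as_form_probs), p=config.as_form_probs))
    scenario = ""
    if n_forms >= 2:
        scenario = _choice(
            rng, list(config.as_scenario_probs), list(config.as_scenario_probs.values())
        )
        if scenario == "truncation_to_IVp" and "IVb" not in domain_types:
            scenario = "domain_loss"  # no truncatable complete IVb present
    truth_genes.append(
        {"gene_id": gene_id, "species_id": sid, "n_forms": n_forms, "scenario": scenario}
    )

    def emit(k: int, seq: str, truth: Sequence[tuple[int, str]]):
        pid = f"{gene_id}.{k}"
        records.append(
            ProteinRecord(protein_id=pid, gene_id=gene_id, species_id=sid, sequence=seq)
        )
        for s, t in truth:
            truth_domains.append(
                {"protein_id": pid, "gene_id": gene_id, "species_id": sid,
                 "start": s, "dtype": t}
            )

    emit(1, base_seq, base_truth)
    for k in range(2, n_forms + 1):
        if scenario == "utr_only":
            emit(k, base_seq, base_truth)
        elif scenario == "truncation_to_IVp" and k == 2:
            emit(k, *_truncate_isoform(rng, base_seq, starts, domain_types, lengths))
        elif scenario == "domain_loss" and k == 2:
            emit(k, *_drop_domain_isoform(rng, base_seq, starts, domain_types, lengths))
        elif scenario == "benign":
            emit(k, _mutate_background(rng, base_seq, starts, lengths), base_truth)
        else:  # extra forms beyond the altered second isoform copy the base
            emit(k, base_seq, base_truth)


def _truncate_isoform(rng, base_seq, starts, domain_types, lengths):
    idx = [i for i, t in enumerate(domain_types) if t == "IVb"][0]
    s, ln = starts[idx], lengths[idx]
    if rng.integers(2) == 0:  # drop the N-terminal cysteine pair (C X2)
        seq = base_seq[:s] + base_seq[s + 3 :]
        shift = 3
    else:  # drop the C-terminal pair (X2 C tail)
        seq = base_seq[: s + ln - 4] + base_seq[s + ln :]
        shift = 4
    truth = []
    for i, (st, t) in enumerate(zip(starts, domain_types)):
        if i < idx:
            truth.append((st, t))
        elif i == idx:
            truth.append((st, "IVp"))
        else:
            truth.append((st - shift, t))
    return seq, truth


def _drop_domain_isoform(rng, base_seq, starts, domain_types, lengths):
    idx = int(rng.integers(len(starts)))
    s, ln = starts[idx], lengths[idx]
    seq = base_seq[:s] + base_seq[s + ln :]
    truth = []
    for i, (st, t) in enumerate(zip(starts, domain_types)):
        if i < idx:
            truth.append((st, t))
        elif i > idx:
            truth.append((st - ln, t))
    return seq, truth


def _mutate_background(rng, base_seq, starts, lengths):
    covered = set()
    for s, ln in zip(starts, lengths):
        covered.update(range(s, s + ln))
    free = [i for i in range(len(base_seq)) if i not in covered]
    if not free:
        return base_seq
    pos = free[int(rng.integers(len(free)))]
    old = base_seq[pos]
    choices = [c for c in NON_CYS if c != old]
    new = choices[int(rng.integers(len(choices)))]
    return base_seq[:pos] + new + base_seq[pos + 1 :]
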