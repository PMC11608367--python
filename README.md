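# gatascan

Detection, typing and cohort analysis of class-IV zinc-finger GATA domains
in plant protein sequences.

GATA transcription factors bind the WGATAR promoter element through a
four-cysteine zinc finger written CX₂CXₙCX₂C, where the spacer *n* between
the second and third cysteines defines the domain type:

| type | motif | note |
|------|-------|------|
| IVb  | CX₂CX₁₈CX₂C | dominant plant type (~75% of domains) |
| IVc  | CX₂CX₂₀CX₂C | second plant type (~17%) |
| IVa  | CX₂CX₁₇CX₂C | the animal/fungal form, rare in plants |
| IV4  | CX₄CX₁₈CX₂C | unusual first spacer |
| IVe  | CX₂CX₍₁₆,₁₉,₂₁₎CX₂C | odd inner spacers unclaimed by named types |
| IVp  | partial | one or more anchor cysteines missing |

`gatascan` scans proteomes for these motifs by exhaustive cysteine-spacer
grammar matching (provably equivalent to brute-force enumeration over all
cysteine quadruples), resolves overlapping parses with a deterministic
priority, vets partial-domain candidates against the IVb consensus, and
builds the cohort-level analyses used in comparative surveys of the gene
family:

* per-gene **alternative-splicing** structure: isoform-count distribution,
  UTR-only splicing (identical proteins across isoforms), and
  splicing-driven domain changes (complete → partial conversion, domain
  loss);
* **positional residue-frequency profiles** of fixed-length domain types,
  stratified by taxon (eudicots / monocots / non-angiosperms), with
  conserved-position calling (modal residue frequency > 0.90);
* **cohort summary tables**: per-species gene/isoform counts, domain-type ×
  taxonomic-group counts with percentage ratios, gene-count and
  sequence-length band statistics, genus- and order-level aggregation;
* a **synthetic proteome generator** that plants domains with fully known
  coordinates and types under census-calibrated conditions, so every
  pipeline stage can be verified against ground truth.

The package also ships a transcribed reference census of GATA genes in 165
plant species (4,762 genes / 5,335 TF isoforms / 5,536 domains) used both
as generator calibration and as arithmetic fixtures.

## Worked example

```python
from gatascan import SyntheticConfig, generate_dataset, scan_dataset

config = SyntheticConfig(
    seed=42,
    species_per_group={"eudicots": 3, "monocots": 2, "chlorophytae": 2},
    gene_count_params={
        "eudicots": (10, 40, 25.0),
        "monocots": (10, 40, 25.0),
        "chlorophytae": (5, 15, 8.0),
    },
)
dataset = generate_dataset(config)
hits = scan_dataset(dataset.records)
```

Running `python examples/simulate_and_scan.py` (the script above plus the
comparison against truth) prints:

```
generated 175 protein isoforms across 7 species with 184 planted domains
recovered 184 domains: precision 1.000, recall 1.000
planted type mixture:
   IVb:  132  (71.74%)
   IVc:   36  (19.57%)
   IVp:   13  (7.07%)
   IVe:    2  (1.09%)
   IV4:    1  (0.54%)
```

Every planted domain is recovered at its exact offset and type — with a
cysteine-free background each cysteine belongs to a planted motif, so
recovery is structurally exact. The mixture percentages scatter
multinomially around the census proportions (74.62% IVb, 17.16% IVc, …).

The other scripts in `examples/` each exercise one capability:
`reference_tables.py` (census arithmetic: ratio column, per-group gene
means, splicing fractions), `conservation_profile.py` (IVb frequency
profile and conserved-position calls), `alternative_splicing.py` (AS-form
distribution and domain-change classification).

## Command line

A thin CLI wraps the same library functions:

```
gatascan simulate --seed 1 --out-dir run/            # synthetic cohort + truth
gatascan scan run/synthetic.fasta run/synthetic.species.tsv --out-dir run/
gatascan summarize run/hits.tsv run/synthetic.fasta run/synthetic.species.tsv --out-dir run/
gatascan profile run/hits.tsv run/synthetic.fasta run/synthetic.species.tsv --dtype IVb --out-dir run/
```

All outputs are plain TSV plus a JSON manifest recording parameters and
input checksums; logs go to standard error. Input FASTA headers carry gene
and species identity as `key=value` tokens
(`>AT4G17570.1 gene=AT4G17570 species=ath`); an optional gene→isoform TSV
can override the headers.

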