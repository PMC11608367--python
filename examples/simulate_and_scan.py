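"""Generate a small synthetic proteome with planted GATA domains, scan it,
and compare the recovered domains against the planted truth.

With a cysteine-free background every cysteine in the cohort belongs to a
planted domain, so the scanner should recover each (protein, offset, type)
triple exactly — precision and recall both 1.0.
"""

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
print(f"generated {len(dataset.records)} protein isoforms across "
      f"{len(dataset.species)} species with {len(dataset.truth_domains)} planted domains")

hits = scan_dataset(dataset.records)
found = {(h.protein_id, h.start, h.dtype) for hs in hits.values() for h in hs}
truth = {(r.protein_id, int(r.start), r.dtype)
         for r in dataset.truth_domains.itertuples()}
tp = len(found & truth)
print(f"recovered {len(found)} domains: precision {tp / len(found):.3f}, "
      f"recall {tp / len(truth):.3f}")

by_type = dataset.truth_domains.groupby("dtype").size().sort_values(ascending=False)
print("planted type mixture:")
for dtype, n in by_type.items():
    print(f"  {dtype:>4}: {n:4d}  ({100 * n / len(dataset.truth_domains):.2f}%)")
# The mixture follows the 165-species census (IVb ~74.6%, IVc ~17.2%, ...);
# small cohorts scatter around those proportions multinomially.
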