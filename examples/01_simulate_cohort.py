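"""Simulate a two-compartment nCounter tumor series with planted entities.

Generates the default 187-sample cohort (92 supratentorial + 95
infratentorial lanes), writes one RCC file per lane plus a ground-truth
table, and prints the composition. The planted entity samples (1 EFT-CIC,
3 NB-FOXR2, 4 HGNET-MN1, 6 HGNET-BCOR) are the known positives every
downstream stage is measured against; one per entity and compartment is
tagged as the methylation-diagnosed reference sample.
"""

from pathlib import Path

import cnssig as cs

out = Path("example_output/cohort")
codeset = cs.default_codeset()

for config in (
    cs.default_supratentorial_config(seed=1),
    cs.default_infratentorial_config(seed=1),
):
    samples, truth = cs.generate_nanostring_cohort(config, codeset)
    rcc_dir = out / config.compartment
    rcc_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        cs.write_rcc(s, rcc_dir / f"{s.sample_id}.rcc")
    truth.to_csv(rcc_dir / "truth.tsv", sep="\t", index=False)

    planted = truth[truth["entity"] != ""]
    print(f"{config.compartment}: {len(samples)} lanes -> {rcc_dir}")
    print(f"  background diagnoses: {dict(config.background_diagnoses)}")
    print(f"  planted entities:     {planted['entity'].value_counts().to_dict()}")
    print(f"  reference samples:    {cs.reference_map(truth)}")

print("\nEach lane is an RCC file: probe counts for entity markers, the")
print("glioma panel, housekeeping genes (ACTB/GAPDH/LDHA) and controls.")
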