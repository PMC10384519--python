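"""Generate a synthetic apple-storage dataset and inspect its structure.

Builds the standard 180-sample design: each sample is an apple observed on a
stratified storage day; its feature row holds the four stable gas values
extracted from a simulated 15-min sensor session, and its label comes from
the dielectric fresh/not-fresh/decay progression of that day.
"""
import numpy as np

import enosecast as ec

config = ec.SimulationConfig()
dataset = ec.generate_dataset(config, n_samples=180, seed=7)

counts = np.bincount([int(l) for l in dataset.labels], minlength=3)
print(f"samples: {len(dataset)}")
print(f"label counts (fresh / not_fresh / decay): {counts[0]} / {counts[1]} / {counts[2]}")

train, test = ec.split_dataset(dataset, train_frac=0.8, seed=7)
print(f"8:2 split -> {len(train)} train / {len(test)} test")

i = 0
print(f"\nfirst sample: day {dataset.days[i]}, label {dataset.labels[i].csv_name}")
for g, v in zip(ec.GASES, dataset.features[i]):
    print(f"  {g:>9}: {v:10.2f}")
# The four numbers are the stable (plateau) concentrations the e-nose would
# report for that apple on that day: ethanol ppm, CO2 ppm, O2 %Vol, ethylene ppm.
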