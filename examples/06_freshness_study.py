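"""Run the complete freshness-prediction study end to end.

Standard design: 180 samples, 144/36 shuffled split, per-gas Tent-SSA-BP
forecasters trained on the mean training trajectory, a 4-9-3 classifier on
the stable-value features, and forecast-then-classify accuracy at 6- and
30-day prediction horizons.
"""
import enosecast as ec

result = ec.run_freshness_study(model_seed=0, horizons=(6, 30))

print(f"forecaster: window x={result.forecaster.x}, "
      f"epsilon={result.forecaster.eps:.5f} (gate {result.forecaster.gate_status})")
print(f"classifier: 4-{result.classifier.topology.n_hidden}-3, "
      f"train accuracy {result.classifier.train_accuracy:.4f}")
print()
print(f"{'horizon (days)':>15} {'n':>4} {'accuracy':>9}")
for row in result.horizons.rows:
    print(f"{row['horizon_day']:>15} {row['n']:>4} {row['accuracy']:>9.3f}")
# n counts the test apples whose future day stays inside the 40-day span at
# that horizon; accuracy compares the argmax decision on the forecasted
# features with the dielectric ground-truth label of the future day.
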