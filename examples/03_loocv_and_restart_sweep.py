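"""Leave-one-out cross-validation and the restart-probability sweep on a
benchmark-shaped synthetic dataset.

Each known (miRNA, disease) association is withheld in turn; the miRNA's
remaining diseases seed the walk and the withheld disease is ranked among
all non-associated diseases. The AUC is the probability that a withheld
true disease outranks a random negative candidate.
"""

from omimwalk import (
    RWRConfig,
    benchmark_shaped_config,
    generate,
    loocv,
    normalize,
    parameter_sweep,
    roc_from_trials,
)

sim, assoc, _ = generate(benchmark_shaped_config(rng_seed=42))
W = normalize(sim)

trials = loocv(assoc, W, RWRConfig(restart_probability=0.8))
curve = roc_from_trials(trials)
print(f"trials: {len(trials)}")
print(f"AUC at r=0.8: {curve.auc:.4f} (trapezoidal cross-check {curve.auc_trapezoid:.4f})")

rows = parameter_sweep(assoc, sim, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
print("r\tAUC")
for r, auc in rows:
    print(f"{r:.1f}\t{auc:.4f}")
best_r, best_auc = max(rows, key=lambda row: row[1])
print(f"best r: {best_r:.1f} (AUC {best_auc:.4f})")
# An AUC well above 0.5 means the walk recovers the planted cluster signal;
# the flat profile across r shows the ranking is robust to the restart
# probability.
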