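"""Paired potency ratios and Dunnett classification of mutants.

Simulates paired 3 µM / 30 µM recordings for wild type (planted ratio
0.64) and three mutants — one unchanged, one with reduced potency, one
silent — extracts peaks from the traces, then classifies each mutant
against WT with the two-stage rule: a zero-response t-test followed by a
Monte-Carlo Dunnett comparison of ratios within a one-way ANOVA frame.
"""

import numpy as np

from peptidegate import classify_mutants, potency_ratio_from_traces, simulate_potency_pairs

rng = np.random.default_rng(7)
ratios, amplitudes = {}, {}
for name, true_ratio, n in (("WT", 0.64, 14), ("M_same", 0.64, 5), ("M_loss", 0.15, 5)):
    traces, _ = simulate_potency_pairs(
        true_ratio, n_recordings=n, noise_sd_fraction=0.05,
        seed=int(rng.integers(2**31)),
    )
    r = potency_ratio_from_traces(traces)
    ratios[name] = np.array(r.per_recording)
    amplitudes[name] = rng.normal(-5.0, 0.3, n)  # clearly responsive
    print(f"{name:7}: I3/I30 = {r.ratio:.3f} ± {r.sem:.3f} (n = {r.n})")

# a construct with no measurable current at either concentration
ratios["M_dead"] = rng.normal(0.5, 0.4, 5)
amplitudes["M_dead"] = rng.normal(0.0, 0.02, 5)

classes = classify_mutants(ratios, amplitudes=amplitudes, seed=7)
print("\nclassification vs WT (reduced = significantly lower ratio):")
for name in ("M_same", "M_loss", "M_dead"):
    print(f"  {name:7}: {classes[name].label}")
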