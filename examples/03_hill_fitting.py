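"""Per-recording Hill fits of simulated concentration-response data.

Generates five recordings at a planted EC50 of 3.4 µM (Hill slope 1, 5%
multiplicative noise, half-log ladder 30 nM-100 µM), fits the Hill
equation to each recording, and reports EC50 as mean ± SEM across
recordings — the per-recording-then-average convention of oocyte
electrophysiology.
"""

from peptidegate import fit_dose_response_set, simulate_dose_response

ds, truth = simulate_dose_response(
    true_ec50=3.4e-6, true_hill=1.0, true_imax=5.0,
    n_recordings=5, noise_sd_fraction=0.05, seed=7,
)
res = fit_dose_response_set(ds)
s = res["summary"]
print(f"planted EC50: {truth.true_ec50 * 1e6:.2f} µM")
print(f"fitted  EC50: {s['ec50_mean'] * 1e6:.2f} ± {s['ec50_sem'] * 1e6:.2f} µM "
      f"(mean ± SEM, n = {s['n_recordings']})")
print(f"fitted  nH:   {s['hill_n_mean']:.2f}")
for rid, fit in res["per_recording"].items():
    print(f"  {rid}: EC50 {fit.ec50 * 1e6:5.2f} µM, nH {fit.hill_n:.2f}, "
          f"Imax {fit.imax:.2f} µA")
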