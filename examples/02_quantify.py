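"""From raw Ct values to absolute log2 copy numbers.

Spike-in correction, per-miRNA standard curves, NTC detectability calls,
duplicate averaging, and interpolation — then a check of how well the
latent simulated copy numbers are recovered.
"""

import numpy as np

import lymphomir as lm

config = lm.SimulationConfig(
    n_mirnas=120,
    n_samples_discovery={c: 8 for c in lm.CLASSES},
    n_samples_validation={c: 4 for c in lm.CLASSES},
    seed=2,
)
plates, annotation, truth = lm.simulate_cohort(config)
em, curve_qc = lm.quantify_plateset(plates)

print("expression matrix:", em.values.shape, "(samples x miRNAs)")
print("detectable entries:", f"{em.mask.to_numpy().mean():.1%}")
print("\nstandard-curve QC (first 3 miRNAs):")
print(curve_qc.head(3).to_string(index=False))

latent = truth.true_log2_copies.loc[em.values.index, em.values.columns]
err = (em.values - latent).to_numpy()[em.mask.to_numpy()]
print(f"\nrecovery of latent log2 copies: rmse {np.sqrt((err**2).mean()):.3f}"
      f" log2 units, {np.mean(np.abs(err) < 3 * config.replicate_sd):.1%}"
      " of entries within 3x the duplicate noise")
# Slopes near -3.32 and efficiencies near 1.0 mean near-perfect per-cycle
# doubling; the rmse reflects duplicate averaging of Ct noise only.
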