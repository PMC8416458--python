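"""Simulate one DDI chemical's exposure series with known ground truth.

Builds a chemical whose transcriptomic benchmark concentration (the dose at
which responsive biomarker genes depart control by one noise SD) is 10 uM,
generates the TempO-Seq-like count matrix, the comet table and the viability
curve, and prints the calibrated expectations next to the simulated data.
"""

import numpy as np

from cometddi import synthetic as syn

cfg = syn.SimulationConfig(seed=42)
truth = syn.GroundTruth("EXAMPLE", is_ddi=True, true_bmc_tgx=10.0,
                        true_bmc_comet=12.0, viability_ec50=160.0)
exp = syn.generate_test_experiment(truth, cfg)

print(f"counts: {exp.counts.shape[0]} probes x {exp.counts.shape[1]} samples, "
      f"median depth {int(exp.counts.sum().median()):,} reads")
conc = np.concatenate([[0.0], exp.concentrations])
print("concentration (uM):", np.round(conc, 2))
print("expected |log2 FC| :", np.round(syn.expected_log2fc(truth, cfg, conc), 3),
      " (crosses the noise SD of", cfg.noise_sd, "exactly at 10 uM)")
print("expected % tail DNA:", np.round(syn.expected_tail_dna(truth, cfg, conc), 2))
print("expected viability :", np.round(syn.expected_viability(truth, cfg, conc), 1))
print("simulated comet means:",
      np.round(exp.comet.groupby("concentration_uM")["median_pct_tail_dna"]
               .mean().to_numpy(), 2))
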