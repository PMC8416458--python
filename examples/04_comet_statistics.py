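"""CometChip statistics: assumption-checked ANOVA, Dunnett, hazard call.

Simulates median % tail DNA for a chemical with a comet benchmark
concentration of 12 uM and prints the per-concentration comparison table
against the matched vehicle control.
"""

from cometddi import comet as cm
from cometddi import synthetic as syn

cfg = syn.SimulationConfig(seed=5)
truth = syn.GroundTruth("DAMAGER", True, true_bmc_tgx=10.0, true_bmc_comet=12.0)
exp = syn.generate_test_experiment(truth, cfg)

res = cm.analyze_comet_table(exp.comet)["DAMAGER"]
print(f"one-way ANOVA p = {res.anova_p:.2e} "
      f"(rank transform used: {res.used_rank_transform})")
print(res.table[["concentration_uM", "mean", "se", "diff_vs_control",
                 "raw_p", "adj_p", "significant"]].round(4).to_string(index=False))
print(f"hazard call: {'positive' if res.positive_call else 'negative'} "
      "(requires a significant increase at a non-cytotoxic concentration)")
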