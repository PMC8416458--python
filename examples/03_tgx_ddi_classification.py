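"""TGx-DDI classification: train the biomarker model, classify two chemicals.

Trains the 64-gene nearest-shrunken-centroid model on simulated reference
compounds (shrinkage chosen by cross-validation, then frozen), then runs the
three analyses (NSC probability, PCA projection, hierarchical clustering)
per concentration for a genotoxic and an inert chemical.  A concentration is
DDI if any analysis calls DDI; a chemical is DDI if any non-cytotoxic
concentration is.
"""

import pandas as pd

from cometddi import classify as cls
from cometddi import qc
from cometddi import synthetic as syn

cfg = syn.SimulationConfig(seed=3)
mat, labels = syn.generate_training_set(cfg)
training = cls.TrainingSet(mat, labels)
delta = cls.choose_delta(training)
print(f"cross-validated shrinkage delta = {delta:.2f}; "
      f"{cls.train_nsc(training, delta).n_active_genes()} active genes")

for truth in (syn.GroundTruth("GENOTOXIC", True, true_bmc_tgx=10.0),
              syn.GroundTruth("INERT", False)):
    exp = syn.generate_test_experiment(truth, cfg)
    norm = qc.normalize_counts(exp.counts)
    gene_level = cls.collapse_probes(norm.log2_shifted, exp.probe_gene_map,
                                     required_genes=pd.Index(training.genes))
    profiles, _ = cls.condition_log2fc(gene_level, exp.metadata)
    calls = cls.classify_conditions(training, profiles, delta)
    print(f"\n{truth.chemical_id}:")
    print("  conc(uM)   PA        PCA       HC        P(DDI)  overall")
    for c in calls:
        print(f"  {c.concentration:8.2f} {c.pa_call:9s} {c.pca_call:9s} "
              f"{c.hc_call:9s} {c.posterior_ddi:6.3f}  {c.overall}")
    overall = cls.chemical_call({c.concentration: c.overall for c in calls})
    print(f"  chemical-level call: {overall}")
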