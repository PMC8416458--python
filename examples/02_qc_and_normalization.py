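"""Sample QC: inject three kinds of bad samples and watch the filters fire.

A clean simulated experiment is augmented with a low-depth column, a
rank-decorrelated 'singleton' column, and a column with reads piled on a
handful of probes; the QC rules (minimum reads, Tukey outer-fence metric
outliers, singleton clustering) each catch their target.
"""

import pandas as pd

from cometddi import qc
from cometddi import synthetic as syn

cfg = syn.SimulationConfig(seed=7)
exp = syn.generate_test_experiment(syn.GroundTruth("CLEAN", False), cfg)

counts = exp.counts.copy()
for kind in ("low_depth", "singleton", "skewed"):
    bad = syn.generate_corrupt_samples(kind, cfg, template=exp.counts)
    counts[bad.name] = bad

metrics = qc.qc_metrics(counts)
flags = qc.flag_metric_outliers(metrics)
norm = qc.normalize_counts(counts)
singles = qc.detect_singletons(norm.log2_shifted)

report = metrics.join(flags).join(singles)
bad_rows = report[report.index.str.startswith("CORRUPT")]
print(bad_rows[["total_reads", "gini", "n_active",
                "outlier_gini", "is_singleton"]])
meta = pd.concat([exp.metadata, pd.DataFrame(
    [dict(sample_id=s, chemical="CLEAN", concentration_uM=0.0,
          replicate=90 + i, is_vehicle=True)
     for i, s in enumerate(counts.columns[-3:])])], ignore_index=True)
exclusions = qc.filter_samples(metrics, meta, outlier_flags=flags,
                               singleton_flags=singles)
print("\nexclusions (sample -> reason):")
print(exclusions.to_string(index=False))
print("\nclean samples excluded:",
      (~exclusions['sample_id'].str.startswith('CORRUPT')).sum())
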