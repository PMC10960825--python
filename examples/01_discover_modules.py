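"""Discover disease-associated multi-omic modules on synthetic data.

Generates a benchmark dataset with one planted cross-omic module (5 taxa,
5 pathways, 5 metabolites sharing a latent factor that separates cases
from controls), runs the full pipeline (preprocessing, 100 sGCCA fits on
80% subsamples, consensus network at the 0.8 co-occurrence threshold,
null-module evaluation), and prints what it found.
"""

import crossomic as co

dataset, truth = co.generate_dataset(co.SyntheticSpec(seed=11))
result = co.run_pipeline(dataset, co.PipelineConfig(seed=11))

print(f"consensus modules found: {len(result.modules)}")
for module in result.modules:
    ev = module.evaluation
    print(
        f"  {module.module_id}: {len(module)} features {module.omic_counts}, "
        f"PC1 AUC {ev.auc:.3f} (null {ev.auc_null.null_mean:.3f}), "
        f"cross-omic rho {ev.cross_omic_rho:.3f} (null {ev.rho_null.null_mean:.3f}), "
        f"disease-associated: {ev.is_disease_associated}"
    )

score = co.recovery_score([m.feature_ids for m in result.modules], truth)
print(f"best F1 against the planted module: {score['mean_f1']:.3f}")

# The module whose PC1 AUC clearly beats size-matched random modules and
# whose member features correlate across omics is the planted one; an AUC
# near the null mean would mean the module merely reflects within-omic
# covariance, not the phenotype.
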