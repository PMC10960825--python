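"""Shared preprocessing of raw omic tables.

Taxa/pathway tables are total-sum-scaled to relative abundances; metabolite
intensities are log-transformed; constant, rare (<15% prevalence), very
low-abundance (<0.005% mean, compositional omics only) and near-duplicate
(|Spearman| > 0.99) features are removed with a per-feature report.
"""

import crossomic as co
from crossomic.pipeline import preprocess_dataset

dataset, _ = co.generate_dataset(
    co.SyntheticSpec(
        n_samples=100,
        n_features={"T": 60, "M": 30},
        # sigma=0.05 makes planted metabolites near-duplicates (|rho| > 0.99)
        # so the collinearity clustering has work to do
        modules=[co.ModuleSpec({"T": 3, "M": 3}, alpha=1.0, sigma=0.05)],
        dropout=0.85,  # zero-inflate taxa so the prevalence filter has work
        seed=2,
    )
)

processed, report = preprocess_dataset(dataset, co.PipelineConfig(seed=2))

for omic in processed.omics:
    before = dataset.omic(omic.omic_id).n_features
    print(f"omic {omic.omic_id}: {before} -> {omic.n_features} features "
          f"({omic.scale_state.value} scale)")

frame = report.to_frame()
print("\nremoval reasons:")
print(frame["reason"].value_counts().to_string())

# Rows of the T table stay a (sub)composition after filtering: the
# remaining relative abundances are never re-normalized, matching how the
# thresholds are defined.
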