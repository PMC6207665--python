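"""Benchmark the four feature-based classifiers with leave-one-out ROC.

Simulates a small five-stage cohort, extracts morphological features and
evaluates ANN, MLR, SVM and RF by leave-one-out cross-validation on the
four Metavir staging dichotomies.  Prints one AUROC per model and
dichotomy: 1.0 is perfect stage discrimination, 0.5 is chance.
"""

from fibrostage import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=0, n_per_stage=6, image_size=256,
                     models=("ann", "mlr", "svm", "rf"), n_boot=50)
table, comparisons, features = run_pipeline(cfg)

print(table.pivot(index="dichotomy", columns="model",
                  values="auroc").round(3))
kw = comparisons[("morph", "F0-2 vs F3-4")]
print(f"\nKruskal-Wallis across models (advanced fibrosis): "
      f"p = {kw.kw_p:.3g}; {sum(kw.significant.values())} of "
      f"{len(kw.pairwise_p)} pairwise tests significant at "
      f"p < {kw.critical_p:.4g}")
print("High AUROCs mean the morphological features separate early from "
      "advanced fibrosis in this cohort.")
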