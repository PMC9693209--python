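"""Run the seven-classifier harness on all vs selected indices.

Trains each classifier on a stratified 75/25 split of the default
synthetic feature table, once with all eight indices and once with the
four selective indicators (RVSI, PSNDb, PSSRb, CI-RedEdge), and prints
the overall accuracies.
"""

from fluorostress import SceneParams, benchmark, benchmark_frame, make_dataset

table = make_dataset(SceneParams(seed=0))
reports = benchmark(table, seeds=(0,))
frame = benchmark_frame(reports)

pivot = frame.pivot_table(index="classifier", columns="feature_set", values="accuracy")
print(pivot.round(2).to_string())
best = frame.loc[frame.accuracy.idxmax()]
print(f"\nbest cell: {best.classifier} / {best.feature_set} "
      f"accuracy={best.accuracy:.2f}")
# Tree ensembles handle the non-linearly separable index space well;
# kernel SVMs trail. The 4-index column shows how much signal the
# selective indicators retain relative to the full set.
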