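"""Generate a synthetic variant cohort and encode it for the model.

Builds a desk-scale cohort (labeled ~1:3 oncogenic:benign, an unlabeled
pool, a held-out test set), then runs the preprocessing pipeline: drop
variants with >13 missing features, impute the rest with 40-neighbour
means, one-hot + dither the 12 discrete evidence scores, and min-max
scale the 23 continuous predictor scores.
"""

import numpy as np

from sganvi import experiments, synthetic

config = synthetic.reference_config(seed=1, n_unlabeled=2000)
dataset = synthetic.generate_dataset(config)
print(f"labeled:   {len(dataset.labeled_table)} rows "
      f"({(dataset.labeled_table['label'] == 'oncogenic').sum()} oncogenic)")
print(f"unlabeled: {len(dataset.unlabeled_table)} rows")
print(f"test:      {len(dataset.test_table)} rows")
missing = dataset.labeled_table.iloc[:, 2:].isna().to_numpy().mean()
print(f"missing entries in the raw labeled table: {missing:.1%}")

data = experiments.prepare(dataset, pipeline_seed=1)
print(f"\nencoded matrix: {data.labeled.matrix.shape} "
      f"({(data.labeled.blocks == 'evidence').sum()} evidence columns + "
      f"{(data.labeled.blocks == 'score').sum()} score columns)")
print("score block range:",
      float(data.labeled.matrix[:, data.labeled.blocks == 'score'].min()),
      "to",
      float(data.labeled.matrix[:, data.labeled.blocks == 'score'].max()))
# The printed shape is n_variants x 71: each of the 12 evidence scores
# occupies four dithered one-hot slots, the 23 predictor scores one
# scaled column each.
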