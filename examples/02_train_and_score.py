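"""Train the semi-supervised adversarial model and score variants.

Trains at desk scale (small nets, a few epochs) on 250 labeled plus 2,000
unlabeled variants, then reports the eight-metric evaluation panel on the
held-out test set.  The interpretation score of a variant is the softmax
probability of the oncogenic class; a variant is called oncogenic when the
score exceeds the cutoff (0.5 here).
"""

import numpy as np

from sganvi import experiments, metrics, synthetic, trainer

dataset = synthetic.generate_dataset(
    synthetic.reference_config(seed=1, n_unlabeled=2000))
data = experiments.prepare(dataset, pipeline_seed=1)

rng = np.random.default_rng(0)
labeled = trainer.select_label_budget(data.labeled, 250, rng)
config = trainer.TrainingConfig(epochs=20, seed=0)
model, history = trainer.train(labeled, data.unlabeled, config,
                               gen_spec=experiments.DESK_GENERATOR_SPEC,
                               disc_spec=experiments.DESK_DISCRIMINATOR_SPEC)
print(f"final losses: supervised={history.supervised[-1]:.3f} "
      f"unsupervised={history.unsupervised[-1]:.3f} "
      f"feature-matching={history.generator[-1]:.4f}")

scores = metrics.interpretation_scores(model, data.test)
report = metrics.evaluate(scores, data.test.label_ints(), cutoff=0.5)
for name, value in report.to_dict().items():
    print(f"{name:>12s}: {value:.3f}")
# MCC is the headline number (class-imbalance robust, in [-1, 1]);
# ROC-AUC / PR-AUC are cutoff-free ranking quality.
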