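"""t-SNE view of generated vs real variants.

Embeds generated (fake) samples, unlabeled variants and labeled variants
in 2-d.  A well-trained generator's samples trace the data clusters, and
unlabeled points colored by interpretation score should separate along
the labeled classes.  Writes embedding.png to the working directory.
"""

import numpy as np

from sganvi import experiments, metrics, synthetic, trainer

dataset = synthetic.generate_dataset(
    synthetic.reference_config(seed=1, n_unlabeled=2000))
data = experiments.prepare(dataset, pipeline_seed=1)

rng = np.random.default_rng(0)
labeled = trainer.select_label_budget(data.labeled, 1000, rng)
model, _ = trainer.train(labeled, data.unlabeled,
                         trainer.TrainingConfig(epochs=15, seed=0),
                         gen_spec=experiments.DESK_GENERATOR_SPEC,
                         disc_spec=experiments.DESK_DISCRIMINATOR_SPEC)

fake = model.generator.sample(400, rng, train=False)
unl_idx = rng.choice(data.unlabeled.n, 400, replace=False)
lab_idx = rng.choice(labeled.n, 400, replace=False)
unl = data.unlabeled.subset_rows(unl_idx)
scores = metrics.interpretation_scores(model, unl)
emb = experiments.embedding_plot(
    fake, unl.matrix, labeled.matrix[lab_idx], labeled.label_ints()[lab_idx],
    "embedding.png", unlabeled_scores=scores, seed=0)
print(f"embedded {emb.shape[0]} points; figure written to embedding.png")
print(f"mean interpretation score of embedded unlabeled variants: "
      f"{scores.mean():.3f}")
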