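"""Scripted experiment designs on synthetic data.

Each entry point trains models at desk scale and returns a tidy DataFrame
of metric rows, so the label-budget sweep, the feature-group ablation and
the supervised-only comparison can be reproduced from a seed with one
call.  Desk scale means the reference synthetic configuration (10,000
unlabeled rows), 200 epochs and small networks; the published-scale
settings (60,000 unlabeled, 2,000 epochs, wider nets) remain reachable
through the same config objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import trainer as _trainer
from .feature_pipeline import FeaturePipeline
from .sgan_core import GeneratorSpec, DiscriminatorSpec
from .synthetic import SyntheticDataset

__all__ = [
    "DESK_GENERATOR_SPEC", "DESK_DISCRIMINATOR_SPEC", "desk_config",
    "PreparedData", "prepare", "label_budget_sweep",
    "feature_group_ablation", "supervised_ablation", "aggregate_sweep",
    "score_histograms", "embedding_plot",
]

DEFAULT_BUDGETS = (250, 500, 1000, 2000, 4000)
FEATURE_GROUPS = ("score", "evidence", "ensemble")

# small desk-scale networks (single-precision); the module-level defaults
# are the wide double-precision ones
DESK_GENERATOR_SPEC = GeneratorSpec(hidden_sizes=(32, 64, 128), dtype="float32")
DESK_DISCRIMINATOR_SPEC = DiscriminatorSpec(channels=(8, 16, 32), dtype="float32")


def desk_config(seed: int = 0, epochs: int = 200,
                **overrides) -> _trainer.TrainingConfig:
    return _trainer.TrainingConfig(epochs=epochs, seed=seed, **overrides)


class PreparedData:
    """A dataset pushed through a pipeline fitted on labeled + unlabeled."""

    def __init__(self, dataset: SyntheticDataset, pipeline_seed: int = 0,
                 k: int = 40, imputer_reference_limit: int | None = 4000) -> None:
        self.dataset = dataset
        train_pool = pd.concat(
            [dataset.labeled_table, dataset.unlabeled_table],
            ignore_index=True)
        self.pipeline = FeaturePipeline(
            k=k, seed=pipeline_seed,
            imputer_reference_limit=imputer_reference_limit)
        self.pipeline.fit(train_pool)
        self.labeled = self.pipeline.transform(dataset.labeled_table)
        self.unlabeled = self.pipeline.transform(dataset.unlabeled_table)
        self.test = self.pipeline.transform(dataset.test_table)


def prepare(dataset: SyntheticDataset, pipeline_seed: int = 0,
            k: int = 40,
            imputer_reference_limit: int | None = 4000) -> PreparedData:
    return PreparedData(dataset, pipeline_seed=pipeline_seed, k=k,
                        imputer_reference_limit=imputer_reference_limit)


def _run_sgan(data: PreparedData, budget: int, seed: int, epochs: int,
              group: str = "ensemble") -> _metrics.MetricReport:
    labeled = data.labeled.select_block(group)
    unlabeled = data.unlabeled.select_block(group)
    test = data.test.select_block(group)
    rng = np.random.default_rng(np.random.SeedSequence([seed, budget]))
    subset = _trainer.select_label_budget(labeled, budget, rng)
    config = desk_config(seed=seed, epochs=epochs)
    model, _ = _trainer.train(subset, unlabeled, config,
                              gen_spec=DESK_GENERATOR_SPEC,
                              disc_spec=DESK_DISCRIMINATOR_SPEC)
    scores = _metrics.interpretation_scores(model, test)
    return _metrics.evaluate(scores, test.label_ints())


def _report_row(report: _metrics.MetricReport, **keys) -> dict:
    row = dict(keys)
    row.update(report.to_dict())
    return row


def label_budget_sweep(data: PreparedData,
                       budgets: tuple[int, ...] = DEFAULT_BUDGETS,
                       seeds: tuple[int, ...] = (0,),
                       epochs: int = 200) -> pd.DataFrame:
    """Train one SGAN per (budget, seed) and evaluate on the test table."""
    if max(budgets) > data.labeled.n:
        raise ValueError(f"budget {max(budgets)} exceeds labeled pool "
                         f"({data.labeled.n})")
    rows = []
    for budget in budgets:
        for seed in seeds:
            report = _run_sgan(data, budget, seed, epochs)
            rows.append(_report_row(report, label_budget=budget,
                                    feature_group="ensemble", seed=seed,
                                    method="sgan"))
    return pd.DataFrame(rows)


def feature_group_ablation(data: PreparedData,
                           groups: tuple[str, ...] = FEATURE_GROUPS,
                           budget: int = 1000,
                           seeds: tuple[int, ...] = (0,),
                           epochs: int = 200) -> pd.DataFrame:
    """Train per feature group: continuous scores only (23 columns),
    evidence one-hot only (48 columns), or the full ensemble (71)."""
    unknown = set(groups) - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature group(s): {sorted(unknown)}")
    rows = []
    for group in groups:
        for seed in seeds:
            report = _run_sgan(data, budget, seed, epochs, group=group)
            rows.append(_report_row(report, label_budget=budget,
                                    feature_group=group, seed=seed,
                                    method="sgan"))
    return pd.DataFrame(rows)


def supervised_ablation(data: PreparedData, budget: int,
                        seeds: tuple[int, ...] = (0,),
                        epochs: int = 200) -> pd.DataFrame:
    """Paired SGAN vs supervised-only runs at one label budget.

    The baseline trains the same discriminator architecture with the
    supervised loss only — no generator, no unlabeled rows — for the same
    number of optimizer steps as the SGAN run.
    """
    steps = epochs * _trainer._steps_per_epoch(
        data.unlabeled.n, desk_config().unlabeled_batch)
    rows = []
    for seed in seeds:
        rows.append(_report_row(_run_sgan(data, budget, seed, epochs),
                                label_budget=budget, feature_group="ensemble",
                                seed=seed, method="sgan"))
        rng = np.random.default_rng(np.random.SeedSequence([seed, budget]))
        subset = _trainer.select_label_budget(data.labeled, budget, rng)
        config = desk_config(seed=seed, epochs=epochs)
        model, _ = _trainer.train_supervised(
            subset, config, disc_spec=DESK_DISCRIMINATOR_SPEC, n_steps=steps)
        scores = _metrics.interpretation_scores(model, data.test)
        report = _metrics.evaluate(scores, data.test.label_ints())
        rows.append(_report_row(report, label_budget=budget,
                                feature_group="ensemble", seed=seed,
                                method="supervised"))
    return pd.DataFrame(rows)


def aggregate_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of every metric per (method, feature_group, budget)."""
    metric_cols = ["accuracy", "precision", "sensitivity", "specificity",
                   "f1", "mcc", "roc_auc", "pr_auc"]
    g = sweep.groupby(["method", "feature_group", "label_budget"])[metric_cols]
    out = g.agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def score_histograms(scores_by_method: dict[str, np.ndarray],
                     truth: np.ndarray, n_bins: int = 20) -> pd.DataFrame:
    """Binned interpretation-score counts per class per method."""
    truth = np.asarray(truth).astype(bool)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for method, scores in scores_by_method.items():
        scores = np.asarray(scores, dtype=np.float64)
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError(f"scores for {method!r} fall outside [0, 1]")
        for cls, mask in (("benign", ~truth), ("oncogenic", truth)):
            counts, _ = np.histogram(scores[mask], bins=edges)
            for left, right, count in zip(edges[:-1], edges[1:], counts):
                rows.append({"method": method, "class": cls,
                             "bin_left": left, "bin_right": right,
                             "count": int(count)})
    return pd.DataFrame(rows)


def embedding_plot(fake: np.ndarray, unlabeled: np.ndarray,
                   labeled: np.ndarray, labeled_classes: np.ndarray,
                   path: str, unlabeled_scores: np.ndarray | None = None,
                   seed: int = 0) -> np.ndarray:
    """2-d t-SNE of fake/unlabeled/labeled points, colored by source (and,
    if scores are given, by interpretation-score gradient).  Returns the
    embedding coordinates; writes a figure to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    blocks = [np.asarray(b, dtype=np.float64) for b in (fake, unlabeled, labeled)]
    if len({b.shape[1] for b in blocks}) != 1:
        raise ValueError("all point sets must share one column manifest")
    stacked = np.vstack(blocks)
    n_fake, n_unl, n_lab = (b.shape[0] for b in blocks)
    perplexity = min(30.0, max(2.0, (stacked.shape[0] - 1) / 4))
    emb = TSNE(n_components=2, random_state=seed,
               perplexity=perplexity, init="pca").fit_transform(stacked)

    fig, axes = plt.subplots(1, 2 if unlabeled_scores is not None else 1,
                             figsize=(11, 5), squeeze=False)
    ax = axes[0, 0]
    ax.scatter(*emb[:n_fake].T, s=4, c="tab:orange", label=f"fake (n={n_fake})")
    ax.scatter(*emb[n_fake:n_fake + n_unl].T, s=4, c="lightgrey",
               label=f"unlabeled (n={n_unl})")
    lab_emb = emb[n_fake + n_unl:]
    onc = np.asarray(labeled_classes) == 1
    ax.scatter(*lab_emb[~onc].T, s=6, c="darkblue", label=f"benign (n={int((~onc).sum())})")
    ax.scatter(*lab_emb[onc].T, s=6, c="darkred", label=f"oncogenic (n={int(onc.sum())})")
    ax.legend(markerscale=3, fontsize=8)
    ax.set_title("t-SNE by source")
    if unlabeled_scores is not None:
        ax2 = axes[0, 1]
        sc = ax2.scatter(*emb[n_fake:n_fake + n_unl].T, s=4,
                         c=np.asarray(unlabeled_scores), cmap="coolwarm",
                         vmin=0, vmax=1)
        fig.colorbar(sc, ax=ax2, label="interpretation score")
        ax2.set_title("unlabeled pool by predicted oncogenicity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return emb
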