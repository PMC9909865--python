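"""Table I/O and checkpointing.

Feature tables travel as TSV with a header row: ``variant_id``, ``label``
(oncogenic|benign|unlabeled, or 1|0|NA), twelve ``evi_*`` and twenty-three
``score_*`` columns; an empty field or ``.`` marks a missing value.

A checkpoint is a single ``.npz`` archive of named numeric arrays plus one
JSON metadata string — network specs, column manifest, preprocessing
states and training config — so a loaded model reproduces the saving
model's interpretation scores bitwise and refuses tables whose manifest
does not match.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import nn
from .feature_pipeline import (FEATURE_COLUMNS, EVIDENCE_LEVELS,
                               FeaturePipeline, validate_table)
from .sgan_core import (Generator, Discriminator, GeneratorSpec,
                        DiscriminatorSpec)
from .trainer import SGANModel, SupervisedModel, TrainingConfig

__all__ = ["read_feature_table", "write_feature_table", "write_scores",
           "read_scores", "save_checkpoint", "load_checkpoint",
           "CHECKPOINT_VERSION"]

CHECKPOINT_VERSION = 1

_LABEL_SYNONYMS = {"oncogenic": "oncogenic", "1": "oncogenic",
                   "benign": "benign", "0": "benign",
                   "unlabeled": "unlabeled", "na": "unlabeled",
                   "nan": "unlabeled", "": "unlabeled"}


def read_feature_table(path) -> pd.DataFrame:
    """Read and validate a raw feature table from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "label": str},
                     na_values=["."], keep_default_na=True)
    required = ["variant_id", "label", *FEATURE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df["label"] = (df["label"].astype(str).str.strip().str.lower()
                   .map(_LABEL_SYNONYMS))
    if df["label"].isna().any():
        rows = df.index[df["label"].isna()].tolist()[:5]
        raise ValueError(f"unrecognized label values at rows {rows}")
    for col in FEATURE_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric entries in column {col!r}: {exc}") from exc
    evi = df[[c for c in FEATURE_COLUMNS if c.startswith("evi_")]]
    bad = ~(evi.isna() | evi.isin(EVIDENCE_LEVELS))
    if bad.to_numpy().any():
        rows = df.index[bad.any(axis=1)].tolist()[:10]
        raise ValueError(f"evidence values outside {EVIDENCE_LEVELS} at rows "
                         f"{rows}")
    return validate_table(df[required])


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=".")


def write_scores(variant_ids: np.ndarray, scores: np.ndarray,
                 calls: np.ndarray, path, cutoff: float = 0.5) -> None:
    pd.DataFrame({"variant_id": variant_ids,
                  "interpretation_score": scores,
                  "call_at_cutoff": np.where(calls, "oncogenic", "benign"),
                  "cutoff": cutoff}).to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant_id": str})


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _net_arrays(prefix: str, net) -> dict[str, np.ndarray]:
    arrays = {f"{prefix}_param_{i}": p.value
              for i, p in enumerate(net.parameters())}
    i = 0
    for layer in _walk_layers(net):
        if isinstance(layer, nn.BatchNorm1d):
            arrays[f"{prefix}_bn_mean_{i}"] = layer.running_mean
            arrays[f"{prefix}_bn_var_{i}"] = layer.running_var
            i += 1
    return arrays


def _walk_layers(net):
    if isinstance(net, Generator):
        yield from net.net.layers
    elif isinstance(net, Discriminator):
        yield from net.trunk.layers
        yield net.head
    elif isinstance(net, nn.Sequential):
        yield from net.layers
    else:
        yield net


def _load_net_arrays(prefix: str, net, data) -> None:
    for i, p in enumerate(net.parameters()):
        value = data[f"{prefix}_param_{i}"]
        if value.shape != p.value.shape:
            raise ValueError(f"shape mismatch for {prefix}_param_{i}")
        p.value = value.copy()
        p.grad = np.zeros_like(p.value)
    i = 0
    for layer in _walk_layers(net):
        if isinstance(layer, nn.BatchNorm1d):
            layer.running_mean = data[f"{prefix}_bn_mean_{i}"].copy()
            layer.running_var = data[f"{prefix}_bn_var_{i}"].copy()
            i += 1


def save_checkpoint(model, path, pipeline: FeaturePipeline | None = None,
                    config: TrainingConfig | None = None,
                    epoch: int | None = None) -> None:
    """Serialize a trained (or initialized) model, optionally with its
    fitted preprocessing pipeline and training config."""
    meta: dict = {
        "version": CHECKPOINT_VERSION,
        "kind": "sgan" if isinstance(model, SGANModel) else "supervised",
        "columns": list(model.columns),
        "disc_spec": asdict(model.discriminator.spec),
        "epoch": epoch,
    }
    arrays = _net_arrays("disc", model.discriminator)
    if isinstance(model, SGANModel):
        meta["gen_spec"] = asdict(model.generator.spec)
        arrays.update(_net_arrays("gen", model.generator))
    if config is not None:
        meta["training_config"] = asdict(config)
        meta["seed"] = config.seed
    if pipeline is not None:
        if not pipeline._fitted:
            raise ValueError("pipeline must be fitted before checkpointing")
        meta["pipeline"] = {"k": pipeline.imputer.k,
                            "max_missing": pipeline.max_missing,
                            "noise_sd": pipeline.encoder.noise_sd,
                            "encoder_seed": pipeline.encoder.seed}
        arrays["scaler_min"] = pipeline.scaler.col_min
        arrays["scaler_max"] = pipeline.scaler.col_max
        arrays["imputer_reference"] = pipeline.imputer._imputer._fit_X
    np.savez_compressed(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path):
    """Rebuild (model, pipeline_or_None, meta) from a checkpoint archive."""
    try:
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
    except Exception as exc:
        raise ValueError(f"unreadable or truncated checkpoint: {exc}") from exc
    version = meta.get("version")
    if version != CHECKPOINT_VERSION:
        raise ValueError(f"checkpoint version {version} != supported "
                         f"version {CHECKPOINT_VERSION}")
    rng = np.random.default_rng(0)  # weights are overwritten below
    disc = Discriminator(DiscriminatorSpec(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in meta["disc_spec"].items()}), rng)
    _load_net_arrays("disc", disc, data)
    if meta["kind"] == "sgan":
        gen = Generator(GeneratorSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["gen_spec"].items()}), rng)
        _load_net_arrays("gen", gen, data)
        model = SGANModel(gen, disc, meta["columns"])
    else:
        model = SupervisedModel(disc, meta["columns"])

    pipeline = None
    if "pipeline" in meta:
        p = meta["pipeline"]
        pipeline = FeaturePipeline(k=p["k"], noise_sd=p["noise_sd"],
                                   seed=p["encoder_seed"],
                                   max_missing=p["max_missing"])
        ref = pd.DataFrame(data["imputer_reference"],
                           columns=list(FEATURE_COLUMNS))
        pipeline.imputer.fit(ref)
        pipeline.scaler.col_min = data["scaler_min"].copy()
        pipeline.scaler.col_max = data["scaler_max"].copy()
        pipeline._fitted = True
    return model, pipeline, meta
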