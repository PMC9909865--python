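"""Raw annotation table -> numeric model input.

A raw per-variant table carries 12 discrete clinical-evidence scores (each
in {-1, 0, 1, 2}: benign evidence, no support, supporting, strong) and 23
continuous deleteriousness scores from third-party predictors, with missing
entries.  The pipeline is:

1. drop variants with more than ``max_missing`` (default 13) missing values
   across the 35 feature columns;
2. impute remaining gaps with the mean of the 40 nearest neighbours
   (nan-Euclidean distance over mutually observed columns);
3. one-hot encode each evidence score over the fixed level order
   (-1, 0, 1, 2) and dither every slot with seeded Gaussian noise
   (mean 0, SD 0.02) so the discrete block becomes continuous;
4. min-max scale the continuous scores to [0, 1] using ranges observed on
   the fitting (training) set, clipping out-of-range values at apply time.

The result is a 71-column matrix (12 x 4 one-hot slots + 23 scores) with a
manifest recording every column's name and block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "EVIDENCE_COLUMNS",
    "SCORE_COLUMNS",
    "FEATURE_COLUMNS",
    "EVIDENCE_LEVELS",
    "LABEL_VALUES",
    "validate_table",
    "filter_by_missingness",
    "NeighborImputer",
    "EvidenceEncoder",
    "MinMaxScaler",
    "EncodedMatrix",
    "FeaturePipeline",
]

N_EVIDENCE = 12
N_SCORES = 23
EVIDENCE_COLUMNS = tuple(f"evi_{i}" for i in range(1, N_EVIDENCE + 1))
SCORE_COLUMNS = tuple(f"score_{i}" for i in range(1, N_SCORES + 1))
FEATURE_COLUMNS = EVIDENCE_COLUMNS + SCORE_COLUMNS
EVIDENCE_LEVELS = (-1, 0, 1, 2)
LABEL_VALUES = ("benign", "oncogenic", "unlabeled")


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the raw-table contract; returns the table unchanged."""
    missing_cols = [c for c in ("variant_id", "label", *FEATURE_COLUMNS)
                    if c not in table.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    if table["variant_id"].duplicated().any():
        dup = table.loc[table["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant_id: {dup!r}")
    bad_labels = set(table["label"].unique()) - set(LABEL_VALUES)
    if bad_labels:
        raise ValueError(f"unknown label values: {sorted(bad_labels)}")
    evi = table[list(EVIDENCE_COLUMNS)].to_numpy(dtype=np.float64)
    observed = evi[~np.isnan(evi)]
    if not np.isin(observed, EVIDENCE_LEVELS).all():
        bad = observed[~np.isin(observed, EVIDENCE_LEVELS)]
        raise ValueError(f"evidence values outside {EVIDENCE_LEVELS}: "
                         f"e.g. {bad[:5].tolist()}")
    return table


def filter_by_missingness(table: pd.DataFrame, max_missing: int = 13) -> pd.DataFrame:
    """Keep rows with at most ``max_missing`` missing feature values.

    Row order is preserved; an empty result is allowed.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be non-negative")
    n_missing = table[list(FEATURE_COLUMNS)].isna().sum(axis=1)
    return table.loc[n_missing <= max_missing].reset_index(drop=True)


class NeighborImputer:
    """k-nearest-neighbour mean imputation over the 35 raw feature columns.

    Distances are nan-Euclidean: squared differences over mutually observed
    coordinates, rescaled by the fraction observed.  Each gap is filled with
    the mean of the column over the k nearest reference rows that observe
    it (fewer if fewer exist).
    """

    def __init__(self, k: int = 40, reference_limit: int | None = None,
                 seed: int = 0) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.reference_limit = reference_limit
        self.seed = seed
        self._imputer: KNNImputer | None = None

    def fit(self, table: pd.DataFrame) -> "NeighborImputer":
        ref = table[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
        if ref.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit the imputer")
        if (self.reference_limit is not None
                and ref.shape[0] > self.reference_limit):
            # neighbour means over a large random reference are statistically
            # indistinguishable from the full pool at a fraction of the cost
            rng = np.random.default_rng(self.seed)
            keep = np.sort(rng.choice(ref.shape[0], self.reference_limit,
                                      replace=False))
            ref = ref[keep]
        all_missing = np.isnan(ref).all(axis=0)
        if all_missing.any():
            names = [FEATURE_COLUMNS[i] for i in np.flatnonzero(all_missing)]
            raise ValueError(f"column(s) missing in every row: {names}")
        k_eff = min(self.k, ref.shape[0] - 1)
        self._imputer = KNNImputer(n_neighbors=k_eff, weights="uniform",
                                   keep_empty_features=True)
        self._imputer.fit(ref)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self._imputer is None:
            raise RuntimeError("imputer not fitted")
        raw = table[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
        filled = self._imputer.transform(raw)
        out = table.copy()
        out[list(FEATURE_COLUMNS)] = filled
        return out

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


@dataclass
class EvidenceEncoder:
    """One-hot + Gaussian dither encoding for the 12 evidence columns.

    Continuous (imputed) evidence values are rounded to the nearest level
    first; a value that rounds outside {-1, 0, 1, 2} is an error.  The
    dither (mean 0, SD ``noise_sd``) is drawn once per encode call from a
    generator seeded with ``seed``, so encoding is deterministic.
    """

    noise_sd: float = 0.02
    seed: int = 0
    levels: tuple[int, ...] = EVIDENCE_LEVELS

    @property
    def column_names(self) -> list[str]:
        return [f"{c}={lv}" for c in EVIDENCE_COLUMNS for lv in self.levels]

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        evi = table[list(EVIDENCE_COLUMNS)].to_numpy(dtype=np.float64)
        if np.isnan(evi).any():
            raise ValueError("evidence block contains missing values; impute first")
        rounded = np.rint(evi)
        if not np.isin(rounded, self.levels).all():
            bad = rounded[~np.isin(rounded, self.levels)]
            raise ValueError(f"evidence values round outside {self.levels}: "
                             f"e.g. {bad[:5].tolist()}")
        n = evi.shape[0]
        onehot = np.zeros((n, N_EVIDENCE, len(self.levels)))
        for j, lv in enumerate(self.levels):
            onehot[:, :, j] = rounded == lv
        onehot = onehot.reshape(n, N_EVIDENCE * len(self.levels))
        if self.noise_sd > 0:
            rng = np.random.default_rng(self.seed)
            onehot = onehot + rng.normal(0.0, self.noise_sd, onehot.shape)
        return onehot


class MinMaxScaler:
    """Per-column min-max scaling to [0, 1], fitted once, clipping at apply.

    A constant column cannot be rescaled; it maps to 0 and a warning is
    issued at fit time.
    """

    def __init__(self) -> None:
        self.col_min: np.ndarray | None = None
        self.col_max: np.ndarray | None = None

    def fit(self, block: np.ndarray) -> "MinMaxScaler":
        block = np.asarray(block, dtype=np.float64)
        self.col_min = block.min(axis=0)
        self.col_max = block.max(axis=0)
        constant = self.col_max == self.col_min
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant column(s) in the score block "
                "map to 0 after scaling", UserWarning, stacklevel=2)
        return self

    def transform(self, block: np.ndarray) -> np.ndarray:
        if self.col_min is None:
            raise RuntimeError("scaler not fitted")
        span = self.col_max - self.col_min
        span = np.where(span == 0, 1.0, span)
        scaled = (np.asarray(block, dtype=np.float64) - self.col_min) / span
        return np.clip(scaled, 0.0, 1.0)

    def fit_transform(self, block: np.ndarray) -> np.ndarray:
        return self.fit(block).transform(block)


@dataclass
class EncodedMatrix:
    """Fully numeric model input plus its column manifest."""

    matrix: np.ndarray                 # (n, 71)
    columns: list[str]
    blocks: np.ndarray                 # per-column: "evidence" | "score"
    labels: np.ndarray                 # per-row: benign|oncogenic|unlabeled
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.columns) or len(self.columns) != len(self.blocks):
            raise ValueError("matrix width disagrees with the column manifest")
        if np.isnan(self.matrix).any():
            raise ValueError("encoded matrix must not contain missing values")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def label_ints(self) -> np.ndarray:
        """0 = benign, 1 = oncogenic, -1 = unlabeled."""
        out = np.full(self.n, -1, dtype=np.int64)
        out[self.labels == "benign"] = 0
        out[self.labels == "oncogenic"] = 1
        return out

    def select_block(self, which: str) -> "EncodedMatrix":
        """Restrict columns to one feature group: evidence | score | ensemble."""
        if which == "ensemble":
            return self
        if which not in ("evidence", "score"):
            raise ValueError(f"unknown feature group: {which!r}")
        mask = self.blocks == which
        return EncodedMatrix(
            matrix=self.matrix[:, mask],
            columns=[c for c, m in zip(self.columns, mask) if m],
            blocks=self.blocks[mask],
            labels=self.labels,
            variant_ids=self.variant_ids,
        )

    def subset_rows(self, idx: np.ndarray) -> "EncodedMatrix":
        return EncodedMatrix(self.matrix[idx], self.columns, self.blocks,
                             self.labels[idx], self.variant_ids[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.columns)
        df.insert(0, "variant_id", self.variant_ids)
        df.insert(1, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   blocks: np.ndarray | None = None) -> "EncodedMatrix":
        cols = [c for c in df.columns if c not in ("variant_id", "label")]
        if blocks is None:
            blocks = np.array(["evidence" if c.startswith("evi_") else "score"
                               for c in cols])
        return cls(matrix=df[cols].to_numpy(dtype=np.float64), columns=cols,
                   blocks=np.asarray(blocks),
                   labels=df["label"].to_numpy(dtype=object),
                   variant_ids=df["variant_id"].to_numpy(dtype=object))


class FeaturePipeline:
    """Fitted imputer + encoder + scaler, applied as one transform.

    Fit on the training pool (labeled + unlabeled together); apply to any
    table sharing the raw-column contract.  The evidence block precedes the
    score block in the assembled matrix.
    """

    def __init__(self, k: int = 40, noise_sd: float = 0.02, seed: int = 0,
                 max_missing: int = 13,
                 imputer_reference_limit: int | None = None) -> None:
        self.max_missing = max_missing
        self.imputer = NeighborImputer(k=k, reference_limit=imputer_reference_limit,
                                       seed=seed)
        self.encoder = EvidenceEncoder(noise_sd=noise_sd, seed=seed)
        self.scaler = MinMaxScaler()
        self._fitted = False

    def fit(self, train_table: pd.DataFrame) -> "FeaturePipeline":
        validate_table(train_table)
        kept = filter_by_missingness(train_table, self.max_missing)
        imputed = self.imputer.fit_transform(kept)
        self.scaler.fit(imputed[list(SCORE_COLUMNS)].to_numpy(dtype=np.float64))
        self._fitted = True
        return self

    def transform(self, table: pd.DataFrame) -> EncodedMatrix:
        if not self._fitted:
            raise RuntimeError("pipeline not fitted")
        validate_table(table)
        kept = filter_by_missingness(table, self.max_missing)
        imputed = self.imputer.transform(kept)
        evidence = self.encoder.encode(imputed)
        scores = self.scaler.transform(
            imputed[list(SCORE_COLUMNS)].to_numpy(dtype=np.float64))
        matrix = np.hstack([evidence, scores])
        columns = self.encoder.column_names + list(SCORE_COLUMNS)
        blocks = np.array(["evidence"] * evidence.shape[1]
                          + ["score"] * scores.shape[1])
        return EncodedMatrix(matrix=matrix, columns=columns, blocks=blocks,
                             labels=kept["label"].to_numpy(dtype=object),
                             variant_ids=kept["variant_id"].to_numpy(dtype=object))

    def fit_transform(self, train_table: pd.DataFrame) -> EncodedMatrix:
        return self.fit(train_table).transform(train_table)
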