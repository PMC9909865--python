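"""Missingness filter, neighbour imputation, encoding and scaling.

The 40-neighbour mean imputation is checked against an exhaustive
all-pairs nan-Euclidean oracle implemented here from the distance
definition, independently of the fitted implementation.
"""

import numpy as np
import pandas as pd
import pytest

from conftest import make_raw_table
from sganvi.feature_pipeline import (EVIDENCE_COLUMNS, SCORE_COLUMNS,
                                     FEATURE_COLUMNS, EncodedMatrix,
                                     EvidenceEncoder, FeaturePipeline,
                                     MinMaxScaler, NeighborImputer,
                                     filter_by_missingness, validate_table)


# ---------------------------------------------------------------------- #
# missingness filter
# ---------------------------------------------------------------------- #

def test_filter_drops_rows_beyond_threshold(rng):
    table = make_raw_table(3, rng)
    # row 0: 14 missing -> dropped; row 1: 13 -> kept; row 2: 0 -> kept
    table.iloc[0, 2:16] = np.nan
    table.iloc[1, 2:15] = np.nan
    kept = filter_by_missingness(table, max_missing=13)
    assert kept["variant_id"].tolist() == ["v1", "v2"]


def test_filter_agrees_with_brute_force_row_scan(rng):
    table = make_raw_table(100, rng, missing_rate=0.35)
    kept = filter_by_missingness(table, max_missing=13)
    expected = [row.variant_id for row in table.itertuples()
                if sum(pd.isna(getattr(row, c)) for c in FEATURE_COLUMNS) <= 13]
    assert kept["variant_id"].tolist() == expected


def test_filter_preserves_order_and_allows_empty(rng):
    table = make_raw_table(5, rng)
    table[list(FEATURE_COLUMNS)] = np.nan
    assert filter_by_missingness(table).empty


# ---------------------------------------------------------------------- #
# neighbour imputation
# ---------------------------------------------------------------------- #

def nan_euclidean(a, b):
    """Distance over mutually observed coordinates, rescaled by coverage."""
    shared = ~(np.isnan(a) | np.isnan(b))
    if not shared.any():
        return np.nan
    sq = np.sum((a[shared] - b[shared]) ** 2)
    return np.sqrt(sq * a.size / shared.sum())


def brute_force_impute(raw: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive nearest-neighbour mean imputation, the oracle."""
    out = raw.copy()
    for i in range(raw.shape[0]):
        missing_cols = np.flatnonzero(np.isnan(raw[i]))
        if missing_cols.size == 0:
            continue
        dists = np.array([nan_euclidean(raw[i], raw[j])
                          for j in range(raw.shape[0])])
        for j in missing_cols:
            donors = np.flatnonzero(~np.isnan(raw[:, j]) & ~np.isnan(dists))
            order = donors[np.argsort(dists[donors], kind="stable")]
            chosen = order[:min(k, order.size)]
            out[i, j] = raw[chosen, j].mean()
    return out


def test_impute_two_neighbour_mean():
    table = pd.DataFrame({
        "variant_id": ["a", "b", "c"], "label": ["benign"] * 3,
        **{c: [0.0, 0.0, 0.0] for c in EVIDENCE_COLUMNS},
        **{c: [1.0, 1.0, 1.0] for c in SCORE_COLUMNS},
    })
    table.loc[0, "score_1"] = np.nan
    table.loc[1, "score_1"] = 0.2
    table.loc[2, "score_1"] = 0.4
    out = NeighborImputer(k=2).fit_transform(table)
    assert out.loc[0, "score_1"] == pytest.approx(0.3)


def test_impute_identity_on_fully_observed(rng):
    table = make_raw_table(20, rng, missing_rate=0.0)
    out = NeighborImputer(k=5).fit_transform(table)
    pd.testing.assert_frame_equal(out, table)


def test_impute_never_alters_observed_entries(rng):
    table = make_raw_table(80, rng, missing_rate=0.1)
    observed = ~table[list(FEATURE_COLUMNS)].isna()
    out = NeighborImputer(k=10).fit_transform(table)
    before = table[list(FEATURE_COLUMNS)].to_numpy()
    after = out[list(FEATURE_COLUMNS)].to_numpy()
    np.testing.assert_array_equal(after[observed.to_numpy()],
                                  before[observed.to_numpy()])
    assert not np.isnan(after).any()


@pytest.mark.parametrize("n,k", [(200, 40), (60, 7)])
def test_impute_agrees_with_exhaustive_oracle(n, k, rng):
    table = make_raw_table(n, rng, missing_rate=0.05)
    out = NeighborImputer(k=k).fit_transform(table)
    expected = brute_force_impute(
        table[list(FEATURE_COLUMNS)].to_numpy(dtype=float), k)
    np.testing.assert_allclose(out[list(FEATURE_COLUMNS)].to_numpy(),
                               expected, atol=1e-9)


def test_impute_reports_column_missing_everywhere(rng):
    table = make_raw_table(10, rng)
    table["score_3"] = np.nan
    with pytest.raises(ValueError, match="score_3"):
        NeighborImputer(k=2).fit(table)


def test_impute_reference_subsample_is_deterministic(rng):
    table = make_raw_table(100, rng, missing_rate=0.05)
    a = NeighborImputer(k=5, reference_limit=30, seed=1).fit_transform(table)
    b = NeighborImputer(k=5, reference_limit=30, seed=1).fit_transform(table)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------- #
# evidence encoding
# ---------------------------------------------------------------------- #

def encode_single(value: float, noise_sd=0.0, seed=0):
    table = pd.DataFrame({
        "variant_id": ["a"], "label": ["benign"],
        **{c: [value] for c in EVIDENCE_COLUMNS},
        **{c: [0.0] for c in SCORE_COLUMNS},
    })
    enc = EvidenceEncoder(noise_sd=noise_sd, seed=seed)
    return enc.encode(table)[0, :4]


@pytest.mark.parametrize("value,expected", [
    (-1, (1, 0, 0, 0)),
    (0, (0, 1, 0, 0)),
    (1, (0, 0, 1, 0)),
    (2, (0, 0, 0, 1)),
    (0.9, (0, 0, 1, 0)),   # imputed values round to the nearest level
])
def test_one_hot_category_order(value, expected):
    np.testing.assert_array_equal(encode_single(value), expected)


def test_encoding_rejects_out_of_range_after_rounding():
    with pytest.raises(ValueError, match="round"):
        encode_single(2.6)


def test_dither_is_seed_deterministic(raw_table):
    imputed = NeighborImputer(k=5).fit_transform(raw_table)
    enc = EvidenceEncoder(noise_sd=0.02, seed=7)
    np.testing.assert_array_equal(enc.encode(imputed), enc.encode(imputed))
    other = EvidenceEncoder(noise_sd=0.02, seed=8)
    assert not np.array_equal(enc.encode(imputed), other.encode(imputed))


def test_noiseless_encoding_decodes_back(rng):
    table = make_raw_table(40, rng)
    enc = EvidenceEncoder(noise_sd=0.0)
    block = enc.encode(table).reshape(40, 12, 4)
    decoded = np.array([-1, 0, 1, 2])[block.argmax(axis=2)]
    np.testing.assert_array_equal(
        decoded, table[list(EVIDENCE_COLUMNS)].to_numpy())


# ---------------------------------------------------------------------- #
# min-max scaling
# ---------------------------------------------------------------------- #

def test_scaler_linear_map_and_clipping():
    scaler = MinMaxScaler()
    out = scaler.fit_transform(np.array([[2.0], [4.0], [6.0]]))
    np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])
    np.testing.assert_allclose(scaler.transform(np.array([[9.0], [-1.0]])).ravel(),
                               [1.0, 0.0])


def test_scaler_constant_column_maps_to_zero_with_warning():
    scaler = MinMaxScaler()
    with pytest.warns(UserWarning, match="constant"):
        out = scaler.fit_transform(np.full((3, 1), 5.0))
    np.testing.assert_array_equal(out, np.zeros((3, 1)))


# ---------------------------------------------------------------------- #
# assembled pipeline
# ---------------------------------------------------------------------- #

def test_pipeline_assembles_71_columns(raw_table):
    enc = FeaturePipeline(k=5, seed=3).fit_transform(raw_table)
    assert enc.matrix.shape[1] == 71
    assert (enc.blocks == "evidence").sum() == 48
    assert (enc.blocks == "score").sum() == 23
    assert enc.columns[:4] == ["evi_1=-1", "evi_1=0", "evi_1=1", "evi_1=2"]
    assert not np.isnan(enc.matrix).any()
    # score block of the fitting set lies in [0, 1]
    scores = enc.matrix[:, enc.blocks == "score"]
    assert scores.min() >= 0.0 and scores.max() <= 1.0


def test_pipeline_is_bitwise_deterministic(raw_table):
    a = FeaturePipeline(k=5, seed=3).fit_transform(raw_table)
    b = FeaturePipeline(k=5, seed=3).fit_transform(raw_table)
    np.testing.assert_array_equal(a.matrix, b.matrix)


def test_pipeline_keeps_unlabeled_labels(rng):
    table = make_raw_table(20, rng, labels=["unlabeled"] * 20)
    enc = FeaturePipeline(k=3, seed=0).fit_transform(table)
    assert (enc.labels == "unlabeled").all()


def test_encoded_matrix_frame_round_trip(raw_table):
    enc = FeaturePipeline(k=5, seed=3).fit_transform(raw_table)
    back = EncodedMatrix.from_frame(enc.to_frame())
    np.testing.assert_array_equal(back.matrix, enc.matrix)
    assert back.columns == enc.columns
    np.testing.assert_array_equal(back.labels, enc.labels)


def test_encoded_matrix_select_block_widths(raw_table):
    enc = FeaturePipeline(k=5, seed=3).fit_transform(raw_table)
    assert enc.select_block("score").matrix.shape[1] == 23
    assert enc.select_block("evidence").matrix.shape[1] == 48
    assert enc.select_block("ensemble") is enc
    with pytest.raises(ValueError, match="unknown"):
        enc.select_block("nonsense")


def test_validate_table_reports_problems(raw_table):
    with pytest.raises(ValueError, match="missing required"):
        validate_table(raw_table.drop(columns=["label"]))
    dup = pd.concat([raw_table, raw_table.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        validate_table(dup)
    bad = raw_table.copy()
    bad.loc[0, "evi_1"] = 7
    with pytest.raises(ValueError, match="evidence"):
        validate_table(bad)
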