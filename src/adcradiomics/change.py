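"""Change-rate indices between pre-treatment and mid-treatment feature values.

Morphological response keeps its sign (shrinkage positive, growth negative):

    response (%) = (pre - mid) / pre * 100

ADC-derived features use the absolute change rate, which is sign-blind:

    response (%) = |mid - pre| / pre * 100

Patients missing one of the two timepoints are excluded from pairing, with a
logged count; no imputation is attempted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "InvalidBaselineError",
    "morph_response",
    "adc_response",
    "change_rate_table",
    "MORPH_FEATURES",
]

logger = logging.getLogger(__name__)

#: features whose change rate keeps its sign
MORPH_FEATURES = ("mtd", "area", "volume")


class InvalidBaselineError(ValueError):
    """Raised when the pre-treatment baseline value is not strictly positive."""


def _check_baseline(pre_value):
    if np.any(np.asarray(pre_value) <= 0):
        raise InvalidBaselineError("pre-treatment baseline must be strictly positive")


def morph_response(pre_value, mid_value):
    """Signed morphological response in percent: (pre - mid)/pre * 100."""
    _check_baseline(pre_value)
    return (np.asarray(pre_value, float) - mid_value) / np.asarray(pre_value, float) * 100.0


def adc_response(pre_value, mid_value):
    """Absolute ADC-feature response in percent: |mid - pre|/pre * 100."""
    _check_baseline(pre_value)
    pre = np.asarray(pre_value, float)
    return np.abs(np.asarray(mid_value, float) - pre) / pre * 100.0


def change_rate_table(
    features: pd.DataFrame,
    feature_columns: list[str] | None = None,
    id_column: str = "patient_id",
    timepoint_column: str = "timepoint",
) -> pd.DataFrame:
    """Pair pre/mid rows per patient and compute all change rates.

    ``features`` is a long-format table with one row per (patient, timepoint).
    Returns one row per patient having both timepoints, with a ``*_response``
    column per feature. Morphological columns use the signed formula; all
    others the absolute one.
    """
    tps = set(features[timepoint_column].unique())
    if not tps <= {"pre", "mid"}:
        raise ValueError(f"unexpected timepoints {tps - {'pre', 'mid'}}")
    if feature_columns is None:
        feature_columns = [
            c
            for c in features.columns
            if c not in (id_column, timepoint_column)
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    pre = features[features[timepoint_column] == "pre"].set_index(id_column)
    mid = features[features[timepoint_column] == "mid"].set_index(id_column)
    both = pre.index.intersection(mid.index)
    dropped = len(pre.index.union(mid.index)) - len(both)
    if dropped:
        logger.info("excluding %d patients missing one timepoint", dropped)
    out = pd.DataFrame(index=both)
    for col in feature_columns:
        fn = morph_response if col in MORPH_FEATURES else adc_response
        out[f"{col}_response"] = fn(pre.loc[both, col].to_numpy(), mid.loc[both, col].to_numpy())
    return out.reset_index().rename(columns={"index": id_column})
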