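"""Personal-characteristic (phenotypic) table cleaning and feature fusion.

Cohort studies ship a per-subject table of non-imaging features — age,
sex, handedness, IQ scores, imaging site, eye status — with missing
entries and mixed categorical/continuous columns.  The cleaning rules
implemented here:

* handedness scores recoded to categories: positive -> 1 (right),
  negative -> 0 (left); a score of exactly 0 (ambidextrous) maps to 1
  with a warning, configurable;
* columns missing for >= 30% of subjects are dropped;
* remaining missing values imputed by the column mean (mode for
  categorical columns, where a mean is meaningless);
* columns directly related to the diagnosis (symptom scores,
  medication status) removed via an explicit blocklist;
* categorical columns encoded numerically — sex/eyestat as 0/1, site as
  a single integer code (one-hot available by flag) — and concatenated
  after the image features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import SchemaError
from .mhpc import LabeledDataset

#: Phenotypic columns that leak the diagnosis and must never be features.
DEFAULT_BLOCKLIST = ("dx", "diagnosis", "adhd_index", "symptom_score",
                     "medication", "med_status", "label")

#: Columns treated as categorical when encoding.
CATEGORICAL_COLUMNS = ("sex", "site", "eyestat", "handedness")


def recode_handedness(score, zero_as: int = 1, categorical: bool | None = None):
    """Recode a handedness score to {0, 1}: positive -> 1, negative -> 0.

    Already-categorical 0/1 values pass through unchanged.  A *signed
    score* of exactly 0 is ambiguous (ambidextrous); it maps to
    ``zero_as`` (default 1) with a warning.  For a pandas Series,
    ``categorical`` is auto-detected (all observed values in {0, 1})
    unless given; missing values are preserved.
    """
    if isinstance(score, pd.Series):
        obs = score.dropna()
        if categorical is None:
            categorical = bool(obs.isin([0, 1]).all())
        out = score.astype(float)
        out[obs.index] = [recode_handedness(v, zero_as, categorical) for v in obs]
        return out
    if categorical or score == 1:
        if score not in (0, 1):
            raise ValueError(f"categorical handedness must be 0 or 1, got {score!r}")
        return int(score)
    if score > 0:
        return 1
    if score < 0:
        return 0
    warnings.warn("handedness score exactly 0 (ambidextrous); "
                  f"recoding to {zero_as}", stacklevel=2)
    return zero_as


def filter_missing_features(table: pd.DataFrame, threshold: float = 0.30,
                            protected: tuple = ("subject_id", "label")):
    """Drop columns missing for >= ``threshold`` of subjects.

    Returns (reduced table, list of dropped column names).  Protected
    columns (ids, labels) are never dropped.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    frac = table.isna().mean()
    dropped = [c for c in table.columns
               if c not in protected and frac[c] >= threshold]
    return table.drop(columns=dropped), dropped


def impute_mean(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing numeric values with the column mean, categorical with the mode."""
    out = table.copy()
    for c in out.columns:
        col = out[c]
        if not col.isna().any():
            continue
        if col.notna().sum() == 0:
            raise SchemaError(f"column {c!r} has no observed values to impute from")
        if pd.api.types.is_numeric_dtype(col):
            out[c] = col.fillna(col.mean())
        else:
            out[c] = col.fillna(col.mode().iloc[0])
    return out


def encode_personal(table: pd.DataFrame, one_hot_site: bool = False) -> pd.DataFrame:
    """Encode cleaned personal columns as a numeric feature frame.

    Handedness is recoded to {0, 1}; sex and eyestat become 0/1 codes;
    site becomes one integer code per site (or one-hot columns when
    ``one_hot_site``).  Numeric columns pass through.  The
    ``subject_id`` and ``label`` columns are excluded.
    """
    cols = {}
    for c in table.columns:
        if c in ("subject_id", "label"):
            continue
        col = table[c]
        if c == "handedness":
            cols[c] = pd.to_numeric(recode_handedness(pd.to_numeric(col)))
        elif c == "site" and one_hot_site:
            dummies = pd.get_dummies(col.astype(str), prefix="site", dtype=float)
            for dc in dummies.columns:
                cols[dc] = dummies[dc]
        elif c in CATEGORICAL_COLUMNS or not pd.api.types.is_numeric_dtype(col):
            levels, codes = np.unique(col.astype(str), return_inverse=True)
            cols[c] = pd.Series(codes.astype(float), index=table.index)
        else:
            cols[c] = pd.to_numeric(col)
    return pd.DataFrame(cols, index=table.index)


def clean_personal_table(table: pd.DataFrame, threshold: float = 0.30,
                         blocklist: tuple = DEFAULT_BLOCKLIST,
                         one_hot_site: bool = False) -> pd.DataFrame:
    """Full cleaning pipeline: blocklist -> missingness filter -> imputation -> encoding."""
    table = table.drop(columns=[c for c in table.columns
                                if c.lower() in blocklist and c != "label"],
                       errors="ignore")
    table, _ = filter_missing_features(table, threshold)
    table = impute_mean(table)
    return encode_personal(table, one_hot_site)


def concat_features(image_features: np.ndarray, personal: pd.DataFrame,
                    labels, image_ids, feature_names=None) -> tuple[LabeledDataset, dict]:
    """Concatenate encoded personal columns after the image features.

    ``personal`` must carry a ``subject_id`` column (or use its index)
    aligning 1:1 with ``image_ids``; row order follows ``image_ids``.
    Returns the combined dataset and a provenance map assigning every
    column to "image" or "personal".
    """
    image_features = np.asarray(image_features, dtype=float)
    n, d_img = image_features.shape
    image_ids = [str(i) for i in image_ids]
    if personal is None or personal.shape[1] == 0:
        encoded = pd.DataFrame(index=image_ids)
    else:
        personal = personal.copy()
        if "subject_id" in personal.columns:
            personal = personal.set_index(personal["subject_id"].astype(str))
        else:
            personal.index = personal.index.astype(str)
        missing = [i for i in image_ids if i not in personal.index]
        extra = [i for i in personal.index if i not in image_ids]
        if missing or extra:
            raise SchemaError(
                f"subject ids do not align: missing from table {missing[:5]}, "
                f"unmatched in table {extra[:5]}")
        encoded = encode_personal(personal.loc[image_ids])
    X = np.hstack([image_features, encoded.to_numpy(dtype=float)]) if encoded.shape[1] \
        else image_features
    if feature_names is None:
        feature_names = [f"hog{j}" for j in range(d_img)]
    names = list(feature_names) + list(encoded.columns)
    provenance = {name: ("image" if j < d_img else "personal")
                  for j, name in enumerate(names)}
    return LabeledDataset(X, np.asarray(labels), names, image_ids), provenance
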