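"""Phenotype editing and model-factor construction for calf birth weight.

Edits applied, in order:

1. records with a missing mandatory field are rejected;
2. birth weights strictly above 60 kg or strictly below 20 kg are excluded
   (the boundaries themselves are retained);
3. gestation lengths outside 260–300 d are excluded (the class definitions
   cover only that range);
4. only dams that still have at least three offspring, spread over at least
   three distinct parities, are retained — repeated records per dam are what
   identifies the maternal permanent-environmental component.

Fixed-effect factors: herd-birth-year (HY), sex × birth type (4 classes),
gestation-length class (6 inclusive bins: 260–269, 270–274, 275–279,
280–284, 285–289, 290–300), dam parity class (1..6 and ">6" pooled as 7),
and the herd-birth-year-month (HYM) contemporary group used as a random term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["MANDATORY_FIELDS", "edit_phenotypes", "assign_classes", "gl_class", "parity_class"]

MANDATORY_FIELDS = [
    "calf_id",
    "dam_id",
    "sire_id",
    "herd_id",
    "birth_date",
    "sex",
    "birth_type",
    "biw_kg",
    "gestation_len_d",
    "dam_parity",
]

GL_BINS = [(260, 269), (270, 274), (275, 279), (280, 284), (285, 289), (290, 300)]

BIW_MIN, BIW_MAX = 20.0, 60.0
GL_MIN, GL_MAX = 260, 300
MIN_OFFSPRING = 3  # "more than 2 offspring from different parities"


def edit_phenotypes(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the editing rules; returns (retained records, per-rule counts).

    The log's counts sum to ``len(records) − len(retained)``.  Editing is
    idempotent: re-editing the output drops nothing.
    """
    df = records.copy()
    log: dict[str, int] = {"input": len(df)}

    missing = df[MANDATORY_FIELDS].isna().any(axis=1)
    log["missing_field"] = int(missing.sum())
    df = df[~missing]

    bad_biw = (df["biw_kg"] > BIW_MAX) | (df["biw_kg"] < BIW_MIN)
    log["biw_out_of_range"] = int(bad_biw.sum())
    df = df[~bad_biw]

    bad_gl = (df["gestation_len_d"] < GL_MIN) | (df["gestation_len_d"] > GL_MAX)
    log["gestation_out_of_range"] = int(bad_gl.sum())
    df = df[~bad_gl]

    by_dam = df.groupby("dam_id").agg(n=("calf_id", "size"), npar=("dam_parity", "nunique"))
    keep_dams = by_dam.index[(by_dam["n"] >= MIN_OFFSPRING) & (by_dam["npar"] >= MIN_OFFSPRING)]
    dropped = ~df["dam_id"].isin(keep_dams)
    log["dam_too_few_offspring"] = int(dropped.sum())
    df = df[~dropped].reset_index(drop=True)

    log["retained"] = len(df)
    return df, log


def gl_class(gestation_len_d):
    """Inclusive gestation-length bin (1..6); raises if no bin covers the value."""
    gl = np.asarray(gestation_len_d)
    out = np.zeros(gl.shape, dtype=int)
    for i, (lo, hi) in enumerate(GL_BINS, start=1):
        out[(gl >= lo) & (gl <= hi)] = i
    if np.any(out == 0):
        bad = np.atleast_1d(gl)[np.atleast_1d(out) == 0][:5]
        raise ValueError(f"gestation length(s) {bad.tolist()} outside 260–300 d")
    return out if out.ndim else int(out)


def parity_class(parity):
    """Parities 1..6 keep their own class; everything above pools into 7."""
    p = np.asarray(parity)
    if np.any(p < 1):
        raise ValueError("dam parity must be >= 1")
    out = np.minimum(p, 7)
    return out if out.ndim else int(out)


def assign_classes(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the model factors (hy, hym, sex_bt, gl_class, parity_class).

    Every edited record maps to exactly one level of each factor.
    """
    df = records.copy()
    bd = pd.to_datetime(df["birth_date"])
    df["hy"] = df["herd_id"].astype(str) + ":" + bd.dt.year.astype(str)
    df["hym"] = df["hy"] + ":" + bd.dt.month.astype(str).str.zfill(2)
    sex = df["sex"].astype(str).str.lower()
    bt = df["birth_type"].astype(str).str.lower()
    bad_sex = ~sex.isin(["male", "female"])
    bad_bt = ~bt.isin(["singleton", "twin"])
    if bad_sex.any() or bad_bt.any():
        raise ValueError("sex must be male/female and birth_type singleton/twin")
    df["sex_bt"] = sex + "_" + bt
    df["gl_class"] = gl_class(df["gestation_len_d"].to_numpy())
    df["parity_class"] = parity_class(df["dam_parity"].to_numpy())
    return df
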