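"""Derived migration phenotypes: condition factor, growth rates, binary life history.

Raw measurements are fork length (mm) and body weight (g) at 12, 15 and 24
months after fertilization, plus a four-level life-history call (mature /
parr / indeterminate / smolt) at 24 months.  Derived columns are appended
and never overwrite inputs; derivation is idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

LIFE_HISTORY_CLASSES = ("mature", "parr", "indeterminate", "smolt")

#: nominal days after fertilization of the three sampling points
#: (12/15/24 months x 30.44 d); used when per-fish dates are absent
NOMINAL_AGE_DAYS = {12: 12 * 30.44, 15: 15 * 30.44, 24: 24 * 30.44}


def condition_factor(weight_g, length_mm):
    """Fulton's condition factor K = (W / L^3) * 100,000.

    Vectorized; non-positive or missing inputs yield NaN (with a warning
    for non-positive values, which indicate data errors).
    """
    W = np.asarray(weight_g, dtype=float)
    L = np.asarray(length_mm, dtype=float)
    bad = (W <= 0) | (L <= 0)
    if np.any(bad & ~np.isnan(W) & ~np.isnan(L)):
        warnings.warn("non-positive weight/length set to missing", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = W / L**3 * 100_000.0
    K = np.where(bad, np.nan, K)
    return K if K.ndim else float(K)


def instantaneous_growth_rate(x1, x2, t1_days, t2_days):
    """Instantaneous growth rate, percent per day.

    IGR = [ln(x2) - ln(x1)] / (t2 - t1) * 100 for lengths or weights x at
    times t (days after fertilization).  t2 must exceed t1; non-positive
    sizes propagate as missing.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    dt = np.asarray(t2_days, dtype=float) - np.asarray(t1_days, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("growth interval requires t2 > t1")
    with np.errstate(invalid="ignore", divide="ignore"):
        igr = (np.log(x2) - np.log(x1)) / dt * 100.0
    igr = np.where((x1 <= 0) | (x2 <= 0), np.nan, igr)
    return igr if igr.ndim else float(igr)


def binarize_life_history(category):
    """Decompose the four-level life-history call into (LHSmolt, LHMature).

    LHSmolt: smolt -> 1; mature, parr -> 0; indeterminate or missing -> NaN.
    LHMature: mature -> 1; parr, indeterminate, smolt -> 0; missing -> NaN.
    """
    if category is None or (np.isscalar(category) and pd.isna(category)):
        return np.nan, np.nan
    cat = pd.Series(category, dtype="object")
    known = cat.dropna().unique()
    bad = [c for c in known if c not in LIFE_HISTORY_CLASSES]
    if bad:
        raise ValueError(f"unknown life-history tokens: {bad}")
    smolt = cat.map({"smolt": 1.0, "mature": 0.0, "parr": 0.0}).astype(float)
    mature = cat.map(
        {"mature": 1.0, "parr": 0.0, "indeterminate": 0.0, "smolt": 0.0}
    ).astype(float)
    if np.isscalar(category) or isinstance(category, str) or category is None:
        return float(smolt.iloc[0]), float(mature.iloc[0])
    return smolt.to_numpy(), mature.to_numpy()


def derive_phenotypes(df: pd.DataFrame, ages_days: dict | None = None) -> pd.DataFrame:
    """Append all derived trait columns to a wide phenotype table.

    Expects Table-1 style columns (``mo12Length``, ``mo12Weight``, ...,
    ``life_history``).  Adds ``moXXKfact``, ``IGRL1/2``, ``IGRW1/2``,
    ``LHSmolt`` and ``LHMature``.  ``ages_days`` overrides the nominal
    month-to-day mapping.
    """
    ages = dict(NOMINAL_AGE_DAYS)
    if ages_days:
        ages.update(ages_days)
    out = df.copy()
    for mo in (12, 15, 24):
        lcol, wcol = f"mo{mo}Length", f"mo{mo}Weight"
        if lcol in out and wcol in out:
            out[f"mo{mo}Kfact"] = condition_factor(out[wcol], out[lcol])
    for name, (m1, m2), kind in (
        ("IGRL1", (12, 15), "Length"),
        ("IGRW1", (12, 15), "Weight"),
        ("IGRL2", (15, 24), "Length"),
        ("IGRW2", (15, 24), "Weight"),
    ):
        c1, c2 = f"mo{m1}{kind}", f"mo{m2}{kind}"
        if c1 in out and c2 in out:
            out[name] = instantaneous_growth_rate(out[c1], out[c2], ages[m1], ages[m2])
    if "life_history" in out:
        smolt, mature = binarize_life_history(out["life_history"])
        out["LHSmolt"] = smolt
        out["LHMature"] = mature
    out.attrs["age_days"] = ages  # provenance of the nominal-age assumption
    return out


def read_phenotypes(path) -> pd.DataFrame:
    """Read the wide phenotype CSV (missing = empty or 'NA')."""
    return pd.read_csv(path, na_values=["NA", ""])


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
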