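"""Longitudinal feature tables, baseline ratios and cohort summaries.

Each capture contributes one row keyed by (patient, side, point, mode,
timepoint) holding the 18 texture features.  Delta-radiomics expresses
every feature as the ratio of its value at a time point to its value in
the baseline (pre-treatment) capture of the *same* key, normalising
inter-individual differences in skin colour, tone and texture; baseline
rows are exactly 1.  Point-level deltas are averaged over the four
anatomical points to one value per breast, and cohort summaries report
the cross-patient mean and sample SD per side x timepoint x mode.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .glcm import FEATURE_NAMES, GLCMParams, extract_image_features

__all__ = [
    "KEY_COLUMNS",
    "build_feature_table",
    "delta_ratios",
    "aggregate_points",
    "summarize",
    "to_long",
]

KEY_COLUMNS = ["patient_id", "side", "point_site", "mode", "timepoint"]


def build_feature_table(
    images,
    params: GLCMParams = GLCMParams(),
    roi_radius: float = 300.0,
    baseline: str = "Before_RT",
) -> pd.DataFrame:
    """Extract features for an iterable of captures into a wide table.

    ``images`` yields objects with ``pixels`` and the five key fields
    (e.g. ``synthetic.SkinImage``).  One row per capture; duplicate keys
    are an error, and keys lacking a baseline capture are flagged with a
    warning (their deltas will be undefined).
    """
    rows = []
    for img in images:
        row = {
            "patient_id": img.patient_id,
            "side": img.side,
            "point_site": img.point_site,
            "mode": img.mode,
            "timepoint": img.timepoint,
        }
        row.update(extract_image_features(img.pixels, params=params, roi_radius=roi_radius))
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no images supplied")
    if table.duplicated(KEY_COLUMNS).any():
        dupes = table.loc[table.duplicated(KEY_COLUMNS), KEY_COLUMNS]
        raise ValueError(f"duplicate capture keys:\n{dupes.to_string(index=False)}")
    series_key = [c for c in KEY_COLUMNS if c != "timepoint"]
    missing = (
        table.groupby(series_key)["timepoint"].apply(lambda t: baseline not in set(t))
    )
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} series lack a {baseline!r} capture; "
            "their deltas will be undefined",
            stacklevel=2,
        )
    return table


def delta_ratios(table: pd.DataFrame, baseline: str = "Before_RT") -> pd.DataFrame:
    """Per-feature ratio of each row to its own-series baseline row.

    Baseline rows emit exactly 1.0.  A zero or non-finite baseline value
    leaves that feature's delta as NaN (flagged, excluded downstream).
    Series without a baseline row are dropped.
    """
    series_key = [c for c in KEY_COLUMNS if c != "timepoint"]
    base = table[table["timepoint"] == baseline].set_index(series_key)[list(FEATURE_NAMES)]
    out = table.copy()
    idx = pd.MultiIndex.from_frame(out[series_key])
    has_base = idx.isin(base.index)
    if not has_base.all():
        warnings.warn(
            f"dropping {int((~has_base).sum())} rows whose series has no baseline",
            stacklevel=2,
        )
        out = out[has_base]
        idx = idx[has_base]
    base_vals = base.reindex(idx).to_numpy()
    vals = out[list(FEATURE_NAMES)].to_numpy()
    ok = np.isfinite(base_vals) & (base_vals != 0) & np.isfinite(vals)
    ratios = np.full_like(vals, np.nan)
    np.divide(vals, base_vals, out=ratios, where=ok)
    is_base = (out["timepoint"] == baseline).to_numpy()
    ratios[is_base] = np.where(ok[is_base], 1.0, np.nan)
    out[list(FEATURE_NAMES)] = ratios
    return out


def aggregate_points(deltas: pd.DataFrame) -> pd.DataFrame:
    """Average deltas over the four anatomical points of each breast.

    Returns one row per (patient, side, mode, timepoint) with the mean
    over the available points per feature and ``n_points`` recording how
    many points contributed (NaN deltas are excluded per feature).
    """
    key = ["patient_id", "side", "mode", "timepoint"]
    grouped = deltas.groupby(key, sort=True)
    means = grouped[list(FEATURE_NAMES)].mean()  # skipna per feature
    n_points = grouped["point_site"].nunique().rename("n_points")
    if (n_points == 0).any():
        raise ValueError("a (patient, side, mode, timepoint) cell has no points")
    return means.join(n_points).reset_index()


def summarize(patient_values: pd.DataFrame) -> pd.DataFrame:
    """Cross-patient mean and sample SD per side x timepoint x mode.

    The output is long-form: one row per (side, mode, timepoint,
    feature) with columns ``mean``, ``sd`` (n-1 denominator; NaN when
    fewer than two patients contribute) and ``n``.
    """
    key = ["side", "mode", "timepoint"]
    records = []
    for (side, mode, tp), grp in patient_values.groupby(key, sort=True):
        for name in FEATURE_NAMES:
            vals = grp[name].dropna()
            n = len(vals)
            records.append(
                {
                    "side": side,
                    "mode": mode,
                    "timepoint": tp,
                    "feature": name,
                    "mean": vals.mean() if n else np.nan,
                    "sd": vals.std(ddof=1) if n >= 2 else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(records)


def to_long(table: pd.DataFrame, value_name: str = "value") -> pd.DataFrame:
    """Wide feature table -> tidy long format (one row per feature)."""
    keys = [c for c in table.columns if c not in FEATURE_NAMES]
    return table.melt(
        id_vars=keys, value_vars=list(FEATURE_NAMES),
        var_name="feature_name", value_name=value_name,
    )
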