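"""Batch analysis and group comparison tables.

``run_batch`` turns a manifest of specimens (image + sidecar paths) into one
measurements row per specimen — the shape of a per-animal results table —
and collects row-level failures in a report instead of aborting the batch.
``run_compare`` summarises a measurements table by treatment group: n,
mean, SD, SEM, percent change versus the designated control group, and a
two-sample t-test p-value for every density measure.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, ConfigError
from .io import read_image, read_sidecar
from .measurement import DensityMeasurements, analyze_whole_mount, compute_density_pct
from .stats import percent_reduction, summarize_group, two_group_test

__all__ = ["run_batch", "run_compare", "MEASURE_COLUMNS"]

log = logging.getLogger("wholemount")

MEASURE_COLUMNS = list(DensityMeasurements.FIELDS)

#: numerator/denominator fields backing each density measure, used by the
#: ratio-of-means group convention
_DENSITY_PARTS = {
    "density_area_pct": ("epithelial_area_cm2", "total_area_cm2"),
    "density_volume_pct": ("epithelial_sum_od", "total_sum_od"),
}


def run_batch(
    manifest: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Analyze every specimen in the manifest.

    ``manifest`` needs columns ``specimen_id``, ``image`` and ``sidecar``
    (paths).  Returns ``(measurements, errors)``: one row per successful
    specimen (stamped with the config hash) and a list of per-row error
    records for the rest.  An empty manifest yields an empty table.
    """
    cfg = config or AnalysisConfig()
    required = {"specimen_id", "image", "sidecar"}
    if len(manifest) and not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    rows, errors = [], []
    for rec in manifest.to_dict("records"):
        sid = rec.get("specimen_id")
        try:
            image = read_image(Path(rec["image"]))
            aoi, lymph = read_sidecar(Path(rec["sidecar"]))
            m = analyze_whole_mount(image, aoi, lymph, cfg)
            row = {"specimen_id": sid, **m.as_dict(), "config_hash": cfg.config_hash()}
            rows.append(row)
            log.info("specimen %s: density %.1f%%", sid, m.density_area_pct)
        except Exception as exc:  # noqa: BLE001 - row-level error contract
            log.warning("specimen %s failed: %s", sid, exc)
            errors.append({"specimen_id": sid, "error": str(exc)})
    columns = ["specimen_id", *MEASURE_COLUMNS, "density_undefined", "config_hash"]
    return pd.DataFrame(rows, columns=columns), errors


def run_compare(
    measurements: pd.DataFrame,
    groups,
    control: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Group-comparison table: one row per (measure, group).

    ``groups`` maps each row of ``measurements`` to a treatment label
    (a column name in the table or an equal-length sequence).  Columns:
    measure, treatment, n, mean, sd, se, percent_reduction_vs_control,
    p_value (two-sample test against the control group; NaN for the control
    itself and for groups with n < 2).

    Under the ``ratio_of_means`` convention the group mean of a density
    measure is recomputed as 100 × (mean numerator)/(mean denominator);
    dispersion always describes the per-specimen ratios.
    """
    cfg = config or AnalysisConfig()
    if isinstance(groups, str):
        labels = measurements[groups].to_numpy()
    else:
        labels = np.asarray(list(groups))
        if labels.size != len(measurements):
            raise ValueError("group labels do not match the measurements table")
    unique = list(dict.fromkeys(labels))
    if control not in unique:
        raise ConfigError(f"control label {control!r} not among groups {unique}")
    if len(unique) < 2:
        raise ValueError("need at least two groups to compare")

    out = []
    for measure in MEASURE_COLUMNS:
        values = {g: measurements.loc[labels == g, measure].to_numpy() for g in unique}
        means = {}
        for g in unique:
            s = summarize_group(values[g])
            mean = s.mean
            if cfg.density_convention == "ratio_of_means" and measure in _DENSITY_PARTS:
                num, den = _DENSITY_PARTS[measure]
                part = float(measurements.loc[labels == g, num].mean())
                total = float(measurements.loc[labels == g, den].mean())
                mean = compute_density_pct(part, total)
            means[g] = mean
            out.append(
                {
                    "measure": measure,
                    "treatment": g,
                    "n": s.n,
                    "mean": mean,
                    "sd": s.sd,
                    "se": s.se,
                }
            )
        for row in out[-len(unique):]:
            g = row["treatment"]
            if g == control:
                row["percent_reduction_vs_control"] = 0.0
                row["p_value"] = np.nan
            else:
                row["percent_reduction_vs_control"] = (
                    percent_reduction(means[control], row["mean"])
                    if means[control] > 0
                    else np.nan
                )
                if len(values[g]) >= 2 and len(values[control]) >= 2:
                    _, p = two_group_test(values[control], values[g])
                    row["p_value"] = p
                else:
                    row["p_value"] = np.nan
    return pd.DataFrame(out)
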