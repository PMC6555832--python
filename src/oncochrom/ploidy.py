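"""DNA-content estimation from DAPI integrated intensities.

A line of intensity on known content is fit over two anchor populations —
diakinesis-stage oocytes (4n) and endoreduplicated intestine nuclei (32n) —
and inverted to assign content to arbitrary nuclei. Endomitotic nuclei may
greatly exceed the 32n anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, ValidationError

OOCYTE = "oocyte_diakinesis"
INTESTINE = "intestine"
ENDOMITOTIC = "endomitotic"
DEFAULT_ANCHORS = {OOCYTE: 4.0, INTESTINE: 32.0}
REFERENCE_CONTENT = 4.0  # wild-type diakinesis oocyte


@dataclass(frozen=True)
class PloidyCalibration:
    slope: float  # intensity per n
    intercept: float  # intensity
    anchor_contents: tuple[float, ...]
    anchor_means: tuple[float, ...]

    def __post_init__(self):
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise CalibrationError("non-finite calibration")
        if self.slope <= 0:
            raise CalibrationError(f"calibration slope must be positive, got {self.slope}")


def calibrate(measurements: pd.DataFrame, anchors: dict[str, float] | None = None) -> PloidyCalibration:
    """Least-squares line of intensity on known content over all anchor
    observations. With two anchor populations the line is saturated, so it
    interpolates both group mean intensities exactly.
    """
    anchors = DEFAULT_ANCHORS if anchors is None else anchors
    for col in ("population", "intensity"):
        if col not in measurements.columns:
            raise ValidationError(f"measurements missing column {col!r}")
    sub = measurements[measurements["population"].isin(anchors)]
    present = set(sub["population"])
    missing = set(anchors) - present
    if missing:
        raise CalibrationError(f"missing anchor population(s): {sorted(missing)}")
    content = sub["population"].map(anchors).to_numpy(dtype=float)
    intensity = sub["intensity"].to_numpy(dtype=float)
    means = tuple(
        float(sub.loc[sub["population"] == pop, "intensity"].mean()) for pop in anchors
    )
    distinct = sorted(set(content))
    if len(distinct) == 2:
        # saturated two-level design: the OLS line interpolates the group mean
        # intensities exactly, so compute it from them in closed form
        c1, c2 = distinct
        m1 = float(intensity[content == c1].mean())
        m2 = float(intensity[content == c2].mean())
        slope = (m2 - m1) / (c2 - c1)
        intercept = m1 - slope * c1
    else:
        slope, intercept = np.polyfit(content, intensity, deg=1)
    return PloidyCalibration(float(slope), float(intercept), tuple(anchors.values()), means)


def estimate_content(intensity, calibration: PloidyCalibration):
    """Invert the calibration: content = (intensity - intercept) / slope."""
    arr = np.asarray(intensity, dtype=float)
    out = (arr - calibration.intercept) / calibration.slope
    return out if out.ndim else float(out)


def relative_content_report(
    contents: pd.DataFrame, reference_content: float = REFERENCE_CONTENT
) -> pd.DataFrame:
    """Per-population quartile stats of content expressed relative to the
    wild-type oocyte reference (4n = 1)."""
    for col in ("population", "content"):
        if col not in contents.columns:
            raise ValidationError(f"contents missing column {col!r}")
    rows = []
    for pop, grp in contents.groupby("population", sort=True):
        ratios = grp["content"].to_numpy(dtype=float) / reference_content
        if ratios.size == 0:
            rows.append({"population": pop, "n": 0, "median": np.nan,
                         "q1": np.nan, "q3": np.nan, "empty": True})
            continue
        q1, med, q3 = np.percentile(ratios, [25, 50, 75])
        rows.append({"population": pop, "n": int(ratios.size), "median": float(med),
                     "q1": float(q1), "q3": float(q3), "empty": False})
    return pd.DataFrame(rows)
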