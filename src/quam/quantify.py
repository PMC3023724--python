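"""Exposure-normalized single-cell intensity measurement.

The integrated pixel intensity of each accepted neuron is normalized against
the neuron's area and the exposure time, which makes intensities comparable
across cells of different sizes and across images taken at different
exposures. Exposure is auto-selected per scene: the longest candidate (up to
0.96 s) is used for which the number of saturated pixels stays within a
budget of 1000 per 100 μm² of evaluated area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingConditionError
from .segmentation import SegmentedObject

__all__ = [
    "ExposurePolicy",
    "select_exposure",
    "measure_cell",
    "measure_objects",
    "normalize_to_control",
]


@dataclass(frozen=True)
class ExposurePolicy:
    """Exposure auto-selection rule.

    ``saturation_budget`` is the maximum allowed number of saturated pixels
    per 100 μm² of evaluated area. The evaluated area defaults to the object
    area when object masks are supplied, or the whole field otherwise (both
    readings of the rule are available because the original definition is
    ambiguous about the reference area).
    """

    exposure_candidates: tuple[float, ...] = (0.96, 0.48, 0.24)
    exposure_max: float = 0.96
    saturation_budget: float = 1000.0
    saturation_level: int = 4095  # 2**bit_depth - 1 for a 12-bit camera

    def validate(self) -> "ExposurePolicy":
        if not self.exposure_candidates:
            raise ConfigurationError("exposure_candidates must not be empty")
        if any(e <= 0 for e in self.exposure_candidates):
            raise ConfigurationError(
                f"exposure candidates must be > 0 s, got {self.exposure_candidates}")
        if any(e > self.exposure_max + 1e-12 for e in self.exposure_candidates):
            raise ConfigurationError(
                f"all candidates must be <= exposure_max={self.exposure_max} s")
        if self.saturation_budget < 0:
            raise ConfigurationError(
                f"saturation_budget must be >= 0, got {self.saturation_budget}")
        return self

    def with_(self, **kw) -> "ExposurePolicy":
        return replace(self, **kw)


def select_exposure(images: Mapping[float, np.ndarray],
                    policy: ExposurePolicy = ExposurePolicy(), *,
                    eval_mask: np.ndarray | None = None,
                    pixel_size_um: float = 0.645) -> float:
    """Pick the exposure time for a scene.

    Parameters
    ----------
    images
        Mapping of candidate exposure (s) to the image of the scene taken at
        that exposure. Must cover every ``policy.exposure_candidates`` entry.
    eval_mask
        Optional boolean mask restricting the saturation count and reference
        area to object pixels (per-object-area reading of the budget). When
        omitted the whole field is evaluated.
    pixel_size_um
        Pixel edge length, to convert pixel counts into μm² of area.

    Returns
    -------
    float
        The longest candidate whose saturated-pixel count per 100 μm² of
        evaluated area is within budget; if none qualifies, the shortest
        candidate (with a warning).
    """
    policy.validate()
    for t in sorted(policy.exposure_candidates, reverse=True):
        if t not in images:
            raise ConfigurationError(f"no image supplied for candidate exposure {t} s")
        img = np.asarray(images[t])
        if eval_mask is not None:
            sat = int((img[eval_mask] >= policy.saturation_level).sum())
            area_um2 = float(eval_mask.sum()) * pixel_size_um ** 2
        else:
            sat = int((img >= policy.saturation_level).sum())
            area_um2 = img.size * pixel_size_um ** 2
        if area_um2 <= 0:
            raise ConfigurationError("evaluated area is empty")
        if sat / (area_um2 / 100.0) <= policy.saturation_budget:
            return t
    shortest = min(policy.exposure_candidates)
    warnings.warn(
        f"saturation budget exceeded at every candidate exposure; "
        f"falling back to the shortest ({shortest} s)", stacklevel=2)
    return shortest


def measure_cell(obj: SegmentedObject, channel_image: np.ndarray,
                 exposure_s: float, background: float | None = None,
                 *, gain: float = 1.0) -> tuple[float, float]:
    """Integrate one cell on one channel.

    Returns ``(raw, normalized)`` where ``raw`` is the background-subtracted
    integrated pixel intensity over the mask (clamped at 0) and
    ``normalized = raw / area_um2 / exposure_s / gain`` — the exposure-,
    area- (and camera-gain-) normalized intensity. ``background`` defaults to
    the object's local-background estimate from detection.
    """
    if exposure_s <= 0:
        raise ConfigurationError(f"exposure_s must be > 0, got {exposure_s}")
    img = np.asarray(channel_image, dtype=np.float64)
    if img.shape != obj.mask.shape:
        raise ValueError(
            f"mask shape {obj.mask.shape} does not match image shape {img.shape}")
    bg = obj.local_background if background is None else float(background)
    raw = float(img[obj.mask].sum() - bg * obj.mask.sum())
    raw = max(raw, 0.0)
    normalized = raw / obj.area_um2 / exposure_s / gain
    return raw, normalized


def measure_objects(objects: list[SegmentedObject],
                    channel_images: Mapping[str, np.ndarray],
                    exposure_s: float, *,
                    gain: float = 1.0,
                    condition: str = "control",
                    field_id: int = 0,
                    culture_id: str | int | None = None,
                    backgrounds: Mapping[str, float] | None = None,
                    ) -> pd.DataFrame:
    """Measure every object on every channel and return a tidy cell table.

    One row per object; per channel two columns, ``raw_<channel>`` and
    ``intensity_<channel>``. Each channel's background defaults to that
    channel's own image-wide median outside the object masks unless
    ``backgrounds`` provides a value (the marker channel typically reuses the
    detection-time local estimate via :func:`measure_cell` semantics).
    """
    rows = []
    chan_bg: dict[str, float] = {}
    any_mask = None
    for ch, img in channel_images.items():
        if backgrounds is not None and ch in backgrounds:
            chan_bg[ch] = float(backgrounds[ch])
        else:
            if any_mask is None:
                any_mask = np.zeros(np.asarray(img).shape, dtype=bool)
                for o in objects:
                    any_mask |= o.mask
            outside = np.asarray(img)[~any_mask]
            chan_bg[ch] = float(np.median(outside)) if outside.size else 0.0

    for obj in objects:
        row = {
            "cell_id": obj.label,
            "field_id": field_id,
            "condition": condition,
            "area_um2": obj.area_um2,
            "equivalent_diameter_um": obj.equivalent_diameter_um,
            "exposure_s": exposure_s,
        }
        if culture_id is not None:
            row["culture_id"] = culture_id
        for ch, img in channel_images.items():
            raw, norm = measure_cell(obj, img, exposure_s, chan_bg[ch], gain=gain)
            row[f"raw_{ch}"] = raw
            row[f"intensity_{ch}"] = norm
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_to_control(cells: pd.DataFrame, control_condition: str, *,
                         condition_col: str = "condition",
                         channels: list[str] | None = None) -> pd.DataFrame:
    """Rescale intensities so the control condition's mean is exactly 1.

    Every ``intensity_*`` column (or the named ``channels`` columns) is
    divided by its mean over the control-condition rows. Idempotent: applying
    it twice changes nothing.
    """
    if condition_col not in cells.columns:
        raise MissingConditionError(f"no column {condition_col!r} in cell table")
    ctrl = cells[cells[condition_col] == control_condition]
    if ctrl.empty:
        raise MissingConditionError(
            f"control condition {control_condition!r} has no cells")
    if channels is None:
        channels = [c for c in cells.columns if c.startswith("intensity_")]
    if not channels:
        raise ConfigurationError("no intensity columns to normalize")
    out = cells.copy()
    for col in channels:
        m = float(ctrl[col].mean())
        if m == 0:
            raise ConfigurationError(f"control mean of {col!r} is zero")
        out[col] = cells[col] / m
    return out
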