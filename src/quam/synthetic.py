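"""Synthetic heterogeneous sensory-neuron cultures with known ground truth.

Dissociated dorsal-root-ganglion (DRG) cultures are extremely heterogeneous:
soma diameters span roughly 14-32 μm, per-cell immunofluorescence intensities
vary with a coefficient of variation near 180%, the IB4 lectin stain is
bimodal (a low "unspecific binding" mode plus a broad specific mode covering
~71% of neurons), and only subgroups (~50%) respond to a given growth factor.
A sizeable fraction of neurons sit in clusters (~16%) or are cut by the field
border (~3%), and fields also contain glia and debris.

This module generates cell populations with exactly that statistical
structure, plus rendered multi-channel field images, so that every downstream
stage (segmentation, quantification, classification, virtual-well resampling)
can be validated against known truth without any external data.

Intensity laws
--------------
Per-cell intensities are lognormal, parameterized by mean ``m`` and
coefficient of variation ``c``::

    sigma^2 = ln(1 + c^2),   mu = ln(m) - sigma^2 / 2

so the arithmetic mean and CV of the draw match ``m`` and ``c`` exactly in
expectation. The IB4 channel is a two-component lognormal mixture; the low
component doubles as the blocked-control (lectin competition) distribution.
Stimulus response is a multiplicative fold change applied to the baseline
intensity of responder cells, times small per-cell lognormal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError

__all__ = [
    "ScenarioConfig",
    "FieldSpec",
    "RenderedField",
    "generate_population",
    "sample_blocked_control",
    "render_fields",
    "lognormal_params",
    "baseline_intensity_population",
]

#: Column order of the ground-truth population table.
POPULATION_COLUMNS = [
    "cell_id",
    "is_neuron",
    "diameter_um",
    "area_um2",
    "is_clustered",
    "touches_border",
    "ib4_status",
    "is_responder",
    "intensity_pgp",
    "intensity_ib4",
    "intensity_perk_baseline",
    "intensity_perk_stimulated",
]


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Return ``(mu, sigma)`` of a lognormal with arithmetic mean and CV."""
    if mean <= 0:
        raise ConfigurationError(f"lognormal mean must be > 0, got {mean}")
    if cv <= 0:
        raise ConfigurationError(f"lognormal cv must be > 0, got {cv}")
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    mu, sigma = lognormal_params(mean, cv)
    return rng.lognormal(mu, sigma, size)


@dataclass(frozen=True)
class ScenarioConfig:
    """Statistical description of one synthetic culture condition.

    Defaults reproduce the heterogeneity of dissociated adult-rat DRG
    cultures: 71% IB4(+) cells, 50% growth-factor responders, baseline
    phospho-signal CV of 1.80 on a control-mean scale of 1.0, IB4(+) soma
    diameters 22-32 μm vs 14-24 μm for IB4(-), 16% clustered cells and 3%
    border-cut cells per field.
    """

    n_cells: int = 5000
    ib4_positive_fraction: float = 0.71
    responder_fraction: float = 0.50
    responder_fold_change: float = 10.0
    baseline_mean: float = 1.0
    baseline_cv: float = 1.80
    response_noise_cv: float = 0.10
    diameter_range_pos: tuple[float, float] = (22.0, 32.0)
    diameter_range_neg: tuple[float, float] = (14.0, 24.0)
    cluster_fraction: float = 0.16
    border_fraction: float = 0.03
    glia_density: float = 3.0  # distractor objects per rendered field
    debris_density: float = 5.0
    marker_mean: float = 1.0  # pan-neuronal marker (PGP 9.5) channel
    marker_cv: float = 0.30
    ib4_neg_mean: float = 0.15  # unspecific-binding (blocked-control) mode
    ib4_neg_cv: float = 0.40
    ib4_pos_mean: float = 2.0
    ib4_pos_cv: float = 0.90
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        if not (isinstance(self.n_cells, (int, np.integer)) and self.n_cells > 0):
            raise ConfigurationError(f"n_cells must be a positive integer, got {self.n_cells}")
        for name in ("ib4_positive_fraction", "responder_fraction",
                     "cluster_fraction", "border_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.cluster_fraction + self.border_fraction > 1.0:
            raise ConfigurationError(
                "cluster_fraction + border_fraction must be <= 1, got "
                f"{self.cluster_fraction} + {self.border_fraction}")
        for name in ("responder_fold_change", "baseline_mean", "baseline_cv",
                     "response_noise_cv", "marker_mean", "marker_cv",
                     "ib4_neg_mean", "ib4_neg_cv", "ib4_pos_mean", "ib4_pos_cv"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        for name in ("diameter_range_pos", "diameter_range_neg"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        for name in ("glia_density", "debris_density"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        return self

    def with_(self, **kw) -> "ScenarioConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario fields: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        return cfg.validate()


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and camera model of one microscope view field.

    The default matches a 1280 x 1024 px camera behind a 10x objective with a
    12-bit quantizer. ``gain`` converts (intensity x μm² x s) of emitted
    signal into camera counts; ``quantize=False`` disables rounding/clipping
    for noise-free oracle renders.
    """

    width_px: int = 1280
    height_px: int = 1024
    pixel_size_um: float = 0.645
    bit_depth: int = 12
    background_level: float = 100.0
    background_noise_sd: float = 2.0
    gain: float = 2000.0
    channels: tuple[str, ...] = ("pgp", "ib4", "perk")
    quantize: bool = True

    @property
    def saturation_level(self) -> int:
        return 2 ** self.bit_depth - 1

    def validate(self) -> "FieldSpec":
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigurationError(
                f"width_px/height_px must be > 0, got {self.width_px}x{self.height_px}")
        if self.pixel_size_um <= 0:
            raise ConfigurationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.bit_depth <= 0:
            raise ConfigurationError(f"bit_depth must be > 0, got {self.bit_depth}")
        if self.gain <= 0:
            raise ConfigurationError(f"gain must be > 0, got {self.gain}")
        if self.background_noise_sd < 0:
            raise ConfigurationError(
                f"background_noise_sd must be >= 0, got {self.background_noise_sd}")
        return self


def generate_population(scenario: ScenarioConfig) -> pd.DataFrame:
    """Draw a ground-truth cell population table for one culture.

    Returns a DataFrame with one row per neuron (columns
    :data:`POPULATION_COLUMNS`). Deterministic for a fixed
    ``scenario.seed``. The pERK channel carries both the baseline
    (unstimulated) intensity and the stimulated intensity, which equals
    baseline x fold-change for responders (x small per-cell noise) and
    baseline x noise otherwise.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = int(scenario.n_cells)

    ib4_positive = rng.random(n) < scenario.ib4_positive_fraction
    responder = rng.random(n) < scenario.responder_fraction

    # cluster / border / singlet are mutually exclusive placement classes
    u = rng.random(n)
    clustered = u < scenario.cluster_fraction
    border = (~clustered) & (u < scenario.cluster_fraction + scenario.border_fraction)

    diam = np.empty(n)
    lo_p, hi_p = scenario.diameter_range_pos
    lo_n, hi_n = scenario.diameter_range_neg
    diam[ib4_positive] = rng.uniform(lo_p, hi_p, int(ib4_positive.sum()))
    diam[~ib4_positive] = rng.uniform(lo_n, hi_n, int((~ib4_positive).sum()))
    area = np.pi * (diam / 2.0) ** 2

    marker = _draw_lognormal(rng, scenario.marker_mean, scenario.marker_cv, n)
    ib4 = np.where(
        ib4_positive,
        _draw_lognormal(rng, scenario.ib4_pos_mean, scenario.ib4_pos_cv, n),
        _draw_lognormal(rng, scenario.ib4_neg_mean, scenario.ib4_neg_cv, n),
    )
    baseline = _draw_lognormal(rng, scenario.baseline_mean, scenario.baseline_cv, n)
    noise = _draw_lognormal(rng, 1.0, scenario.response_noise_cv, n)
    fold = np.where(responder, scenario.responder_fold_change, 1.0)
    stimulated = baseline * fold * noise

    df = pd.DataFrame({
        "cell_id": np.arange(n, dtype=np.int64),
        "is_neuron": np.ones(n, dtype=bool),
        "diameter_um": diam,
        "area_um2": area,
        "is_clustered": clustered,
        "touches_border": border,
        "ib4_status": np.where(ib4_positive, "positive", "negative"),
        "is_responder": responder,
        "intensity_pgp": marker,
        "intensity_ib4": ib4,
        "intensity_perk_baseline": baseline,
        "intensity_perk_stimulated": stimulated,
    }, columns=POPULATION_COLUMNS)
    df.attrs["glia_density"] = scenario.glia_density
    df.attrs["debris_density"] = scenario.debris_density
    return df


def baseline_intensity_population(n_cells: int = 49_503, mean: float = 1.0,
                                  sd: float = 1.80, seed: int = 0) -> np.ndarray:
    """Lognormal intensity pool with *exact* sample mean and SD.

    Stands in for a large pool of measured per-cell intensities whose
    empirical moments are known (control-mean scale 1.0, SD 1.80 for
    unstimulated phospho-signal). A raw lognormal draw of ~50k values still
    carries ~5% sampling error in its SD (the distribution's kurtosis is
    ~520), so the draw is affinely rescaled to the stated sample moments and
    clamped at zero (the clamp touches at most a vanishing mass near the
    origin; its effect on the moments is < 1e-4 relative).
    """
    if n_cells < 2:
        raise ConfigurationError(f"n_cells must be >= 2, got {n_cells}")
    rng = np.random.default_rng(seed)
    x = _draw_lognormal(rng, mean, sd / mean, int(n_cells))
    x = mean + (x - x.mean()) * (sd / x.std(ddof=1))
    return np.clip(x, 0.0, None)


def sample_blocked_control(scenario: ScenarioConfig, n_cells: int,
                           seed: int | None = None) -> np.ndarray:
    """Draw IB4 intensities of a lectin-blocked control culture.

    Competitive block with unlabeled lectin removes all specific binding, so
    every cell draws from the scenario's low (unspecific-binding) IB4
    component.
    """
    scenario.validate()
    if n_cells <= 0:
        raise ConfigurationError(f"n_cells must be > 0, got {n_cells}")
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    return _draw_lognormal(rng, scenario.ib4_neg_mean, scenario.ib4_neg_cv, int(n_cells))


# --------------------------------------------------------------------------
# field rendering
# --------------------------------------------------------------------------

@dataclass
class RenderedField:
    """One rendered view field: channel images plus its slice of the truth."""

    field_id: int
    images: dict[str, np.ndarray]
    truth: pd.DataFrame = field(repr=False, default=None)


#: population column rendered into each image channel by default
DEFAULT_CHANNEL_MAP = {
    "pgp": "intensity_pgp",
    "ib4": "intensity_ib4",
    "perk": "intensity_perk_baseline",
}


def _ellipse_mask_coords(cy, cx, r_px, aspect, angle, shape):
    """Pixel coordinates of an ellipse with area ~= pi r^2 and given aspect."""
    a = r_px * math.sqrt(aspect)  # semi-major
    b = r_px / math.sqrt(aspect)  # semi-minor
    return draw_ellipse(cy, cx, a, b, shape=shape, rotation=angle)


def _paint(img, rr, cc, amplitude):
    img[rr, cc] += amplitude


def _render_glia(img, rng, spec, exposure):
    """A distractor violating contrast (dim blob) or concavity (bright crescent)."""
    h, w = img.shape
    cy = rng.uniform(40, h - 40)
    cx = rng.uniform(40, w - 40)
    r = rng.uniform(18.0, 25.0) / spec.pixel_size_um / 2.0
    if rng.random() < 0.5:
        # low-contrast blob: 15% above background, below the 30% contrast rule
        rr, cc = _ellipse_mask_coords(cy, cx, r, rng.uniform(1.0, 1.6),
                                      rng.uniform(0, math.pi), img.shape)
        _paint(img, rr, cc, 0.15 * spec.background_level)
        return "glia_dim"
    # bright crescent: disc minus offset disc, deeply concave
    rr, cc = draw_ellipse(cy, cx, r, r, shape=img.shape)
    mask = np.zeros(img.shape, dtype=bool)
    mask[rr, cc] = True
    rr2, cc2 = draw_ellipse(cy + 0.8 * r, cx, r, r, shape=img.shape)
    mask[rr2, cc2] = False
    amp = 1.2 * spec.background_level
    img[mask] += amp
    return "glia_crescent"


def _render_debris(img, rng, spec, exposure):
    """Bright sub-150 μm² speck."""
    h, w = img.shape
    cy = rng.uniform(10, h - 10)
    cx = rng.uniform(10, w - 10)
    r = rng.uniform(1.5, 4.5)  # px; well under the minimum neuron area
    rr, cc = draw_ellipse(cy, cx, r, r, shape=img.shape)
    _paint(img, rr, cc, 2.0 * spec.background_level)
    return "debris"


def render_fields(cells: pd.DataFrame, spec: FieldSpec = FieldSpec(),
                  exposure: float = 0.96, *,
                  channel_map: dict[str, str] | None = None,
                  seed: int = 0) -> list[RenderedField]:
    """Rasterize a ground-truth population into multi-channel field images.

    Neurons are near-circular ellipses (aspect ratio < 2) of uniform surface
    brightness ``true_intensity x pixel_size² x exposure x gain`` counts per
    pixel above background, so integrating a noise-free render over the mask
    and dividing by mask area, exposure and gain returns ``true_intensity``
    exactly. Clustered neurons are placed as touching pairs, border neurons
    cut by the field edge; glia and debris distractors are added per field at
    the scenario densities encoded in ``cells.attrs`` (or defaults).

    Parameters
    ----------
    cells
        Population table from :func:`generate_population`.
    spec
        Field geometry / camera model.
    exposure
        Exposure time in seconds (> 0).
    channel_map
        Maps each ``spec.channels`` entry to a population intensity column.
    seed
        Layout / noise RNG seed (independent of the population seed).

    Returns
    -------
    list of :class:`RenderedField`
        Each with float or quantized-integer images per channel and the truth
        table augmented with ``field_id``, ``center_x``, ``center_y``,
        ``render_aspect``.
    """
    spec.validate()
    if exposure <= 0:
        raise ConfigurationError(f"exposure must be > 0 s, got {exposure}")
    channel_map = dict(DEFAULT_CHANNEL_MAP if channel_map is None else channel_map)
    for ch in spec.channels:
        if ch not in channel_map:
            raise ConfigurationError(f"channel {ch!r} missing from channel_map")
        if channel_map[ch] not in cells.columns:
            raise ConfigurationError(
                f"channel_map[{ch!r}] = {channel_map[ch]!r} is not a population column")

    rng = np.random.default_rng(seed)
    px = spec.pixel_size_um
    glia_per_field = cells.attrs.get("glia_density", 3.0)
    debris_per_field = cells.attrs.get("debris_density", 5.0)

    # interior slot grid; one slot holds one singlet or one touching pair
    max_r_px = float(cells["diameter_um"].max()) / 2.0 / px
    pitch = int(math.ceil(4.6 * max_r_px))
    margin = int(math.ceil(2.4 * max_r_px))
    xs = np.arange(margin, spec.width_px - margin, pitch)
    ys = np.arange(margin, spec.height_px - margin, pitch)
    if len(xs) == 0 or len(ys) == 0:
        raise ConfigurationError("field too small for the population's cell sizes")
    interior_slots = [(y, x) for y in ys for x in xs]
    border_slots_per_field = max(4, len(xs) // 2)

    singles = cells.index[~cells["is_clustered"] & ~cells["touches_border"]].to_list()
    borders = cells.index[cells["touches_border"]].to_list()
    clustered = cells.index[cells["is_clustered"]].to_list()
    pairs = [clustered[i:i + 2] for i in range(0, len(clustered), 2)]

    interior_units: list[list[int]] = [[i] for i in singles] + pairs
    rng.shuffle(interior_units)

    n_fields = max(
        1,
        math.ceil(len(interior_units) / len(interior_slots)),
        math.ceil(len(borders) / border_slots_per_field) if borders else 1,
    )

    out: list[RenderedField] = []
    cols = {c: cells[c].to_numpy() for c in cells.columns}
    placed_field = np.full(len(cells), -1, dtype=np.int64)
    placed_cy = np.full(len(cells), np.nan)
    placed_cx = np.full(len(cells), np.nan)
    placed_aspect = np.full(len(cells), np.nan)

    unit_iter = iter(interior_units)
    border_iter = iter(borders)
    units_left = len(interior_units)
    borders_left = len(borders)

    for fid in range(n_fields):
        imgs = {ch: np.zeros((spec.height_px, spec.width_px), dtype=np.float64)
                for ch in spec.channels}
        field_rows: list[int] = []

        def place(idx_row: int, cy: float, cx: float, aspect: float, angle: float):
            r_px = cols["diameter_um"][idx_row] / 2.0 / px
            for ch in spec.channels:
                inten = cols[channel_map[ch]][idx_row]
                rr, cc = _ellipse_mask_coords(cy, cx, r_px, aspect, angle,
                                              imgs[ch].shape)
                amp = inten * px * px * exposure * spec.gain
                _paint(imgs[ch], rr, cc, amp)
            placed_field[idx_row] = fid
            placed_cy[idx_row] = cy
            placed_cx[idx_row] = cx
            placed_aspect[idx_row] = aspect
            field_rows.append(idx_row)

        # interior units on jittered grid slots
        slots = list(interior_slots)
        rng.shuffle(slots)
        for (sy, sx) in slots:
            if units_left == 0:
                break
            unit = next(unit_iter)
            units_left -= 1
            jy = sy + rng.uniform(-0.1, 0.1) * pitch
            jx = sx + rng.uniform(-0.1, 0.1) * pitch
            if len(unit) == 1:
                place(unit[0], jy, jx, rng.uniform(1.0, 1.3), rng.uniform(0, math.pi))
            else:
                a, b = unit
                ra = cols["diameter_um"][a] / 2.0 / px
                rb = cols["diameter_um"][b] / 2.0 / px
                gap = 0.9 * (ra + rb)  # overlap slightly -> one merged blob
                ang = rng.uniform(0, math.pi)
                dy, dx = math.sin(ang) * gap / 2, math.cos(ang) * gap / 2
                place(a, jy - dy, jx - dx, rng.uniform(1.0, 1.15), ang)
                place(b, jy + dy, jx + dx, rng.uniform(1.0, 1.15), ang)

        # border cells: center close enough to an edge that the disc is cut
        edges = ["top", "bottom", "left", "right"]
        for _ in range(border_slots_per_field):
            if borders_left == 0:
                break
            i = next(border_iter)
            borders_left -= 1
            r_px = cols["diameter_um"][i] / 2.0 / px
            off = rng.uniform(0.2, 0.6) * r_px
            edge = edges[int(rng.integers(len(edges)))]
            if edge == "top":
                cy, cx = off, rng.uniform(margin, spec.width_px - margin)
            elif edge == "bottom":
                cy, cx = spec.height_px - 1 - off, rng.uniform(margin, spec.width_px - margin)
            elif edge == "left":
                cy, cx = rng.uniform(margin, spec.height_px - margin), off
            else:
                cy, cx = rng.uniform(margin, spec.height_px - margin), spec.width_px - 1 - off
            place(i, cy, cx, rng.uniform(1.0, 1.2), rng.uniform(0, math.pi))

        # distractors on the neuron-marker channel (they express no marker
        # specifically, but autofluoresce / scatter into every channel alike)
        n_glia = rng.poisson(glia_per_field)
        n_debris = rng.poisson(debris_per_field)
        marker_ch = spec.channels[0]
        for _ in range(n_glia):
            _render_glia(imgs[marker_ch], rng, spec, exposure)
        for _ in range(n_debris):
            _render_debris(imgs[marker_ch], rng, spec, exposure)

        for ch in spec.channels:
            img = imgs[ch] + spec.background_level
            if spec.background_noise_sd > 0:
                img = img + rng.normal(0.0, spec.background_noise_sd, img.shape)
            if spec.quantize:
                img = np.clip(np.rint(img), 0, spec.saturation_level).astype(np.uint16)
            imgs[ch] = img

        truth = cells.iloc[sorted(field_rows)].copy()
        truth["field_id"] = fid
        truth["center_y"] = placed_cy[sorted(field_rows)]
        truth["center_x"] = placed_cx[sorted(field_rows)]
        truth["render_aspect"] = placed_aspect[sorted(field_rows)]
        out.append(RenderedField(field_id=fid, images=imgs, truth=truth))

    return out
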