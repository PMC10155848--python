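"""Hair-swatch cleanability from CIELAB L* readings.

A white hair swatch darkened by the sebum/carbon-black mixture loses
lightness; washing recovers part of it. The cleanability index normalizes
the recovered lightness between the tainted and untreated states::

    cleanability% = (L*_wash - L*_sebollution) / (L*_control - L*_sebollution) * 100

so 0% means the wash changed nothing and 100% means full recovery to the
untreated control. Measurement noise can push individual replicates outside
[0, 100]; such values are reported as-is and flagged, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .images import LabeledImage

__all__ = [
    "ColorReading",
    "RoiSpec",
    "CleanabilityResult",
    "mean_lightness_from_image",
    "cleanability_hair",
    "aggregate_swatches",
    "cleanability_from_readings",
    "readings_to_frame",
]

#: States a swatch reading can be attached to.
STATES = ("control", "sebollution", "wash")


@dataclass(frozen=True)
class ColorReading:
    """One CIELAB triple attached to a swatch state."""

    L: float
    a: float
    b: float
    state: str
    swatch_id: str = ""

    def __post_init__(self):
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must be in [0, 100], got {self.L}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")


@dataclass(frozen=True)
class RoiSpec:
    """Centered rectangular region of interest on the swatch (cm)."""

    length: float = 7.2
    width: float = 0.6

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValueError("ROI length and width must be > 0")


@dataclass
class CleanabilityResult:
    """A cleanability percentage with its provenance."""

    cleanability: float
    site: str  # forearm | scalp | swatch
    formula_id: str | None = None
    n_replicates: int = 1
    sd: float = math.nan
    flags: tuple[str, ...] = field(default_factory=tuple)


def _lightness_raster(image: LabeledImage | np.ndarray) -> np.ndarray:
    """Convert an image to an L* raster.

    RGB inputs go through sRGB -> CIELAB (D65, skimage); 8-bit grey is
    treated as sRGB grey and converted the same way; float 2-D arrays with
    values in [0, 100] are taken to be L* already (the colorimeter outputs
    L* directly, so synthetic rasters are usually in this form).
    """
    px = image.pixels if isinstance(image, LabeledImage) else np.asarray(image)
    if px.ndim == 3 and px.shape[-1] in (3, 4):
        rgb = px[..., :3]
        if rgb.dtype == np.uint8:
            rgb = rgb / 255.0
        return skcolor.rgb2lab(rgb)[..., 0]
    if px.ndim == 2:
        if np.issubdtype(px.dtype, np.floating) and px.max() <= 100.0:
            return px.astype(float)
        rgb = np.repeat((px / 255.0)[..., None], 3, axis=-1)
        return skcolor.rgb2lab(rgb)[..., 0]
    raise ValueError(f"expected grey or RGB image, got shape {px.shape}")


def mean_lightness_from_image(
    image: LabeledImage | np.ndarray,
    roi: RoiSpec = RoiSpec(),
    pixel_scale: float | None = None,
) -> float:
    """Mean L* over a centered ROI aligned with the swatch long axis.

    The ROI (``roi.length`` x ``roi.width`` cm) is placed at the geometric
    center of the image, its long side along the longer image dimension.

    Parameters
    ----------
    pixel_scale :
        mm per pixel; taken from ``image.pixel_scale`` when omitted.
    """
    if pixel_scale is None and isinstance(image, LabeledImage):
        pixel_scale = image.pixel_scale
    if pixel_scale is None or pixel_scale <= 0:
        raise ValueError("pixel_scale (mm/px) is required and must be > 0")
    lab = _lightness_raster(image)
    h, w = lab.shape
    len_px = int(round(roi.length * 10.0 / pixel_scale))
    wid_px = int(round(roi.width * 10.0 / pixel_scale))
    long_dim, short_dim = max(h, w), min(h, w)
    if len_px > long_dim or wid_px > short_dim:
        raise ValueError(
            f"ROI {roi.length} x {roi.width} cm needs {len_px} x {wid_px} px "
            f"but the image is only {h} x {w} px at {pixel_scale} mm/px"
        )
    if h >= w:
        ry, rx = len_px, wid_px
    else:
        ry, rx = wid_px, len_px
    y0 = (h - ry) // 2
    x0 = (w - rx) // 2
    return float(lab[y0:y0 + ry, x0:x0 + rx].mean())


def cleanability_hair(L_wash: float, L_sebollution: float,
                      L_control: float) -> float:
    """Cleanability% = (L_wash - L_seb) / (L_control - L_seb) * 100.

    Raises
    ------
    ValueError
        If ``L_control <= L_sebollution`` (non-positive denominator: the
        index is undefined when soiling did not darken the swatch).
    """
    if L_control <= L_sebollution:
        raise ValueError(
            f"cleanability undefined: L_control ({L_control}) must exceed "
            f"L_sebollution ({L_sebollution})"
        )
    return (L_wash - L_sebollution) / (L_control - L_sebollution) * 100.0


def aggregate_swatches(results: Sequence[float], formula_id: str | None = None,
                       site: str = "swatch") -> CleanabilityResult:
    """Mean and sample sd (n-1 denominator) over replicate cleanabilities.

    Replicates outside [0, 100] raise the ``out_of_range`` flag; values are
    never clamped.
    """
    vals = np.asarray(list(results), dtype=float)
    if vals.size == 0:
        raise ValueError("aggregate_swatches needs at least one replicate")
    flags = []
    if np.any((vals < 0) | (vals > 100)):
        flags.append("out_of_range")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan
    return CleanabilityResult(
        cleanability=float(vals.mean()), site=site, formula_id=formula_id,
        n_replicates=int(vals.size), sd=sd, flags=tuple(flags),
    )


def readings_to_frame(
    triples: Iterable[tuple[ColorReading, ColorReading, ColorReading]],
    formula_id: str = "F01",
) -> pd.DataFrame:
    """Flatten generator-style reading triples into the readings table."""
    rows = [
        {"swatch_id": r.swatch_id, "formula_id": formula_id, "state": r.state,
         "L": r.L, "a": r.a, "b": r.b}
        for triple in triples for r in triple
    ]
    return pd.DataFrame(rows)


def cleanability_from_readings(readings: pd.DataFrame) -> pd.DataFrame:
    """Per-formula cleanability from a long-format readings table.

    Expects columns ``swatch_id, formula_id, state, L`` (a/b optional).
    ``L_control`` is the batch-wide mean over all ``control`` readings (the
    control is a single untreated swatch measured repeatedly, shared across
    formulae); per replicate, the wash and sebollution L* of the same
    swatch enter the index. Returns one row per formula:
    ``formula_id, mean_cleanability, sd, n, flags``.
    """
    required = {"swatch_id", "formula_id", "state", "L"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"readings table missing columns: {sorted(missing)}")
    controls = readings.loc[readings["state"] == "control", "L"]
    if controls.empty:
        raise ValueError("readings table contains no control-state rows")
    l_control = float(controls.mean())

    out = []
    for formula_id, grp in readings.groupby("formula_id", sort=True):
        reps = []
        for _, swatch in grp.groupby("swatch_id", sort=True):
            by_state = swatch.set_index("state")["L"]
            if "wash" not in by_state.index or "sebollution" not in by_state.index:
                continue
            reps.append(cleanability_hair(
                float(by_state["wash"]), float(by_state["sebollution"]),
                l_control,
            ))
        if not reps:
            continue
        res = aggregate_swatches(reps, formula_id=formula_id)
        out.append({
            "formula_id": formula_id,
            "mean_cleanability": res.cleanability,
            "sd": res.sd,
            "n": res.n_replicates,
            "flags": ";".join(res.flags),
        })
    if not out:
        raise ValueError("no formula had complete (sebollution, wash) readings")
    return pd.DataFrame(out)
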