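"""In-vivo skin cleanability from paired dermatoscope images.

The soiled area at T0 (before washing) and T1 (after) is photographed; the
fraction of dark pixels measures how much pigment-loaded sebum remains, and

    cleanability% = (T0_dark - T1_dark) / T0_dark * 100

is the relative reduction. Negative values (net re-deposition) are possible
and are reported, not clipped. Thresholding is done per pair: by default
Otsu's threshold is computed on the T0 image and the same absolute grey
level is reused on T1, so that washing cannot shift the dark-pixel
criterion between the two frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .hair_cleanability import CleanabilityResult
from .images import LabeledImage, as_gray, read_image

__all__ = [
    "DarkPixelMeasurement",
    "ThresholdConfig",
    "dark_pixel_fraction",
    "cleanability_skin",
    "batch_skin_cleanability",
    "batch_from_manifest",
    "summarize_skin_batch",
]

_FALLBACK_THRESHOLD = 128.0


@dataclass(frozen=True)
class ThresholdConfig:
    """Dark-pixel threshold: Otsu (adaptive per image) or a fixed grey level."""

    method: str = "otsu"
    value: float | None = None

    def __post_init__(self):
        if self.method not in ("otsu", "fixed"):
            raise ValueError("threshold method must be 'otsu' or 'fixed'")
        if self.method == "fixed" and self.value is None:
            raise ValueError("fixed threshold requires a value")

    @classmethod
    def parse(cls, text: str) -> "ThresholdConfig":
        """Parse ``"otsu"`` or ``"fixed:<grey level>"``."""
        if text == "otsu":
            return cls("otsu")
        if text.startswith("fixed:"):
            return cls("fixed", float(text.split(":", 1)[1]))
        raise ValueError(f"cannot parse threshold spec {text!r}")


@dataclass
class DarkPixelMeasurement:
    """Dark-pixel fraction of a delineated area."""

    dark_fraction: float  # percent of area pixels classified dark
    threshold_used: float  # grey level actually applied
    area_px: int


def dark_pixel_fraction(
    image: LabeledImage | np.ndarray,
    threshold_cfg: ThresholdConfig = ThresholdConfig(),
    area_mask: np.ndarray | None = None,
) -> DarkPixelMeasurement:
    """Percent of area pixels strictly below the dark threshold.

    RGB input is converted to grey by ITU-R BT.601 luma. ``area_mask``
    restricts the measurement to a delineated region (default: whole
    frame). A uniform-intensity image under Otsu falls back to a fixed
    threshold of 128 with a warning.
    """
    grey = as_gray(image)
    if area_mask is not None:
        area_mask = np.asarray(area_mask, bool)
        if area_mask.shape != grey.shape:
            raise ValueError("area_mask shape does not match the image")
        vals = grey[area_mask]
    else:
        vals = grey.ravel()
    if vals.size == 0:
        raise ValueError("empty area mask: no pixels to measure")

    if threshold_cfg.method == "fixed":
        thr = float(threshold_cfg.value)
    else:
        if np.ptp(vals) == 0:
            warnings.warn(
                "uniform-intensity image: Otsu undefined, falling back to "
                f"fixed threshold {_FALLBACK_THRESHOLD}", stacklevel=2,
            )
            thr = _FALLBACK_THRESHOLD
        else:
            thr = float(threshold_otsu(vals))
    dark = int(np.count_nonzero(vals < thr))
    return DarkPixelMeasurement(
        dark_fraction=100.0 * dark / vals.size,
        threshold_used=thr,
        area_px=int(vals.size),
    )


def cleanability_skin(
    t0: DarkPixelMeasurement | float,
    t1: DarkPixelMeasurement | float,
    *,
    clamp: bool = False,
    site: str = "forearm",
    formula_id: str | None = None,
) -> CleanabilityResult:
    """Cleanability% = (T0_dark - T1_dark) / T0_dark * 100 for one area.

    ``clamp=True`` limits the result to [0, 100] (off by default; the raw
    index may be negative when washing deposited more pigment).

    Raises
    ------
    ValueError
        If the T0 dark fraction is zero (index undefined).
    """
    f0 = t0.dark_fraction if isinstance(t0, DarkPixelMeasurement) else float(t0)
    f1 = t1.dark_fraction if isinstance(t1, DarkPixelMeasurement) else float(t1)
    if f0 <= 0:
        raise ValueError("cleanability undefined: T0 dark fraction is zero")
    value = (f0 - f1) / f0 * 100.0
    if clamp:
        value = min(100.0, max(0.0, value))
    return CleanabilityResult(cleanability=value, site=site,
                              formula_id=formula_id, n_replicates=1)


def _measure_pair(t0_img, t1_img, threshold_cfg: ThresholdConfig):
    """Measure a pair with the T0 threshold reused on T1."""
    g0, g1 = as_gray(t0_img), as_gray(t1_img)
    if g0.shape != g1.shape:
        raise ValueError(
            f"mismatched image shapes within a pair: {g0.shape} vs {g1.shape}"
        )
    m0 = dark_pixel_fraction(g0, threshold_cfg)
    m1 = dark_pixel_fraction(
        g1, ThresholdConfig("fixed", m0.threshold_used)
    )
    return m0, m1


def batch_skin_cleanability(
    pairs: Sequence[tuple],
    threshold_cfg: ThresholdConfig = ThresholdConfig(),
    area_ids: Sequence[str] | None = None,
    formula_ids: Sequence[str] | None = None,
    site: str = "forearm",
) -> pd.DataFrame:
    """Cleanability for every (T0, T1) image pair; one row per area.

    Returns columns ``area_id, formula_id, t0_dark, t1_dark,
    threshold, cleanability``. Group with :func:`summarize_skin_batch` for
    per-formula mean +/- sd.
    """
    if len(pairs) == 0:
        raise ValueError("batch_skin_cleanability needs at least one pair")
    area_ids = area_ids or [f"A{i + 1:02d}" for i in range(len(pairs))]
    formula_ids = formula_ids or [""] * len(pairs)
    rows = []
    for aid, fid, (t0_img, t1_img) in zip(area_ids, formula_ids, pairs):
        m0, m1 = _measure_pair(t0_img, t1_img, threshold_cfg)
        res = cleanability_skin(m0, m1, site=site, formula_id=fid or None)
        rows.append({"area_id": aid, "formula_id": fid,
                     "t0_dark": m0.dark_fraction, "t1_dark": m1.dark_fraction,
                     "threshold": m0.threshold_used,
                     "cleanability": res.cleanability})
    return pd.DataFrame(rows)


def summarize_skin_batch(per_area: pd.DataFrame) -> pd.DataFrame:
    """Per-formula mean +/- sample sd of the per-area cleanabilities."""
    grouped = per_area.groupby("formula_id", sort=True)["cleanability"]
    out = grouped.agg(mean_cleanability="mean",
                      sd=lambda v: v.std(ddof=1) if len(v) > 1 else math.nan,
                      n="count").reset_index()
    return out


def batch_from_manifest(
    manifest_path: str | Path,
    threshold_cfg: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Run the batch from a manifest CSV (area_id, t0_path, t1_path, formula_id)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"area_id", "t0_path", "t1_path", "formula_id"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    pairs, area_ids, formula_ids = [], [], []
    for _, row in manifest.iterrows():
        t0 = read_image(base / str(row["t0_path"]))
        t1 = read_image(base / str(row["t1_path"]))
        pairs.append((t0, t1))
        area_ids.append(str(row["area_id"]))
        formula_ids.append(str(row["formula_id"]))
    return batch_skin_cleanability(pairs, threshold_cfg,
                                   area_ids=area_ids, formula_ids=formula_ids)
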