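"""Ground-truthed synthetic inputs for the soiling/cleanability pipelines.

Real measurements in this domain come from three very different instruments:
SEM micrographs of hair fibers carrying carbon-black (CB) particles,
dermatoscope pictures of pigment-soiled skin, and colorimeter L* readings of
hair swatches. None of those data are publicly deposited, so every pipeline
stage in this package is validated by parameter recovery against the
generators below, each of which records its exact ground truth.

All generators are seeded with a single integer and are bit-reproducible:
identical arguments and seed give identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .hair_cleanability import ColorReading
from .images import LabeledImage, write_image, write_mask

__all__ = [
    "SebollutionSpec",
    "SemGroundTruth",
    "SkinPairTruth",
    "SwatchTruth",
    "CoverageUnreachableError",
    "generate_sem_field",
    "generate_skin_pair",
    "generate_swatch_readings",
    "generate_study_table",
    "calibrate_study_noise",
    "sample_particle_diameters",
    "save_sem_dataset",
]

# Rendering constants for SEM-like fields (8-bit grey levels).
_BACKGROUND_LEVEL = 70.0
_FIBER_LEVEL = 160.0
_PARTICLE_LEVEL = 35.0
_PIXEL_NOISE_SD = 3.0
_FIBER_BAND_FRACTION = 0.4  # fraction of field width occupied by the fiber
# Correlation length of the cuticle-like texture: cuticle cells are tens of
# um long, an order of magnitude above the ~2 um particles.
_TEXTURE_SCALE_UM = 20.0


class CoverageUnreachableError(RuntimeError):
    """Raised when a requested particle coverage cannot be reached.

    Carries the maximum coverage actually achieved in ``achieved``.
    """

    def __init__(self, target: float, achieved: float):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"target coverage {target:.2f}% unreachable at this geometry; "
            f"achieved at most {achieved:.2f}%"
        )


@dataclass(frozen=True)
class SebollutionSpec:
    """Composition and dosing of the artificial pollutant mixture.

    The mixture ("sebollution") is artificial sebum blended 9/1 (w/w) with
    dark pigments (carbon black CI 77266 plus iron oxides CI 77492);
    ``cb_fraction`` is the pigment mass fraction, i.e. the 1 part of that
    9/1 split. Doses follow the in-vivo / in-vitro protocols: 2 mg/cm^2 on
    delineated skin areas, 90 ul per 1 g hair swatch. CB particle diameters
    are 2.07 +/- 0.3 um.
    """

    cb_fraction: float = 0.1
    skin_dose: float = 2.0  # mg/cm^2
    swatch_dose: float = 90.0  # ul per g hair
    particle_diameter_mean: float = 2.07  # um
    particle_diameter_sd: float = 0.3  # um

    def __post_init__(self):
        vals = (self.cb_fraction, self.skin_dose, self.swatch_dose,
                self.particle_diameter_mean, self.particle_diameter_sd)
        if any(v <= 0 for v in vals):
            raise ValueError("all SebollutionSpec fields must be > 0")
        if self.particle_diameter_sd >= self.particle_diameter_mean:
            raise ValueError("particle_diameter_sd must be < mean diameter")


@dataclass
class SemGroundTruth:
    """Exact masks and coverage for a synthetic SEM field."""

    particle_mask: np.ndarray
    fiber_mask: np.ndarray
    true_coverage: float  # percent of fiber surface covered

    def recompute_coverage(self) -> float:
        return 100.0 * np.count_nonzero(
            self.particle_mask & self.fiber_mask
        ) / np.count_nonzero(self.fiber_mask)


@dataclass
class SkinPairTruth:
    """Exact dark fractions behind a synthetic T0/T1 skin image pair."""

    t0_dark_fraction: float  # percent of area pixels
    t1_dark_fraction: float
    true_cleanability: float  # percent, recomputed from the pixel counts


@dataclass(frozen=True)
class SwatchTruth:
    """Ground truth behind a set of swatch colorimeter readings.

    ``L_control`` is the lightness of the untreated (white) swatch,
    ``L_sebollution`` of the tainted one; washing with a product of
    ``true_cleanability`` percent recovers that fraction of the lost
    lightness. Replicate readings carry Gaussian noise with sd
    ``replicate_noise_sd`` (in L* units; about 1 for the instrument
    emulated here).
    """

    L_control: float = 85.0
    L_sebollution: float = 35.0
    true_cleanability: float = 60.0
    replicate_noise_sd: float = 1.0

    def __post_init__(self):
        if not self.L_control > self.L_sebollution:
            raise ValueError("L_control must exceed L_sebollution")
        if self.true_cleanability < 0:
            raise ValueError("true_cleanability must be >= 0")


def sample_particle_diameters(spec: SebollutionSpec, n: int,
                              rng: np.random.Generator,
                              min_diameter: float = 0.5) -> np.ndarray:
    """Draw ``n`` CB particle diameters (um): normal truncated below.

    The distribution is N(mean, sd) truncated at ``min_diameter`` um by
    rejection; with the default parameters the truncation point sits >5 sd
    below the mean, so the sample mean/sd match the spec values closely.
    """
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.particle_diameter_mean,
                          spec.particle_diameter_sd, n - filled)
        keep = draw[draw > min_diameter]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def _smooth_noise_field(shape: tuple[int, int], sigma: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-sd spatially correlated Gaussian field (cuticle-like texture)."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma)
    return sm / sm.std()


def generate_sem_field(
    spec: SebollutionSpec = SebollutionSpec(),
    target_coverage: float = 8.0,
    image_shape: tuple[int, int] = (512, 512),
    pixel_scale: float = 0.2,
    noise_level: float = 0.08,
    seed: int = 0,
    coverage_tolerance: float = 0.25,
) -> tuple[LabeledImage, SemGroundTruth]:
    """Render a SEM-like field: grey textured fiber band + dark CB particles.

    The fiber is a vertical band covering ~40% of the field width, textured
    with multiplicative noise of relative amplitude ``noise_level`` and
    separated from the background by ~90 grey levels. Dark ellipses
    (axis ratio uniform in [0.7, 1.0], diameters from the spec's truncated
    normal) are added on the fiber until the union covers
    ``target_coverage`` percent of it, within ``coverage_tolerance``
    percentage points.

    Parameters
    ----------
    pixel_scale :
        um per pixel; must resolve the mean particle diameter to >= 4 px.
    target_coverage :
        Percent of fiber surface to cover, in [0, 50].

    Returns
    -------
    (LabeledImage, SemGroundTruth)
        The 8-bit image and the exact particle/fiber masks; the stored
        ``true_coverage`` is recomputed from those masks.

    Raises
    ------
    CoverageUnreachableError
        If the requested coverage cannot be reached at this geometry.
    """
    if not 0 <= target_coverage <= 50:
        raise ValueError("target_coverage must be in [0, 50] percent")
    mean_d_px = spec.particle_diameter_mean / pixel_scale
    if mean_d_px < 4:
        raise ValueError(
            f"pixel_scale={pixel_scale} um/px resolves the mean particle "
            f"diameter to {mean_d_px:.1f} px (< 4 px); use a finer scale"
        )

    rng = np.random.default_rng(seed)
    h, w = image_shape
    band_half = int(round(_FIBER_BAND_FRACTION * w / 2))
    c0, c1 = w // 2 - band_half, w // 2 + band_half
    fiber_mask = np.zeros(image_shape, dtype=bool)
    fiber_mask[:, c0:c1] = True
    fiber_area = np.count_nonzero(fiber_mask)

    # Place particles until the union coverage hits the target band.
    particle_mask = np.zeros(image_shape, dtype=bool)
    covered = 0
    achieved = 0.0
    attempts = 0
    rejects = 0
    max_attempts = 100_000
    while target_coverage - achieved > coverage_tolerance:
        attempts += 1
        if attempts > max_attempts or rejects > 500:
            raise CoverageUnreachableError(target_coverage, achieved)
        d_um = sample_particle_diameters(spec, 1, rng)[0]
        ratio = rng.uniform(0.7, 1.0)
        angle = rng.uniform(0.0, np.pi)
        r_major = d_um / pixel_scale / 2.0
        r_minor = r_major * ratio
        cy = rng.uniform(0, h)
        cx = rng.uniform(c0, c1)
        rr, cc = draw_ellipse(cy, cx, r_major, r_minor,
                              shape=image_shape, rotation=angle)
        keep = fiber_mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
        new = np.count_nonzero(~particle_mask[rr, cc])
        new_cov = 100.0 * (covered + new) / fiber_area
        if new_cov > target_coverage + coverage_tolerance:
            rejects += 1
            continue
        particle_mask[rr, cc] = True
        covered += new
        achieved = new_cov

    # Render: background, textured fiber, dark particles, read-out noise.
    img = np.full(image_shape, _BACKGROUND_LEVEL)
    texture = _smooth_noise_field(image_shape, _TEXTURE_SCALE_UM / pixel_scale,
                                  rng)
    img[fiber_mask] = _FIBER_LEVEL * (1.0 + noise_level * texture[fiber_mask])
    img[particle_mask] = _PARTICLE_LEVEL + 5.0 * texture[particle_mask]
    img += rng.normal(0.0, _PIXEL_NOISE_SD, image_shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = SemGroundTruth(
        particle_mask=particle_mask,
        fiber_mask=fiber_mask,
        true_coverage=100.0 * covered / fiber_area,
    )
    image = LabeledImage(img, pixel_scale=pixel_scale, scale_unit="um/px",
                         truth_mask=particle_mask)
    return image, truth


def generate_skin_pair(
    baseline_dark_fraction: float = 40.0,
    true_cleanability: float = 75.0,
    image_shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[LabeledImage, LabeledImage, SkinPairTruth]:
    """Render a T0 (soiled) / T1 (washed) dermatoscope-like image pair.

    T0 scatters dark pigment pixels over ``baseline_dark_fraction`` percent
    of the frame; washing removes ``true_cleanability`` percent of them, so
    T1 keeps the complementary subset at the same positions. The returned
    truth stores the exact dark fractions and the cleanability they imply
    (which can differ from the request by one-pixel rounding).
    """
    if not 0 <= true_cleanability <= 100:
        raise ValueError("true_cleanability must be in [0, 100]")
    if not 0 < baseline_dark_fraction <= 100:
        raise ValueError("baseline_dark_fraction must be in (0, 100]")

    rng = np.random.default_rng(seed)
    h, w = image_shape
    n_px = h * w
    n0 = max(1, int(round(baseline_dark_fraction / 100.0 * n_px)))
    n1 = int(round(n0 * (1.0 - true_cleanability / 100.0)))
    dark_idx = rng.choice(n_px, size=n0, replace=False)
    kept_idx = dark_idx[rng.permutation(n0)[:n1]]

    def _render(idx: np.ndarray) -> np.ndarray:
        img = rng.normal(200.0, 6.0, n_px)
        img[idx] = rng.normal(45.0, 4.0, idx.size)
        return np.clip(np.rint(img.reshape(image_shape)), 0, 255).astype(np.uint8)

    t0_mask = np.zeros(n_px, bool)
    t0_mask[dark_idx] = True
    t1_mask = np.zeros(n_px, bool)
    t1_mask[kept_idx] = True
    t0 = LabeledImage(_render(dark_idx), pixel_scale=None,
                      truth_mask=t0_mask.reshape(image_shape))
    t1 = LabeledImage(_render(kept_idx), pixel_scale=None,
                      truth_mask=t1_mask.reshape(image_shape))
    f0 = 100.0 * n0 / n_px
    f1 = 100.0 * n1 / n_px
    truth = SkinPairTruth(
        t0_dark_fraction=f0,
        t1_dark_fraction=f1,
        true_cleanability=100.0 * (n0 - n1) / n0,
    )
    return t0, t1, truth


def generate_swatch_readings(
    truth: SwatchTruth,
    n_replicates: int = 6,
    seed: int = 0,
) -> list[tuple[ColorReading, ColorReading, ColorReading]]:
    """Emit (control, sebollution, wash) colorimeter triples per replicate.

    The noiseless washed lightness is
    ``L_seb + (true_cleanability/100) * (L_control - L_seb)``; every reading
    is then perturbed by independent N(0, replicate_noise_sd) noise, the
    repeated control readings emulating repeated measurements of the single
    untreated control swatch. a*/b* channels are filled with plausible
    values for white vs. sebollution-tainted hair; only L* carries signal.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    c = truth.true_cleanability / 100.0
    l_wash_true = truth.L_sebollution + c * (truth.L_control - truth.L_sebollution)
    sd = truth.replicate_noise_sd

    triples = []
    for i in range(n_replicates):
        sid = f"SW{i + 1:02d}"
        noise = rng.normal(0.0, sd, 3) if sd > 0 else np.zeros(3)
        ab_noise = rng.normal(0.0, 0.3 * sd, 6) if sd > 0 else np.zeros(6)
        triples.append((
            ColorReading(L=truth.L_control + noise[0],
                         a=0.5 + ab_noise[0], b=12.0 + ab_noise[1],
                         state="control", swatch_id=sid),
            ColorReading(L=truth.L_sebollution + noise[1],
                         a=1.0 + ab_noise[2], b=5.0 + ab_noise[3],
                         state="sebollution", swatch_id=sid),
            ColorReading(L=l_wash_true + noise[2],
                         a=0.8 + ab_noise[4], b=5.0 + 7.0 * c + ab_noise[5],
                         state="wash", swatch_id=sid),
        ))
    return triples


def generate_study_table(
    n_formulae: int = 4,
    site_link: tuple[float, float, float] = (1.0, 0.0, 0.0),
    forearm_range: tuple[float, float] = (5.0, 100.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Paired forearm/scalp cleanability table with a known linear link.

    Forearm cleanabilities are drawn uniformly over ``forearm_range``
    (defaults to the 5-100% span observed across shampoo formulae); scalp
    values follow ``slope * forearm + intercept + N(0, noise_sd)`` with
    ``site_link = (slope, intercept, noise_sd)``.
    """
    if n_formulae < 2:
        raise ValueError("n_formulae must be >= 2")
    slope, intercept, noise_sd = site_link
    rng = np.random.default_rng(seed)
    forearm = rng.uniform(*forearm_range, n_formulae)
    scalp = slope * forearm + intercept
    if noise_sd > 0:
        scalp = scalp + rng.normal(0.0, noise_sd, n_formulae)
    df = pd.DataFrame({
        "formula_id": [f"F{i + 1:02d}" for i in range(n_formulae)],
        "forearm_cleanability": forearm,
        "scalp_cleanability": scalp,
    })
    truth = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd,
             "forearm_range": forearm_range, "seed": seed}
    return df, truth


def _mean_fitted_r2(noise_sd: float, n_formulae: int, slope: float,
                    forearm_range: tuple[float, float], n_sims: int,
                    seed: int) -> float:
    """Monte-Carlo mean of the OLS r^2 over repeated small study tables."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(*forearm_range, (n_sims, n_formulae))
    y = slope * x + rng.normal(0.0, noise_sd, (n_sims, n_formulae))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1) ** 2
    den = (xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1)
    return float(np.mean(num / den))


def calibrate_study_noise(
    target_r2: float = 0.942,
    n_formulae: int = 4,
    slope: float = 1.0,
    forearm_range: tuple[float, float] = (5.0, 100.0),
    n_sims: int = 2000,
    seed: int = 12345,
) -> float:
    """Noise sd for which the mean fitted R^2 equals ``target_r2``.

    Small-sample OLS R^2 is biased upward relative to the population value,
    so the sd is found by bisection on a common-random-numbers Monte-Carlo
    estimate of the mean fitted R^2 rather than from the population formula
    ``sd^2 = var(signal) * (1 - R^2) / R^2``.
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    lo, hi = 1e-6, 80.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r2 = _mean_fitted_r2(mid, n_formulae, slope, forearm_range,
                             n_sims, seed)
        if r2 > target_r2:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def save_sem_dataset(
    out_dir: str | Path,
    fields: list[tuple[LabeledImage, SemGroundTruth]],
    seed: int,
    image_format: str = "png",
) -> Path:
    """Write SEM fields + masks + a ground-truth sidecar CSV to ``out_dir``.

    Images go out as 8-bit grey, masks as 0/255 PNG; the sidecar has columns
    ``id, true_coverage, pixel_scale_um_per_px, seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, truth) in enumerate(fields):
        fid = f"sem_{i:03d}"
        write_image(out_dir / f"{fid}.{image_format}", img.pixels)
        write_mask(out_dir / f"{fid}_particles.png", truth.particle_mask)
        write_mask(out_dir / f"{fid}_fiber.png", truth.fiber_mask)
        rows.append({"id": fid, "true_coverage": truth.true_coverage,
                     "pixel_scale_um_per_px": img.pixel_scale, "seed": seed})
    sidecar = out_dir / "truth.csv"
    pd.DataFrame(rows).to_csv(sidecar, index=False)
    return sidecar
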