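"""End-to-end run: simulate -> quantify -> analyze, with provenance.

Every stage derives an independent random stream from the single run seed,
so the whole bundle of CSV outputs is bit-reproducible for a fixed config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .hair_cleanability import CleanabilityResult, cleanability_from_readings, readings_to_frame
from .particle_coverage import (CoverageConfig, category_summary,
                                product_coverage)
from .skin_cleanability import (ThresholdConfig, batch_skin_cleanability,
                                summarize_skin_batch)
from .study_analysis import reproducibility_report, rank_formulae, site_calibration
from .synthetic_data import (SwatchTruth, calibrate_study_noise,
                             generate_sem_field, generate_skin_pair,
                             generate_study_table, generate_swatch_readings)

__all__ = ["run_end_to_end"]

log = logging.getLogger("sebquant")
_FLOAT_FMT = "%.6f"


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from the run seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def run_end_to_end(config: RunConfig) -> dict[str, Path]:
    """Run all simulated arms and analyses; return the written file paths.

    Raises with a stage-named message if any stage fails; files written
    before the failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    seeds = _stage_seeds(config.seed, 4)
    paths: dict[str, Path] = {}

    # --- skin arm: per-area dark-pixel pairs, per-formula summary ---------
    try:
        sk = config.skin
        rng = np.random.default_rng(seeds[0])
        truths = np.linspace(*sk.truth_range, sk.n_formulae)
        pairs, area_ids, formula_ids = [], [], []
        for i, truth in enumerate(truths):
            fid = f"F{i + 1:02d}"
            for a in range(sk.areas_per_formula):
                t0, t1, _ = generate_skin_pair(
                    sk.baseline_dark_fraction, float(truth), sk.image_shape,
                    seed=int(rng.integers(2**31 - 1)))
                pairs.append((t0, t1))
                area_ids.append(f"{fid}-A{a + 1}")
                formula_ids.append(fid)
        per_area = batch_skin_cleanability(
            pairs, ThresholdConfig.parse(sk.threshold),
            area_ids=area_ids, formula_ids=formula_ids)
        per_formula = summarize_skin_batch(per_area)
        paths["skin_per_area"] = _write(per_area, out / "skin_per_area.csv")
        paths["skin_per_formula"] = _write(per_formula,
                                           out / "skin_per_formula.csv")
    except Exception as exc:
        raise RuntimeError(f"skin stage failed: {exc}") from exc

    # --- swatch arm: L* readings -> per-formula cleanability --------------
    try:
        sw = config.swatch
        rng = np.random.default_rng(seeds[1])
        truths = np.linspace(*sw.truth_range, sw.n_formulae)
        frames = []
        for i, truth in enumerate(truths):
            swt = SwatchTruth(L_control=sw.L_control,
                              L_sebollution=sw.L_sebollution,
                              true_cleanability=float(truth),
                              replicate_noise_sd=sw.noise_sd)
            triples = generate_swatch_readings(
                swt, sw.n_replicates, seed=int(rng.integers(2**31 - 1)))
            frames.append(readings_to_frame(triples, formula_id=f"SH{i + 1:02d}"))
        readings = pd.concat(frames, ignore_index=True)
        hair = cleanability_from_readings(readings)
        paths["swatch_readings"] = _write(readings, out / "swatch_readings.csv")
        paths["hair_results"] = _write(hair, out / "hair_results.csv")
    except Exception as exc:
        raise RuntimeError(f"swatch stage failed: {exc}") from exc

    # --- anti-deposit arm: SEM fields -> coverage per fiber/product/category
    try:
        sem = config.sem
        rng = np.random.default_rng(seeds[2])
        cov_cfg = CoverageConfig(
            pixel_scale=sem.pixel_scale, threshold_method="otsu",
            min_diameter_um=sem.min_diameter_um)
        fiber_rows, product_rows, results = [], [], []
        for cat, center in sem.category_coverage.items():
            k = sem.products_per_category
            offsets = np.linspace(-1.5, 1.5, k) if k > 1 else np.array([0.0])
            for j, off in enumerate(offsets):
                pid = f"{cat}-{j + 1:02d}"
                target = max(0.0, center + float(off))
                imgs = [generate_sem_field(
                            target_coverage=target,
                            image_shape=sem.image_shape,
                            pixel_scale=sem.pixel_scale,
                            noise_level=sem.noise_level,
                            seed=int(rng.integers(2**31 - 1)))[0]
                        for _ in range(sem.fibers_per_product)]
                res = product_coverage(imgs, cov_cfg, product_id=pid,
                                       category=cat,
                                       n_fibers_expected=sem.fibers_per_product)
                results.append(res)
                product_rows.append({
                    "product_id": pid, "category": cat,
                    "true_coverage_target": target,
                    "mean_coverage": res.product_mean, "sd": res.product_sd,
                    "n_fibers": res.n_fibers})
                fiber_rows += [{"product_id": pid, "category": cat,
                                "fiber": i, "coverage": c}
                               for i, c in enumerate(res.per_fiber_coverage)]
        per_product = pd.DataFrame(product_rows)
        paths["coverage_per_fiber"] = _write(pd.DataFrame(fiber_rows),
                                             out / "coverage_per_fiber.csv")
        paths["coverage_per_product"] = _write(per_product,
                                               out / "coverage_per_product.csv")
        paths["coverage_per_category"] = _write(category_summary(results),
                                                out / "coverage_per_category.csv")
    except Exception as exc:
        raise RuntimeError(f"coverage stage failed: {exc}") from exc

    # --- study analysis: site calibration, ranking, reproducibility -------
    try:
        st = config.study
        noise_sd = st.noise_sd
        if noise_sd is None:
            noise_sd = calibrate_study_noise(st.target_r2, st.n_formulae,
                                             st.slope)
        table, _ = generate_study_table(
            st.n_formulae, (st.slope, st.intercept, noise_sd), seed=seeds[3])
        fit = site_calibration(table)
        paths["study_table"] = _write(table, out / "study_table.csv")
        paths["calibration"] = _write(
            pd.DataFrame([{**fit, "noise_sd": noise_sd}]),
            out / "calibration.csv")

        ranked = rank_formulae([
            CleanabilityResult(cleanability=r.mean_cleanability, site="forearm",
                               formula_id=r.formula_id, n_replicates=int(r.n),
                               sd=r.sd)
            for r in per_formula.itertuples()])
        paths["ranking"] = _write(ranked, out / "ranking.csv")
        paths["reproducibility"] = _write(
            reproducibility_report(per_area), out / "reproducibility.csv")
    except Exception as exc:
        raise RuntimeError(f"analysis stage failed: {exc}") from exc

    if config.make_plots:
        try:
            from . import plots
            paths["fig_calibration"] = plots.plot_site_calibration(
                table, fit, out / "fig_calibration.png")
            paths["fig_ranking"] = plots.plot_ranking(
                ranked, out / "fig_ranking.png")
            paths["fig_categories"] = plots.plot_category_coverage(
                per_product, out / "fig_categories.png")
        except Exception as exc:
            raise RuntimeError(f"plotting stage failed: {exc}") from exc

    provenance = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "versions": {"sebquant": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True,
                                    default=str))
    paths["provenance"] = prov_path
    log.info("end-to-end run complete: %d files in %s", len(paths), out)
    return paths
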