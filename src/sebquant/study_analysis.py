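"""Cross-site calibration and product-ranking summaries.

Soiled forearms are far easier to instrument than scalps, so the study
design validates the forearm as a proxy site: cleanabilities of the same
formulae measured on both sites are regressed (scalp ~ forearm, ordinary
least squares) and the fit's R^2 quantifies how predictive the forearm
model is. The remaining helpers produce the ranked-formula and
reproducibility tables used to compare products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hair_cleanability import CleanabilityResult

__all__ = [
    "SitePair",
    "site_calibration",
    "rank_formulae",
    "reproducibility_report",
]


@dataclass(frozen=True)
class SitePair:
    """Cleanability of one formula measured on both skin sites (percent)."""

    formula_id: str
    forearm_cleanability: float
    scalp_cleanability: float

    def __post_init__(self):
        if not (math.isfinite(self.forearm_cleanability)
                and math.isfinite(self.scalp_cleanability)):
            raise ValueError("site cleanabilities must be finite")


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        x = pairs["forearm_cleanability"].to_numpy(float)
        y = pairs["scalp_cleanability"].to_numpy(float)
    else:
        x = np.array([p.forearm_cleanability for p in pairs], float)
        y = np.array([p.scalp_cleanability for p in pairs], float)
    return x, y


def site_calibration(pairs: Sequence[SitePair] | pd.DataFrame) -> dict:
    """OLS fit of scalp ~ forearm cleanability.

    Accepts a list of :class:`SitePair` or a DataFrame with
    ``forearm_cleanability`` / ``scalp_cleanability`` columns (formula-level
    means or subject-level points alike). Returns
    ``{"slope", "intercept", "r_squared", "n"}`` where ``r_squared`` is the
    squared Pearson correlation.
    """
    x, y = _pairs_to_arrays(pairs)
    n = x.size
    if n < 3:
        raise ValueError(f"site_calibration needs >= 3 pairs, got {n}")
    if np.var(x) == 0:
        raise ValueError("zero variance in forearm cleanabilities: fit undefined")
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue ** 2), "n": int(n)}


def rank_formulae(results: Sequence[CleanabilityResult]) -> pd.DataFrame:
    """Formulae sorted by increasing mean cleanability.

    Ties are broken by sd ascending, then formula_id lexicographically, so
    the order is total and independent of the input permutation. The
    observed range is stored in ``df.attrs["range"]``.
    """
    if len(results) < 2:
        raise ValueError("rank_formulae needs at least two results")
    df = pd.DataFrame({
        "formula_id": [r.formula_id or "" for r in results],
        "mean_cleanability": [r.cleanability for r in results],
        "sd": [r.sd for r in results],
        "n": [r.n_replicates for r in results],
    })
    # NaN sd (singletons) sorts last among ties.
    df = df.sort_values(
        ["mean_cleanability", "sd", "formula_id"],
        na_position="last", ignore_index=True,
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["range"] = (float(df["mean_cleanability"].min()),
                         float(df["mean_cleanability"].max()))
    return df


def reproducibility_report(values: pd.DataFrame,
                           group_col: str = "formula_id",
                           value_col: str = "cleanability") -> pd.DataFrame:
    """Per-group mean, sample sd and coefficient of variation (percent).

    Singleton groups are flagged and their sd/CV left as NaN. CV is
    ``100 * sd / |mean|`` and NaN for zero-mean groups.
    """
    if values.empty:
        raise ValueError("reproducibility_report needs a non-empty table")
    rows = []
    for gid, grp in values.groupby(group_col, sort=True):
        v = grp[value_col].to_numpy(float)
        mean = float(v.mean())
        if v.size > 1:
            sd = float(v.std(ddof=1))
            cv = 100.0 * sd / abs(mean) if mean != 0 else math.nan
            flag = ""
        else:
            sd, cv, flag = math.nan, math.nan, "singleton"
        rows.append({group_col: gid, "mean": mean, "sd": sd, "cv": cv,
                     "n": int(v.size), "flags": flag})
    return pd.DataFrame(rows)
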