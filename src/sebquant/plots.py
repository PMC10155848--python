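"""Figure helpers mirroring the study's summary graphics.

All functions write a file and return its path; they use the Agg backend so
they run headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_site_calibration(pairs: pd.DataFrame, fit: dict,
                          path: str | Path) -> Path:
    """Scatter of scalp vs forearm cleanability with the OLS line."""
    x = pairs["forearm_cleanability"].to_numpy(float)
    y = pairs["scalp_cleanability"].to_numpy(float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="k")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, fit["slope"] * xs + fit["intercept"], "r-",
            label=f"R$^2$ = {fit['r_squared']:.3f}")
    ax.set_xlabel("forearm cleanability (%)")
    ax.set_ylabel("scalp cleanability (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_ranking(ranking: pd.DataFrame, path: str | Path,
                 clamp_display: bool = True) -> Path:
    """Ordered bar chart (mean +/- sd) of formula cleanabilities.

    Out-of-range means are clamped to [0, 100] for display only.
    """
    means = ranking["mean_cleanability"].to_numpy(float)
    if clamp_display:
        means = np.clip(means, 0, 100)
    sds = np.nan_to_num(ranking["sd"].to_numpy(float))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(ranking["formula_id"], means, yerr=sds, capsize=3, color="0.6")
    ax.set_ylabel("cleanability (%)")
    ax.set_xlabel("formula (increasing cleanability)")
    plt.setp(ax.get_xticklabels(), rotation=60, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_category_coverage(per_product: pd.DataFrame, path: str | Path) -> Path:
    """Per-category box plot of product coverages with red median lines."""
    cats = list(per_product["category"].unique())
    data = [per_product.loc[per_product["category"] == c, "mean_coverage"]
            .to_numpy(float) for c in cats]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=cats, medianprops={"color": "red"})
    ax.set_ylabel("CB coverage (% of fiber surface)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
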