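"""Optional diagnostic figures (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .unity import BinnedSimilarity, GaussianFit


def plot_similarity_curve(
    bins: BinnedSimilarity, fit: Optional[GaussianFit], path: Path
) -> None:
    """Per-bin similar proportions (with SEM when available) and the fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = bins.table
    fig, ax = plt.subplots(figsize=(6, 4))
    yerr = table["sem"] if "sem" in table.columns else None
    ax.errorbar(table["bin_center"], table["p_similar"], yerr=yerr,
                fmt="o", color="k", capsize=2, label="observed")
    if fit is not None:
        xs = np.linspace(table["bin_center"].min(), table["bin_center"].max(), 200)
        ax.plot(xs, fit.predict(xs), "-", color="tab:blue",
                label=f"a={fit.amplitude:.2f}, b={fit.center:.2f}, c={fit.width:.2f}")
    ax.set_xlabel("audiovisual intensity difference (face - voice, Likert points)")
    ax.set_ylabel("P(judged similar)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_reliance(reliance: pd.DataFrame, path: Path) -> None:
    """Mean sensory reliance per similarity-by-emotion cell with SEM bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = reliance[
        reliance["similarity"].isin(["similar", "not_similar"])
        & reliance["emotion"].isin(["angry", "happy"])
    ]
    agg = cells.groupby(["emotion", "similarity"])["reliance"].agg(["mean", "sem"]).reset_index()
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.35
    for i, similarity in enumerate(("similar", "not_similar")):
        sub = agg[agg["similarity"] == similarity].set_index("emotion")
        xs = np.arange(len(sub.index)) + (i - 0.5) * width
        ax.bar(xs, sub["mean"], width=width, yerr=sub["sem"], capsize=3, label=similarity)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(np.arange(agg["emotion"].nunique()))
    ax.set_xticklabels(sorted(agg["emotion"].unique()))
    ax.set_ylabel("sensory reliance (beta_v - beta_a)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
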