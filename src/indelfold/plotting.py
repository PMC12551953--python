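"""Minimal rendering of SD-vs-distance/size curve panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .constants import KT_KCAL_MOL


def plot_sd_curves(df: pd.DataFrame, path, hue: str | None = None) -> None:
    """One panel of SD vs group key with CI shading, one line per cohort.

    ``df`` is a curve table as written by the pipeline (columns key, sd,
    ci_low, ci_high plus optional grouping columns such as size, category,
    site_type)."""
    if hue is None:
        for candidate in ("site_type", "category", "size", "site_side"):
            if candidate in df.columns and df[candidate].nunique() > 1:
                hue = candidate
                break
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = df.groupby(hue) if hue else [("all", df)]
    for label, sub in groups:
        sub = sub.sort_values("key")
        ax.plot(sub["key"], sub["sd"], label=str(label))
        if sub["ci_low"].notna().all():
            ax.fill_between(sub["key"], sub["ci_low"], sub["ci_high"], alpha=0.25)
    ax.axhline(KT_KCAL_MOL, linestyle=":", color="grey", label="$k_BT$")
    ax.set_xlabel("distance / size (nt)")
    ax.set_ylabel(r"SD of $\Delta\Delta G$ (kcal/mol)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
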