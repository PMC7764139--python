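"""Caterpillar-plot rendering (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def render_caterpillar(
    data: pd.DataFrame | dict[str, pd.DataFrame],
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Render one caterpillar panel per indicator to ``path`` (SVG/PNG).

    Each facility is a horizontal whisker (95% CI) around its centred
    empirical-Bayes estimate, sorted ascending; the vertical line marks the
    grand mean (zero on the centred logit scale).  Facilities whose whisker
    clears the line are drawn in colour.
    """
    panels = data if isinstance(data, dict) else {"indicator": data}
    n = len(panels)
    ncols = min(3, max(1, n))
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows), squeeze=False
    )
    colors = {"at_mean": "0.6", "below_mean": "tab:blue", "above_mean": "tab:red"}
    for ax, (name, cat) in zip(axes.ravel(), panels.items()):
        if cat is None or cat.empty:
            ax.annotate(
                "no estimable facilities",
                xy=(0.5, 0.5), xycoords="axes fraction", ha="center",
            )
            ax.set_title(name)
            continue
        for _, row in cat.iterrows():
            c = colors.get(row["significance"], "0.6")
            ax.plot(
                [row["ci_lower"], row["ci_upper"]],
                [row["rank"], row["rank"]],
                color=c, lw=0.6, zorder=1,
            )
        ax.scatter(cat["estimate"], cat["rank"], s=4, color="k", zorder=2)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_title(name)
        ax.set_xlabel("centred EB estimate (logit)")
        ax.set_ylabel("facility rank")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path)
    plt.close(fig)
    return path
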