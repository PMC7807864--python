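"""Scan plot: -log10(p) by lab, triangles oriented by effect direction."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .scan import ScanResult  # noqa: E402


def render_scan_plot(result: ScanResult, output_path: str | Path):
    """Write the scan figure and return the matplotlib Figure.

    Tested labs are drawn as upward triangles (positive beta) or downward
    triangles (negative beta), grouped and colored by category.  The red
    horizontal line marks the Bonferroni threshold, the blue line p = 0.05;
    labs passing the threshold are labeled.
    """
    tested = [r for r in result.records if r.tested]
    if not tested:
        raise ValueError("no tested labs to plot")

    fig, ax = plt.subplots(figsize=(max(6.0, 0.25 * len(tested)), 4.5))
    categories = sorted({r.category for r in tested})
    cmap = plt.get_cmap("tab10")
    xpos = {r.lab_id: i for i, r in enumerate(tested)}
    floor = np.nextafter(0, 1)  # guard log10(0)
    for ci, cat in enumerate(categories):
        for direction, marker in (("up", "^"), ("down", "v")):
            rs = [r for r in tested if r.category == cat and r.direction == direction]
            if not rs:
                continue
            ax.scatter(
                [xpos[r.lab_id] for r in rs],
                [-np.log10(max(r.p_value, floor)) for r in rs],
                marker=marker,
                color=cmap(ci % 10),
                label=f"{cat} {direction}".strip(),
                s=30,
            )
    ax.axhline(-np.log10(result.threshold), color="red", linewidth=1)
    ax.axhline(-np.log10(0.05), color="blue", linewidth=1)
    for r in tested:
        if r.significant:
            ax.annotate(
                r.lab_id,
                (xpos[r.lab_id], -np.log10(max(r.p_value, floor))),
                fontsize=7,
                rotation=45,
                textcoords="offset points",
                xytext=(2, 2),
            )
    ax.set_xticks([])
    ax.set_xlabel("lab")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(output_path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return fig
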