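"""Face-grid rendering: the star-coded report as a schematic face.

One panel per emotion; each AU occupies a marker at its template
centroid location, coloured by the strongest significance level among
its cells (optionally filtered to one feature/section).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .au import au_definitions
from .simulate import neutral_face_template

__all__ = ["render_face_grid"]

_STAR_ORDER = {"ns": 0, "*": 1, "**": 2, "***": 3}
_STAR_COLOR = {0: "#d0d0d0", 1: "#ffd166", 2: "#f3722c", 3: "#d62828"}


def render_face_grid(
    cell_table: pd.DataFrame,
    path: str | None = None,
    feature: str | None = None,
    section: str | None = None,
):
    """Render the comparison grid; returns the matplotlib figure.

    ``feature`` / ``section`` filter the cells before taking, per AU,
    the maximum star level.  With ``path`` given the figure is saved.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = cell_table
    if feature is not None:
        df = df[df.feature == feature]
    if section is not None:
        df = df[df.section == section]
    emotions = sorted(df.emotion.dropna().unique())
    if not emotions:
        raise ValueError("no cells to render")

    template = neutral_face_template()
    centroids = {
        d.name: template[list(d.landmarks)].mean(axis=0) for d in au_definitions()
    }
    fig, axes = plt.subplots(1, len(emotions), figsize=(3.2 * len(emotions), 3.4))
    axes = np.atleast_1d(axes)
    for ax, emotion in zip(axes, emotions):
        emo = df[df.emotion == emotion]
        ax.plot(*template.T, ".", ms=2, color="#b8c4d0", zorder=1)
        for au, pos in centroids.items():
            stars = emo.loc[emo.au == au, "stars"]
            level = max((_STAR_ORDER.get(s, 0) for s in stars), default=0)
            ax.scatter(*pos, s=160, color=_STAR_COLOR[level], zorder=2,
                       edgecolor="black", linewidth=0.5)
        ax.set_title(emotion)
        ax.invert_yaxis()  # image coordinates: y grows downward
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
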