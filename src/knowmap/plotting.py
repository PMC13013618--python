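"""Optional basic rendering of knowledge / learning maps to image files.

Maps are primarily emitted as CSV grids; these helpers give a quick visual
check without any styling ambitions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["render_map_grid"]


def render_map_grid(
    grid: np.ndarray,
    values: np.ndarray,
    path: str | Path,
    shape: tuple[int, int] = (100, 100),
    diverging: bool = False,
    title: str | None = None,
) -> None:
    """Render a (n_grid, 2) coordinate grid with per-point values to an image.

    ``diverging=True`` centers the color scale at zero (learning maps).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.asarray(values, dtype=np.float64).reshape(shape)
    xs = np.asarray(grid)[:, 0].reshape(shape)
    ys = np.asarray(grid)[:, 1].reshape(shape)
    fig, ax = plt.subplots(figsize=(5, 4))
    if diverging:
        vmax = max(abs(vals.min()), abs(vals.max()), 1e-9)
        mesh = ax.pcolormesh(xs, ys, vals, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    else:
        mesh = ax.pcolormesh(xs, ys, vals, cmap="viridis", vmin=0.0, vmax=1.0)
    fig.colorbar(mesh, ax=ax)
    if title:
        ax.set_title(title)
    ax.set_xlabel("map x")
    ax.set_ylabel("map y")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
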