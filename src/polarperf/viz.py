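"""Bull's eye rendering with significance overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless, deterministic backend
import matplotlib.pyplot as plt
import numpy as np

from .database import NormalDatabase
from .stats import ComparisonResult

__all__ = ["render_bullseye"]

_LOWER_COLOR = (0.0, 0.65, 0.0, 1.0)  # green: significantly lower
_HIGHER_COLOR = (1.0, 0.9, 0.0, 1.0)  # yellow: significantly higher


def render_bullseye(
    obj,
    path,
    mean_map: np.ndarray | None = None,
    title: str | None = None,
    vmin: float = 0.0,
    vmax: float = 110.0,
) -> None:
    """Render a database or comparison result as a bull's eye PNG.

    For a :class:`NormalDatabase` the mean map is drawn as a colour disc.
    For a :class:`ComparisonResult` the significance masks are overlaid in
    green (A significantly lower) and yellow (A significantly higher) on top
    of ``mean_map`` if given, else on the t-map.  Outside-mask pixels are
    transparent.  Output is deterministic for identical inputs.
    """
    if isinstance(obj, NormalDatabase):
        base = obj.mean_map
        geometry = obj.geometry
        overlay_lower = overlay_higher = None
    elif isinstance(obj, ComparisonResult):
        base = mean_map if mean_map is not None else obj.t_map
        geometry = obj.geometry
        overlay_lower, overlay_higher = obj.sig_lower, obj.sig_higher
        if mean_map is None:
            lim = float(np.nanmax(np.abs(base))) or 1.0
            vmin, vmax = -lim, lim
    else:
        raise TypeError(f"cannot render object of type {type(obj).__name__}")

    masked = np.ma.masked_invalid(base)
    fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad(alpha=0.0)
    ax.imshow(masked, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
    if overlay_lower is not None:
        overlay = np.zeros((*base.shape, 4))
        overlay[overlay_lower] = _LOWER_COLOR
        overlay[overlay_higher] = _HIGHER_COLOR
        ax.imshow(overlay, interpolation="nearest")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.savefig(Path(path), bbox_inches="tight", metadata={"Software": None})
    plt.close(fig)
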