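"""Static per-probe diagnostic plots.

One image per probe: the beta-value histogram, the fitted density
curve, markers at each final peak apex, and dashed lines at the
interior bounding minima.  Rendering uses an Agg canvas directly so no
interactive backend is required.
"""

from __future__ import annotations

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .detection import DensityCurve
from .summary import ProbeResult

__all__ = ["render_probe_plot"]


def render_probe_plot(betas, result: ProbeResult, curve: DensityCurve, path) -> None:
    """Write one diagnostic image for a classified probe."""
    x = np.asarray(betas, dtype=float)
    x = x[~np.isnan(x)]
    fig = Figure(figsize=(6.0, 4.0))
    FigureCanvasAgg(fig)
    ax = fig.subplots()
    ax.hist(x, bins=40, density=True, color="#c6dbef", edgecolor="white")
    ax.plot(curve.grid, curve.density, color="#08519c", lw=1.5, label="KDE")
    apexes = np.asarray(result.peak_locations)
    if apexes.size:
        apex_density = np.interp(apexes, curve.grid, curve.density)
        ax.plot(apexes, apex_density, "v", color="#de2d26", ms=8, label="peak apex")
    if result.modality is not None:
        for p in result.modality.peaks:
            for b in (p.left_bound, p.right_bound):
                if np.isfinite(b):
                    ax.axvline(b, color="grey", ls="--", lw=0.8)
    label = result.modality.label if result.modality is not None else result.status
    ax.set_title(
        f"{result.probe_id} — {label}, "
        f"proportionSample_2={result.proportion_sample_2:.3f}"
    )
    ax.set_xlabel("beta value")
    ax.set_ylabel("density")
    ax.set_xlim(-0.05, 1.05)
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
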