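"""Diagnostic plot of GC bias and the main copy-number state."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .coverage_metrics import CoverageProfile  # noqa: E402
from .gc_evenness import GcBiasModel  # noqa: E402

__all__ = ["plot_gc_bias"]


def plot_gc_bias(profile: CoverageProfile, model: GcBiasModel, path,
                 title: str = "") -> None:
    """GC vs normalized coverage, main-state windows and both lowess fits.

    The red cloud is the main copy-number state the correction is fitted
    on; grey points are windows from other states or noise.
    """
    gc = profile.grid.gc_fraction[profile.retained]
    norm = profile.normalized[profile.retained]
    mask = model.main_state_mask
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(gc[~mask], norm[~mask], s=4, c="0.7", label="other states")
    ax.scatter(gc[mask], norm[mask], s=4, c="crimson", label="main state")
    xs = np.linspace(gc.min(), gc.max(), 200)
    ax.plot(xs, model.trend(xs), "k--", lw=1, label="fit 1 (all windows)")
    ax.plot(xs, model.correction(xs), "b-", lw=1.2, label="fit 2 (correction)")
    ax.set_xlabel("window GC fraction")
    ax.set_ylabel("normalized coverage")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
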