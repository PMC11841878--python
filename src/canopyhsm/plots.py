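"""Diagnostic plots: P/E curve with breakpoints, and marginal responses."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_pe_curve(curve, fit=None, classes=None, path: str | Path | None = None):
    """Raw and smoothed P/E ratios, the fitted piecewise line, and class
    boundaries.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    d = curve.defined
    ax.plot(curve.centers[d], curve.raw[d], ".", ms=3, color="0.6",
            label="raw P/E")
    if curve.smoothed is not None:
        ax.plot(curve.centers[d], curve.smoothed[d], color="tab:blue",
                label="smoothed")
    if fit is not None:
        x = curve.centers[d & (curve.centers > fit.forced_break)]
        ax.plot(x, fit.predict(x), color="tab:red", label="piecewise fit")
    if classes is not None:
        for b in classes.boundaries[:-1]:
            ax.axvline(b, color="0.3", ls="--", lw=0.8)
    ax.axhline(1.0, color="0.3", lw=0.8)
    ax.set_xlabel("HSI")
    ax.set_ylabel("P/E ratio")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_marginal_responses(curves, path: str | Path | None = None):
    """One panel per covariate: HSI response with optional replicate band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(curves), 1, figsize=(6, 2.6 * len(curves)),
                             squeeze=False)
    for ax, curve in zip(axes[:, 0], curves):
        ax.plot(curve.values, curve.hsi, color="tab:red")
        if curve.hsi_sd is not None:
            ax.fill_between(curve.values, curve.hsi - curve.hsi_sd,
                            np.clip(curve.hsi + curve.hsi_sd, None, 1.0),
                            alpha=0.25, color="tab:blue")
        ax.set_ylabel("HSI")
        ax.set_ylim(0, 1)
        ax.set_xlabel(curve.covariate)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
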