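"""Optional figures (requires matplotlib, installed via the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .rates import RateCurve
from .simulate import SpikeTrain


def plot_mise_vs_alpha(table, out_path, title: str | None = None) -> None:
    """MISE-versus-alpha curves, one line per scenario, with 95% CI bars.

    ``table`` is the long-format frame from :func:`baks.tune_alpha`
    (columns scenario, alpha, mise, ci95).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, grp in table.groupby("scenario"):
        ax.errorbar(grp["alpha"], grp["mise"], yerr=grp["ci95"], marker="*",
                    capsize=2, label=label)
    ax.set_xlabel(r"prior shape $\alpha$")
    ax.set_ylabel(r"MISE ((spikes/s)$^2\cdot$s)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_estimate(truth: RateCurve, estimate: RateCurve, spikes: SpikeTrain,
                  out_path, title: str | None = None) -> None:
    """Overlay of the true rate, the estimate, and the spike raster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(truth.times, truth.values, "k-", label="true rate")
    ax.plot(estimate.times, estimate.values, "b-", label="BAKS estimate")
    ymin = -0.06 * max(float(np.max(truth.values)), float(np.max(estimate.values)))
    ax.plot(spikes.times, np.full(spikes.n, ymin), "|", color="black",
            markersize=6, label="spikes")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("rate (spikes/s)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
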