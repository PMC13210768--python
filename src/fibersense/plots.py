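"""Plot helpers (Bland–Altman scatter, funnel)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .stats import AgreementResult, FunnelPoint, PairedSeries, relative_differences


def bland_altman_plot(pairs: PairedSeries, result: AgreementResult, path) -> None:
    """Relative difference vs pair mean with mean line and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diffs, _ = relative_differences(pairs)
    means = (pairs.method_x + pairs.method_y) / 2.0
    means = means[means > 0]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, color="k", alpha=0.7)
    ax.axhline(result.mean_rel_diff, color="red")
    if result.loa_low is not None:
        ax.axhline(result.loa_low, color="red", linestyle="--")
        ax.axhline(result.loa_high, color="red", linestyle="--")
    ax.set_xlabel("Mean concentration of the two methods (f/L)")
    ax.set_ylabel("Relative difference (%)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def funnel_plot(points: list[FunnelPoint], path) -> None:
    """Limits-of-agreement width against mean detected fiber count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = [p.mean_detected_count for p in points]
    widths = [p.agreement.loa_width for p in points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(counts, widths, "o-", color="k")
    ax.set_xscale("log")
    ax.set_xlabel("Mean detected fibers per measurement")
    ax.set_ylabel("Width of 95% limits of agreement (%)")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
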