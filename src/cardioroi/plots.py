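"""Optional static plots (tornado diagram, cost-effectiveness plane).

Requires matplotlib; import is deferred so the core model has no plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

from .uncertainty import PSAResult, TornadoResult


def plot_tornado(result: TornadoResult, path: str | Path) -> None:
    """Horizontal-bar tornado diagram of ROI swings, widest on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(reversed(result.entries))
    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(entries), 2) + 1.5))
    for y, e in enumerate(entries):
        lo, hi = sorted((e.roi_at_low, e.roi_at_high))
        ax.barh(y, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.axvline(result.base_roi, color="black", lw=1, label="base-case ROI")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.name for e in entries])
    ax.set_xlabel("ROI")
    ax.set_title("One-way sensitivity of ROI")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(result: PSAResult, path: str | Path) -> None:
    """Scatter of PSA iterations: incremental QALYs vs ROI."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.qaly_gain, result.roi, s=4, alpha=0.3, color="#4878a8")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("incremental QALYs per member")
    ax.set_ylabel("ROI")
    ax.set_title(f"PSA ({result.n_iter} iterations)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
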