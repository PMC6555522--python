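"""Optional figure regeneration from result CSVs.

Plots are derived artifacts only — every assertion and metric in the
package reads the CSV/JSON outputs, never an image.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_PANELS = (
    ("theta_deg", "pole angle (deg)"),
    ("Fh_N", "hand force (N)"),
    ("Fsx_N", "shoulder force, fore-aft (N)"),
    ("Fsy_N", "shoulder force, vertical (N)"),
)


def plot_results(csv_paths, out_path, title: str | None = None) -> Path:
    """Four-panel comparison plot (angle, hand force, shoulder forces)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(8, 10), sharex=True)
    for path in csv_paths:
        path = Path(path)
        frame = pd.read_csv(path, comment="#")
        for ax, (col, label) in zip(axes, _PANELS):
            ax.plot(frame["t"], frame[col], label=path.stem, linewidth=0.9)
            ax.set_ylabel(label)
    axes[-1].set_xlabel("time (s)")
    axes[0].legend(loc="upper right", fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
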