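"""Cosmetic visualization of motor fields and symmetry dipoles."""

from __future__ import annotations

import numpy as np

from .indices import IndexReport


def plot_index_report(report: IndexReport, ax=None):
    """Draw a participant's motor-field polygons and bias dipoles.

    Returns the matplotlib Axes. Import is deferred so headless use of
    the library never touches a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for tips, color, label in (
        (report.mf_od.polygon, "tab:red", "MF OD"),
        (report.mf_os.polygon, "tab:blue", "MF OS"),
    ):
        ring = np.vstack([tips, tips[:1]])
        ax.fill(ring[:, 0], ring[:, 1], alpha=0.2, color=color, label=label)
        ax.plot(ring[:, 0], ring[:, 1], color=color, lw=1)
    scale = max(np.abs(report.mf_od.polygon).max(), 1.0)
    for dip, color in (
        (report.mb_od, "tab:red"),
        (report.mb_os, "tab:blue"),
        (report.mdiff, "tab:purple"),
        (report.gdiff, "black"),
    ):
        if dip.magnitude > 0:
            v = dip.pro / dip.magnitude * dip.magnitude * scale
            ax.annotate(
                "", xy=v, xytext=(0, 0),
                arrowprops={"arrowstyle": "->", "color": color},
            )
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("horizontal rotation (deg)")
    ax.set_ylabel("vertical rotation (deg)")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title(f"participant {report.participant_id}")
    return ax
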