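"""Minimal diagnostic plots (not part of the tested analysis contract)."""

from __future__ import annotations

import numpy as np

from .compare import ApproachResult
from .dynamics import DynamicMembership


def size_histogram(results: list[ApproachResult], ax=None):
    """Histogram of detected unit sizes, one series per approach."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for res in results:
        ax.hist(
            res.size_distribution,
            bins=range(0, max(res.size_distribution, default=1) + 2),
            histtype="step",
            label=res.config.label,
        )
    ax.set_xlabel("unit size (individuals)")
    ax.set_ylabel("count")
    ax.legend(fontsize="small")
    return ax


def membership_bands(dyn: DynamicMembership, ax=None):
    """Stacked bands of global-unit sizes across windows."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    units = sorted(dyn.global_units)
    x = np.arange(len(dyn.window_ids))
    bottoms = np.zeros(len(x))
    for gid in units:
        heights = np.array(
            [len(dyn.members(wid, gid)) for wid in dyn.window_ids], dtype=float
        )
        ax.bar(x, heights, bottom=bottoms, width=0.8, label=gid)
        bottoms += heights
    ax.set_xticks(x, dyn.window_ids, rotation=45, ha="right")
    ax.set_ylabel("individuals")
    return ax
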