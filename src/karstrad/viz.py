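"""Quick-look plots for the through-time analyses (matplotlib)."""

from __future__ import annotations

import numpy as np

from .disparity import DTTResult
from .mk import CTTResult
from .tree import TimeTree

__all__ = ["plot_ltt", "plot_dtt", "plot_ctt"]


def plot_ltt(tree: TimeTree, ax=None, log_scale: bool = True, **kw):
    """Lineage-through-time step curve (age on x, lineage count on y)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bt = tree.branching_times()
    ages = np.concatenate([bt, [0.0]])
    counts = np.arange(2, len(bt) + 2)
    ax.step(-ages, counts, where="post", **kw)
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("age (My)")
    ax.set_ylabel("lineages")
    return ax


def plot_dtt(result: DTTResult, ax=None):
    """Observed DTT curve with the null mean and 95% pointwise band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.times, result.observed, lw=2, label="observed")
    if result.null_curves is not None:
        m = result.null_curves.mean(axis=0)
        lo = np.percentile(result.null_curves, 2.5, axis=0)
        hi = np.percentile(result.null_curves, 97.5, axis=0)
        ax.plot(result.times, m, ls="--", label="BM null mean")
        ax.fill_between(result.times, lo, hi, alpha=0.2, label="95% band")
    ax.set_xlabel("relative time (root to present)")
    ax.set_ylabel("mean relative subclade disparity")
    ax.legend()
    return ax


def plot_ctt(result: CTTResult, ax=None):
    """Observed CTT curve with the null band where available."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mids = (result.bin_edges[:-1] + result.bin_edges[1:]) / 2
    ax.step(-mids, result.observed, where="mid", lw=2, label="observed")
    if result.null_curves is not None:
        lo = np.percentile(result.null_curves, 2.5, axis=0)
        hi = np.percentile(result.null_curves, 97.5, axis=0)
        ax.fill_between(-mids, lo, hi, step="mid", alpha=0.2, label="null 95% band")
    ax.set_xlabel("age (My)")
    ax.set_ylabel("changes per My of branch length")
    ax.legend()
    return ax
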