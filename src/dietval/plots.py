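"""Small matplotlib helpers mirroring the usual validation figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .agreement_stats import BlandAltmanResult, PairedEstimates, bland_altman

__all__ = ["bland_altman_plot", "scatter_plot"]


def bland_altman_plot(pairs: PairedEstimates, ax=None,
                      result: BlandAltmanResult | None = None):
    """Differences against pair means, with bias and limits of agreement."""
    result = result or bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    means = (pairs.value_a + pairs.value_b) / 2.0
    ax.scatter(means, pairs.differences, s=18, alpha=0.8)
    ax.axhline(result.bias, ls=":", color="tab:blue", label=f"bias {result.bias:.1f}")
    for v in result.loa:
        ax.axhline(v, ls=":", color="tab:brown")
    ax.set_xlabel(f"mean of {pairs.label_a} and {pairs.label_b} (kcal/day)")
    ax.set_ylabel(f"{pairs.label_a} − {pairs.label_b} (kcal/day)")
    ax.legend(frameon=False)
    return ax


def scatter_plot(pairs: PairedEstimates, ax=None):
    """Method-vs-method scatter with the identity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pairs.value_b, pairs.value_a, s=18, alpha=0.8)
    lo = min(pairs.value_a.min(), pairs.value_b.min())
    hi = max(pairs.value_a.max(), pairs.value_b.max())
    ax.plot([lo, hi], [lo, hi], color="grey", lw=0.8)
    ax.set_xlabel(f"{pairs.label_b} (kcal/day)")
    ax.set_ylabel(f"{pairs.label_a} (kcal/day)")
    return ax
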