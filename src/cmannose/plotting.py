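"""Volcano and EIC plots for screen results."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .glyco import Chromatogram
from .secretome import DifferentialResult


def volcano(
    result: DifferentialResult,
    highlight: Optional[Iterable[str]] = None,
    ax=None,
    title: str = "",
):
    """Volcano plot: log2 fold change vs −log10 p, threshold line at alpha."""
    import numpy as np
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = result.table
    ax.scatter(t["log2_fc"], -np.log10(t["p"]), s=8, c="0.6", lw=0)
    if highlight:
        sel = t.index.isin(set(highlight))
        ax.scatter(
            t.loc[sel, "log2_fc"], -np.log10(t.loc[sel, "p"]), s=14, c="crimson", lw=0
        )
    ax.axhline(-np.log10(result.alpha), color="k", ls="--", lw=0.8)
    ax.set_xlabel("log2 fold change (KO − WT)")
    ax.set_ylabel("−log10 p")
    if title:
        ax.set_title(title)
    return ax


def plot_eics(chromatograms: Sequence[Chromatogram], labels: Sequence[str], ax=None):
    """Overlay EIC traces, each max-normalised, as in glycoform ladder panels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for eic, label in zip(chromatograms, labels):
        peak = eic.apex_intensity or 1.0
        ax.plot(eic.rt, eic.intensity / peak, label=label, lw=1)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("relative intensity")
    ax.legend(fontsize=7)
    return ax
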