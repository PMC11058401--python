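"""Figures for fitted study results: interaction profile and change scatter."""

from __future__ import annotations

import numpy as np

from .study import StudyResults, _change_table

__all__ = ["plot_interaction", "plot_change_scatter"]


def plot_interaction(results: StudyResults, measure: str = "fa_bhq", ax=None):
    """Pre/post group means with 95% CI error bars for one measure."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    frame = results.model.frame
    for group, marker in (("intervention", "o"), ("control", "s")):
        wide = _change_table(frame, measure)
        wide = wide[wide["group"] == group]
        means, cis = [], []
        for col in ("pre", "post"):
            x = wide[col].to_numpy()
            means.append(x.mean())
            cis.append(1.96 * x.std(ddof=1) / np.sqrt(x.size))
        ax.errorbar([0, 1], means, yerr=cis, marker=marker, capsize=4, label=group)
    ax.set_xticks([0, 1], ["pre", "post"])
    ax.set_ylabel(measure)
    ax.legend(frameon=False)
    return ax


def plot_change_scatter(
    results: StudyResults, brain: str, behavior: str, group: str = "intervention", ax=None
):
    """Brain change vs behavioral change with the fitted least-squares line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    frame = results.model.frame
    cb = _change_table(frame, brain).set_index("participant")
    cv = _change_table(frame, behavior).set_index("participant")
    cb, cv = cb[cb["group"] == group], cv[cv["group"] == group]
    common = cb.index.intersection(cv.index)
    x = cb.loc[common, "change"].to_numpy()
    y = cv.loc[common, "change"].to_numpy()
    ax.scatter(x, y, s=18, alpha=0.8)
    slope, intercept = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 10)
    ax.plot(xs, slope * xs + intercept, lw=1.2)
    ax.set_xlabel(f"change in {brain}")
    ax.set_ylabel(f"change in {behavior}")
    ax.set_title(group)
    return ax
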