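"""Figures: smoothed group mean activity profiles and effect bands."""

from __future__ import annotations

import numpy as np

from .basis import WaveletBasis, build_basis
from .preprocess import N_EPOCHS, CovariateRow, EpochDay

__all__ = ["plot_group_profiles"]


def plot_group_profiles(
    days: list[EpochDay],
    covariates: list[CovariateRow],
    basis: WaveletBasis | None = None,
    ax=None,
):
    """Wavelet-smoothed mean log-activity curve per group over the 24 h cycle."""
    import matplotlib.pyplot as plt

    if basis is None:
        basis = build_basis()
    group_of = {c.subject_id: c.group for c in covariates}
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    hours = np.arange(N_EPOCHS) * 5 / 60
    for g, label in ((0, "group 0"), (1, "group 1")):
        mats = [d.log_counts for d in days if group_of[d.subject_id] == g]
        if not mats:
            continue
        mean_curve = basis.smooth(np.mean(mats, axis=0))
        ax.plot(hours, mean_curve, label=label)
    ax.set_xlabel("hour of day")
    ax.set_ylabel("mean log(1+count) per 5-min epoch")
    ax.set_xlim(0, 24)
    ax.legend(loc="best", fontsize=8)
    ax.set_title("Smoothed mean activity profiles")
    return ax
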