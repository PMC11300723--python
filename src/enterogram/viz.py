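"""Plots: diameter/volume-vs-longitude curves and the statistics panel."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .profile import (
    DIAMETER_THRESHOLD_MM,
    ILEOCECAL_LONGITUDE,
    TREITZ_LONGITUDE,
    LongitudeProfile,
    diameter_vs_length,
)

__all__ = ["plot_profile", "plot_eval_panel"]


def plot_profile(profile: LongitudeProfile):
    """Volume and diameter vs longitude, and diameter vs cumulative length.

    Vertical dotted lines mark the ligament of Treitz (longitude 40) and
    the ileocecal valve (80); the horizontal dotted line is the 30 mm
    dilation threshold.
    """
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), constrained_layout=True)
    nonempty = ~np.isnan(profile.mean_diameter_mm)
    lon = profile.bin_lo + 0.5

    axes[0].bar(lon, profile.volume_mm3 / 1e3, width=1.0, color="tab:blue")
    axes[0].set_ylabel("volume (cm³)")
    axes[1].plot(lon[nonempty], profile.mean_diameter_mm[nonempty], ".-", color="tab:red")
    axes[1].axhline(DIAMETER_THRESHOLD_MM, ls=":", color="k")
    axes[1].set_ylabel("diameter (mm)")
    for ax in axes[:2]:
        ax.axvline(TREITZ_LONGITUDE, ls=":", color="k")
        ax.axvline(ILEOCECAL_LONGITUDE, ls=":", color="k")
        ax.set_xlabel("longitude")

    series = diameter_vs_length(profile)
    axes[2].plot(series.x_mm / 10.0, series.diameter_mm, ".-", color="tab:red")
    axes[2].axhline(series.threshold_mm, ls=":", color="k")
    axes[2].axvline(series.treitz_x_mm / 10.0, ls=":", color="k")
    axes[2].axvline(series.ileocecal_x_mm / 10.0, ls=":", color="k")
    axes[2].set_xlabel("cumulative length (cm)")
    axes[2].set_ylabel("diameter (mm)")
    return fig


def plot_eval_panel(report, table, jitter: float = 1.0, seed: int = 0):
    """Dice strip, ICC scatters with identity line, and ROC-style summary.

    Presumed longitudes are jittered slightly so coincident organ midpoints
    do not overplot.
    """
    rng = np.random.default_rng(seed)
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), constrained_layout=True)

    d = np.asarray(report.dice_per_scan)
    axes[0].plot(rng.uniform(-0.1, 0.1, len(d)), d, "o", alpha=0.6)
    axes[0].set_xlim(-0.5, 0.5)
    axes[0].set_xticks([])
    axes[0].set_ylabel("Dice")
    axes[0].set_title(f"Dice {report.dice_mean:.2f} ± {report.dice_sd:.2f}")

    axes[1].plot(
        table.measured_diameter_mm, table.predicted_diameter_mm, ".", alpha=0.5
    )
    lim = max(table.measured_diameter_mm.max(), table.predicted_diameter_mm.max()) * 1.05
    axes[1].plot([0, lim], [0, lim], "k:", lw=1)
    axes[1].axvline(DIAMETER_THRESHOLD_MM, ls=":", color="gray")
    axes[1].set_xlabel("measured diameter (mm)")
    axes[1].set_ylabel("predicted diameter (mm)")
    axes[1].set_title(f"ICC {report.icc_diameter[0]:.2f}")

    x = table.presumed_longitude + rng.uniform(-jitter, jitter, len(table))
    axes[2].plot(x, table.predicted_longitude, ".", alpha=0.5)
    axes[2].plot([10, 150], [10, 150], "k:", lw=1)
    for v in (TREITZ_LONGITUDE, ILEOCECAL_LONGITUDE):
        axes[2].axvline(v, ls=":", color="gray")
    axes[2].set_xlabel("presumed longitude")
    axes[2].set_ylabel("predicted longitude")
    axes[2].set_title(f"ICC {report.icc_longitude[0]:.2f}")
    return fig
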