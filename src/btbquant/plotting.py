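"""Optional report figures: uptake-ratio fits, fold-vs-size scatter, class bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .kinetics import KinEstimate, RatioSeries


def plot_uptake_fit(series: RatioSeries, estimate: KinEstimate, ax=None):
    """Scatter the trimmed uptake ratio with the fitted line."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.times, series.ratio, "o", ms=4, label="measured ratio")
    tt = np.linspace(series.times.min(), series.times.max(), 50)
    ax.plot(tt, estimate.oc + estimate.kin * tt, "-",
            label=f"k_in={estimate.kin:.3g}/min")
    ax.set_xlabel("time from steady state (min)")
    ax.set_ylabel("(C_CC + C_PF) / C_PF")
    ax.set_title(f"{estimate.device_id} ({estimate.model_label})")
    ax.legend(frameon=False)
    return ax


def plot_fold_vs_size(lesion_table, ax=None, fold_col="fold_125I"):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(lesion_table["area_mm2"], lesion_table[fold_col], "o", ms=4)
    ax.set_xlabel("metastasis size (mm$^2$)")
    ax.set_ylabel("fold increase over normal brain")
    return ax


def plot_class_bars(summary, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(summary["perm_class"], summary["mean_fold"],
           yerr=summary["sd_fold"], capsize=3)
    ax.set_ylabel("fold increase (mean ± SD)")
    return ax


def save_report_figures(chip_result: dict, section_result: dict, outdir) -> list:
    """Write the standard figure set for a full synthetic run."""
    outdir = Path(outdir)
    written = []
    est_df = chip_result["estimates"]
    if len(est_df):
        fig, ax = plt.subplots()
        for label, grp in est_df.groupby("model_label"):
            ax.errorbar([label], [grp["kin"].mean()],
                        yerr=[grp["kin"].sem()], fmt="o", capsize=4)
        ax.set_ylabel("k_in (1/min, mean ± S.E.M.)")
        p = outdir / "chip_kin_groups.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    table = section_result["lesion_table"]
    if len(table):
        fig, ax = plt.subplots()
        plot_fold_vs_size(table, ax=ax)
        p = outdir / "fold_vs_size.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        fig, ax = plt.subplots()
        plot_class_bars(section_result["group_summary"].dropna(subset=["mean_fold"]), ax=ax)
        p = outdir / "perm_class_bars.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
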