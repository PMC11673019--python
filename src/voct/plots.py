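"""Accuracy-bar figures for the two localization procedures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_accuracy_curves(curves: pd.DataFrame, path) -> None:
    """Two-panel bar chart: per-frequency mixture-scan accuracy (top) and
    leave-one-frequency-out classifier accuracy (bottom), ±1 sd."""
    methods = [
        ("vbgmm_scan", "two-cluster accuracy per frequency"),
        ("svc_ablation", "classifier accuracy per excluded frequency"),
    ]
    fig, axes = plt.subplots(len(methods), 1, figsize=(8, 6), sharex=True)
    for ax, (method, title) in zip(axes, methods):
        sub = curves[curves["method"] == method]
        ax.bar(
            sub["frequency_hz"], sub["mean_accuracy"], width=8.0,
            yerr=sub["accuracy_sd"], capsize=2, color="#4878b0",
        )
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("accuracy")
        ax.set_title(title, fontsize=10)
    axes[-1].set_xlabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
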