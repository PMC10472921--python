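"""Small diagnostic figures.

Two plots mirror the reports a user of this pipeline actually inspects:
the per-run EGG spectrogram (to eyeball the gastric peak and its
stability) and the confound-synchrony bar chart (paired t of empirical
vs surrogate PLV per nuisance series, with FDR-significant bars
highlighted).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import signal

from .egg import EGGRecording, NORMOGASTRIC_BAND

__all__ = ["plot_spectrogram", "plot_confound_sync_bars"]


def plot_spectrogram(rec: EGGRecording, path: Path, channel: int = 0,
                     window_s: float = 200.0, fmax: float = 0.1) -> Path:
    """Spectrogram of one EGG channel with the normogastric band marked."""
    nperseg = int(window_s * rec.fs)
    f, t, sxx = signal.spectrogram(rec.samples[channel], fs=rec.fs,
                                   nperseg=nperseg, noverlap=nperseg * 3 // 4)
    sel = f <= fmax
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.pcolormesh(t / 60.0, f[sel], 10 * np.log10(sxx[sel] + 1e-20),
                  shading="gouraud", cmap="magma")
    for edge in NORMOGASTRIC_BAND:
        ax.axhline(edge, color="w", lw=0.8, ls="--")
    ax.set_xlabel("time [min]")
    ax.set_ylabel("frequency [Hz]")
    ax.set_title(f"{rec.subject_id} {rec.run_id} ch{channel}".strip())
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_confound_sync_bars(ttests: pd.DataFrame, path: Path) -> Path:
    """Bar chart of per-confound paired t (empirical vs surrogate PLV)."""
    frame = ttests.dropna(subset=["t"])
    colors = ["#8c510a" if sig else "#c7c7c7"
              for sig in frame["fdr_significant"]]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(frame["confound"], frame["t"], color=colors)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("paired t (empirical vs surrogate PLV)")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
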