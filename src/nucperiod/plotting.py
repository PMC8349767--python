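"""Plots of dyad-relative counts, periodograms and permutation nulls.

Every figure writes its plotted series alongside as a TSV, so the data
layer is byte-reproducible even if image encoding is not.  Translational
count profiles are smoothed for display only; stored SNR and peak-period
values always come from the unsmoothed series.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .periodicity import Periodogram, extract_series, smooth_for_display


def plot_counts_and_periodogram(
    data,
    periodogram: Periodogram,
    out_prefix: str | Path,
    smoothing_window: int | None = None,
) -> list[Path]:
    """Write a counts-vs-offset figure and an annotated periodogram figure.

    ``data`` is raw or normalized dyad-relative counts.  ``smoothing_window``
    (odd, bp) smooths the displayed count profile; pass None to plot raw
    values (rotational analyses are conventionally unsmoothed).
    Returns the written file paths (two PNGs and two TSVs).
    """
    out_prefix = Path(out_prefix)
    offsets, values = extract_series(data)
    if len(offsets) == 0:
        raise ValueError("empty series")
    display = (
        smooth_for_display(values, smoothing_window) if smoothing_window else values
    )

    written = []
    counts_tsv = out_prefix.with_name(out_prefix.name + "_counts_plotdata.tsv")
    pd.DataFrame({"offset": offsets, "value": values, "display": display}).to_csv(
        counts_tsv, sep="\t", index=False
    )
    written.append(counts_tsv)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(offsets, display, lw=0.9, color="#2c5f8a")
    ax.set_xlabel("position relative to dyad center (bp)")
    ylabel = "normalized mutation rate" if hasattr(data, "normalized") else "mutation count"
    ax.set_ylabel(ylabel + (" (smoothed)" if smoothing_window else ""))
    ax.set_xlim(offsets.min(), offsets.max())
    fig.tight_layout()
    counts_png = out_prefix.with_name(out_prefix.name + "_counts.png")
    fig.savefig(counts_png, dpi=150)
    plt.close(fig)
    written.append(counts_png)

    pg_tsv = out_prefix.with_name(out_prefix.name + "_periodogram.tsv")
    pd.DataFrame({"period": periodogram.periods, "power": periodogram.power}).to_csv(
        pg_tsv, sep="\t", index=False
    )
    written.append(pg_tsv)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(periodogram.periods, periodogram.power, lw=0.9, color="#444444")
    ax.axvline(periodogram.peak_period, color="#c0392b", ls="--", lw=0.8)
    snr_txt = f"{periodogram.snr:.1f}" if periodogram.snr is not None else "n/a"
    ax.set_title(f"peak period = {periodogram.peak_period:.2f} bp, SNR = {snr_txt}")
    ax.set_xlabel("period (bp)")
    ax.set_ylabel("normalized power")
    fig.tight_layout()
    pg_png = out_prefix.with_name(out_prefix.name + "_periodogram.png")
    fig.savefig(pg_png, dpi=150)
    plt.close(fig)
    written.append(pg_png)
    return written


def plot_null_distribution(
    null_diffs: np.ndarray, observed_diff: float, out_prefix: str | Path
) -> list[Path]:
    """Histogram of permutation-null SNR differences with the observed value marked."""
    out_prefix = Path(out_prefix)
    tsv = out_prefix.with_name(out_prefix.name + "_null_diffs.tsv")
    pd.DataFrame({"null_diff": null_diffs}).to_csv(tsv, sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(null_diffs, bins=20, color="#7f8c8d")
    ax.axvline(float(np.median(null_diffs)), color="#c0392b", lw=1.2, label="null median")
    ax.axvline(observed_diff, color="#27ae60", lw=1.2, ls="--", label="observed")
    ax.set_xlabel("SNR difference (permuted labels)")
    ax.set_ylabel("replicates")
    ax.legend(frameon=False)
    fig.tight_layout()
    png = out_prefix.with_name(out_prefix.name + "_null.png")
    fig.savefig(png, dpi=150)
    plt.close(fig)
    return [tsv, png]
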