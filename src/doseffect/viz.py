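"""Genome-wide karyotype CNA-frequency plot and DES distribution histogram.

The karyotype plot shows, per gene at its genomic position, an upward bar for
the fraction of samples with copy-number gain and a downward bar for the
fraction with loss, colored by the gene's dosage effect score (viridis,
colorblind-safe); genes without a defined DES are gray. A gray reference bar
at the start of each chromosome marks 100%. Figures are written by file
extension (png/svg/pdf); embedded timestamps are suppressed so vector output
is byte-stable for a fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import cm, colors

from .dosage import DesParams, DesTable
from .io import ValidationError
from .preprocess import PairedDataset

AUTOSOMES = [str(i) for i in range(1, 23)]


@dataclass
class KaryotypeTrack:
    """Per-gene plotting record: chromosome, midpoint, gain/loss sample
    fractions and DES (NaN when undefined). Sorted by chromosome then
    midpoint; sex chromosomes are excluded."""

    table: pd.DataFrame

    def __post_init__(self):
        frac = self.table[["gain_fraction", "loss_fraction"]].to_numpy()
        if (frac < 0).any() or (frac > 1).any():
            raise ValidationError("fractions must lie in [0, 1]")
        if (frac.sum(axis=1) > 1 + 1e-9).any():
            raise ValidationError("gain + loss fraction exceeds 1 for some gene")

    def chromosomes(self) -> list[str]:
        seen = self.table["chromosome"]
        return [c for c in AUTOSOMES if (seen == c).any()]


def build_karyotype_track(
    dataset: PairedDataset, des: DesTable, params: DesParams | None = None
) -> KaryotypeTrack:
    """Per-gene CNA gain/loss sample fractions at the gene's midpoint,
    carrying the gene's DES for coloring. Order: chromosome, then midpoint."""
    params = params or des.params
    cn = dataset.copy_number.data
    n = cn.shape[1]
    with np.errstate(invalid="ignore"):
        gain_fraction = (cn > params.gain_threshold).sum(axis=1) / n
        loss_fraction = (cn < params.loss_threshold).sum(axis=1) / n
    ann = dataset.annotation.table.loc[cn.index]
    table = pd.DataFrame(
        {
            "chromosome": ann["chromosome"],
            "midpoint": (ann["tx_start"] + ann["tx_end"]) / 2.0,
            "gain_fraction": gain_fraction,
            "loss_fraction": loss_fraction,
            "des": des.table.loc[cn.index, "des"],
        }
    )
    table = table[table["chromosome"].isin(AUTOSOMES)]
    order = table["chromosome"].map({c: i for i, c in enumerate(AUTOSOMES)})
    table = table.iloc[np.lexsort((table["midpoint"].to_numpy(), order.to_numpy()))]
    return KaryotypeTrack(table)


def _save(fig, out_path, dpi: int = 150) -> None:
    # strip embedded dates and fix the SVG id salt so vector output is
    # reproducible byte-for-byte
    with matplotlib.rc_context({"svg.hashsalt": "doseffect"}):
        fig.savefig(out_path, dpi=dpi, metadata=_neutral_metadata(str(out_path)))
    plt.close(fig)


def _neutral_metadata(path: str):
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".pdf"):
        return {"CreationDate": None}
    return None


def plot_karyotype(
    track: KaryotypeTrack,
    out_path,
    figsize: tuple[float, float] | None = None,
    dpi: int = 150,
) -> None:
    """Render the genome-wide CNA-frequency karyotype plot, one panel per
    autosome present in the track."""
    chroms = track.chromosomes()
    if not chroms:
        raise ValidationError("karyotype track is empty")
    ncols = 4
    nrows = int(np.ceil(len(chroms) / ncols))
    figsize = figsize or (4.0 * ncols, 1.8 * nrows)
    fig, axes = plt.subplots(nrows, ncols, figsize=figsize, squeeze=False)
    cmap = plt.get_cmap("viridis")
    norm = colors.Normalize(vmin=0.0, vmax=1.0)
    for ax in axes.ravel()[len(chroms):]:
        ax.axis("off")
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = track.table[track.table["chromosome"] == chrom]
        x = sub["midpoint"].to_numpy()
        des = sub["des"].to_numpy()
        bar_colors = np.array(
            [cmap(norm(v)) if np.isfinite(v) else (0.6, 0.6, 0.6, 1.0) for v in des]
        )
        span = max(x.max(), 1.0)
        # 100% reference bar at the chromosome start
        ax.axvline(-0.01 * span, ymin=0, ymax=1, color="0.5", linewidth=3)
        ax.vlines(x, 0, sub["gain_fraction"], colors=bar_colors, linewidth=0.8)
        ax.vlines(x, -sub["loss_fraction"], 0, colors=bar_colors, linewidth=0.8)
        ax.axhline(0, color="black", linewidth=0.5)
        ax.set_ylim(-1.02, 1.02)
        ax.set_xlim(-0.03 * span, 1.02 * span)
        ax.set_title(f"chr{chrom}", fontsize=9)
        ax.set_yticks([-1, 0, 1])
        ax.set_yticklabels(["100% loss", "0", "100% gain"], fontsize=6)
        ax.set_xticks([])
    fig.colorbar(
        cm.ScalarMappable(norm=norm, cmap=cmap),
        ax=axes,
        label="dosage effect score",
        shrink=0.6,
    )
    fig.suptitle("CNA frequency by gene, colored by dosage effect score")
    _save(fig, out_path, dpi=dpi)


def plot_des_distribution(
    des: DesTable,
    out_path,
    bins: int = 40,
    figsize: tuple[float, float] = (6.0, 4.0),
    dpi: int = 150,
) -> dict:
    """Histogram of defined DES values with the low/medium/high category
    boundaries marked and the category percentages annotated.

    Returns the annotated percentages (they sum to 100 over defined genes)."""
    values = des.defined()["des"]
    if len(values) == 0:
        raise ValidationError("no defined DES values to plot")
    fractions = des.category_fractions(among_defined=True) * 100
    fig, ax = plt.subplots(figsize=figsize)
    ax.hist(values, bins=bins, range=(0, 1), color="#4878d0", edgecolor="white")
    for boundary in (des.params.low_max, des.params.high_min):
        ax.axvline(boundary, color="black", linestyle="--", linewidth=1)
    ax.set_xlabel("dosage effect score")
    ax.set_ylabel("genes")
    annotation = (
        f"low {fractions['low']:.1f}%  |  medium {fractions['medium']:.1f}%  |  "
        f"high {fractions['high']:.1f}%"
    )
    ax.set_title(annotation, fontsize=10)
    _save(fig, out_path, dpi=dpi)
    return fractions.to_dict()
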