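"""Diagnostic plots: per-read annotation diagrams and dataset QC figures."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from seqgrammar.annotate import AnnotatedRead

logger = logging.getLogger(__name__)

#: Fixed label palette so figures are comparable across runs; labels not
#: listed fall back to the tab10 cycle in a deterministic order.
PALETTE = {
    "RANDOM": "#bdbdbd",
    "ADAPTER5": "#1f77b4",
    "CBC": "#d62728",
    "UMI": "#9467bd",
    "POLYT": "#ff7f0e",
    "CDNA": "#2ca02c",
    "ADAPTER3": "#17becf",
}
_FALLBACK = [
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#aec7e8", "#ffbb78",
]


def _color(label: str, extra: dict) -> str:
    if label in PALETTE:
        return PALETTE[label]
    if label not in extra:
        extra[label] = _FALLBACK[len(extra) % len(_FALLBACK)]
    return extra[label]


def plot_read_annotation(
    sequence: str, annotation: AnnotatedRead, out_path: str | Path
) -> Path:
    """Color-coded span diagram of one annotated read, captioned with its call."""
    n = len(sequence)
    for seg in annotation.segments:
        if seg.start < 0 or seg.end > n:
            raise ValueError(
                f"segment {seg.label} [{seg.start},{seg.end}) outside read of length {n}"
            )
    extra: dict = {}
    fig, ax = plt.subplots(figsize=(10, 1.8))
    seen = set()
    for seg in annotation.segments:
        color = _color(seg.label, extra)
        ax.broken_barh(
            [(seg.start, seg.length)],
            (0, 1),
            facecolors=color,
            label=seg.label if seg.label not in seen else None,
        )
        seen.add(seg.label)
    ax.set_xlim(0, n)
    ax.set_yticks([])
    ax.set_xlabel("position (bp)")
    ax.set_title(f"{annotation.read_id}: {annotation.call.render()}", fontsize=10)
    ax.legend(loc="upper right", ncol=min(len(seen), 7), fontsize=7, frameon=False)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_qc(
    annotations: pd.DataFrame,
    assignments: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    """Read-length histogram and assigned-barcode edit-distance bar plot.

    Both figures are views of the tables: the bar heights sum to the number
    of assigned reads, the histogram to the number of annotated reads.
    Returns the written paths ([] with a warning when the tables are empty).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if len(annotations) == 0 and len(assignments) == 0:
        logger.warning("plot_qc: empty tables, nothing to plot")
        return written
    if len(annotations):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(annotations["read_length"], bins=50, color="#1f77b4")
        ax.set_xlabel("read length (bp)")
        ax.set_ylabel("reads")
        ax.set_title("read length distribution")
        p = out_dir / "read_lengths.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if len(assignments):
        assigned = assignments[assignments["status"] == "assigned"]
        counts = assigned["distance"].value_counts().sort_index()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(counts.index.astype(int), counts.values, color="#d62728")
        ax.set_xlabel("Levenshtein distance to corrected barcode")
        ax.set_ylabel("assigned reads")
        ax.set_title("barcode correction distances")
        p = out_dir / "barcode_distances.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
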