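"""Static renderings of the jump map and chimeric-read layout."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_jump_map(table: pd.DataFrame, path: str | Path, title: str = "Jump map") -> None:
    """Scatter of (from, to) signed coordinates sized/colored by count."""
    fig, ax = plt.subplots(figsize=(6, 6))
    if not table.empty:
        sizes = 4 + 40 * table["count"] / table["count"].max()
        sc = ax.scatter(
            table["to_coord"], table["from_coord"],
            s=sizes, c=table["count"], cmap="viridis", alpha=0.8,
        )
        fig.colorbar(sc, ax=ax, label="count")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("5' base of 3' k-mer (signed ncRNA position)")
    ax.set_ylabel("3' base of 5' k-mer (signed ncRNA position)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_read_layout(layout: pd.DataFrame, path: str | Path, max_reads: int = 200) -> None:
    """Per-read segment rendering; color encodes mapped ncRNA position."""
    fig, ax = plt.subplots(figsize=(8, 6))
    if not layout.empty:
        sub = layout[layout["y_rank"] < max_reads]
        mapped = sub.dropna(subset=["position"])
        ax.scatter(
            mapped["x_coord"], mapped["y_rank"],
            c=mapped["position"], cmap="turbo", s=3, marker="s",
        )
    ax.set_xlabel("layout x (ncRNA frame of the longest run)")
    ax.set_ylabel("read rank")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
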