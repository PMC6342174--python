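"""Plot-data structures and static renderers.

The tested surface is the plot *data*: a stacked-bar structure (one
bar per distinct chromosome number, segmented by species, heights =
record frequencies) and the species-by-count percentage matrix.
Renderers draw them with matplotlib to PNG or SVG; the same bar data
can be exported as JSON so an interactive front end can consume it.

Colors come from a fixed qualitative palette cycled in species sort
order, so the same table always renders identically; SVG output is
made byte-reproducible by pinning matplotlib's hash salt and stripping
the embedded date.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .summary import FrequencyTable

__all__ = [
    "StackedBarData",
    "stacked_bar_data",
    "render_stacked_bar",
    "render_heatmap",
]

_PALETTE = plt.get_cmap("tab20").colors


@dataclass
class StackedBarData:
    """Data behind a stacked bar chart of record frequencies.

    ``segments[count]`` lists ``(species, height)`` pairs in fixed
    species order; a species observed at several counts appears in
    several bars.
    """

    x_values: list[int]
    segments: dict[int, list[tuple[str, int]]]
    legend: dict[str, int]  # species -> color index

    @property
    def total(self) -> int:
        return sum(h for segs in self.segments.values() for _, h in segs)

    def to_json(self) -> str:
        """JSON export: {bars: [{count, segments: [{species, n_records}]}]}."""
        payload = {
            "bars": [
                {
                    "count": c,
                    "segments": [
                        {"species": s, "n_records": h}
                        for s, h in self.segments[c]
                    ],
                }
                for c in self.x_values
            ]
        }
        return json.dumps(payload, indent=2)


def stacked_bar_data(freq: FrequencyTable) -> StackedBarData:
    """Build stacked-bar data from a frequency table."""
    if not freq.entries:
        raise ValueError("frequency table is empty")
    species = freq.species
    legend = {s: i % len(_PALETTE) for i, s in enumerate(species)}
    segments: dict[int, list[tuple[str, int]]] = {}
    for c in freq.counts:
        segs = [
            (s, freq.entries[(s, c)])
            for s in species
            if (s, c) in freq.entries
        ]
        segments[c] = segs
    return StackedBarData(
        x_values=freq.counts, segments=segments, legend=legend
    )


def _deterministic_savefig(fig, path: Union[str, Path]) -> None:
    path = Path(path)
    with plt.rc_context({"svg.hashsalt": "karyocurate"}):
        if path.suffix.lower() == ".svg":
            fig.savefig(path, metadata={"Date": None})
        else:
            fig.savefig(path)


def render_stacked_bar(
    data: StackedBarData, path: Union[str, Path]
) -> None:
    """Render the stacked bar chart to a PNG or SVG file."""
    if not data.x_values:
        raise ValueError("no bars to render")
    fig, ax = plt.subplots(figsize=(max(6, len(data.x_values) * 0.8), 4.5))
    positions = np.arange(len(data.x_values))
    seen: set[str] = set()
    for xi, count in zip(positions, data.x_values):
        bottom = 0
        for species, height in data.segments[count]:
            ax.bar(
                xi,
                height,
                bottom=bottom,
                width=0.8,
                color=_PALETTE[data.legend[species]],
                label=species if species not in seen else None,
            )
            seen.add(species)
            bottom += height
    ax.set_xticks(positions)
    ax.set_xticklabels([str(c) for c in data.x_values])
    ax.set_xlabel("chromosome number")
    ax.set_ylabel("number of records")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    _deterministic_savefig(fig, path)
    plt.close(fig)


def render_heatmap(
    matrix: pd.DataFrame, path: Union[str, Path], atol: float = 1e-6
) -> None:
    """Render a species-by-count percentage matrix to an image file.

    Rows are species, columns ascending counts; cells hold the
    percentage of that species' records at that count, so every row
    must sum to 100 (within ``atol``).  Zero cells render at the
    bottom of the color scale, distinct from an absent species (which
    simply has no row).
    """
    sums = matrix.sum(axis=1).to_numpy(dtype=float)
    if not np.allclose(sums, 100.0, atol=atol):
        raise ValueError("heatmap rows must each sum to 100 percent")
    matrix = matrix.reindex(
        index=sorted(matrix.index), columns=sorted(matrix.columns)
    )
    fig, ax = plt.subplots(
        figsize=(
            max(5, matrix.shape[1] * 0.9),
            max(3, matrix.shape[0] * 0.5),
        )
    )
    im = ax.imshow(
        matrix.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=100
    )
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels([str(c) for c in matrix.columns])
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=8)
    ax.set_xlabel("chromosome number")
    fig.colorbar(im, ax=ax, label="% of species' records")
    fig.tight_layout()
    _deterministic_savefig(fig, path)
    plt.close(fig)
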