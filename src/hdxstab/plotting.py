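"""Presentation plots: chiclet heatmaps, skyline profiles, difference maps.

These are visual aids over the analysis outputs; nothing downstream depends
on them.
"""

from __future__ import annotations

import numpy as np

from .exchange import FLAG_OK, compute_percent_d
from .io import StateTable
from .residue import DifferenceMap, ResidueExchangeMap


def chiclet_plot(table: StateTable, condition: str, ax=None):
    """Peptide-level %D heatmap: peptides (rows) by labeling time (columns)."""
    import matplotlib.pyplot as plt

    peptides = sorted({(r.start, r.end) for r in table.records if r.condition == condition})
    times = sorted({r.exposure for r in table.records if r.condition == condition})
    grid = np.full((len(peptides), len(times)), np.nan)
    for rec in table.records:
        if rec.condition != condition:
            continue
        uv = compute_percent_d(rec)
        if uv.flag == FLAG_OK and uv.percent_d is not None:
            grid[peptides.index((rec.start, rec.end)), times.index(rec.exposure)] = uv.percent_d
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + len(times), 0.3 * len(peptides) + 1))
    im = ax.imshow(grid, aspect="auto", vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(times)), [f"{t:g}s" for t in times], rotation=45)
    ax.set_yticks(range(len(peptides)), [f"{s}-{e}" for s, e in peptides])
    ax.set_xlabel("labeling time")
    ax.set_title(f"%D, {condition}")
    ax.figure.colorbar(im, ax=ax, label="%D")
    return ax


def skyline_plot(residue_map: ResidueExchangeMap, condition: str, time: float, ax=None):
    """Residue-level %D profile along the alignment at one labeling time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    xs, ys = [], []
    for pos in residue_map.positions:
        v = residue_map.value(pos, condition, time)
        xs.append(pos)
        ys.append(np.nan if v is None else v)
    ax.step(xs, ys, where="mid")
    ax.set_xlabel("alignment position")
    ax.set_ylabel("%D")
    ax.set_ylim(0, 100)
    ax.set_title(f"{residue_map.protein}, {condition}, {time:g} s")
    return ax


def difference_heatmap(dmap: DifferenceMap, ax=None):
    """Residue-by-time heatmap of %D(A) - %D(B); protection plots blue."""
    import matplotlib.pyplot as plt

    grid = np.full((len(dmap.times), len(dmap.positions)), np.nan)
    for (pos, t), v in dmap.delta.items():
        grid[dmap.times.index(t), dmap.positions.index(pos)] = v
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2 + 0.4 * len(dmap.times)))
    limit = max(5.0, float(np.nanmax(np.abs(grid))) if np.isfinite(grid).any() else 5.0)
    im = ax.imshow(grid, aspect="auto", cmap="RdBu", vmin=-limit, vmax=limit)
    ax.set_yticks(range(len(dmap.times)), [f"{t:g}s" for t in dmap.times])
    ax.set_xlabel("alignment position")
    ax.set_title(f"{dmap.protein}: d%D ({dmap.condition_a} - {dmap.condition_b})")
    ax.figure.colorbar(im, ax=ax, label="d%D")
    return ax
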