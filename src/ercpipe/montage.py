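"""Electrode montage, lobe grouping, rank-averaged ERC maps, scalp grids.

The 14-channel consumer headset exposes these 10-10 positions, grouped
into cerebral lobes for lobe-level statistics:

====================  =========
Electrodes            Lobe
====================  =========
AF3, AF4              Frontal
F7, F8                Frontal
F3, F4                Frontal
FC5, FC6              Frontal
T7, T8                Temporal
P7, P8                Parietal
O1, O2                Occipital
====================  =========

2-D scalp coordinates are standard 10-10 spherical positions projected
onto the unit head circle (nose up, +x to the subject's right); left and
right homologues mirror across the midline, which the symmetry tests
rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Electrode -> lobe for the 14 headset positions.
ELECTRODE_LOBES: dict[str, str] = {
    "AF3": "Frontal", "AF4": "Frontal",
    "F7": "Frontal", "F8": "Frontal",
    "F3": "Frontal", "F4": "Frontal",
    "FC5": "Frontal", "FC6": "Frontal",
    "T7": "Temporal", "T8": "Temporal",
    "P7": "Parietal", "P8": "Parietal",
    "O1": "Occipital", "O2": "Occipital",
}

#: Canonical channel order (matches the headset's published listing).
CHANNEL_ORDER = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

LOBES = ("Frontal", "Temporal", "Parietal", "Occipital")

#: Lobe -> member electrodes, in canonical channel order.
LOBE_ELECTRODES: dict[str, tuple[str, ...]] = {
    lobe: tuple(ch for ch in CHANNEL_ORDER if ELECTRODE_LOBES[ch] == lobe)
    for lobe in LOBES
}

#: Electrode -> (x, y) on the unit head circle.
ELECTRODE_POSITIONS: dict[str, tuple[float, float]] = {
    "AF3": (-0.29, 0.80), "AF4": (0.29, 0.80),
    "F7": (-0.76, 0.49), "F8": (0.76, 0.49),
    "F3": (-0.35, 0.50), "F4": (0.35, 0.50),
    "FC5": (-0.65, 0.25), "FC6": (0.65, 0.25),
    "T7": (-0.90, 0.00), "T8": (0.90, 0.00),
    "P7": (-0.76, -0.49), "P8": (0.76, -0.49),
    "O1": (-0.29, -0.90), "O2": (0.29, -0.90),
}


def lobe_of_electrode(label: str) -> str:
    """Return the cerebral lobe of a headset electrode."""
    try:
        return ELECTRODE_LOBES[label]
    except KeyError:
        raise KeyError(
            f"unknown electrode {label!r}; valid labels: "
            f"{sorted(ELECTRODE_LOBES)}"
        ) from None


@dataclass(frozen=True)
class Montage:
    """Electrode labels with lobes and 2-D scalp coordinates."""

    labels: tuple[str, ...] = CHANNEL_ORDER

    def position(self, label: str) -> tuple[float, float]:
        lobe_of_electrode(label)  # validates
        return ELECTRODE_POSITIONS[label]

    def lobe(self, label: str) -> str:
        return lobe_of_electrode(label)


def average_erc_by_rank(
    erc_table: pd.DataFrame,
    rank_table: pd.DataFrame,
) -> pd.DataFrame:
    """Average ERC per (band, rank, channel) over events of that rank.

    Parameters
    ----------
    erc_table:
        Tidy ERC table with columns ``event_id, channel, band, erc, valid``
        (and optionally ``subject``).
    rank_table:
        Columns ``event_id, rank`` (ranks ``fast``/``medium``/``slow``),
        optionally ``subject``.

    Returns a tidy frame with columns
    ``[subject,] band, rank, channel, mean_erc, n_events``; empty rank
    groups simply yield no row (flagged by the missing combination).
    Only rows flagged valid enter the averages.
    """
    required = {"event_id", "channel", "band", "erc"}
    if missing := required - set(erc_table.columns):
        raise ValueError(f"erc_table missing columns {sorted(missing)}")
    if missing := {"event_id", "rank"} - set(rank_table.columns):
        raise ValueError(f"rank_table missing columns {sorted(missing)}")

    ercs = erc_table
    if "valid" in ercs.columns:
        ercs = ercs[ercs["valid"]]
    join_keys = ["event_id"]
    if "subject" in ercs.columns and "subject" in rank_table.columns:
        join_keys = ["subject", "event_id"]
    merged = ercs.merge(rank_table, on=join_keys, how="inner")

    group_keys = (["subject"] if "subject" in merged.columns else []) + [
        "band", "rank", "channel"
    ]
    out = (
        merged.groupby(group_keys, observed=True)["erc"]
        .agg(mean_erc="mean", n_events="size")
        .reset_index()
    )
    return out


def scalp_grid(
    values: dict[str, float],
    montage: Montage | None = None,
    grid_resolution: int = 64,
    idw_power: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate per-electrode values onto a masked head-circle grid.

    Inverse-distance weighting with exponent ``idw_power`` over all 14
    electrodes; grid nodes outside the unit circle are NaN.  Returns
    ``(grid, x_coords, y_coords)`` where ``grid`` is
    ``(grid_resolution, grid_resolution)`` indexed ``[iy, ix]``.
    """
    montage = montage or Montage()
    missing = [ch for ch in montage.labels if ch not in values]
    if missing:
        raise ValueError(f"missing electrode values for {missing}")

    pos = np.array([montage.position(ch) for ch in montage.labels])
    vals = np.array([float(values[ch]) for ch in montage.labels])

    coords = np.linspace(-1.0, 1.0, grid_resolution)
    gx, gy = np.meshgrid(coords, coords)
    inside = gx**2 + gy**2 <= 1.0

    d2 = (gx[..., None] - pos[:, 0]) ** 2 + (gy[..., None] - pos[:, 1]) ** 2
    dist = np.sqrt(d2)
    grid = np.full(gx.shape, np.nan)

    exact = dist < 1e-12
    any_exact = exact.any(axis=-1)
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**idw_power
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=-1)
    interp = (w * vals).sum(axis=-1) / np.where(denom > 0, denom, 1.0)
    # Nodes coinciding with an electrode take its value exactly.
    idx_exact = exact.argmax(axis=-1)
    interp = np.where(any_exact, vals[idx_exact], interp)
    grid[inside] = interp[inside]
    return grid, coords, coords
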