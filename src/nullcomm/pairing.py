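"""Mutual-nearest-neighbour plot pairing within Level IV ecoregions.

For the presence contrast each plot is matched to the closest plot in
the same ecoregion (great-circle distance).  Only mutual pairs are
kept: if a plot's nearest neighbour is itself nearer to some third
plot, both sides of that would-be pair are not mutual and the plot is
discarded.  Pairs whose two plots sit at identical coordinates (zero
distance) are removed as unresolvable duplicates.  Pairing is a single
pass: discarded plots are not re-matched.  Nearest-neighbour ties are
broken lexicographically by plot id, which makes the pairing
deterministic on gridded synthetic data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["haversine_km", "pair_plots", "EARTH_RADIUS_KM"]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = (np.asarray(a, float) for a in (lat1, lon1, lat2, lon2))
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("coordinates outside valid decimal-degree range")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def _pair_one_ecoregion(sub: pd.DataFrame):
    """Mutual-NN pairs for the plots of one ecoregion (already id-sorted)."""
    ids = sub["plot_id"].to_numpy()
    n = len(ids)
    lat = np.radians(sub["latitude"].to_numpy(float))
    lon = np.radians(sub["longitude"].to_numpy(float))
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)  # first minimum = lexicographically smallest id
    mutual = nn[nn] == np.arange(n)
    pairs, discards = [], []
    for i in range(n):
        j = nn[i]
        if not mutual[i]:
            discards.append((ids[i], "non_mutual"))
        elif i < j:
            if d[i, j] == 0.0:
                discards.append((ids[i], "identical_coordinates"))
                discards.append((ids[j], "identical_coordinates"))
            else:
                pairs.append((ids[i], ids[j], d[i, j]))
    return pairs, discards


def pair_plots(plots: pd.DataFrame):
    """Build the mutual-NN pair set, stratified by ecoregion.

    Returns ``(pairs, discards)``: a frame with columns plot_a, plot_b,
    ecoregion_l4, distance_km (plot_a < plot_b), and a frame of
    discarded plots with the reason (non_mutual, identical_coordinates,
    singleton_ecoregion).
    """
    pair_rows, disc_rows = [], []
    plots = plots.sort_values("plot_id", kind="mergesort")
    for eco, sub in plots.groupby("ecoregion_l4", sort=True):
        if len(sub) < 2:
            for pid in sub["plot_id"]:
                disc_rows.append((pid, eco, "singleton_ecoregion"))
            continue
        pairs, discards = _pair_one_ecoregion(sub)
        pair_rows.extend((a, b, eco, dist) for a, b, dist in pairs)
        disc_rows.extend((pid, eco, reason) for pid, reason in discards)
    pairs = pd.DataFrame(pair_rows, columns=["plot_a", "plot_b", "ecoregion_l4", "distance_km"])
    discards = pd.DataFrame(disc_rows, columns=["plot_id", "ecoregion_l4", "reason"])
    return pairs, discards
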