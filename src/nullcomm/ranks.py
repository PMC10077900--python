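"""Global rank-abundance structure and rank-matched null focal sets.

A species' global abundance is its percentage cover summed over every
retained plot; ranking by descending abundance (rank 1 = most abundant)
gives the rank-abundance curve.  The focal guild occupies a window of
that curve, and each null replicate draws an equally sized set of
non-focal species uniformly from the same window, so that null sets are
matched to the guild in commonness.  Ties in abundance are broken
lexicographically by species id so that ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FocalSet",
    "build_rank_abundance",
    "focal_rank_range",
    "sample_null_set",
    "sample_null_sets",
    "occupancy_diagnostics",
]


@dataclass(frozen=True)
class FocalSet:
    """A labelled set of species ids with the rank window they span."""

    species: frozenset
    label: str
    rank_range: tuple[int, int]


def build_rank_abundance(cover: pd.DataFrame) -> pd.DataFrame:
    """Rank species by descending summed cover; ties broken by species_id.

    Returns a frame with columns species_id, abundance, rank (1-based),
    sorted by rank.
    """
    if cover.empty:
        raise ValueError("cover table is empty")
    ab = cover.groupby("species_id", as_index=False)["cover"].sum()
    ab = ab.rename(columns={"cover": "abundance"})
    ab = ab.sort_values(
        ["abundance", "species_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ab["rank"] = np.arange(1, len(ab) + 1)
    return ab


def focal_rank_range(rank_abundance: pd.DataFrame, focal) -> tuple[int, int]:
    """(min, max) global rank over the members of ``focal`` present in the curve."""
    focal = set(focal)
    if not focal:
        raise ValueError("focal set is empty")
    ranks = rank_abundance.loc[rank_abundance["species_id"].isin(focal), "rank"]
    if ranks.empty:
        raise ValueError("no focal species appear in the rank-abundance curve")
    return int(ranks.min()), int(ranks.max())


def sample_null_set(
    rank_abundance: pd.DataFrame,
    focal,
    rng,
    size: int | None = None,
    label: str = "null",
) -> FocalSet:
    """Draw a rank-matched null focal set.

    ``size`` species are sampled uniformly without replacement from the
    non-focal species whose rank falls inside the focal guild's rank
    window; it defaults to the number of focal species observed in the
    rank-abundance curve (catalog members absent from every plot carry
    no cover and must not inflate the matched set size).  ``rng`` is a
    seeded :class:`numpy.random.Generator`, making the draw
    reproducible.
    """
    focal = set(focal)
    lo, hi = focal_rank_range(rank_abundance, focal)
    if size is None:
        size = int(rank_abundance["species_id"].isin(focal).sum())
    in_window = rank_abundance["rank"].between(lo, hi)
    pool = rank_abundance.loc[
        in_window & ~rank_abundance["species_id"].isin(focal), "species_id"
    ].to_numpy()
    if len(pool) < size:
        raise ValueError(
            f"null candidate pool has {len(pool)} species inside ranks "
            f"[{lo}, {hi}] but {size} are required"
        )
    chosen = rng.choice(pool, size=size, replace=False)
    return FocalSet(frozenset(chosen.tolist()), label, (lo, hi))


def sample_null_sets(rank_abundance, focal, n_replicates: int, master_seed: int, size=None):
    """List of independent null sets, one per replicate.

    Each replicate gets its own substream spawned from the master seed,
    so ensembles are reproducible and order-independent.
    """
    seeds = np.random.SeedSequence(master_seed).spawn(n_replicates)
    return [
        sample_null_set(
            rank_abundance,
            focal,
            np.random.default_rng(seeds[i]),
            size=size,
            label=f"null_rep_{i:04d}",
        )
        for i in range(n_replicates)
    ]


def occupancy_diagnostics(cover: pd.DataFrame, species_ids) -> dict:
    """Per-species and joint plot-occupancy counts for a species set.

    Reports both readings of set occupancy: the range of per-species
    plot counts and the number of plots holding at least one member.
    """
    sub = cover.loc[cover["species_id"].isin(set(species_ids))]
    per_species = sub.groupby("species_id")["plot_id"].nunique()
    return {
        "per_species_plot_counts": {
            "min": int(per_species.min()) if len(per_species) else 0,
            "max": int(per_species.max()) if len(per_species) else 0,
        },
        "n_plots_with_any_member": int(sub["plot_id"].nunique()),
    }
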