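"""Diversity and community-weighted-mean covariates.

Shannon-Wiener diversity (natural log), species richness as the mean
species count per plot, and community-weighted means (CWM) of leaf traits
weighted by species dominance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy


class EmptyCommunityError(ValueError):
    """All abundances (or weights) are zero where a positive sum is required."""


def shannon_index(abundances: Sequence[float]) -> float:
    """Shannon-Wiener index H = −Σ pᵢ ln pᵢ (nats) from raw abundances.

    Zero-abundance species contribute nothing; invariant to rescaling the
    abundance vector.  Bounded by [0, ln S].
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise EmptyCommunityError("at least one positive abundance is required")
    return float(entropy(a / total))


def species_richness(plots: Sequence[Sequence[float]]) -> float:
    """Mean number of species with positive abundance across plots.

    ``plots`` is an iterable of per-plot abundance vectors; an empty plot
    contributes a count of zero to the mean.
    """
    counts = [int(np.sum(np.asarray(p, dtype=float) > 0)) for p in plots]
    if not counts:
        raise ValueError("at least one plot is required")
    return float(np.mean(counts))


def community_weighted_mean(
    traits: Sequence[float], weights: Sequence[float]
) -> float:
    """CWM = Σ wᵢ·traitᵢ / Σ wᵢ, weights ≥ 0 (dominance or biomass)."""
    t = np.asarray(traits, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise EmptyCommunityError("weights must not all be zero")
    return float(np.average(t, weights=w))


def site_community_metrics(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-site SR and Shannon from a long abundance sheet.

    ``abundance`` has columns site_id, plot_id, species_id, abundance.
    Shannon is computed on species abundances pooled over plots; richness
    is the mean per-plot species count.
    """
    records = []
    for site_id, site_df in abundance.groupby("site_id", sort=True):
        pooled = site_df.groupby("species_id")["abundance"].sum()
        plots = [
            plot_df["abundance"].to_numpy()
            for _, plot_df in site_df.groupby("plot_id")
        ]
        records.append(
            {
                "site_id": site_id,
                "sr": species_richness(plots),
                "shannon": shannon_index(pooled.to_numpy()),
            }
        )
    return pd.DataFrame.from_records(records)
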