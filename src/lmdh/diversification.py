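"""Genus-level diversification proxies from ultrametric gene trees.

For each genus (or genus partition corresponding to a single colonization
event), a UPGMA tree over one sequence per species gives node divergences in
substitutions/site per lineage.  The mean node divergence summarizes the
temporal spread of splits; the maximum is a crown-age proxy.  The
age-richness rate ARR = S / t_max (endemic species richness over crown age)
is the diversification-rate proxy.  A strict molecular clock converts
substitution heights to absolute time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_distance import AlignedSequenceSet, distance_matrix
from .delimitation import UltrametricTree, upgma, percentage, ULTRAMETRIC_TOL

__all__ = [
    "ClockModel",
    "CLOCKS",
    "GenusDiversification",
    "node_ages",
    "divergence_summaries",
    "to_time",
    "genus_pipeline",
    "normalize01",
    "coverage_report",
]


@dataclass(frozen=True)
class ClockModel:
    """Strict clock: substitutions/site/Myr per lineage, with reported sd.

    The sd accompanies published rate estimates and is carried as metadata
    only; conversion uses the mean rate.
    """

    taxon_group: str
    rate: float
    sd: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")


# Published COI rate calibrations per taxon group and gene region.
CLOCKS = {
    "spider_COIa": ClockModel("spider_COIa", 0.0125, 0.0036),
    "polyphaga_COIa": ClockModel("polyphaga_COIa", 0.0168, 0.0018),
    "polyphaga_COIb": ClockModel("polyphaga_COIb", 0.0177, 0.0019),
    "adephaga_COIa": ClockModel("adephaga_COIa", 0.0113, 0.0034),
    "adephaga_COIb": ClockModel("adephaga_COIb", 0.0145, 0.0054),
}


@dataclass
class GenusDiversification:
    """Per-genus richness, node-divergence summaries and ARR."""

    genus_unit: str
    order: str
    dispersal: str
    richness: int
    t_mean: float
    t_max: float
    units: str                      # "subs_per_site" or "Myr"
    arr: float | None               # richness / t_max; None when undefined
    n_sequenced: int


def node_ages(tree: UltrametricTree, tol: float = ULTRAMETRIC_TOL) -> list[float]:
    """Heights of all internal nodes of an ultrametric tree (leaves excluded)."""
    if len(tree.leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    tree.validate(tol=tol)
    return [n.height for n in tree.internal_nodes()]


def divergence_summaries(heights: list[float]) -> tuple[float, float]:
    """(mean node divergence, maximum node divergence) of internal heights."""
    if len(heights) == 0:
        raise ValueError("no internal node heights")
    arr = np.asarray(heights, dtype=float)
    return float(arr.mean()), float(arr.max())


def to_time(height: float, clock: ClockModel) -> float:
    """Convert a per-lineage substitution height to Myr under a strict clock."""
    if height < 0:
        raise ValueError("height must be non-negative")
    return height / clock.rate


def genus_pipeline(
    species_seqs: AlignedSequenceSet,
    grouping: pd.DataFrame,
    richness: pd.DataFrame,
    clock: ClockModel | dict[str, ClockModel] | None = None,
    distance_model: str = "P_DIST",
) -> tuple[list[GenusDiversification], list[str]]:
    """Node-divergence summaries and ARR for every genus unit.

    ``species_seqs`` holds one sequence per species (ids = species names);
    ``grouping`` maps ``species`` to ``genus_unit``, ``order`` and
    ``dispersal`` (genus partitioning by colonization event is the caller's
    responsibility, expressed through the genus_unit column); ``richness``
    maps ``genus_unit`` to endemic species count ``S``.  ``clock`` converts
    heights to Myr — either one model for all genera or a per-genus_unit
    dict; None leaves heights in substitutions/site.

    Returns (results, skipped genus units).  Genera with fewer than two
    sequenced species are skipped; a genus of identical sequences has
    t_max = 0 and an undefined (None) ARR.
    """
    grouping = grouping.set_index("species") if "species" in grouping.columns else grouping
    rich = richness.set_index("genus_unit")["S"] if "genus_unit" in richness.columns else richness
    results: list[GenusDiversification] = []
    skipped: list[str] = []
    for unit, members in grouping.groupby("genus_unit"):
        species = [s for s in members.index if s in set(species_seqs.ids)]
        if len(species) < 2:
            skipped.append(str(unit))
            continue
        sub = species_seqs.subset(species)
        tree = upgma(distance_matrix(sub, model=distance_model))
        t_mean, t_max = divergence_summaries(node_ages(tree))
        units = "subs_per_site"
        if clock is not None:
            model = clock[unit] if isinstance(clock, dict) else clock
            t_mean, t_max = to_time(t_mean, model), to_time(t_max, model)
            units = "Myr"
        S = int(rich.loc[unit])
        arr = S / t_max if t_max > 0 and S >= 2 else None
        results.append(
            GenusDiversification(
                genus_unit=str(unit),
                order=str(members["order"].iloc[0]),
                dispersal=str(members["dispersal"].iloc[0]),
                richness=S,
                t_mean=t_mean,
                t_max=t_max,
                units=units,
                arr=arr,
                n_sequenced=len(species),
            )
        )
    return results, skipped


def normalize01(values) -> np.ndarray:
    """Min-max scale values to [0, 1]; errors if fewer than 2 or all equal.

    Intended to be applied within each order separately, since substitution
    and richness scales differ between orders.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ValueError("need at least 2 finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("all values equal; normalization undefined")
    return (arr - lo) / (hi - lo)


def results_to_frame(results: list[GenusDiversification]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "genus_unit": [r.genus_unit for r in results],
            "order": [r.order for r in results],
            "dispersal": [r.dispersal for r in results],
            "S": [r.richness for r in results],
            "n_sequenced": [r.n_sequenced for r in results],
            "t_mean": [r.t_mean for r in results],
            "t_max": [r.t_max for r in results],
            "units": [r.units for r in results],
            "arr": [r.arr for r in results],
        }
    )
    df["arr_norm"] = np.nan
    for order, grp in df.groupby("order"):
        vals = grp["arr"].astype(float)
        ok = vals.notna()
        if ok.sum() >= 2 and vals[ok].nunique() > 1:
            df.loc[vals[ok].index, "arr_norm"] = normalize01(vals[ok].to_numpy())
    return df


def coverage_report(counts: dict[str, tuple[int, int]], decimals: int = 0) -> dict[str, float]:
    """Percentages a/b for sampling-coverage tallies.

    ``counts`` maps a name to (numerator, denominator); values are rounded
    half-up to ``decimals`` places (0 for richness/genera coverage, 1 for
    assignment rates).  A zero denominator is an error.
    """
    out = {}
    for name, (a, b) in counts.items():
        if a > b:
            raise ValueError(f"{name}: count {a} exceeds total {b}")
        out[name] = percentage(a, b, decimals)
    return out
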