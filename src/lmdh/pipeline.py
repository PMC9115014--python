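"""End-to-end study analysis and replicated simulation experiments.

Chains the stages over a synthetic (or real-format) survey: per-order
lineage delimitation, fixation-index scan at all spatial scales, and the
dispersal-category comparison of N_ST.  Also provides the replicated
experiments used for calibration: mean G_ST as a function of migration rate,
the direction of the category effect under the strong-effect preset, and the
type-I error of the category test under the null preset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import rand_score

from .comparative import wilcoxon_rank_sum
from .delimitation import DEFAULT_THRESHOLDS, LineagePartition, delimit
from .seq_distance import AlignedSequenceSet
from .structure import (
    HaplotypeFrequencyTable,
    build_table,
    _drop_small_pops,
    gst,
    haplotype_delta,
    nst,
    results_to_frame,
    structure_scan,
)
from .synthetic_data import (
    SimulationConfig,
    SyntheticStudy,
    _fresh_seed,
    decode,
    evolve_sequences,
    simulate_genealogy,
    simulate_study,
)

__all__ = [
    "delimit_study",
    "analyze_study",
    "per_lineage_mean_nst",
    "simulate_lineage_fixation",
    "mean_gst_by_migration",
    "direction_rate",
    "null_rejection_rate",
]


def delimit_study(
    seqs: AlignedSequenceSet, thresholds: dict[str, float] | None = None
) -> LineagePartition:
    """Delimit lineages separately per order, at per-order thresholds.

    Thresholds default to 6.8% for spiders and 5% for beetles (cophenetic
    K2P divergence).  Lineage ids are prefixed by order so the combined
    partition has unique ids.
    """
    if seqs.metadata is None:
        raise ValueError("sequences must carry metadata")
    thresholds = thresholds or DEFAULT_THRESHOLDS
    assignment: dict[str, str] = {}
    tau_used = []
    for order in sorted(set(seqs.metadata["order"])):
        ids = [sid for sid in seqs.ids if seqs.metadata.loc[sid, "order"] == order]
        tau = thresholds[order]
        tau_used.append(tau)
        part, _ = delimit(seqs.subset(ids), tau, prefix=f"{order[:2].upper()}_")
        assignment.update(part.assignment)
    return LineagePartition(threshold=max(tau_used), assignment=assignment)


def per_lineage_mean_nst(fixation: pd.DataFrame, within_island_only: bool = True) -> pd.Series:
    """One N_ST value per lineage: the mean over its defined scale results.

    Within-island scales carry the strongest dispersal signal; the
    archipelago scale can be included by setting ``within_island_only``
    False.  Lineages with no defined result are absent from the output.
    """
    df = fixation[fixation["defined"]]
    if within_island_only:
        df = df[df["scale"] != "archipelago"]
    return df.groupby("lmdh_id")["NST"].mean()


def analyze_study(
    study: SyntheticStudy,
    thresholds: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Full pipeline over one synthetic study.

    Returns the partition, its Rand index against the generating truth, the
    fixation table, per-category mean N_ST (per-lineage means at the
    within-island scales), and the Wilcoxon comparison between categories.
    """
    partition = delimit_study(study.seqs, thresholds)
    truth = study.truth["specimens"].set_index("specimen_id")["true_lineage"]
    labels_pred = [partition.assignment[sid] for sid in study.seqs.ids]
    labels_true = [truth.loc[sid] for sid in study.seqs.ids]
    ri = float(rand_score(labels_true, labels_pred))

    fixation = results_to_frame(structure_scan(partition, study.seqs))
    lineage_nst = per_lineage_mean_nst(fixation)

    meta = study.seqs.metadata
    lineage_cat = {
        lid: meta.loc[members, "dispersal"].iloc[0]
        for lid, members in partition.lineages.items()
    }
    cat = lineage_nst.index.map(lineage_cat)
    nd = lineage_nst[cat == "non_dispersive"].to_numpy()
    dd = lineage_nst[cat == "dispersive"].to_numpy()
    comparison = None
    if nd.size and dd.size:
        comparison = wilcoxon_rank_sum(nd, dd)
    return {
        "partition": partition,
        "rand_index": ri,
        "fixation": fixation,
        "mean_nst_non_dispersive": float(nd.mean()) if nd.size else float("nan"),
        "mean_nst_dispersive": float(dd.mean()) if dd.size else float("nan"),
        "wilcoxon": comparison,
        "significant": bool(comparison and comparison.p_two_sided < alpha),
    }


def simulate_lineage_fixation(
    config: SimulationConfig,
    migration: float,
    rng: np.random.Generator,
    scale: str = "archipelago",
    theta_site: float | None = None,
) -> tuple[float | None, float | None]:
    """(G_ST, N_ST) for one simulated lineage, demes grouped by scale.

    ``scale`` "archipelago" pools each island's sites into one population;
    "site" treats every deme as a population.  Returns (None, None) when the
    lineage is monomorphic (indices undefined).
    """
    theta = config.theta_site if theta_site is None else theta_site
    genealogy, demes = simulate_genealogy(
        config.n_demes, config.samples_per_site, migration, _fresh_seed(rng)
    )
    seq_map = evolve_sequences(genealogy, config.seq_length, theta, config.kappa, rng)
    ids = sorted(seq_map, key=int)
    seqs = AlignedSequenceSet(
        ids=ids,
        sequences=[decode(seq_map[i]) for i in ids],
        alignment_length=config.seq_length,
    )
    if scale == "archipelago":
        pops = [str(demes[int(i)] // config.sites_per_island) for i in ids]
    elif scale == "site":
        pops = [str(demes[int(i)]) for i in ids]
    else:
        raise ValueError(f"unknown scale {scale!r}")
    table = _drop_small_pops(build_table(seqs, ids, pd.Series(pops, index=ids)))
    if table.K < 2:
        return None, None
    g, _, _ = gst(table)
    n_st, _, _ = nst(table, haplotype_delta(table))
    return g, n_st


def mean_gst_by_migration(
    migrations: list[float],
    n_reps: int,
    seed: int,
    config: SimulationConfig | None = None,
    theta_site: float = 2e-4,
) -> dict[float, float]:
    """Mean G_ST over replicate single-lineage simulations per migration rate.

    theta is raised above the study default so nearly every replicate is
    polymorphic; undefined replicates are excluded from the mean.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    for M in migrations:
        vals = []
        for _ in range(n_reps):
            g, _ = simulate_lineage_fixation(config, M, rng, scale="site",
                                             theta_site=theta_site)
            if g is not None:
                vals.append(g)
        out[M] = float(np.mean(vals))
    return out


def direction_rate(config: SimulationConfig, n_reps: int, seed: int) -> float:
    """Fraction of replicate studies where mean N_ST (non-dispersive) exceeds
    mean N_ST (dispersive) after the full pipeline."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        res = analyze_study(simulate_study(config, _fresh_seed(rng)))
        if res["mean_nst_non_dispersive"] > res["mean_nst_dispersive"]:
            hits += 1
    return hits / n_reps


def null_rejection_rate(
    config: SimulationConfig, n_reps: int, seed: int, alpha: float = 0.05
) -> float:
    """Fraction of replicate studies rejecting the category Wilcoxon test.

    With both categories sharing one migration rate this estimates the
    pipeline's type-I error at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        res = analyze_study(simulate_study(config, _fresh_seed(rng)), alpha=alpha)
        if res["significant"]:
            rejections += 1
    return rejections / n_reps
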