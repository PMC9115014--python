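"""Haplotype fixation indices G_ST and N_ST within delimited lineages.

G_ST uses haplotype frequencies only ("unordered alleles"); N_ST weights
haplotype pairs by a genetic distance delta ("ordered alleles"), so
N_ST > G_ST indicates phylogeographically structured variation.  Both use
unbiased within-population diversity estimators with equal population
weighting and the h_S/(n~ K) correction to total diversity, where n~ is the
harmonic mean sample size.

Populations are sampling sites (within-island scale) or islands
(archipelago scale).  A lineage enters the analysis only if, after dropping
populations with fewer than two sampled individuals, it retains at least two
populations and more than three individuals in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_distance import AlignedSequenceSet, DistanceMatrix, distance_matrix
from .delimitation import LineagePartition

__all__ = [
    "HaplotypeFrequencyTable",
    "FixationResult",
    "collapse_haplotypes",
    "filter_lineages",
    "gst",
    "nst",
    "nst_permutation_null",
    "structure_scan",
    "results_to_frame",
]

MIN_POP_SIZE = 2         # n_k/(n_k - 1) correction needs n_k >= 2
MIN_TOTAL = 4            # "more than three individuals"
MIN_POPULATIONS = 2


@dataclass
class HaplotypeFrequencyTable:
    """Haplotype counts per population for one lineage.

    counts[k, i] = copies of haplotype i in population k.  Representative
    sequences (first member by specimen label) index the distance matrix used
    by N_ST.
    """

    haplotypes: list[str]          # representative specimen ids
    sequences: list[str]           # representative sequences (masked columns removed)
    populations: list[str]
    counts: np.ndarray             # (K, H) int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.populations), len(self.haplotypes)):
            raise ValueError("counts shape does not match labels")

    @property
    def n_k(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def K(self) -> int:
        return len(self.populations)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def harmonic_mean_n(self) -> float:
        n_k = self.n_k
        return float(len(n_k) / np.sum(1.0 / n_k))


@dataclass
class FixationResult:
    lmdh_id: str
    scale: str                     # "island:<name>" or "archipelago"
    gst: float | None
    nst: float | None
    h_s: float
    h_t: float
    v_s: float | None
    v_t: float | None
    K: int
    n_total: int
    defined: bool


def collapse_haplotypes(seqs: AlignedSequenceSet, ids: list[str] | None = None) -> tuple[
    list[str], list[str], dict[str, str]
]:
    """Collapse a lineage's sequences into haplotypes by exact match.

    Alignment columns that are not A/C/G/T in *every* member are dropped
    lineage-wide before comparison.  Returns (representative ids,
    representative masked sequences, specimen_id -> representative id).
    Raises if every column is masked.
    """
    sub = seqs if ids is None else seqs.subset(ids)
    codes = sub.codes
    keep = np.all(codes != 255, axis=0)
    if not keep.any():
        raise ValueError("all alignment columns masked within lineage")
    masked = codes[:, keep]
    reps: list[str] = []
    rep_seqs: list[str] = []
    mapping: dict[str, str] = {}
    seen: dict[bytes, str] = {}
    letters = np.array(list("AGCT"))
    for sid, row in zip(sub.ids, masked):
        key = row.tobytes()
        if key not in seen:
            seen[key] = sid
            reps.append(sid)
            rep_seqs.append("".join(letters[row]))
        mapping[sid] = seen[key]
    return reps, rep_seqs, mapping


def build_table(
    seqs: AlignedSequenceSet, ids: list[str], populations: pd.Series
) -> HaplotypeFrequencyTable:
    """Haplotype frequency table for one lineage over given population labels."""
    reps, rep_seqs, mapping = collapse_haplotypes(seqs, ids)
    pops = sorted(set(populations.loc[ids]))
    hap_index = {h: i for i, h in enumerate(reps)}
    pop_index = {p: k for k, p in enumerate(pops)}
    counts = np.zeros((len(pops), len(reps)), dtype=np.int64)
    for sid in ids:
        counts[pop_index[populations.loc[sid]], hap_index[mapping[sid]]] += 1
    return HaplotypeFrequencyTable(
        haplotypes=reps, sequences=rep_seqs, populations=pops, counts=counts
    )


def _drop_small_pops(table: HaplotypeFrequencyTable) -> HaplotypeFrequencyTable:
    keep = table.n_k >= MIN_POP_SIZE
    counts = table.counts[keep]
    used = counts.sum(axis=0) > 0
    return HaplotypeFrequencyTable(
        haplotypes=[h for h, u in zip(table.haplotypes, used) if u],
        sequences=[s for s, u in zip(table.sequences, used) if u],
        populations=[p for p, k in zip(table.populations, keep) if k],
        counts=counts[:, used],
    )


def filter_lineages(
    partition: LineagePartition,
    metadata: pd.DataFrame,
    scale: str,
) -> list[str]:
    """Lineages eligible for fixation indices at a spatial scale.

    ``scale`` is "archipelago" (populations = islands) or "island:<name>"
    (populations = that island's sites, using only that island's specimens).
    Populations below ``MIN_POP_SIZE`` are dropped first; a lineage is kept
    with >= 2 retained populations and > 3 retained individuals.
    """
    meta = metadata
    if "specimen_id" in meta.columns:
        meta = meta.set_index("specimen_id")
    pop_col, mask = _scale_populations(meta, scale)
    eligible = []
    for lid, members in partition.lineages.items():
        ids = [m for m in members if mask.loc[m]]
        if not ids:
            continue
        sizes = pop_col.loc[ids].value_counts()
        sizes = sizes[sizes >= MIN_POP_SIZE]
        if len(sizes) >= MIN_POPULATIONS and sizes.sum() >= MIN_TOTAL:
            eligible.append(lid)
    return eligible


def _scale_populations(meta: pd.DataFrame, scale: str) -> tuple[pd.Series, pd.Series]:
    if scale == "archipelago":
        return meta["island"], pd.Series(True, index=meta.index)
    if scale.startswith("island:"):
        island = scale.split(":", 1)[1]
        return meta["site"], meta["island"] == island
    raise ValueError(f"unknown scale: {scale!r}")


def gst(table: HaplotypeFrequencyTable) -> tuple[float | None, float, float]:
    """G_ST = (h_T - h_S)/h_T from haplotype frequencies.

    h_k is the unbiased within-population gene diversity, h_S their
    unweighted mean, and h_T the diversity of mean frequencies plus the
    h_S/(n~ K) sampling correction.  Returns (G_ST, h_S, h_T); G_ST is None
    (undefined) when h_T <= 0.
    """
    n_k = table.n_k
    if np.any(n_k < MIN_POP_SIZE) or table.K < 2:
        raise ValueError("table must have K >= 2 populations with n_k >= 2")
    p = table.counts / n_k[:, None]
    h_k = n_k / (n_k - 1.0) * (1.0 - np.sum(p**2, axis=1))
    h_s = float(h_k.mean())
    p_bar = p.mean(axis=0)
    h_t = float(1.0 - np.sum(p_bar**2) + h_s / (table.harmonic_mean_n * table.K))
    if h_t <= 0.0:
        return None, h_s, h_t
    return (h_t - h_s) / h_t, h_s, h_t


def nst(
    table: HaplotypeFrequencyTable, delta: np.ndarray
) -> tuple[float | None, float | None, float | None]:
    """N_ST: fixation index with haplotype pairs weighted by distance delta.

    v_k = n_k/(n_k-1) sum_ij p_ki p_kj delta_ij; v_S is the unweighted mean;
    v_T = sum_ij pbar_i pbar_j delta_ij + v_S/(n~ K).  With delta_ij = 1 for
    all i != j this reduces exactly to G_ST.  Returns (N_ST, v_S, v_T); N_ST
    is None when v_T <= 0.
    """
    delta = np.asarray(delta, dtype=np.float64)
    H = len(table.haplotypes)
    if delta.shape != (H, H):
        raise ValueError("delta shape does not match haplotype count")
    if not np.allclose(delta, delta.T):
        raise ValueError("delta must be symmetric")
    if np.any(np.abs(np.diag(delta)) > 0):
        raise ValueError("delta must have a zero diagonal")
    n_k = table.n_k
    if np.any(n_k < MIN_POP_SIZE) or table.K < 2:
        raise ValueError("table must have K >= 2 populations with n_k >= 2")
    p = table.counts / n_k[:, None]
    v_k = n_k / (n_k - 1.0) * np.einsum("ki,kj,ij->k", p, p, delta)
    v_s = float(v_k.mean())
    p_bar = p.mean(axis=0)
    v_t = float(p_bar @ delta @ p_bar + v_s / (table.harmonic_mean_n * table.K))
    if v_t <= 0.0:
        return None, v_s, v_t
    return (v_t - v_s) / v_t, v_s, v_t


def haplotype_delta(table: HaplotypeFrequencyTable, model: str = "K2P") -> np.ndarray:
    """Distance matrix between haplotype representatives for N_ST."""
    if len(table.haplotypes) == 1:
        return np.zeros((1, 1))
    sub = AlignedSequenceSet(
        ids=list(table.haplotypes),
        sequences=list(table.sequences),
        alignment_length=len(table.sequences[0]),
    )
    return distance_matrix(sub, model=model).d


def nst_permutation_null(
    table: HaplotypeFrequencyTable,
    delta: np.ndarray,
    reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Null distribution of N_ST under random relabelling of haplotypes.

    Permuting haplotype identities over the rows/columns of delta destroys
    any association between haplotype relatedness and geography while keeping
    the frequency structure, so the permuted N_ST behaves like G_ST.  Returns
    the observed N_ST, the null mean/sd, and the observed value's rank
    quantile within the null.
    """
    if reps < 100:
        raise ValueError("need at least 100 permutation replicates")
    H = len(table.haplotypes)
    if H < 3:
        raise ValueError("need at least 3 haplotypes to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed, _, _ = nst(table, delta)
    null = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(H)
        null[r], _, _ = nst(table, delta[np.ix_(perm, perm)])
    rank = float(np.mean(null < observed)) if observed is not None else float("nan")
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "rank_quantile": rank,
        "null": null,
    }


def structure_scan(
    partition: LineagePartition,
    seqs: AlignedSequenceSet,
    scales: list[str] | None = None,
    delta_model: str = "K2P",
) -> list[FixationResult]:
    """G_ST and N_ST for every eligible lineage at every requested scale.

    ``scales`` defaults to the archipelago plus every island present in the
    metadata.  Negative estimates are reported as computed; lineages whose
    total diversity is <= 0 are emitted with ``defined=False``.
    """
    if seqs.metadata is None:
        raise ValueError("sequences must carry metadata (attach_metadata)")
    meta = seqs.metadata
    if scales is None:
        scales = ["archipelago"] + [f"island:{i}" for i in sorted(set(meta["island"]))]
    results: list[FixationResult] = []
    for scale in scales:
        pop_col, mask = _scale_populations(meta, scale)
        for lid in filter_lineages(partition, meta, scale):
            ids = [m for m in partition.lineages[lid] if mask.loc[m]]
            table = _drop_small_pops(build_table(seqs, ids, pop_col))
            g, h_s, h_t = gst(table)
            delta = haplotype_delta(table, model=delta_model)
            n_st, v_s, v_t = nst(table, delta)
            results.append(
                FixationResult(
                    lmdh_id=lid,
                    scale=scale,
                    gst=g,
                    nst=n_st,
                    h_s=h_s,
                    h_t=h_t,
                    v_s=v_s,
                    v_t=v_t,
                    K=table.K,
                    n_total=table.n_total,
                    defined=g is not None and n_st is not None,
                )
            )
    return results


def results_to_frame(results: list[FixationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lmdh_id": [r.lmdh_id for r in results],
            "scale": [r.scale for r in results],
            "K": [r.K for r in results],
            "n_total": [r.n_total for r in results],
            "GST": [r.gst for r in results],
            "NST": [r.nst for r in results],
            "hS": [r.h_s for r in results],
            "hT": [r.h_t for r in results],
            "vS": [r.v_s for r in results],
            "vT": [r.v_t for r in results],
            "defined": [r.defined for r in results],
        }
    )
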