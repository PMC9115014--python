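"""Synthetic island-survey generator for the whole pipeline.

Emulates the statistical structure the analysis assumes: mtDNA lineages
sampled from sites nested in islands, within-lineage gene flow governed by a
dispersal category (scaled migration rate M, lower for non-dispersive
lineages), between-lineage divergence imposed well above the delimitation
threshold, and genus-level richness/crown-age tables for the
diversification side.

Genealogies follow the finite-island structured coalescent (msprime): within
a deme, k lineages coalesce at rate k(k-1)/2; each lineage migrates to a
uniformly chosen other deme at total rate M/2.  Time is in units of deme-size
generations; M is the composite migration parameter.  Sequences evolve along
genealogies under the Kimura 2-parameter jump process: substitution events
are Poisson with rate theta_site per site per time unit, each event hits a
uniform site and is a transition with probability kappa/(kappa+2),
transversions splitting evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import pandas as pd

from .delimitation import TreeNode
from .seq_distance import AlignedSequenceSet, attach_metadata

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "strong_effect_config",
    "null_effect_config",
    "simulate_genealogy",
    "evolve_sequences",
    "mutate_sequence",
    "simulate_study",
    "random_ultrametric_tree",
    "write_study",
    "decode",
]

_LETTERS = np.array(list("AGCT"))

# per-order strict-clock rates used for the synthetic genus alignments
# (COIa region; substitutions/site/Myr per lineage)
GENUS_CLOCK_RATES = {"spider": 0.0125, "beetle": 0.0168}


def decode(codes: np.ndarray) -> str:
    return "".join(_LETTERS[codes])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults are the strong-effect conditions: four islands of three sites
    with four specimens per site per lineage, twenty lineages per dispersal
    category (split between spiders and beetles), migration M = 20 for
    dispersive and M = 0.2 for non-dispersive lineages, a 658 bp COI-like
    locus with theta_site tuned so intra-lineage divergence sits around
    0.3-1.5% (typical intraspecific barcode variation, far below the
    delimitation threshold), and a 0.15 substitutions/site backbone
    separation between lineages (far above it).
    """

    n_islands: int = 4
    sites_per_island: int = 3
    samples_per_site: int = 4
    n_lineages_per_category: int = 20
    m_dispersive: float = 20.0
    m_non_dispersive: float = 0.2
    seq_length: int = 658
    theta_site: float = 5e-5
    kappa: float = 2.0
    d_sep: float = 0.15
    threshold: float = 0.068
    n_genera_per_category: int = 15
    richness_mean_dispersive: float = 2.93
    richness_mean_non_dispersive: float = 5.65
    crown_age_range: tuple[float, float] = (0.5, 6.0)

    def __post_init__(self) -> None:
        if min(self.m_dispersive, self.m_non_dispersive, self.theta_site, self.d_sep) <= 0:
            raise ValueError("rates must be positive")

    @property
    def n_demes(self) -> int:
        return self.n_islands * self.sites_per_island

    @property
    def islands(self) -> list[str]:
        return [f"I{i + 1}" for i in range(self.n_islands)]

    @property
    def sites(self) -> list[str]:
        return [
            f"{isl}-{chr(65 + s)}"
            for isl in self.islands
            for s in range(self.sites_per_island)
        ]


def strong_effect_config(**overrides) -> SimulationConfig:
    """The default preset: dispersal categories differ strongly in M."""
    return SimulationConfig(**overrides)


def null_effect_config(m: float = 2.0, **overrides) -> SimulationConfig:
    """Null preset: both categories share the same migration rate."""
    return replace(SimulationConfig(**overrides), m_dispersive=m, m_non_dispersive=m)


def _fresh_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31))


def simulate_genealogy(
    n_demes: int,
    samples_per_deme: int | list[int],
    migration: float,
    seed: int,
    labels: list[str] | None = None,
) -> tuple[TreeNode, list[int]]:
    """Finite-island structured-coalescent genealogy.

    Each deme has size 1 (haploid), so k lineages within a deme coalesce at
    rate k(k-1)/2; each lineage leaves its deme at total rate M/2, choosing
    the destination uniformly.  Returns the rooted genealogy (TreeNode with
    heights = coalescent times) and the deme index of each sample, in sample
    order.  Deterministic given ``seed``.
    """
    if isinstance(samples_per_deme, int):
        samples_per_deme = [samples_per_deme] * n_demes
    if len(samples_per_deme) != n_demes:
        raise ValueError("samples_per_deme length must equal n_demes")
    n = int(sum(samples_per_deme))
    if n < 2:
        raise ValueError("need at least 2 samples in total")
    per_pair = migration / (2.0 * (n_demes - 1)) if n_demes > 1 else 0.0
    demography = msprime.Demography.island_model([1.0] * n_demes, migration_rate=per_pair)
    ts = msprime.sim_ancestry(
        samples={i: k for i, k in enumerate(samples_per_deme)},
        demography=demography,
        ploidy=1,
        random_seed=seed,
    )
    tree = ts.first()
    if labels is None:
        labels = [str(i) for i in range(n)]

    def build(u: int) -> TreeNode:
        children = tree.children(u)
        if not children:
            return TreeNode(height=tree.time(u), label=labels[u])
        return TreeNode(height=tree.time(u), children=tuple(build(c) for c in children))

    demes = [ts.node(i).population for i in range(n)]
    return build(tree.root), demes


def mutate_sequence(
    seq: np.ndarray, n_events: int, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply ``n_events`` K2P substitution events to an encoded sequence."""
    if n_events == 0:
        return seq
    s = seq.copy()
    L = s.size
    sites = rng.integers(0, L, size=n_events)
    is_transition = rng.random(n_events) < kappa / (kappa + 2.0)
    tv_pick = rng.integers(0, 2, size=n_events)
    for site, ts_event, pick in zip(sites, is_transition, tv_pick):
        b = s[site]
        if ts_event:
            s[site] = b ^ 1
        else:
            s[site] = (1 - (b >> 1)) * 2 + pick
    return s


def evolve_sequences(
    root: TreeNode,
    seq_length: int,
    theta_site: float,
    kappa: float,
    rng: np.random.Generator,
    root_seq: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Evolve sequences down a genealogy under the K2P jump process.

    The root sequence is uniform over {A,C,G,T}^L unless supplied.  Per
    branch, the substitution count is Poisson(theta_site * L * branch
    length).  Returns encoded sequences keyed by leaf label.
    """
    if root_seq is None:
        root_seq = rng.integers(0, 4, size=seq_length, dtype=np.uint8)
    out: dict[str, np.ndarray] = {}
    stack: list[tuple[TreeNode, np.ndarray]] = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf:
            out[node.label] = seq
            continue
        for child in node.children:
            bl = node.height - child.height
            n_events = int(rng.poisson(theta_site * seq_length * bl))
            stack.append((child, mutate_sequence(seq, n_events, kappa, rng)))
    return out


def random_ultrametric_tree(
    labels: list[str], crown_age: float, rng: np.random.Generator
) -> TreeNode:
    """Random ultrametric tree with a fixed crown (root) age.

    The deepest split is at ``crown_age``; the remaining n-2 split times are
    uniform on (0, crown_age); join order is random.  A neutral stand-in for
    a within-genus species tree with known crown age.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 tips")
    heights = np.sort(rng.uniform(0.0, crown_age, size=n - 2)) if n > 2 else np.array([])
    heights = np.append(heights, crown_age)
    nodes: list[TreeNode] = [TreeNode(height=0.0, label=lab) for lab in labels]
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(height=float(h), children=(nodes[i], nodes[j]))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


@dataclass
class SyntheticStudy:
    """A complete synthetic dataset plus its generating truth."""

    seqs: AlignedSequenceSet                 # specimen alignment with metadata
    metadata: pd.DataFrame
    genus_seqs: AlignedSequenceSet | None    # one sequence per species
    genus_grouping: pd.DataFrame
    richness: pd.DataFrame                   # genus_unit, S
    truth: dict = field(default_factory=dict)


def simulate_study(config: SimulationConfig, seed: int) -> SyntheticStudy:
    """Generate a full synthetic survey under ``config``.

    Lineages alternate between spiders and beetles within each dispersal
    category; every lineage is sampled at every site.  Between-lineage
    divergence is imposed by placing each lineage's root Poisson(L*d_sep/2)
    substitutions from a per-order ancestral sequence (a star backbone), so
    between-lineage distances concentrate around d_sep and never approach the
    threshold from below.  Genus richness tables are drawn per category with
    the non-dispersive mean exceeding the dispersive mean, and genus
    alignments are evolved on random ultrametric trees with known crown ages.
    """
    rng = np.random.default_rng(seed)
    L = config.seq_length
    n_demes = config.n_demes
    sites = config.sites
    site_to_island = {s: s.split("-")[0] for s in sites}

    lineage_specs = []
    idx = 0
    for category, M in (
        ("non_dispersive", config.m_non_dispersive),
        ("dispersive", config.m_dispersive),
    ):
        for i in range(config.n_lineages_per_category):
            order = "spider" if i % 2 == 0 else "beetle"
            lineage_specs.append({"lineage": f"L{idx:03d}", "order": order,
                                  "category": category, "M": M})
            idx += 1

    ancestral = {order: rng.integers(0, 4, size=L, dtype=np.uint8)
                 for order in ("spider", "beetle")}

    ids: list[str] = []
    sequences: list[str] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    specimen_counter = 0
    for spec in lineage_specs:
        lineage_root = mutate_sequence(
            ancestral[spec["order"]],
            int(rng.poisson(L * config.d_sep / 2.0)),
            config.kappa,
            rng,
        )
        n_samples = n_demes * config.samples_per_site
        labels = []
        for site in sites:
            for _ in range(config.samples_per_site):
                labels.append(f"{spec['order'][:2].upper()}{specimen_counter:05d}")
                specimen_counter += 1
        genealogy, demes = simulate_genealogy(
            n_demes, config.samples_per_site, spec["M"], _fresh_seed(rng), labels=labels
        )
        seq_map = evolve_sequences(
            genealogy, L, config.theta_site, config.kappa, rng, root_seq=lineage_root
        )
        for k, lab in enumerate(labels):
            site = sites[demes[k]]
            ids.append(lab)
            sequences.append(decode(seq_map[lab]))
            meta_rows.append(
                {
                    "specimen_id": lab,
                    "site": site,
                    "island": site_to_island[site],
                    "order": spec["order"],
                    "genus": f"gen_{spec['lineage']}",
                    "species": f"sp_{spec['lineage']}",
                    "dispersal": spec["category"],
                }
            )
            truth_rows.append({"specimen_id": lab, "true_lineage": spec["lineage"]})
        assert n_samples == len(labels)

    metadata = pd.DataFrame(meta_rows)
    seqs = AlignedSequenceSet(ids=ids, sequences=sequences, alignment_length=L)
    seqs = attach_metadata(seqs, metadata)

    # --- genus-level diversification tables ---
    genus_ids: list[str] = []
    genus_sequences: list[str] = []
    grouping_rows: list[dict] = []
    richness_rows: list[dict] = []
    genus_truth_rows: list[dict] = []
    g_idx = 0
    for category, mean_S in (
        ("non_dispersive", config.richness_mean_non_dispersive),
        ("dispersive", config.richness_mean_dispersive),
    ):
        for i in range(config.n_genera_per_category):
            order = "spider" if i % 2 == 0 else "beetle"
            unit = f"G{g_idx:03d}"
            g_idx += 1
            S = 1 + int(rng.poisson(mean_S - 1.0))
            richness_rows.append({"genus_unit": unit, "S": S})
            row = {"genus_unit": unit, "order": order, "dispersal": category,
                   "S": S, "crown_age": np.nan}
            if S >= 2:
                crown = float(rng.uniform(*config.crown_age_range))
                row["crown_age"] = crown
                species = [f"{unit}_sp{j}" for j in range(S)]
                tree = random_ultrametric_tree(species, crown, rng)
                rate = GENUS_CLOCK_RATES[order]
                seq_map = evolve_sequences(tree, L, rate, config.kappa, rng)
                for sp in species:
                    genus_ids.append(sp)
                    genus_sequences.append(decode(seq_map[sp]))
                    grouping_rows.append(
                        {"species": sp, "genus_unit": unit, "order": order,
                         "dispersal": category}
                    )
            genus_truth_rows.append(row)

    genus_seqs = (
        AlignedSequenceSet(ids=genus_ids, sequences=genus_sequences, alignment_length=L)
        if genus_ids
        else None
    )
    truth = {
        "specimens": pd.DataFrame(truth_rows),
        "lineages": pd.DataFrame(lineage_specs),
        "genera": pd.DataFrame(genus_truth_rows),
    }
    return SyntheticStudy(
        seqs=seqs,
        metadata=metadata,
        genus_seqs=genus_seqs,
        genus_grouping=pd.DataFrame(grouping_rows),
        richness=pd.DataFrame(richness_rows),
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write FASTA/TSV artefacts (byte-identical for a fixed seed)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "sequences.fasta", "w") as fh:
        for sid, seq in zip(study.seqs.ids, study.seqs.sequences):
            fh.write(f">{sid}\n{seq}\n")
    study.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    study.richness.to_csv(out / "richness.tsv", sep="\t", index=False)
    study.genus_grouping.to_csv(out / "genus_grouping.tsv", sep="\t", index=False)
    if study.genus_seqs is not None:
        with open(out / "genus_sequences.fasta", "w") as fh:
            for sid, seq in zip(study.genus_seqs.ids, study.genus_seqs.sequences):
                fh.write(f">{sid}\n{seq}\n")
    study.truth["specimens"].to_csv(out / "truth_specimens.tsv", sep="\t", index=False)
    study.truth["lineages"].to_csv(out / "truth_lineages.tsv", sep="\t", index=False)
    study.truth["genera"].to_csv(out / "truth_genera.tsv", sep="\t", index=False)
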