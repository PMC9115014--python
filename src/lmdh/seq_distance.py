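"""Aligned mtDNA sequences, specimen metadata, and pairwise genetic distances.

Two distance models are provided: Kimura 2-parameter (K2P), which corrects
for multiple hits while distinguishing transitions (A<->G, C<->T) from
transversions, and the uncorrected p-distance (proportion of mismatching
sites).  Both use pairwise deletion: any alignment column where either
sequence carries a gap, N or other ambiguity code is excluded for that pair
only.  Ambiguity codes are never fractionally matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedSequenceSet",
    "DistanceMatrix",
    "AlignmentError",
    "MetadataError",
    "SaturationError",
    "read_fasta",
    "attach_metadata",
    "k2p_distance",
    "p_distance",
    "distance_matrix",
    "encode",
]

DISPERSAL_CATEGORIES = ("dispersive", "non_dispersive", "unassigned")
METADATA_COLUMNS = ["specimen_id", "site", "island", "order", "genus", "species", "dispersal"]

# Base encoding: A=0, G=1, C=2, T=3 so that code >> 1 gives the purine (0) /
# pyrimidine (1) class and code ^ 1 is the transition partner.  Anything that
# is not an unambiguous base encodes as 255 and is dropped by pairwise deletion.
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"AGCT", (0, 1, 2, 3)):
    _CODE[_b] = _c
    _CODE[_b + 32] = _c  # lowercase


class AlignmentError(ValueError):
    """Raised for malformed alignments (length mismatch, duplicate ids, empty)."""


class MetadataError(ValueError):
    """Raised when the specimen metadata table does not match the alignment."""


class SaturationError(ValueError):
    """Raised when the K2P logarithms are undefined (saturated divergence)."""


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as uint8 codes (255 = not A/C/G/T)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignedSequenceSet:
    """Aligned sequences keyed by specimen id, optionally joined to metadata.

    ``metadata`` is a DataFrame indexed by specimen_id with columns
    site, island, order, genus, species, dispersal.
    """

    ids: list[str]
    sequences: list[str]
    alignment_length: int
    metadata: pd.DataFrame | None = None
    _codes: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def codes(self) -> np.ndarray:
        """(n, L) uint8 encoding of the alignment."""
        if self._codes is None:
            self._codes = np.vstack([encode(s) for s in self.sequences])
        return self._codes

    def subset(self, ids: list[str]) -> "AlignedSequenceSet":
        index = {sid: k for k, sid in enumerate(self.ids)}
        rows = [index[i] for i in ids]
        meta = self.metadata.loc[ids] if self.metadata is not None else None
        sub = AlignedSequenceSet(
            ids=list(ids),
            sequences=[self.sequences[r] for r in rows],
            alignment_length=self.alignment_length,
            metadata=meta,
        )
        if self._codes is not None:
            sub._codes = self._codes[rows]
        return sub


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with pairwise-deletion site counts."""

    labels: list[str]
    d: np.ndarray          # (n, n) float, substitutions/site
    sites: np.ndarray      # (n, n) int, retained positions per pair
    model: str             # "K2P" or "P_DIST"

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in distance matrix")

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path, sep="\t")


def read_fasta(path) -> AlignedSequenceSet:
    """Read an aligned FASTA file into an :class:`AlignedSequenceSet`.

    All records must have equal length; ids must be unique; characters are
    uppercased.  Raises :class:`AlignmentError` otherwise.
    """
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AlignmentError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no records in {path}")
    length = len(seqs[0])
    for sid, s in zip(ids, seqs):
        if len(s) != length:
            raise AlignmentError(
                f"sequence {sid!r} has length {len(s)}, expected alignment length {length}"
            )
    return AlignedSequenceSet(ids=ids, sequences=seqs, alignment_length=length)


def attach_metadata(seqs: AlignedSequenceSet, metadata: pd.DataFrame) -> AlignedSequenceSet:
    """Join a specimen metadata table onto an alignment.

    Every specimen id in the alignment must appear exactly once in
    ``metadata`` (a DataFrame with the columns of ``METADATA_COLUMNS``, or
    already indexed by specimen_id).  The dispersal category must be constant
    within each species.
    """
    meta = metadata.copy()
    if "specimen_id" in meta.columns:
        meta = meta.set_index("specimen_id")
    if meta.index.has_duplicates:
        dups = sorted(meta.index[meta.index.duplicated()].unique())
        raise MetadataError(f"duplicate specimen ids in metadata: {dups}")
    missing = [sid for sid in seqs.ids if sid not in meta.index]
    if missing:
        raise MetadataError(f"specimen ids missing from metadata: {missing}")
    meta = meta.loc[seqs.ids]
    bad = meta[~meta["dispersal"].isin(DISPERSAL_CATEGORIES)]
    if len(bad):
        raise MetadataError(f"unknown dispersal categories: {sorted(bad['dispersal'].unique())}")
    per_species = meta.groupby("species")["dispersal"].nunique()
    conflicted = per_species[per_species > 1]
    if len(conflicted):
        raise MetadataError(
            f"conflicting dispersal categories within species: {sorted(conflicted.index)}"
        )
    out = AlignedSequenceSet(
        ids=list(seqs.ids),
        sequences=list(seqs.sequences),
        alignment_length=seqs.alignment_length,
        metadata=meta,
    )
    out._codes = seqs._codes
    return out


def _pair_counts(c1: np.ndarray, c2: np.ndarray) -> tuple[int, int, int]:
    """(retained sites, transitions, transversions) for two encoded sequences."""
    valid = (c1 != 255) & (c2 != 255)
    n = int(valid.sum())
    diff = valid & (c1 != c2)
    ts = int((diff & ((c1 >> 1) == (c2 >> 1))).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def _k2p_from_counts(n: int, ts: int, tv: int, pair: str = "") -> float:
    P, Q = ts / n, tv / n
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError(f"K2P distance undefined (saturation){pair}")
    return float(-0.5 * np.log(a1) - 0.25 * np.log(a2))


def k2p_distance(s1: str, s2: str) -> tuple[float, int]:
    """Kimura 2-parameter distance between two aligned sequences.

    Returns ``(d, sites)`` where ``sites`` is the pairwise-deletion count.
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P, Q the transition and
    transversion proportions over retained sites.
    """
    if len(s1) != len(s2):
        raise AlignmentError("sequences have unequal length")
    n, ts, tv = _pair_counts(encode(s1), encode(s2))
    if n == 0:
        raise AlignmentError("no retained sites for pair (all positions masked)")
    return _k2p_from_counts(n, ts, tv), n


def p_distance(s1: str, s2: str) -> tuple[float, int]:
    """Uncorrected p-distance (mismatches / retained sites) for a pair."""
    if len(s1) != len(s2):
        raise AlignmentError("sequences have unequal length")
    n, ts, tv = _pair_counts(encode(s1), encode(s2))
    if n == 0:
        raise AlignmentError("no retained sites for pair (all positions masked)")
    return (ts + tv) / n, n


def distance_matrix(seqs: AlignedSequenceSet, model: str = "K2P") -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` ("K2P" or "P_DIST").

    Pairwise counts are computed with one-hot matrix products, so the cost is
    a handful of BLAS calls rather than an explicit pair loop.  A saturated
    K2P pair or a pair with zero retained sites raises, naming the pair.
    """
    model = model.upper()
    if model not in ("K2P", "P_DIST"):
        raise ValueError(f"unknown distance model: {model}")
    n = len(seqs)
    if n < 2:
        raise AlignmentError("need at least 2 sequences for a distance matrix")
    codes = seqs.codes
    onehot = [(codes == b).astype(np.float32) for b in range(4)]
    valid = (codes != 255).astype(np.float32)

    sites = valid @ valid.T
    matches = sum(x @ x.T for x in onehot)
    # transitions: A<->G and C<->T
    transitions = (
        onehot[0] @ onehot[1].T + onehot[1] @ onehot[0].T
        + onehot[2] @ onehot[3].T + onehot[3] @ onehot[2].T
    )
    sites = np.rint(sites).astype(np.int64)
    matches = np.rint(matches).astype(np.int64)
    ts = np.rint(transitions).astype(np.int64)
    diff = sites - matches
    tv = diff - ts

    iu = np.triu_indices(n, k=1)
    if np.any(sites[iu] == 0):
        i, j = next(zip(*[idx[sites[iu] == 0] for idx in iu]))
        raise AlignmentError(
            f"no retained sites for pair ({seqs.ids[int(i)]!r}, {seqs.ids[int(j)]!r})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / sites
        Q = tv / sites
        if model == "P_DIST":
            d = diff / sites
        else:
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            bad = (a1 <= 0.0) | (a2 <= 0.0)
            bad[np.diag_indices(n)] = False
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise SaturationError(
                    "K2P distance undefined (saturation) for pair "
                    f"({seqs.ids[int(i)]!r}, {seqs.ids[int(j)]!r})"
                )
            d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float round-off
    return DistanceMatrix(labels=list(seqs.ids), d=d, sites=sites, model=model)
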