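"""G_ST / N_ST estimators, haplotype collapsing, filters and permutations."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_delta, random_hap_table
from lmdh.seq_distance import AlignedSequenceSet, attach_metadata
from lmdh.delimitation import LineagePartition
from lmdh.structure import (
    HaplotypeFrequencyTable,
    collapse_haplotypes,
    filter_lineages,
    gst,
    nst,
    nst_permutation_null,
    results_to_frame,
    structure_scan,
)


def make_table(counts, haps=None):
    counts = np.asarray(counts)
    K, H = counts.shape
    return HaplotypeFrequencyTable(
        haplotypes=haps or [f"h{i}" for i in range(H)],
        sequences=["A" * 8] * H,
        populations=[f"p{k}" for k in range(K)],
        counts=counts,
    )


class TestCollapseHaplotypes:
    def test_exact_match_classes(self):
        seqs = AlignedSequenceSet(
            ids=["a", "b", "c"], sequences=["AAAA", "AAAA", "AAAT"], alignment_length=4
        )
        reps, rep_seqs, mapping = collapse_haplotypes(seqs)
        assert reps == ["a", "c"]
        assert mapping == {"a": "a", "b": "a", "c": "c"}

    def test_masked_column_merges(self):
        seqs = AlignedSequenceSet(
            ids=["a", "b"], sequences=["AAAN", "AAAA"], alignment_length=4
        )
        reps, rep_seqs, mapping = collapse_haplotypes(seqs)
        assert reps == ["a"]
        assert rep_seqs == ["AAA"]
        assert mapping["b"] == "a"

    def test_singleton(self):
        seqs = AlignedSequenceSet(ids=["x"], sequences=["ACGT"], alignment_length=4)
        reps, _, _ = collapse_haplotypes(seqs)
        assert reps == ["x"]

    def test_all_masked_is_error(self):
        seqs = AlignedSequenceSet(ids=["a", "b"], sequences=["NN", "AN"], alignment_length=2)
        with pytest.raises(ValueError, match="masked"):
            collapse_haplotypes(seqs)


class TestGst:
    def test_complete_fixation(self):
        g, h_s, h_t = gst(make_table([[10, 0], [0, 10]]))
        assert h_s == 0.0
        assert h_t == pytest.approx(0.5)
        assert g == 1.0

    def test_identical_frequencies(self):
        g, h_s, h_t = gst(make_table([[5, 5], [5, 5]]))
        assert h_s == pytest.approx(5.0 / 9.0)
        assert h_t == pytest.approx(0.5 + (5.0 / 9.0) / 20.0)
        assert g == pytest.approx(-0.052631578947368, abs=1e-12)
        assert g <= 0

    def test_monomorphic_is_undefined(self):
        g, _, h_t = gst(make_table([[10], [10]]))
        assert g is None and h_t <= 0


class TestNst:
    def test_fixed_populations_distinct_haplotypes(self):
        delta = np.array([[0.0, 0.1], [0.1, 0.0]])
        n_st, v_s, v_t = nst(make_table([[10, 0], [0, 10]]), delta)
        assert v_s == 0.0
        assert v_t == pytest.approx(0.05)
        assert n_st == 1.0

    def test_unit_delta_reduces_to_gst(self, rng):
        for _ in range(25):
            table = random_hap_table(rng)
            H = len(table.haplotypes)
            unit = 1.0 - np.eye(H)
            g, _, _ = gst(table)
            n_st, _, _ = nst(table, unit)
            assert n_st == pytest.approx(g, abs=1e-12)

    def test_shared_single_haplotype_undefined(self):
        n_st, _, v_t = nst(make_table([[10], [10]]), np.zeros((1, 1)))
        assert n_st is None and v_t <= 0


class TestPermutationNull:
    def test_constant_delta_gives_constant_null(self):
        table = make_table([[4, 3, 1], [1, 2, 6]])
        delta = 0.07 * (1.0 - np.eye(3))
        res = nst_permutation_null(table, delta, reps=100, seed=1)
        assert res["null_sd"] == pytest.approx(0.0, abs=1e-15)
        assert res["null_mean"] == pytest.approx(res["observed"], abs=1e-12)

    def test_mean_matches_gst_within_mc_error(self, rng):
        """Relabelling haplotypes washes out delta: E[N_ST] ~= G_ST."""
        for seed in range(3):
            table = random_hap_table(rng)
            delta = random_delta(rng, len(table.haplotypes))
            g, _, _ = gst(table)
            res = nst_permutation_null(table, delta, reps=600, seed=seed)
            se = res["null_sd"] / np.sqrt(600)
            assert abs(res["null_mean"] - g) < 3 * se + 1e-12

    def test_structured_data_ranks_high(self, rng):
        # geography tracks haplotype relatedness: each population holds one
        # pair of closely related haplotypes, all cross-pair distances large
        # -> the observed N_ST sits above the 95th percentile of the null
        H = 8
        counts = np.zeros((4, H), dtype=int)
        for k in range(4):
            counts[k, 2 * k] = 3
            counts[k, 2 * k + 1] = 3
        delta = rng.uniform(0.15, 0.25, size=(H, H))
        delta = (delta + delta.T) / 2.0
        for k in range(4):
            delta[2 * k, 2 * k + 1] = delta[2 * k + 1, 2 * k] = 0.01 + 0.001 * k
        np.fill_diagonal(delta, 0.0)
        res = nst_permutation_null(make_table(counts), delta, reps=500, seed=7)
        assert res["rank_quantile"] > 0.95

    def test_seed_reproducibility(self):
        table = make_table([[4, 3, 1], [1, 2, 6]])
        delta = random_delta(np.random.default_rng(5), 3)
        a = nst_permutation_null(table, delta, reps=200, seed=11)
        b = nst_permutation_null(table, delta, reps=200, seed=11)
        assert np.array_equal(a["null"], b["null"])

    def test_too_few_haplotypes(self):
        with pytest.raises(ValueError, match="3 haplotypes"):
            nst_permutation_null(make_table([[4, 2], [2, 4]]), 1 - np.eye(2), reps=100)


def study_fixture():
    """Two lineages: one on two islands (2 sites each), one at a single site."""
    ids, seqs, rows = [], [], []
    k = 0
    layout = [("i1", "s1"), ("i1", "s2"), ("i2", "s3"), ("i2", "s4")]
    for isl, site in layout:
        for copy in range(3):
            sid = f"a{k:02d}"
            ids.append(sid)
            # haplotype varies by island
            seqs.append("AAAAAAAA" if isl == "i1" else "AAAAAAAT")
            rows.append([sid, site, isl, "spider", "g1", "sp1", "non_dispersive"])
            k += 1
    for copy in range(10):
        sid = f"b{k:02d}"
        ids.append(sid)
        seqs.append("TTTTTTTT" if copy % 2 else "TTTTTTTA")
        rows.append([sid, "s1", "i1", "spider", "g2", "sp2", "dispersive"])
        k += 1
    meta = pd.DataFrame(
        rows, columns=["specimen_id", "site", "island", "order", "genus", "species", "dispersal"]
    )
    aln = AlignedSequenceSet(ids=ids, sequences=seqs, alignment_length=8)
    aln = attach_metadata(aln, meta)
    assignment = {sid: ("L1" if sid.startswith("a") else "L2") for sid in ids}
    return aln, LineagePartition(threshold=0.068, assignment=assignment)


class TestFiltersAndScan:
    def test_single_population_lineage_excluded(self):
        aln, part = study_fixture()
        # L2 sits at one site only: excluded everywhere
        assert "L2" not in filter_lineages(part, aln.metadata, "archipelago")
        assert "L2" not in filter_lineages(part, aln.metadata, "island:i1")

    def test_filter_boundaries(self):
        meta = pd.DataFrame(
            {
                "specimen_id": ["a", "b", "c", "d"],
                "site": ["s1", "s1", "s2", "s2"],
                "island": ["i1"] * 4,
                "order": ["spider"] * 4,
                "genus": ["g"] * 4,
                "species": ["sp"] * 4,
                "dispersal": ["dispersive"] * 4,
            }
        )
        part4 = LineagePartition(0.068, {s: "L1" for s in "abcd"})
        assert filter_lineages(part4, meta, "island:i1") == ["L1"]  # 2+2 included
        part3 = LineagePartition(0.068, {s: "L1" for s in "abc"})
        # 2+1 -> second population dropped (n_k < 2) -> only 1 population left
        assert filter_lineages(part3, meta.iloc[:3], "island:i1") == []

    def test_scan_scales_and_exclusions(self):
        aln, part = study_fixture()
        results = results_to_frame(structure_scan(part, aln))
        # L1 spans 2 islands x 2 sites: archipelago + 2 within-island results
        assert set(results["lmdh_id"]) == {"L1"}
        assert sorted(results["scale"]) == ["archipelago", "island:i1", "island:i2"]
        arch = results[results["scale"] == "archipelago"].iloc[0]
        # islands fixed for different haplotypes -> complete fixation
        assert arch["GST"] == pytest.approx(1.0)
        assert arch["NST"] == pytest.approx(1.0)
        # within island i1 all sequences identical -> undefined
        i1 = results[results["scale"] == "island:i1"].iloc[0]
        assert not i1["defined"]

    def test_empty_scan_is_fine(self):
        aln, _ = study_fixture()
        lonely = LineagePartition(0.068, {sid: "X1" for sid in aln.ids[:1]})
        assert structure_scan(lonely, aln) == []
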