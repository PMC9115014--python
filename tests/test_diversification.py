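"""Node divergences, clock conversion, ARR and coverage arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from lmdh.seq_distance import AlignedSequenceSet
from lmdh.delimitation import TreeNode, UltrametricTree, cophenetic, upgma
from lmdh.diversification import (
    CLOCKS,
    ClockModel,
    coverage_report,
    divergence_summaries,
    genus_pipeline,
    node_ages,
    normalize01,
    to_time,
)
from lmdh.synthetic_data import decode, evolve_sequences, random_ultrametric_tree


def three_taxon_tree():
    ab = TreeNode(height=0.01, children=(TreeNode(0.0, "A"), TreeNode(0.0, "B")))
    return UltrametricTree(root=TreeNode(height=0.055, children=(ab, TreeNode(0.0, "C"))))


class TestNodeAges:
    def test_three_taxon(self):
        assert sorted(node_ages(three_taxon_tree())) == pytest.approx([0.01, 0.055])

    def test_two_leaf(self):
        t = UltrametricTree(TreeNode(height=0.03, children=(TreeNode(0, "a"), TreeNode(0, "b"))))
        assert node_ages(t) == [0.03]

    def test_star_of_identical(self):
        t = UltrametricTree(TreeNode(height=0.0, children=tuple(TreeNode(0, l) for l in "abc")))
        assert node_ages(t) == [0.0]

    def test_non_ultrametric_rejected(self):
        bad = UltrametricTree(
            TreeNode(height=0.01, children=(TreeNode(0.05, "a"), TreeNode(0, "b")))
        )
        with pytest.raises(ValueError):
            node_ages(bad)

    def test_roundtrip_through_cophenetic(self, rng):
        """upgma(cophenetic(tree)) reproduces the original node heights."""
        for _ in range(10):
            labels = [f"x{i}" for i in range(int(rng.integers(3, 10)))]
            tree = UltrametricTree(random_ultrametric_tree(labels, float(rng.uniform(1, 5)), rng))
            rebuilt = upgma(cophenetic(tree))
            assert sorted(node_ages(rebuilt)) == pytest.approx(
                sorted(node_ages(tree)), abs=1e-9
            )


def test_divergence_summaries():
    assert divergence_summaries([0.01, 0.055]) == pytest.approx((0.0325, 0.055))
    assert divergence_summaries([0.3]) == (0.3, 0.3)
    assert divergence_summaries([0.2, 0.2]) == (0.2, 0.2)
    with pytest.raises(ValueError):
        divergence_summaries([])


def test_t_max_never_below_t_mean(rng):
    for _ in range(20):
        heights = rng.uniform(0, 0.2, size=int(rng.integers(1, 12)))
        t_mean, t_max = divergence_summaries(heights)
        assert t_max >= t_mean
        if len(heights) > 1 and len(set(heights)) > 1:
            assert t_max > t_mean


class TestClock:
    def test_conversions(self):
        assert to_time(0.0, CLOCKS["spider_COIa"]) == 0.0
        assert to_time(0.0168, CLOCKS["polyphaga_COIa"]) == pytest.approx(1.0)
        assert to_time(0.025, CLOCKS["spider_COIa"]) == pytest.approx(2.0)

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            ClockModel("bad", -1.0, 0.1)


def toy_genus_seqs():
    """Three species whose p-distances are 0.02, 0.10, 0.12."""
    L = 100
    base = ["A"] * L
    a = base.copy()
    b = base.copy()
    c = base.copy()
    for i in (0, 1):
        b[i] = "T"
    for i in range(2, 12):
        c[i] = "G"
    return AlignedSequenceSet(
        ids=["g1_a", "g1_b", "g1_c"],
        sequences=["".join(a), "".join(b), "".join(c)],
        alignment_length=L,
    )


def grouping(species, unit="g1"):
    return pd.DataFrame(
        {
            "species": species,
            "genus_unit": unit,
            "order": "spider",
            "dispersal": "non_dispersive",
        }
    )


class TestGenusPipeline:
    def test_toy_node_divergences(self):
        res, skipped = genus_pipeline(
            toy_genus_seqs(),
            grouping(["g1_a", "g1_b", "g1_c"]),
            pd.DataFrame({"genus_unit": ["g1"], "S": [3]}),
        )
        assert skipped == []
        (g,) = res
        assert g.t_mean == pytest.approx(0.0325)
        assert g.t_max == pytest.approx(0.055)
        assert g.units == "subs_per_site"
        assert g.arr == pytest.approx(3 / 0.055)

    def test_clock_conversion_and_arr(self):
        clock = ClockModel("test", 0.0275, 0.001)
        res, _ = genus_pipeline(
            toy_genus_seqs(),
            grouping(["g1_a", "g1_b", "g1_c"]),
            pd.DataFrame({"genus_unit": ["g1"], "S": [10]}),
            clock=clock,
        )
        (g,) = res
        assert g.t_max == pytest.approx(2.0)  # 0.055 / 0.0275
        assert g.units == "Myr"
        assert g.arr == pytest.approx(5.0)

    def test_arr_scale_equivariance(self):
        """Converting heights to Myr divides ARR by the clock rate exactly."""
        rich = pd.DataFrame({"genus_unit": ["g1"], "S": [7]})
        subs, _ = genus_pipeline(toy_genus_seqs(), grouping(["g1_a", "g1_b", "g1_c"]), rich)
        clock = CLOCKS["spider_COIa"]
        myr, _ = genus_pipeline(
            toy_genus_seqs(), grouping(["g1_a", "g1_b", "g1_c"]), rich, clock=clock
        )
        assert myr[0].arr == pytest.approx(subs[0].arr * clock.rate)

    def test_identical_sequences_flagged(self):
        L = 50
        seqs = AlignedSequenceSet(
            ids=["s1", "s2"], sequences=["A" * L, "A" * L], alignment_length=L
        )
        res, _ = genus_pipeline(
            seqs, grouping(["s1", "s2"]), pd.DataFrame({"genus_unit": ["g1"], "S": [2]})
        )
        assert res[0].t_max == 0.0
        assert res[0].arr is None

    def test_undersampled_genus_skipped(self):
        seqs = AlignedSequenceSet(ids=["only"], sequences=["ACGT" * 10], alignment_length=40)
        res, skipped = genus_pipeline(
            seqs, grouping(["only"]), pd.DataFrame({"genus_unit": ["g1"], "S": [5]})
        )
        assert res == [] and skipped == ["g1"]


def expected_p_distance(d: float, kappa: float = 2.0) -> float:
    """Expected mismatch proportion after d substitutions/site under K2P."""
    a = kappa / (kappa + 2.0)   # transition probability per event
    b = 1.0 / (kappa + 2.0)     # each transversion target
    Q = np.array(
        [
            [-1.0, a, b, b],
            [a, -1.0, b, b],
            [b, b, -1.0, a],
            [b, b, a, -1.0],
        ]
    )
    P = expm(Q * d)
    return 1.0 - float(np.mean(np.diag(P)))


def test_crown_age_recovery(rng):
    """Recovered t_max tracks the generating crown age over replicates.

    UPGMA heights use uncorrected p-distances, so the expectation is the
    finite-sites (saturation-adjusted) value, slightly below the true age.
    """
    T, rate, L, kappa, reps = 3.0, 0.0125, 658, 2.0, 100
    est = []
    for _ in range(reps):
        labels = [f"sp{i}" for i in range(6)]
        tree = random_ultrametric_tree(labels, T, rng)
        seq_map = evolve_sequences(tree, L, rate, kappa, rng)
        seqs = AlignedSequenceSet(
            ids=labels, sequences=[decode(seq_map[l]) for l in labels], alignment_length=L
        )
        res, _ = genus_pipeline(
            seqs,
            grouping(labels),
            pd.DataFrame({"genus_unit": ["g1"], "S": [6]}),
            clock=ClockModel("test", rate, 0.0),
        )
        est.append(res[0].t_max)
    est = np.asarray(est)
    t_adjusted = expected_p_distance(2 * rate * T, kappa) / (2 * rate)
    sem = est.std(ddof=1) / np.sqrt(reps)
    assert abs(est.mean() - t_adjusted) < 4 * sem
    assert abs(est.mean() - T) / T < 0.10


class TestNormalize01:
    def test_values(self):
        assert normalize01([2, 4, 6]) == pytest.approx([0.0, 0.5, 1.0])

    def test_endpoints(self, rng):
        v = rng.uniform(-5, 5, size=10)
        out = normalize01(v)
        assert out[np.argmin(v)] == 0.0 and out[np.argmax(v)] == 1.0

    def test_all_equal_is_error(self):
        with pytest.raises(ValueError):
            normalize01([1.0, 1.0, 1.0])


class TestCoverageReport:
    def test_integer_percentages(self):
        out = coverage_report(
            {
                "spider_richness": (153, 317),
                "beetle_richness": (502, 1314),
                "all_richness": (655, 1631),
                "spider_genera": (29, 47),
                "beetle_genera": (70, 198),
            }
        )
        assert out == {
            "spider_richness": 48,
            "beetle_richness": 38,
            "all_richness": 40,
            "spider_genera": 62,
            "beetle_genera": 35,
        }

    def test_one_decimal_rates(self):
        out = coverage_report({"beetle_assignment": (335, 416)}, decimals=1)
        assert out["beetle_assignment"] == 80.5

    def test_bounds(self):
        assert coverage_report({"full": (5, 5)}) == {"full": 100}
        with pytest.raises(ZeroDivisionError):
            coverage_report({"bad": (0, 0)})
        with pytest.raises(ValueError):
            coverage_report({"bad": (6, 5)})
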