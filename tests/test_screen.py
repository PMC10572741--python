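import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indigoferm import screen
from indigoferm.errors import InputError


def _functions(data, functions=None, samples=None):
    functions = functions or [f"K{i:05d}" for i in range(1, len(data) + 1)]
    samples = samples or [f"s{i}" for i in range(len(data[0]))]
    return pd.DataFrame(data, index=functions, columns=samples, dtype=float)


def _hierarchy(mapping):
    return pd.DataFrame(
        [(fn, sub, "sp", "cat") for fn, sub in mapping.items()],
        columns=["function_id", "subpathway", "superpathway", "category"],
    ).set_index("function_id")


class TestSubpathwayPercentages:
    def test_single_subpathway_is_100(self):
        funcs = _functions([[3.0], [1.0]])
        hier = _hierarchy({"K00001": "A", "K00002": "A"})
        pct = screen.subpathway_percentages(funcs, hier)
        assert pct.loc["A", "s0"] == pytest.approx(100.0)

    def test_hand_summed_percentages(self):
        funcs = _functions([[1.0, 2.0], [3.0, 2.0], [2.0, 4.0], [2.0, 0.0]])
        hier = _hierarchy({"K00001": "A", "K00002": "A", "K00003": "B"})
        pct = screen.subpathway_percentages(funcs, hier)
        # sample s0: A = 4/8, B = 2/8, unmapped K00004 -> Unclassified 2/8
        assert pct["s0"].tolist() == pytest.approx([50.0, 25.0, 25.0])
        assert set(pct.index) == {"A", "B", screen.UNCLASSIFIED}
        assert np.allclose(pct.sum(axis=0), 100.0, atol=1e-6)

    def test_zero_total_sample_rejected(self):
        funcs = _functions([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(InputError, match="s1"):
            screen.subpathway_percentages(funcs, _hierarchy({}))


class TestRatioSelect:
    days = pd.Series({"a1": 10, "a2": 10, "b1": 212, "b2": 212})

    def _profiles(self, day10, day212):
        data = np.column_stack([day10, day10, day212, day212])
        return pd.DataFrame(data, index=[f"sub{i}" for i in range(len(day10))],
                            columns=["a1", "a2", "b1", "b2"])

    def test_identical_profiles_nothing_selected(self):
        prof = self._profiles([40.0, 60.0], [40.0, 60.0])
        out = screen.ratio_select(prof, self.days, [(10, 212)])
        assert (out["D10/D212"] == 1.0).all()
        assert not out["selected"].any()

    def test_boundary_threshold_is_inclusive(self):
        # ratios of exactly 1.0 are selected at a threshold of 1.0
        prof = self._profiles([40.0, 60.0], [40.0, 60.0])
        out = screen.ratio_select(prof, self.days, [(10, 212)], select_threshold=1.0)
        assert out["selected"].all()
        # and a subpathway that declined (ratio < 1) is not
        mixed = screen.ratio_select(self._profiles([40.0, 60.0], [42.0, 58.0]),
                                    self.days, [(10, 212)], select_threshold=1.0)
        assert not mixed.loc["sub0", "selected"]
        assert bool(mixed.loc["sub1", "selected"])

    def test_hand_arithmetic_selection_and_highlight(self):
        prof = self._profiles([2.1, 1.0], [1.4, 1.0])
        out = screen.ratio_select(prof, self.days, [(10, 212)],
                                  select_threshold=1.05, highlight_threshold=1.4)
        assert out.loc["sub0", "D10/D212"] == pytest.approx(1.5)
        assert bool(out.loc["sub0", "selected"]) and bool(out.loc["sub0", "highlighted"])
        assert not out.loc["sub1", "selected"]

    def test_zero_denominator_excluded(self, caplog):
        prof = self._profiles([2.0, 1.0], [0.0, 1.0])
        with caplog.at_level("WARNING"):
            out = screen.ratio_select(prof, self.days, [(10, 212)])
        assert np.isnan(out.loc["sub0", "D10/D212"])
        assert not out.loc["sub0", "selected"]

    def test_raising_threshold_never_adds_selections(self):
        rng = np.random.default_rng(2)
        prof = self._profiles(rng.uniform(1, 10, 6), rng.uniform(1, 10, 6))
        selected = None
        for thr in (1.0, 1.05, 1.2, 1.5, 2.0):
            now = screen.ratio_select(prof, self.days, [(10, 212)],
                                      select_threshold=thr)["selected"]
            if selected is not None:
                assert (now <= selected).all()
            selected = now


def _strat(rows):
    return pd.DataFrame(rows, columns=["Sample", "Gene", "OTU", "taxon",
                                       "GeneCountPerGenome",
                                       "OTUAbundanceInSample",
                                       "CountContributedByOTU"])


class TestTaxonContribution:
    def test_single_taxon_is_100(self):
        strat = _strat([("s1", "K1", "o1", "A", 2, 5, 10)])
        out = screen.taxon_contribution(strat, ["K1"], "s1")
        assert out.loc["A", "contribution_pct"] == pytest.approx(100.0)

    def test_hand_summed_split(self):
        strat = _strat([
            ("s1", "K1", "o1", "A", 1, 324, 324),
            ("s1", "K1", "o2", "A", 2, 162, 324),
            ("s1", "K1", "o3", "B", 8, 44, 352),
        ])
        out = screen.taxon_contribution(strat, ["K1"], "s1")
        assert out.loc["A", "contribution_pct"] == pytest.approx(64.8)
        assert out.loc["B", "contribution_pct"] == pytest.approx(35.2)

    def test_errors(self):
        strat = _strat([("s1", "K1", "o1", "A", 1, 1, 1)])
        with pytest.raises(InputError):
            screen.taxon_contribution(strat, [], "s1")
        with pytest.raises(InputError):
            screen.taxon_contribution(strat, ["K1"], "missing")

    def test_otu_contribution_for_function(self, caplog):
        strat = _strat([
            ("s1", "K1", "o1", "A", 3, 1, 3),
            ("s1", "K1", "o2", "A", 1, 1, 1),
            ("s1", "K1", "o3", "B", 4, 1, 4),
            ("s1", "K2", "o3", "B", 9, 1, 9),
        ])
        out = screen.otu_contribution_for_function(strat, "K1", "s1")
        assert out.loc["A", "contribution_pct"] == pytest.approx(50.0)
        assert out.loc["B", "contribution_pct"] == pytest.approx(50.0)
        assert out["contribution_pct"].sum() == pytest.approx(100.0)
        with caplog.at_level("WARNING"):
            empty = screen.otu_contribution_for_function(strat, "K9", "s1")
        assert empty.empty


class TestCLR:
    def test_equal_parts_map_to_zero(self):
        clr = screen.clr_transform(_functions([[2.0]] * 4))
        assert np.allclose(clr["s0"], 0.0)

    def test_geometric_series_hand_logs(self):
        clr = screen.clr_transform(_functions([[1.0], [2.0], [4.0], [8.0]]))
        expected = [-1.0397, -0.3466, 0.3466, 1.0397]
        assert clr["s0"].to_numpy() == pytest.approx(expected, abs=1e-4)

    def test_matches_skbio_without_zeros(self):
        composition = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(3)
        funcs = _functions(rng.uniform(0.5, 20, size=(10, 4)))
        ours = screen.clr_transform(funcs)
        for j, sample in enumerate(funcs.columns):
            ref = composition.clr(funcs[sample].to_numpy()
                                  / funcs[sample].sum())
            assert ours[sample].to_numpy() == pytest.approx(np.asarray(ref))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        funcs = _functions(rng.uniform(0.1, 5, size=(6, 3)))
        perm = rng.permutation(6)
        permuted = screen.clr_transform(funcs.iloc[perm])
        pd.testing.assert_frame_equal(permuted, screen.clr_transform(funcs).iloc[perm])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=1000.0),
           seed=st.integers(min_value=0, max_value=50))
    def test_scale_invariance(self, scale, seed):
        """Multiplying a sample's abundances by a constant leaves CLR unchanged."""
        rng = np.random.default_rng(seed)
        funcs = _functions(rng.uniform(0.1, 10, size=(5, 2)))
        scaled = screen.clr_transform(funcs * scale)
        pd.testing.assert_frame_equal(scaled, screen.clr_transform(funcs),
                                      atol=1e-9, rtol=0)

    def test_zero_replacement_keeps_columns_centered(self):
        funcs = _functions([[0.0, 1.0], [2.0, 1.0], [3.0, 4.0]])
        clr = screen.clr_transform(funcs)
        assert np.allclose(clr.sum(axis=0), 0.0, atol=1e-9)
        with pytest.raises(InputError):
            screen.clr_transform(_functions([[1.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(InputError):
            screen.clr_transform(funcs, zero_replacement="nope")


class TestCorrelateWithPhenotype:
    def test_perfect_tracker_selected(self):
        pheno = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        clr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
                           index=["up", "down"], columns=list("abcd"))
        out = screen.correlate_with_phenotype(clr, pheno, threshold=0.9)
        assert bool(out.loc["up", "selected"])
        assert out.loc["down", "r"] == pytest.approx(-1.0)
        assert not out.loc["down", "selected"]

    def test_constant_function_undefined_never_selected(self):
        pheno = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        clr = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                           index=["flat", "up"], columns=list("abc"))
        out = screen.correlate_with_phenotype(clr, pheno, threshold=0.0)
        assert np.isnan(out.loc["flat", "r"])
        assert not out.loc["flat", "selected"]

    def test_spearman_option_and_input_checks(self):
        pheno = pd.Series([1.0, 4.0, 9.0], index=list("abc"))
        clr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["up"], columns=list("abc"))
        out = screen.correlate_with_phenotype(clr, pheno, method="spearman")
        assert out.loc["up", "r"] == pytest.approx(1.0)
        with pytest.raises(InputError):
            screen.correlate_with_phenotype(clr[["a", "b"]], pheno[["a", "b"]])
        with pytest.raises(InputError):
            screen.correlate_with_phenotype(clr, pheno, method="kendall")
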