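import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bloodtrac as bt
from bloodtrac.datatypes import ValidationError
from bloodtrac.enrichment import (
    cell_type_index,
    collapse_to_symbols,
    marker_correlations,
    match_symbols,
    overlap_enrichment,
    treg_fold_from_fractions,
    treg_fold_from_reduction,
)


def _sets(na, nb, k):
    """Two gene sets with |A|=na, |B|=nb sharing exactly k symbols."""
    a = {f"S{i}" for i in range(na)}
    b = {f"S{i}" for i in range(k)} | {f"T{i}" for i in range(nb - k)}
    return (
        bt.GeneSet("A", "", frozenset(a)),
        bt.GeneSet("B", "", frozenset(b)),
    )


def _enumeration_p(N, na, nb, k):
    """Exact upper-tail probability by enumerating all C(N, na) draws."""
    universe = list(range(N))
    b = set(range(nb))
    total = hits = 0
    for draw in itertools.combinations(universe, na):
        total += 1
        if len(b & set(draw)) >= k:
            hits += 1
    return hits / total


class TestOverlapEnrichment:
    def test_worked_example(self):
        a, b = _sets(5, 4, 4)
        res = overlap_enrichment(a, b, universe=10)
        assert res.overlap == 4
        assert res.fold == pytest.approx(2.0)
        assert res.p == pytest.approx(6 / 252)

    def test_saturated_sets(self):
        a, b = _sets(4, 4, 4)
        res = overlap_enrichment(a, b, universe=4)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_disjoint_sets(self):
        a, b = _sets(3, 3, 0)
        res = overlap_enrichment(a, b, universe=20)
        assert res.overlap == 0 and res.fold == 0.0
        assert res.p == pytest.approx(1.0)

    def test_universe_smaller_than_union_rejected(self):
        a, b = _sets(5, 5, 0)
        with pytest.raises(ValidationError, match="universe"):
            overlap_enrichment(a, b, universe=8)

    @given(
        st.integers(4, 15).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(1, N - 1),
                st.integers(1, N - 1),
            )
        ),
        st.randoms(use_true_random=False),
    )
    def test_matches_brute_force_enumeration(self, Nab, rnd):
        N, na, nb = Nab
        k = rnd.randint(max(0, na + nb - N), min(na, nb))
        a_members = {f"S{i}" for i in range(na)}
        b_members = {f"S{i}" for i in range(k)} | {
            f"T{i}" for i in range(nb - k)
        }
        res = overlap_enrichment(
            bt.GeneSet("A", "", frozenset(a_members)),
            bt.GeneSet("B", "", frozenset(b_members)),
            universe=N,
        )
        assert res.p == pytest.approx(_enumeration_p(N, na, nb, k), abs=1e-12)

    def test_shuffled_overlap_matches_expectation(self):
        """Random draws of A from the universe overlap B at |A||B|/N."""
        rng = np.random.default_rng(5)
        N, na, nb = 200, 30, 40
        b = set(range(nb))
        overlaps = [
            len(b & set(rng.choice(N, size=na, replace=False)))
            for _ in range(500)
        ]
        expected = na * nb / N
        sem = np.std(overlaps, ddof=1) / np.sqrt(len(overlaps))
        assert abs(np.mean(overlaps) - expected) < 3 * sem


class TestMatchSymbols:
    def test_exact_match(self):
        rep = match_symbols(["FOXP1"], ["FOXP1"])
        assert rep.exact == [("FOXP1", "FOXP1")]
        assert rep.close == []

    def test_trailing_digit_close_match(self):
        rep = match_symbols(["ELP3"], ["ELP2"])
        assert rep.exact == []
        assert rep.close == [("ELP3", "ELP2", "trailing")]

    def test_distance_two_no_match(self):
        rep = match_symbols(["ELP3"], ["ERP5"])
        assert rep.exact == [] and rep.close == []

    def test_exact_and_close_disjoint(self):
        rep = match_symbols(["ABC1", "XYZ2"], ["ABC1", "ABC2", "XYZ2"])
        exact_syms = {a for a, _ in rep.exact}
        close_syms = {a for a, _, _ in rep.close}
        assert exact_syms.isdisjoint(close_syms)

    def test_exact_mode_skips_close(self):
        rep = match_symbols(["ELP3"], ["ELP2"], mode="exact")
        assert rep.close == []


class TestMarkerCorrelations:
    def _matrix(self):
        return bt.ExpressionMatrix(
            pd.DataFrame(
                {
                    "s1": [1.0, 1.0, 4.0, 2.0],
                    "s2": [2.0, 3.0, 3.0, 2.0],
                    "s3": [3.0, 2.0, 2.0, 2.0],
                    "s4": [4.0, 4.0, 1.0, 2.0],
                },
                index=["ANCH", "PANEL1", "ANTI", "FLAT"],
            ),
            "RPKM",
        )

    def test_anchor_with_itself(self):
        out = marker_correlations(
            self._matrix(), "ANCH", bt.GeneSet("P", "", frozenset({"ANCH"}))
        )
        assert out.loc["ANCH", "r"] == pytest.approx(1.0)

    def test_hand_computed_r(self):
        out = marker_correlations(
            self._matrix(), "ANCH", bt.GeneSet("P", "", frozenset({"PANEL1"})),
            on_log=False,
        )
        assert out.loc["PANEL1", "r"] == pytest.approx(0.8)

    def test_anticorrelated_pair(self):
        out = marker_correlations(
            self._matrix(), "ANCH", bt.GeneSet("P", "", frozenset({"ANTI"})),
            on_log=False,
        )
        assert out.loc["ANTI", "r"] == pytest.approx(-1.0)

    def test_zero_variance_missing(self):
        out = marker_correlations(
            self._matrix(), "ANCH", bt.GeneSet("P", "", frozenset({"FLAT"}))
        )
        assert np.isnan(out.loc["FLAT", "r"])


class TestTregArithmetic:
    @pytest.mark.parametrize(
        "reduction, fold", [(0.0, 1.0), (0.303, 1.4347), (0.5, 2.0)]
    )
    def test_fold_from_reduction(self, reduction, fold):
        assert treg_fold_from_reduction(reduction) == pytest.approx(fold, abs=5e-5)

    @pytest.mark.parametrize(
        "fn, fd, fold", [(3.0, 3.0, 1.0), (4.7, 3.2, 1.46875), (9.4, 3.2, 2.9375)]
    )
    def test_fold_from_fractions(self, fn, fd, fold):
        assert treg_fold_from_fractions(fn, fd) == pytest.approx(fold)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            treg_fold_from_reduction(1.0)
        with pytest.raises(ValidationError):
            treg_fold_from_fractions(0.0, 1.0)

    @given(
        st.floats(0.001, 0.3, allow_nan=False),
        st.floats(0.0, 0.95, allow_nan=False),
    )
    def test_algebraic_identity_between_forms(self, f_normal, reduction):
        f_disease = f_normal * (1.0 - reduction)
        if f_disease <= 0:
            return
        assert treg_fold_from_fractions(f_normal, f_disease) == pytest.approx(
            treg_fold_from_reduction(reduction), rel=1e-9
        )


class TestCellTypeIndex:
    def test_singleton_set_equals_group_mean(self, toy_matrix):
        groups = {"s1": "LOW", "s2": "LOW", "s3": "MID", "s4": "MID"}
        out = cell_type_index(
            toy_matrix, [bt.GeneSet("X", "", frozenset({"T2"}))], groups
        )
        assert out.loc["X", "LOW"] == pytest.approx(3.0)
        assert out.loc["X", "MID"] == pytest.approx(20.0)

    def test_linearity_in_expression(self, toy_matrix):
        groups = {"s1": "LOW", "s2": "LOW", "s3": "MID", "s4": "MID"}
        sets = [bt.GeneSet("X", "", frozenset({"T1", "T2"}))]
        base = cell_type_index(toy_matrix, sets, groups)
        doubled = cell_type_index(
            bt.ExpressionMatrix(toy_matrix.values * 2, "RPKM"), sets, groups
        )
        np.testing.assert_allclose(
            doubled.to_numpy(), 2 * base.to_numpy(), rtol=1e-12
        )

    def test_no_overlap_names_the_set(self, toy_matrix):
        groups = {"s1": "LOW", "s2": "LOW", "s3": "MID", "s4": "MID"}
        with pytest.raises(ValidationError, match="GHOST"):
            cell_type_index(
                toy_matrix, [bt.GeneSet("GHOST", "", frozenset({"ZZ"}))], groups
            )

    def test_treg_index_steps_down_with_cad_severity(self):
        """With Treg shares 4.7 / 3.2 / 2.8% the Treg marker index falls
        stepwise LOW → MID → HIGH while the granulocyte index does not."""
        spec = bt.MixtureSpec(
            n_per_group={"LOW": 200, "MID": 200, "HIGH": 200},
            n_transcripts=800, markers_per_type=8, n_trac=20, rng_seed=3,
        )
        co = bt.simulate(spec)
        mat = bt.rpkm(co.counts, co.transcripts)
        symbols = {t.transcript_id: t.gene_symbol for t in co.transcripts}
        sym = collapse_to_symbols(mat, symbols)
        sets = {g.name: g for g in co.profiles.marker_sets()}
        out = cell_type_index(
            sym, [sets["Treg_markers"], sets["granulocyte_markers"]],
            co.group_map(),
        )
        treg = out.loc["Treg_markers"]
        assert treg["LOW"] > treg["MID"] > treg["HIGH"]
        gran = out.loc["granulocyte_markers"]
        assert abs(gran["LOW"] / gran["MID"] - 1) < 0.1


def test_collapse_keeps_highest_expressed_transcript():
    m = bt.ExpressionMatrix(
        pd.DataFrame(
            {"s1": [1.0, 10.0], "s2": [2.0, 20.0]}, index=["tA", "tB"]
        ),
        "RPKM",
    )
    out = collapse_to_symbols(m, {"tA": "G1", "tB": "G1"})
    assert out.transcript_ids == ["G1"]
    np.testing.assert_allclose(out.values.loc["G1"].to_numpy(), [10.0, 20.0])
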