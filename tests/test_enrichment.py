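import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossarray import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    ProbeGeneMap,
    bh_adjust,
    collapse_probes_to_genes,
    compare_enrichment_across_contrasts,
    enrich,
    hypergeometric_overrep,
    read_gmt,
)


# ---- independent oracles -----------------------------------------------------

def exact_tail(r, n, R, N):
    """P(X >= r) as an exact rational comb-sum."""
    total = Fraction(0)
    for i in range(r, min(n, R) + 1):
        total += Fraction(math.comb(n, i) * math.comb(N - n, R - i), math.comb(N, R))
    return total


def subset_enumeration_tail(r, n, R, N):
    """P(X >= r) by enumerating every R-subset of an N-element universe."""
    hits = 0
    universe = range(N)
    pathway = set(range(n))  # first n elements are the pathway
    for draw in itertools.combinations(universe, R):
        if len(pathway.intersection(draw)) >= r:
            hits += 1
    return Fraction(hits, math.comb(N, R))


def test_exact_tail_oracle_agrees_with_subset_enumeration():
    # validates the comb-sum oracle itself on small exhaustive cases
    for N in range(1, 9):
        for n in range(N + 1):
            for R in range(N + 1):
                for r in range(max(0, R + n - N), min(n, R) + 1):
                    assert exact_tail(r, n, R, N) == subset_enumeration_tail(r, n, R, N)


# ---- GMT parsing -------------------------------------------------------------

class TestReadGmt:
    def _write(self, tmp_path, lines):
        path = tmp_path / "sets.gmt"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_two_sets(self, tmp_path):
        gsc = read_gmt(self._write(tmp_path, [
            "pw1\tdesc\tA\tB\tC",
            "pw2\tdesc\tA\tD\tE\tF\tG",
        ]))
        assert len(gsc) == 2
        assert len(gsc.genes("pw1")) == 3
        assert len(gsc.genes("pw2")) == 5

    def test_duplicate_gene_counted_once(self, tmp_path):
        gsc = read_gmt(self._write(tmp_path, ["pw1\tdesc\tA\tB\tA"]))
        assert len(gsc.genes("pw1")) == 2

    def test_duplicate_pathway_name(self, tmp_path):
        with pytest.raises(FormatError, match="duplicate"):
            read_gmt(self._write(tmp_path, ["pw1\tdesc\tA", "pw1\tdesc\tB"]))

    def test_short_line(self, tmp_path):
        with pytest.raises(FormatError, match="3"):
            read_gmt(self._write(tmp_path, ["pw1\tdesc-only"]))


class TestCollapse:
    pmap = ProbeGeneMap({"p1": "GENEA", "p2": "GENEA", "p3": "GENEB"})

    def test_many_to_one(self):
        assert collapse_probes_to_genes({"p1", "p2"}, self.pmap) == {"GENEA"}

    def test_empty(self):
        assert collapse_probes_to_genes(set(), self.pmap) == set()

    def test_unmapped_dropped(self):
        assert collapse_probes_to_genes({"p1", "p9"}, self.pmap) == {"GENEA"}


# ---- hypergeometric tail -----------------------------------------------------

class TestHypergeometric:
    def test_r_zero_is_exactly_one(self):
        assert hypergeometric_overrep(0, 5, 5, 10) == 1.0

    def test_all_overlap_case(self):
        # drawing all 5 pathway genes among 5 draws from 10: 1/C(10,5)
        assert hypergeometric_overrep(5, 5, 5, 10) == pytest.approx(1 / 252, abs=1e-15)

    def test_matches_exact_oracle_on_small_grid(self):
        for N in (5, 9, 12):
            for n in range(N + 1):
                for R in range(N + 1):
                    for r in range(max(0, R + n - N), min(n, R) + 1):
                        p = hypergeometric_overrep(r, n, R, N)
                        assert p == pytest.approx(float(exact_tail(r, n, R, N)), abs=1e-12)

    @pytest.mark.parametrize("r,n,R,N", [(3, 2, 5, 10), (1, 5, 5, 4), (0, 11, 5, 10), (-1, 2, 2, 4)])
    def test_margin_violations(self, r, n, R, N):
        with pytest.raises(ParameterError):
            hypergeometric_overrep(r, n, R, N)


# ---- Benjamini-Hochberg ------------------------------------------------------

class TestBhAdjust:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_input_order_preserved(self):
        q = bh_adjust([0.04, 0.001, 0.5])
        assert q[1] == min(q)
        assert q[2] == max(q)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_dominates_p_and_is_monotone_in_p(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.5])


# ---- enrichment table --------------------------------------------------------

def _setup_universe(n_genes=100, seed=0):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    pmap = ProbeGeneMap({f"{g}_probe": g for g in genes})
    probes = set(pmap.entries)
    return genes, pmap, probes


class TestEnrich:
    def test_de_equals_universe_gives_p_one(self):
        genes, pmap, probes = _setup_universe(20)
        gsc = read_gmt_from_sets({"pw": genes[:5]})
        table = enrich(probes, probes, pmap, gsc)
        row = table.iloc[0]
        assert row["r"] == row["n"] == 5
        assert row["p"] == 1.0

    def test_disjoint_pathway_p_one(self):
        genes, pmap, probes = _setup_universe(20)
        gsc = read_gmt_from_sets({"pw": genes[:5]})
        de = {f"{g}_probe" for g in genes[10:15]}
        table = enrich(de, probes, pmap, gsc)
        assert table.iloc[0]["r"] == 0
        assert table.iloc[0]["p"] == 1.0

    def test_planted_pathway_matches_oracle_and_ranks_first(self):
        genes, pmap, probes = _setup_universe(100)
        rng = np.random.default_rng(1)
        sets = {"planted": genes[:10]}
        for i in range(5):
            sets[f"random{i}"] = list(rng.choice(genes, 10, replace=False))
        gsc = read_gmt_from_sets(sets)
        de_genes = genes[:8] + genes[50:62]  # 8 of 10 pathway genes among 20 DE
        de = {f"{g}_probe" for g in de_genes}
        table = enrich(de, probes, pmap, gsc)
        assert table.iloc[0]["pathway"] == "planted"
        expected = float(exact_tail(8, 10, 20, 100))
        got = table.set_index("pathway").loc["planted", "p"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_pathway_size_restricted_to_universe(self):
        genes, pmap, probes = _setup_universe(20)
        gsc = read_gmt_from_sets({"pw": genes[:5] + ["NOT_ON_CHIP"]})
        table = enrich(set(), probes, pmap, gsc)
        assert table.iloc[0]["n"] == 5

    def test_de_outside_universe_rejected(self):
        genes, pmap, probes = _setup_universe(10)
        with pytest.raises(ParameterError):
            enrich({"alien_probe"}, probes, pmap, read_gmt_from_sets({"pw": genes[:3]}))

    def test_empty_universe_degenerate(self):
        genes, pmap, _ = _setup_universe(10)
        with pytest.raises(DegenerateInputError):
            enrich(set(), {"unmapped1"}, pmap, read_gmt_from_sets({"pw": genes[:3]}))

    def test_invariant_under_probe_relabeling(self):
        genes, pmap, probes = _setup_universe(50)
        gsc = read_gmt_from_sets({"pw": genes[:8], "other": genes[20:30]})
        de = {f"{g}_probe" for g in genes[:6]}
        table1 = enrich(de, probes, pmap, gsc)
        relabeled = ProbeGeneMap({f"x{p}": g for p, g in pmap.entries.items()})
        table2 = enrich(
            {f"x{p}" for p in de}, {f"x{p}" for p in probes}, relabeled, gsc
        )
        assert np.allclose(table1["p"], table2["p"])


def read_gmt_from_sets(sets):
    """Build a GeneSetCollection directly from {name: genes} (test helper)."""
    from crossarray import GeneSetCollection

    return GeneSetCollection({name: ("", frozenset(genes)) for name, genes in sets.items()})


class TestCompareAcrossContrasts:
    def _table(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["pathway", "r", "n", "R", "N", "p", "q", "significant"])

    def test_identical_tables_identical_columns(self):
        t = self._table([("pw1", 3, 5, 10, 100, 0.01, 0.02, True),
                         ("pw2", 1, 5, 10, 100, 0.5, 0.5, False)])
        out = compare_enrichment_across_contrasts({"c1": t, "c2": t.copy()}, top_k=2)
        assert np.allclose(out["c1"], out["c2"])

    def test_missing_pathway_filled_with_zero(self):
        t1 = self._table([("pw1", 3, 5, 10, 100, 0.001, 0.01, True)])
        t2 = self._table([("pw2", 2, 5, 10, 100, 0.2, 0.4, False)])
        out = compare_enrichment_across_contrasts({"c1": t1, "c2": t2}, top_k=1)
        assert out.loc["pw1", "c2"] == 0.0
        assert out.loc["pw1", "c1"] == pytest.approx(3.0)

    def test_requires_two_contrasts(self):
        t = self._table([("pw1", 3, 5, 10, 100, 0.01, 0.02, True)])
        with pytest.raises(ParameterError):
            compare_enrichment_across_contrasts({"c1": t})
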