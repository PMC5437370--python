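import numpy as np
import pytest

from barcodeval.io_formats import MarkerAlignment, SpeciesMap
from barcodeval.matrix_prep import (CleanPolicy, ItsChecks, clean_alignment,
                                    code_indels, find_diagnostic_characters,
                                    screen_its, site_stats)


def _smap(assignments):
    return SpeciesMap({i: (sp, None, None) for i, sp in assignments.items()})


class TestCleanAlignment:
    def test_all_ambiguous_column_removed(self):
        aln = MarkerAlignment("m", ["a", "b"], ["ANGT", "ANGT"])
        cleaned, kept = clean_alignment(aln)
        assert cleaned.rows == ["AGT", "AGT"]
        assert kept == [0, 2, 3]

    def test_poly_a_run_removed(self):
        rows = ["CG" + "A" * 10 + "CG", "CG" + "A" * 10 + "CG"]
        aln = MarkerAlignment("m", ["a", "b"], rows)
        cleaned, kept = clean_alignment(aln)
        assert cleaned.rows == ["CGCG", "CGCG"]
        assert kept == [0, 1, 12, 13]

    def test_clean_is_identity_without_offending_columns(self):
        aln = MarkerAlignment("m", ["a", "b"], ["ACGTAC", "ACGTAT"])
        cleaned, kept = clean_alignment(aln)
        assert cleaned.rows == aln.rows
        assert kept == list(range(6))

    def test_everything_removed_is_an_error(self):
        aln = MarkerAlignment("m", ["a"], ["NNN"])
        with pytest.raises(ValueError):
            clean_alignment(aln)

    def test_short_runs_survive(self):
        rows = ["CGAAAACG", "CGAAAACG"]
        aln = MarkerAlignment("m", ["a", "b"], rows)
        cleaned, _ = clean_alignment(aln, CleanPolicy(polyAT_min=8))
        assert cleaned.rows == rows


class TestCodeIndels:
    def test_textbook_simple_indel_coding(self):
        aln = MarkerAlignment("m", ["r1", "r2", "r3"],
                              ["AC--GT", "ACTTGT", "AC--GT"])
        coded, chars = code_indels(aln)
        assert len(chars) == 1
        assert chars[0].span == (2, 4)
        assert chars[0].presence == {"r1": True, "r2": False, "r3": True}
        assert [r[-1] for r in coded.rows] == ["T", "A", "T"]

    def test_strict_containment_scores_unknown(self):
        aln = MarkerAlignment("m", ["r1", "r2"], ["AC----GT", "ACT--TGT"])
        _, chars = code_indels(aln)
        spans = {c.span: c for c in chars}
        assert set(spans) == {(2, 6), (3, 5)}
        # r1's [2,6) gap strictly contains the [3,5) character
        assert spans[(3, 5)].presence["r1"] is None
        assert spans[(3, 5)].presence["r2"] is True
        assert spans[(2, 6)].presence["r2"] is False

    def test_no_gaps_is_identity(self):
        aln = MarkerAlignment("m", ["a", "b"], ["ACGT", "ACGA"])
        coded, chars = code_indels(aln)
        assert chars == []
        assert coded.rows == aln.rows

    def test_gap_topology_recoverable(self):
        rows = ["AAA---TTTT", "AAATTTTTTT", "AAA---TTTT", "AA----TTTT"]
        aln = MarkerAlignment("m", list("abcd"), rows)
        coded, chars = code_indels(aln)
        # appended column count equals distinct gap spans
        assert coded.length == aln.length + len(chars)
        assert {c.span for c in chars} == {(3, 6), (2, 6)}
        for ch in chars:
            carriers = {i for i, p in ch.presence.items() if p is True}
            expected = {i for i, r in zip(aln.ids, aln.rows)
                        if "-" * (ch.span[1] - ch.span[0]) ==
                        r[ch.span[0]:ch.span[1]]
                        and (ch.span[0] == 0 or r[ch.span[0] - 1] != "-")
                        and (ch.span[1] == len(r) or r[ch.span[1]] != "-")}
            assert carriers == expected

    def test_diagnostic_indel_annotation(self):
        rows = ["AAA---TTTT", "AAA---TTTT", "AAATTTTTTT", "AAATTTTTTT"]
        aln = MarkerAlignment("m", ["x1", "x2", "y1", "y2"], rows)
        smap = _smap({"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"})
        _, chars = code_indels(aln, smap)
        assert chars[0].diagnostic_for == "X"


class TestScreenIts:
    def test_gc_bounds(self):
        aln = MarkerAlignment("m", ["lo", "ok"],
                              ["ATATATATAT", "GCGCGCATAT"])
        flags = screen_its(aln)  # defaults 45-70%
        assert flags == {"lo": False, "ok": True}

    def test_motif_check_iupac_aware(self):
        aln = MarkerAlignment("m", ["a", "b"],
                              ["ATGCGATCGC", "ATGAGATCGC"])  # GC 60% / 50%
        checks = ItsChecks(motifs_5_8s=["ATGY"])  # Y matches C/T
        flags = screen_its(aln, checks)
        assert flags["a"] is True   # ATGC matches ATGY
        assert flags["b"] is False  # ATGA does not

    def test_empty_motif_list_passes_vacuously(self):
        aln = MarkerAlignment("m", ["a"], ["GCGCGCATAT"])
        assert screen_its(aln)["a"] is True


class TestSiteStats:
    def test_single_variable_uninformative_column(self):
        aln = MarkerAlignment("m", list("abc"), ["AAAA", "AAAT", "AAAA"])
        smap = _smap({"a": "X", "b": "X", "c": "Y"})
        s = site_stats(aln, smap)
        assert (s.n_variable, s.n_informative) == (1, 0)

    def test_all_columns_informative(self):
        aln = MarkerAlignment("m", list("abcd"),
                              ["AAT", "AAT", "CCA", "CCA"])
        smap = _smap({"a": "X", "b": "X", "c": "Y", "d": "Y"})
        s = site_stats(aln, smap)
        assert (s.n_variable, s.n_informative) == (3, 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_recount(self, seed):
        rng = np.random.default_rng(seed)
        n, L = 8, 30
        rows = ["".join(rng.choice(list("ACGTN-"), L, p=[.22, .22, .22, .22, .06, .06]))
                for _ in range(n)]
        ids = [f"i{k}" for k in range(n)]
        aln = MarkerAlignment("m", ids, rows)
        smap = _smap({i: f"sp{k % 3}" for k, i in enumerate(ids)})
        s = site_stats(aln, smap)
        n_var = n_inf = 0
        for c in range(L):
            from collections import Counter
            counts = Counter(r[c] for r in rows if r[c] in "ACGT")
            if len(counts) >= 2:
                n_var += 1
                if sum(1 for v in counts.values() if v >= 2) >= 2:
                    n_inf += 1
        assert (s.n_variable, s.n_informative) == (n_var, n_inf)
        assert s.n_diagnostic_indels <= s.n_indels


class TestDiagnostics:
    def test_simple_diagnostic(self):
        aln = MarkerAlignment("m", ["x1", "x2", "y1", "y2"],
                              ["AATAA", "AATAA", "AACAA", "AACAA"])
        smap = _smap({"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"})
        d = find_diagnostic_characters(aln, smap)
        assert (2, "T") in d["X"]
        assert (2, "C") in d["Y"]

    def test_polymorphic_species_not_diagnostic(self):
        aln = MarkerAlignment("m", ["x1", "x2", "y1"],
                              ["AATAA", "AACAA", "AAGAA"])
        smap = _smap({"x1": "X", "x2": "X", "y1": "Y"})
        d = find_diagnostic_characters(aln, smap)
        assert d["X"] == []

    def test_ambiguity_blocks_diagnostic_conservatively(self):
        # Y = C/T: the heterospecific Y overlaps T and blocks it
        aln = MarkerAlignment("m", ["x1", "x2", "y1"],
                              ["AATAA", "AATAA", "AAYAA"])
        smap = _smap({"x1": "X", "x2": "X", "y1": "Y"})
        d = find_diagnostic_characters(aln, smap)
        assert (2, "T") not in d["X"]
        # and an ambiguity code never supplies a state
        assert d["Y"] == []
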