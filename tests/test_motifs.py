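import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import (
    binomial_tail_exact,
    count_matches_oracle,
    discover_oracle,
)
from promin import (
    MotifPattern,
    ProteinSequence,
    SequenceSet,
    binomial_tail,
    collapse_motifs,
    count_matches,
    discover_at_center,
    enrichment,
    extract_windows,
    ps_values,
    run_motif_finder,
    spike_motif,
)
from promin.motifs import MotifError, MotifStats, WindowSet
from promin.seqio import AA_ORDER


def _window_set(strings, center, width=None):
    width = width or len(strings[0])
    codes = np.array(
        [np.frombuffer(w.encode(), dtype=np.uint8) for w in strings]
    )
    return WindowSet(
        codes=codes,
        source_ids=[f"s{i}" for i in range(len(strings))],
        source_index=np.arange(len(strings)),
        center_pos=np.ones(len(strings), dtype=np.int64),
        center=center,
        width=width,
    )


class TestExtractWindows:
    def test_edge_padding(self):
        sset = SequenceSet("s", [ProteinSequence("p", "MKSAP")])
        ws = extract_windows(sset, "S", 7)
        assert [w.text for w in ws.windows()] == ["-MKSAP-"]
        assert ws.windows()[0].center_pos == 3

    def test_one_window_per_occurrence(self):
        sset = SequenceSet("s", [ProteinSequence("p", "SS")])
        ws = extract_windows(sset, "S", 3)
        assert [w.text for w in ws.windows()] == ["-SS", "SS-"]

    def test_absent_center_and_even_width(self):
        sset = SequenceSet("s", [ProteinSequence("p", "MKAP")])
        assert len(extract_windows(sset, "S", 3)) == 0
        with pytest.raises(MotifError):
            extract_windows(sset, "S", 4)


class TestBinomialTail:
    @pytest.mark.parametrize(
        "k,n,p,expected",
        [(2, 2, 0.5, 0.25), (0, 7, 0.3, 1.0), (5, 5, 0.05, 3.125e-7)],
    )
    def test_known_values(self, k, n, p, expected):
        assert binomial_tail(k, n, p) == pytest.approx(expected, rel=1e-9)

    @given(
        st.integers(0, 30),
        st.integers(0, 30),
        st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_matches_exact_summation(self, k, n, p):
        if k > n:
            k, n = n, k
        assert binomial_tail(k, n, p) == pytest.approx(
            binomial_tail_exact(k, n, p), rel=1e-9, abs=1e-12
        )

    def test_deep_tail_stability(self):
        # 200 of 200 successes at p=0.03: ~1e-305, must not underflow to 0
        assert 0 < binomial_tail(200, 200, 0.03) < 1e-300

    def test_range_errors(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(1, 3, 1.5)


class TestDiscoverAtCenter:
    def test_strong_identical_foreground(self):
        rng = np.random.default_rng(0)
        fg = ["ASA"] * 30
        bg = ["".join(rng.choice(list("ACDE"))) + "S" + "".join(rng.choice(list("ACDE")))
              for _ in range(400)]
        res = discover_at_center(
            _window_set(fg, "S"), _window_set(bg, "S"), p_thresh=1e-6, min_occ=5
        )
        assert len(res) == 1
        pattern, trace = res[0]
        assert pattern.pattern == "ASA"
        assert {step.position for step in trace} == {0, 2}

    def test_null_foreground_gives_nothing(self):
        rng = np.random.default_rng(1)
        for rep in range(5):
            bg = ["".join(rng.choice(list(AA_ORDER), 3)) for _ in range(500)]
            bg = [w[0] + "S" + w[2] for w in bg]
            idx = rng.choice(len(bg), 40, replace=False)
            fg = [bg[i] for i in idx]
            res = discover_at_center(
                _window_set(fg, "S"), _window_set(bg, "S"), 1e-6, 5
            )
            assert res == []

    def test_min_occ_larger_than_foreground(self):
        fg = ["ASA"] * 3
        bg = ["CSC"] * 50
        assert discover_at_center(_window_set(fg, "S"), _window_set(bg, "S"), 1e-6, 5) == []

    def test_empty_background_is_error(self):
        with pytest.raises(MotifError):
            discover_at_center(
                _window_set(["ASA"], "S"),
                _window_set(["ASA"], "S").__class__(
                    codes=np.empty((0, 3), dtype=np.uint8),
                    source_ids=[],
                    source_index=np.empty(0, dtype=np.int64),
                    center_pos=np.empty(0, dtype=np.int64),
                    center="S",
                    width=3,
                ),
                1e-6,
                5,
            )

    def test_trace_is_conservative(self):
        rng = np.random.default_rng(2)
        bg = [
            "".join(rng.choice(list("ACDE"), 5)) for _ in range(600)
        ]
        bg = [w[:2] + "S" + w[3:] for w in bg]
        fg = ["CASAC" if i % 2 else "DASAD" for i in range(40)]
        res = discover_at_center(_window_set(fg, "S"), _window_set(bg, "S"), 1e-4, 5)
        assert res
        for _pattern, trace in res:
            assert all(step.p < 1e-4 for step in trace)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_enumeration_oracle(self, seed):
        """Every fixing decision matches a naive exhaustive re-enactment
        on a restricted 4-letter alphabet."""
        rng = np.random.default_rng(seed)
        alphabet = "ACDE"
        bg = ["".join(rng.choice(list(alphabet), 3)) for _ in range(300)]
        bg = [w[0] + "A" + w[2] for w in bg]
        # foreground: noisy mixture biased towards C at position 0
        fg = []
        for _ in range(60):
            w = "".join(rng.choice(list(alphabet), 3))
            if rng.random() < 0.6:
                w = "C" + w[1:]
            fg.append(w[0] + "A" + w[2])
        got = discover_at_center(
            _window_set(fg, "A"), _window_set(bg, "A"), p_thresh=1e-3, min_occ=5
        )
        expected = discover_oracle(fg, bg, 1, 1e-3, 5, alphabet=AA_ORDER)
        assert [p.pattern for p, _ in got] == [p for p, _ in expected]
        for (_, trace), (_, exp_trace) in zip(got, expected):
            assert [(s.position, s.residue) for s in trace] == [
                (j, r) for j, r, _ in exp_trace
            ]
            for s, (_, _, pv) in zip(trace, exp_trace):
                assert s.p == pytest.approx(pv, rel=1e-6, abs=1e-15)


class TestCollapse:
    def test_paper_style_redundancy(self):
        motifs = [MotifPattern("...S.S.."), MotifPattern("..S.S...")]
        assert [m.pattern for m in collapse_motifs(motifs)] == ["S.S"]

    def test_idempotent_and_trivial(self):
        assert [m.pattern for m in collapse_motifs([MotifPattern("AG")])] == ["AG"]
        motifs = [MotifPattern(".A."), MotifPattern("A")]
        assert [m.pattern for m in collapse_motifs(motifs)] == ["A"]

    @given(
        st.lists(
            st.text(alphabet=list(AA_ORDER) + ["."], min_size=1, max_size=9).filter(
                lambda s: set(s) != {"."}
            ),
            min_size=0,
            max_size=12,
        )
    )
    def test_idempotence_property(self, patterns):
        motifs = [MotifPattern(p) for p in patterns]
        once = collapse_motifs(motifs)
        twice = collapse_motifs(once)
        assert [m.pattern for m in once] == [m.pattern for m in twice]
        for m in once:
            assert not m.pattern.startswith(".") and not m.pattern.endswith(".")


class TestCountMatches:
    @pytest.mark.parametrize(
        "pattern,seq,occ",
        [("GG", "GGGAGG", 3), ("S.S", "SASTS", 2), ("Q", "AAA", 0)],
    )
    def test_enumerated_examples(self, pattern, seq, occ):
        o, p = count_matches(
            MotifPattern(pattern), SequenceSet("s", [ProteinSequence("x", seq)])
        )
        assert o == occ
        assert p == (1 if occ else 0)

    def test_wildcard_never_matches_unknowns(self):
        o, _ = count_matches(
            MotifPattern("S.S"), SequenceSet("s", [ProteinSequence("x", "SXS")])
        )
        assert o == 0

    def test_against_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        letters = list(AA_ORDER + "X")
        for _ in range(300):
            seq = "".join(rng.choice(letters, rng.integers(5, 60)))
            width = int(rng.integers(1, 6))
            pat = "".join(rng.choice(list(AA_ORDER + "...."), width))
            if set(pat) == {"."}:
                pat = "A" + pat[1:]
            got, _ = count_matches(
                MotifPattern(pat), SequenceSet("s", [ProteinSequence("x", seq)])
            )
            assert got == count_matches_oracle(pat, seq)


class TestEnrichmentAndPs:
    def test_identical_sets_give_unity(self, small_background):
        m = MotifPattern("A")
        assert enrichment(m, small_background, small_background) == pytest.approx(1.0)

    def test_absent_from_background_is_infinite(self):
        fg = SequenceSet("fg", [ProteinSequence("a", "WWCWWAAAA")])
        bg = SequenceSet("bg", [ProteinSequence("b", "AAAAAAAAA")])
        assert np.isinf(enrichment(MotifPattern("WWCWW"), fg, bg))

    def test_constructed_double_density(self):
        fg = SequenceSet("fg", [ProteinSequence("a", "GG" + "A" * 8)])  # 1 per 10
        bg = SequenceSet("bg", [ProteinSequence("b", "GG" + "A" * 18)])  # 1 per 20
        assert enrichment(MotifPattern("GG"), fg, bg) == pytest.approx(2.0)

    def test_swap_symmetry(self, small_background):
        fg, _ = spike_motif(small_background, "HMH", 0.3, seed=8)
        for pat in ["A", "G.G", "HMH"]:
            m = MotifPattern(pat)
            e1 = enrichment(m, fg, small_background)
            e2 = enrichment(m, small_background, fg)
            if np.isfinite(e1) and e1 > 0:
                assert e1 * e2 == pytest.approx(1.0)

    def test_ps_value_worked_example(self):
        def stat(fp, enr):
            return MotifStats(MotifPattern("A"), 1, 1, fp, 1, enr, enr)

        stats = ps_values([stat(10, 2.0), stat(5, 4.0), stat(7, 3.0)])
        assert [s.ps_value for s in stats] == pytest.approx([0.0, 0.0, 0.2])

    def test_ps_degenerate_conventions(self):
        def stat(fp, enr):
            return MotifStats(MotifPattern("A"), 1, 1, fp, 1, enr, enr)

        (single,) = ps_values([stat(4, 2.0)])
        assert single.ps_value == 1.0
        same = ps_values([stat(4, 2.0), stat(4, 2.0)])
        assert [s.ps_value for s in same] == [1.0, 1.0]
        with pytest.warns(UserWarning):
            stats = ps_values([stat(4, np.inf)])
        assert stats[0].ps_value is None


class TestRunMotifFinder:
    def test_spiked_motif_recovered(self, uniform_background):
        fg, rec = spike_motif(uniform_background, "WCWCW", 0.5, seed=11)
        stats = run_motif_finder(fg, uniform_background)
        matching = [
            s for s in stats if count_matches_oracle(s.motif.pattern, rec.motif) > 0
        ]
        assert matching, "no reported motif matches within the spiked literal"
        assert max(s.fg_proteins for s in matching) >= len(rec.spiked_ids)

    def test_negative_control_is_empty(self, uniform_background):
        from promin import sample_without_replacement

        fg = sample_without_replacement(uniform_background, 60, seed=21)
        assert run_motif_finder(fg, uniform_background) == []
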