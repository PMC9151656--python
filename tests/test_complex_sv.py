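"""Junction graph, oscillation counting, chromothripsis gate, classification."""

import itertools

import numpy as np
import pytest

from svtopo.complex_sv import (
    CHROMOPLEXY,
    CHROMOTHRIPSIS,
    TEMPLATED_INSERTION,
    ComplexParams,
    build_junction_graph,
    call_complex_events,
    classify_event,
    count_oscillations,
    detect_chromothripsis,
    extract_bridges,
    find_candidates,
)
from svtopo.io_formats import Breakend, CNSegment, Junction
from svtopo.synthetic_data import SimParams, simulate_chain, simulate_chromothripsis


def _j(jid, c1, p1, c2, p2, sample="s1", svclass=None):
    svclass = svclass or ("TRA" if c1 != c2 else "INV")
    return Junction(
        jid, sample, Breakend(c1, p1, "head"), Breakend(c2, p2, "head" if svclass == "INV" else "tail"), svclass
    ).canonical()


def _segs(cns, chrom="chr1", start=0, width=100, sample="s1"):
    """CN segment run from a list of (total, minor) or totals."""
    out = []
    for i, cn in enumerate(cns):
        total, minor = cn if isinstance(cn, tuple) else (cn, 0 if cn <= 1 else 1)
        out.append(
            CNSegment(sample, chrom, start + i * width, start + (i + 1) * width,
                      total, minor)
        )
    return out


class TestJunctionGraph:
    def test_edge_within_window(self):
        a = _j("a", "chr1", 100, "chr2", 200)
        b = _j("b", "chr2", 700, "chr3", 50)
        g = build_junction_graph([a, b], w_chain=10_000)
        assert g.has_edge("a", "b")

    def test_no_edge_beyond_window(self):
        a = _j("a", "chr1", 100, "chr2", 200)
        b = _j("b", "chr2", 2_000_200, "chr3", 50)
        g = build_junction_graph([a, b], w_chain=1_000_000)
        assert not g.has_edge("a", "b")

    def test_adjacency_matches_all_pairs_scan(self):
        rng = np.random.default_rng(2)
        chroms = ["chr1", "chr2", "chr3"]
        js = []
        for i in range(50):
            c1, c2 = rng.choice(chroms, 2, replace=False)
            js.append(
                _j(f"j{i}", c1, int(rng.integers(0, 5_000_000)), c2,
                   int(rng.integers(0, 5_000_000)))
            )
        w = 400_000
        g = build_junction_graph(js, w)
        for a, b in itertools.combinations(js, 2):
            expected = any(
                x.chrom == y.chrom and abs(x.pos - y.pos) <= w
                for x in a.breakends
                for y in b.breakends
            )
            assert g.has_edge(a.id, b.id) == expected

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(4)
        js = [
            _j(f"j{i}", "chr1", int(rng.integers(0, 3_000_000)), "chr2",
               int(rng.integers(0, 3_000_000)))
            for i in range(40)
        ]
        w = 200_000
        g = build_junction_graph(js, w)
        cands = find_candidates(g, js, min_junctions=1)
        # independent union-find
        parent = {j.id: j.id for j in js}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in itertools.combinations(js, 2):
            if any(
                x.chrom == y.chrom and abs(x.pos - y.pos) <= w
                for x in a.breakends
                for y in b.breakends
            ):
                parent[find(a.id)] = find(b.id)
        oracle = {}
        for j in js:
            oracle.setdefault(find(j.id), set()).add(j.id)
        assert {frozenset(c.junction_ids) for c in cands} == {
            frozenset(v) for v in oracle.values()
        }

    def test_min_junctions_filters_small_components(self):
        js = [_j(f"j{i}", "chr1", 10_000_000 * (i + 1), "chr2",
                 10_000_000 * (i + 1)) for i in range(3)]
        g = build_junction_graph(js, w_chain=1_000)
        assert find_candidates(g, js, min_junctions=3) == []


class TestOscillations:
    def test_alternating_two_state_sequence(self):
        m = count_oscillations(_segs([2, 1, 2, 1, 2, 1, 2]))
        assert m["n_oscillations"] == 6
        assert m["n_cn_states"] == 2
        assert m["has_loh"]

    def test_constant_sequence(self):
        assert count_oscillations(_segs([2, 2, 2]))["n_oscillations"] == 0

    def test_third_state_breaks_the_run(self):
        m = count_oscillations(_segs([2, 1, 2, 4, 2, 1]))
        assert m["n_oscillations"] == 3
        assert m["n_cn_states"] == 3

    def test_empty_input(self):
        assert count_oscillations([]) == {
            "n_oscillations": 0, "n_cn_states": 0, "has_loh": False
        }

    def test_matches_enumeration_oracle(self):
        """Exhaustive check against a direct transition enumerator: all
        sequences up to length 8 over copy numbers {0,1,2,3}, plus a seeded
        random sample of longer ones (lengths 9-12)."""

        def oracle(values):
            if not values:
                return 0
            from collections import Counter

            freq = Counter(values)
            top2 = {
                cn
                for cn, _ in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
            }
            n = 0
            for a, b in zip(values, values[1:]):
                if a in top2 and b in top2 and a != b:
                    n += 1
            return n

        cases = []
        for length in range(1, 9):
            cases.extend(itertools.product(range(4), repeat=length))
        rng = np.random.default_rng(0)
        for _ in range(5000):
            length = int(rng.integers(9, 13))
            cases.append(tuple(rng.integers(0, 4, size=length).tolist()))
        for values in cases:
            got = count_oscillations(_segs(list(values)))["n_oscillations"]
            assert got == oracle(list(values)), values


class TestBridges:
    def _candidate(self, js):
        from svtopo.complex_sv import CandidateEvent

        return CandidateEvent(
            "e", "s1", frozenset(j.id for j in js),
            frozenset(b.chrom for j in js for b in j.breakends),
        )

    def test_deletion_bridge(self):
        js = [_j("a", "chr1", 1_000_000, "chr2", 5_000_000),
              _j("b", "chr1", 1_400_000, "chr3", 5_000_000)]
        cn = (
            _segs([2], "chr1", 0, 1_000_000)
            + _segs([(1, 0)], "chr1", 1_000_000, 400_000)
            + [CNSegment("s1", "chr1", 1_400_000, 3_000_000, 2, 1)]
            + [CNSegment("s1", "chr2", 0, 10_000_000, 2, 1)]
            + [CNSegment("s1", "chr3", 0, 10_000_000, 2, 1)]
        )
        (bridge,) = extract_bridges(self._candidate(js), {j.id: j for j in js}, cn)
        assert bridge.kind == "del" and bridge.cn_delta == -1

    def test_gain_bridge(self):
        js = [_j("a", "chr1", 1_000_000, "chr2", 5_000_000),
              _j("b", "chr1", 1_400_000, "chr3", 5_000_000)]
        cn = (
            _segs([2], "chr1", 0, 1_000_000)
            + [CNSegment("s1", "chr1", 1_000_000, 1_400_000, 3, 1)]
            + [CNSegment("s1", "chr1", 1_400_000, 3_000_000, 2, 1)]
            + [CNSegment("s1", "chr2", 0, 10_000_000, 2, 1)]
            + [CNSegment("s1", "chr3", 0, 10_000_000, 2, 1)]
        )
        (bridge,) = extract_bridges(self._candidate(js), {j.id: j for j in js}, cn)
        assert bridge.kind == "gain" and bridge.cn_delta == 1

    def test_uncovered_breakend_is_an_error(self):
        js = [_j("a", "chr1", 1_000_000, "chr2", 5_000_000),
              _j("b", "chr1", 1_400_000, "chr3", 5_000_000)]
        with pytest.raises(ValueError, match="outside CN"):
            extract_bridges(self._candidate(js), {j.id: j for j in js}, [])


class TestChromothripsis:
    def _planted(self, seed=0):
        rng = np.random.default_rng(seed)
        js, overlays = simulate_chromothripsis(
            "s1", "chr1", 50_000_000, n_breakends=16, max_gap=450_000,
            rng=rng, id_start=0,
        )
        cn = [CNSegment("s1", "chr1", 0, 50_000_000, 2, 1)]
        # apply overlays onto the baseline tiling
        from svtopo.synthetic_data import _CNProfile

        prof = _CNProfile(50_000_000)
        for s, e, t, m in overlays:
            prof.overlay(s, e, t, m)
        cn = [CNSegment("s1", "chr1", a, b, t, m) for a, b, t, m in prof.segments]
        return js, cn

    def test_planted_cluster_called(self):
        js, cn = self._planted()
        calls = detect_chromothripsis(js, cn)
        assert len(calls) == 1
        assert calls[0].n_breakends >= 10
        assert calls[0].has_loh

    def test_flat_cn_never_called(self):
        js, _ = self._planted()
        flat = [CNSegment("s1", "chr1", 0, 50_000_000, 2, 1)]
        assert detect_chromothripsis(js, flat) == []

    def test_too_few_breakends_not_called(self):
        rng = np.random.default_rng(1)
        js, overlays = simulate_chromothripsis(
            "s1", "chr1", 50_000_000, n_breakends=4, max_gap=450_000,
            rng=rng, id_start=0,
        )
        from svtopo.synthetic_data import _CNProfile

        prof = _CNProfile(50_000_000)
        for s, e, t, m in overlays:
            prof.overlay(s, e, t, m)
        cn = [CNSegment("s1", "chr1", a, b, t, m) for a, b, t, m in prof.segments]
        assert detect_chromothripsis(js, cn) == []

    def test_loh_requirement_is_a_switch(self):
        js, cn = self._planted()
        no_loh = [
            CNSegment(s.sample_id, s.chrom, s.start, s.end, s.total_cn,
                      max(s.minor_cn, 1) if s.total_cn else 0)
            for s in cn
        ]
        assert detect_chromothripsis(js, no_loh) == []
        relaxed = ComplexParams(require_loh=False)
        assert len(detect_chromothripsis(js, no_loh, relaxed)) == 1


class TestClassification:
    def _chain_sample(self, kind, seed=0):
        rng = np.random.default_rng(seed)
        js, overlays = simulate_chain(
            "s1", ["chr1", "chr2", "chr3"], 50_000_000, kind, rng, id_start=0
        )
        from svtopo.synthetic_data import _CNProfile

        cn = []
        for chrom in ["chr1", "chr2", "chr3"]:
            prof = _CNProfile(50_000_000)
            for s, e, t, m in overlays.get(chrom, []):
                prof.overlay(s, e, t, m)
            cn += [CNSegment("s1", chrom, a, b, t, m) for a, b, t, m in prof.segments]
        return js, cn

    def test_gain_chain_is_templated_insertion(self):
        js, cn = self._chain_sample("gain")
        events, flags = call_complex_events(js, cn)
        assert [e.label for e in events] == [TEMPLATED_INSERTION]
        assert not events[0].simple_chain  # 3 chromosomes involved
        assert flags["has_templated_insertion"]

    def test_del_chain_is_chromoplexy(self):
        js, cn = self._chain_sample("del")
        events, flags = call_complex_events(js, cn)
        assert [e.label for e in events] == [CHROMOPLEXY]
        assert flags["has_chromoplexy"]

    def test_classification_invariant_to_junction_order(self):
        js, cn = self._chain_sample("del", seed=3)
        fwd, _ = call_complex_events(js, cn)
        rev, _ = call_complex_events(list(reversed(js)), cn)
        assert [e.label for e in fwd] == [e.label for e in rev]
        assert [e.junction_ids for e in fwd] == [e.junction_ids for e in rev]

    def test_chromothripsis_outranks_bridges(self):
        """Junctions inside a chromothripsis call take the chromothripsis
        label even though oscillating CN yields incidental del bridges."""
        rng = np.random.default_rng(6)
        js, overlays = simulate_chromothripsis(
            "s1", "chr1", 50_000_000, 16, 450_000, rng, 0
        )
        from svtopo.synthetic_data import _CNProfile

        prof = _CNProfile(50_000_000)
        for s, e, t, m in overlays:
            prof.overlay(s, e, t, m)
        cn = [CNSegment("s1", "chr1", a, b, t, m) for a, b, t, m in prof.segments]
        events, flags = call_complex_events(js, cn)
        assert flags["has_chromothripsis"]
        assert all(e.label == CHROMOTHRIPSIS for e in events)

    def test_each_junction_in_at_most_one_event(self, small_cohort):
        for sample_id in list(small_cohort.truth.burden_class)[:10]:
            events, _ = call_complex_events(
                small_cohort.junctions_of(sample_id),
                small_cohort.cn_of(sample_id),
                chrom_lengths=small_cohort.chrom_lengths,
            )
            seen = set()
            for e in events:
                assert not (e.junction_ids & seen)
                seen |= e.junction_ids


class TestCohortRecovery:
    def test_planted_labels_recovered(self, small_cohort):
        c = small_cohort
        for sample_id, planted in c.truth.events.items():
            events, flags = call_complex_events(
                c.junctions_of(sample_id), c.cn_of(sample_id),
                chrom_lengths=c.chrom_lengths,
            )
            for ev in planted:
                assert flags[f"has_{ev.event_type}"], (sample_id, ev.event_type)
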