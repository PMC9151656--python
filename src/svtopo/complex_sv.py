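"""Complex rearrangement calling: junction graph, chained candidates, and
classification as chromothripsis, chromoplexy or templated insertion.

The classifier operationalizes the field's qualitative definitions:

* **chromothripsis** — localized clustered rearrangements with copy number
  oscillating between two dominant states and loss of heterozygosity;
* **chromoplexy** — chained junctions whose bridge segments (the intervals
  between chained breakends on one chromosome) show copy-number loss;
* **templated insertion** — chained junctions with copy-number *gain*
  bridges; called "complex" when more than two chromosomes participate.

All thresholds live in :class:`ComplexParams` and are surfaced on the CLI.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from svtopo.io_formats import Breakend, CNSegment, Junction

CHROMOTHRIPSIS = "chromothripsis"
CHROMOPLEXY = "chromoplexy"
TEMPLATED_INSERTION = "templated_insertion"
UNCLASSIFIED = "unclassified_complex"

LABELS = (CHROMOTHRIPSIS, CHROMOPLEXY, TEMPLATED_INSERTION, UNCLASSIFIED)


@dataclass(frozen=True)
class ComplexParams:
    """Tunable thresholds for complex-event calling (all in bp or counts)."""

    w_chain: int = 1_000_000  # max breakend distance for chaining two junctions
    min_junctions: int = 3  # smallest chained component kept as a candidate
    min_breakends: int = 10  # chromothripsis: cluster size gate
    ct_window: int = 50_000_000  # chromothripsis: max gap between clustered breakends
    min_oscillations: int = 7  # chromothripsis: 2-state CN transitions required
    require_loh: bool = True  # chromothripsis: demand a minor_cn=0 segment
    flank: int = 1_000_000  # bridge flank width for the modal-CN baseline
    ct_overlap: float = 0.5  # fraction of junctions inside a call => chromothripsis
    min_bridges: int = 2  # del/gain bridges needed for chromoplexy/TI


@dataclass(frozen=True)
class CandidateEvent:
    event_id: str
    sample_id: str
    junction_ids: frozenset[str]
    chroms: frozenset[str]

    @property
    def n_junctions(self) -> int:
        return len(self.junction_ids)


@dataclass(frozen=True)
class Bridge:
    """Interval between two chained breakends on one chromosome."""

    chrom: str
    start: int
    end: int
    cn_delta: int

    @property
    def kind(self) -> str:
        if self.cn_delta < 0:
            return "del"
        if self.cn_delta > 0:
            return "gain"
        return "neutral"


@dataclass(frozen=True)
class ChromothripsisCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_breakends: int
    n_oscillations: int
    n_cn_states: int
    has_loh: bool


@dataclass(frozen=True)
class ComplexEvent(CandidateEvent):
    label: str = UNCLASSIFIED
    metrics: dict = field(default_factory=dict, compare=False)
    simple_chain: bool = False  # templated insertion spanning only 2 chromosomes


# ---------------------------------------------------------------------------
# Graph construction and candidate extraction
# ---------------------------------------------------------------------------

def build_junction_graph(
    junctions: Sequence[Junction], w_chain: int
) -> "nx.Graph":
    """Graph with one node per junction; edge iff the two junctions each
    have a breakend on the same chromosome within ``w_chain`` bp."""
    if w_chain <= 0:
        raise ValueError("w_chain must be positive")
    g = nx.Graph()
    for j in junctions:
        g.add_node(j.id)
    # sweep per chromosome instead of the all-pairs scan
    per_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for j in junctions:
        for bnd in j.breakends:
            per_chrom[bnd.chrom].append((bnd.pos, j.id))
    for positions in per_chrom.values():
        positions.sort()
        for i, (pos_i, id_i) in enumerate(positions):
            for pos_k, id_k in positions[i + 1 :]:
                if pos_k - pos_i > w_chain:
                    break
                if id_i != id_k:
                    g.add_edge(id_i, id_k)
    return g


def find_candidates(
    graph: "nx.Graph",
    junctions: Sequence[Junction],
    min_junctions: int = 3,
) -> list[CandidateEvent]:
    """Connected components with >= ``min_junctions`` junctions."""
    by_id = {j.id: j for j in junctions}
    candidates: list[CandidateEvent] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    for idx, comp in enumerate(components):
        if len(comp) < min_junctions:
            continue
        members = [by_id[i] for i in comp]
        sample_ids = {j.sample_id for j in members}
        if len(sample_ids) != 1:
            raise ValueError("candidate event spans multiple samples")
        chroms = frozenset(b.chrom for j in members for b in j.breakends)
        candidates.append(
            CandidateEvent(
                event_id=f"{members[0].sample_id}_ev{idx}",
                sample_id=members[0].sample_id,
                junction_ids=frozenset(comp),
                chroms=chroms,
            )
        )
    return candidates


# ---------------------------------------------------------------------------
# Copy-number helpers
# ---------------------------------------------------------------------------

def _segments_in(
    segments: Sequence[CNSegment], chrom: str, start: int, end: int
) -> list[CNSegment]:
    return [
        s
        for s in segments
        if s.chrom == chrom and s.start < end and s.end > start
    ]


def _modal_cn(segments: Sequence[CNSegment], start: int, end: int) -> int | None:
    """Most common total_cn in [start, end), weighted by overlap length.

    Ties break toward the lower copy number (deterministic)."""
    weight: Counter[int] = Counter()
    for s in segments:
        ov = min(s.end, end) - max(s.start, start)
        if ov > 0:
            weight[s.total_cn] += ov
    if not weight:
        return None
    return min(cn for cn, w in weight.items() if w == max(weight.values()))


def extract_bridges(
    event: CandidateEvent,
    junctions: Mapping[str, Junction],
    cn: Sequence[CNSegment],
    params: ComplexParams = ComplexParams(),
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[Bridge]:
    """Bridges of a chained event: for each pair of chained breakends from
    different junctions on one chromosome, the intervening interval.

    ``cn_delta`` = modal total copy number inside the bridge minus the
    modal copy number of the two flanking regions (``params.flank`` bp each
    side, clipped at chromosome ends).
    """
    cn_by_chrom: dict[str, list[CNSegment]] = defaultdict(list)
    for s in cn:
        cn_by_chrom[s.chrom].append(s)

    per_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for jid in event.junction_ids:
        j = junctions[jid]
        for bnd in j.breakends:
            per_chrom[bnd.chrom].append((bnd.pos, jid))

    bridges: list[Bridge] = []
    for chrom, positions in per_chrom.items():
        positions.sort()
        segs = sorted(cn_by_chrom.get(chrom, []), key=lambda s: s.start)
        for pos, jid in positions:
            if not any(s.start <= pos < s.end for s in segs):
                raise ValueError(
                    f"breakend {chrom}:{pos} outside CN segment coverage"
                )
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        for (p1, id1), (p2, id2) in zip(positions, positions[1:]):
            if id1 == id2 or p2 - p1 > params.w_chain or p2 == p1:
                continue
            inner = _modal_cn(_segments_in(segs, chrom, p1, p2), p1, p2)
            lo = max(0, p1 - params.flank)
            hi = p2 + params.flank if length is None else min(p2 + params.flank, length)
            flank_segs = _segments_in(segs, chrom, lo, p1) + _segments_in(
                segs, chrom, p2, hi
            )
            weight: Counter[int] = Counter()
            for s in flank_segs:
                for a, b in ((lo, p1), (p2, hi)):
                    ov = min(s.end, b) - max(s.start, a)
                    if ov > 0:
                        weight[s.total_cn] += ov
            flank_cn = (
                min(cn for cn, w in weight.items() if w == max(weight.values()))
                if weight
                else None
            )
            if inner is None or flank_cn is None:
                continue
            bridges.append(
                Bridge(chrom=chrom, start=p1, end=p2, cn_delta=inner - flank_cn)
            )
    return bridges


def count_oscillations(segments: Sequence[CNSegment]) -> dict:
    """Oscillation metrics over ordered CN segments of one chromosome window.

    * ``n_cn_states`` — number of distinct total copy numbers;
    * ``n_oscillations`` — adjacent-segment transitions alternating between
      the two most frequent copy-number states (a transition touching any
      other state does not count, and equal adjacent values do not
      alternate);
    * ``has_loh`` — any segment with minor_cn = 0 and total_cn >= 1.

    Ties for the two dominant states break toward the lower copy number.
    """
    if not segments:
        return {"n_oscillations": 0, "n_cn_states": 0, "has_loh": False}
    values = [s.total_cn for s in segments]
    freq = Counter(values)
    # top-2 states by frequency, ties to lower CN
    top2 = {cn for cn, _ in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:2]}
    n_osc = sum(
        1
        for a, b in zip(values, values[1:])
        if a != b and a in top2 and b in top2
    )
    return {
        "n_oscillations": n_osc,
        "n_cn_states": len(freq),
        "has_loh": any(s.has_loh for s in segments),
    }


# ---------------------------------------------------------------------------
# Chromothripsis detection
# ---------------------------------------------------------------------------

def detect_chromothripsis(
    junctions: Sequence[Junction],
    cn: Sequence[CNSegment],
    params: ComplexParams = ComplexParams(),
) -> list[ChromothripsisCall]:
    """Call chromothripsis regions for one sample.

    Per chromosome, breakends are grouped into maximal clusters where
    adjacent breakends are <= ``params.ct_window`` apart. A cluster is
    chromothripsis iff it has >= ``params.min_breakends`` breakends, the CN
    segments spanning it oscillate >= ``params.min_oscillations`` times
    between the two dominant copy-number states, and (when
    ``params.require_loh``) the span contains loss of heterozygosity.
    """
    sample_ids = {j.sample_id for j in junctions}
    if len(sample_ids) > 1:
        raise ValueError("detect_chromothripsis expects junctions from one sample")
    sample_id = sample_ids.pop() if sample_ids else ""

    per_chrom: dict[str, list[int]] = defaultdict(list)
    for j in junctions:
        for bnd in j.breakends:
            per_chrom[bnd.chrom].append(bnd.pos)
    cn_by_chrom: dict[str, list[CNSegment]] = defaultdict(list)
    for s in cn:
        cn_by_chrom[s.chrom].append(s)

    calls: list[ChromothripsisCall] = []
    for chrom in sorted(per_chrom):
        positions = sorted(per_chrom[chrom])
        clusters: list[list[int]] = [[positions[0]]]
        for pos in positions[1:]:
            if pos - clusters[-1][-1] <= params.ct_window:
                clusters[-1].append(pos)
            else:
                clusters.append([pos])
        segs = sorted(cn_by_chrom.get(chrom, []), key=lambda s: s.start)
        for cluster in clusters:
            if len(cluster) < params.min_breakends:
                continue
            lo, hi = cluster[0], cluster[-1] + 1
            window = _segments_in(segs, chrom, lo, hi)
            m = count_oscillations(sorted(window, key=lambda s: s.start))
            if m["n_oscillations"] < params.min_oscillations:
                continue
            if params.require_loh and not m["has_loh"]:
                continue
            calls.append(
                ChromothripsisCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=lo,
                    end=hi,
                    n_breakends=len(cluster),
                    n_oscillations=m["n_oscillations"],
                    n_cn_states=m["n_cn_states"],
                    has_loh=m["has_loh"],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _junction_in_calls(j: Junction, calls: Sequence[ChromothripsisCall]) -> bool:
    return any(
        bnd.chrom == c.chrom and c.start <= bnd.pos < c.end
        for bnd in j.breakends
        for c in calls
    )


def classify_event(
    candidate: CandidateEvent,
    junctions: Mapping[str, Junction],
    cn: Sequence[CNSegment],
    chromothripsis_calls: Sequence[ChromothripsisCall],
    params: ComplexParams = ComplexParams(),
    chrom_lengths: Mapping[str, int] | None = None,
) -> ComplexEvent:
    """Label a chained candidate by precedence:

    1. >= ``params.ct_overlap`` of its junctions inside a chromothripsis
       region call -> chromothripsis (chromothriptic regions generate
       incidental bridges, so this outranks the bridge rules);
    2. deletion bridges outnumber gain bridges and number >=
       ``params.min_bridges`` -> chromoplexy;
    3. the mirror-image gain condition -> templated insertion;
    4. otherwise unclassified_complex.
    """
    members = [junctions[i] for i in candidate.junction_ids]
    bridges = extract_bridges(candidate, junctions, cn, params, chrom_lengths)
    n_del = sum(1 for b in bridges if b.kind == "del")
    n_gain = sum(1 for b in bridges if b.kind == "gain")
    n_neutral = len(bridges) - n_del - n_gain

    # oscillation metrics over the widest per-chromosome event span
    spans: dict[str, tuple[int, int]] = {}
    for j in members:
        for bnd in j.breakends:
            lo, hi = spans.get(bnd.chrom, (bnd.pos, bnd.pos + 1))
            spans[bnd.chrom] = (min(lo, bnd.pos), max(hi, bnd.pos + 1))
    cn_by_chrom: dict[str, list[CNSegment]] = defaultdict(list)
    for s in cn:
        cn_by_chrom[s.chrom].append(s)
    best = {"n_oscillations": 0, "n_cn_states": 0, "has_loh": False}
    for chrom, (lo, hi) in spans.items():
        segs = sorted(
            _segments_in(cn_by_chrom.get(chrom, []), chrom, lo, hi),
            key=lambda s: s.start,
        )
        m = count_oscillations(segs)
        if m["n_oscillations"] > best["n_oscillations"]:
            best["n_oscillations"] = m["n_oscillations"]
        best["n_cn_states"] = max(best["n_cn_states"], m["n_cn_states"])
        best["has_loh"] = best["has_loh"] or m["has_loh"]

    n_in_ct = sum(1 for j in members if _junction_in_calls(j, chromothripsis_calls))
    if members and n_in_ct >= params.ct_overlap * len(members) and n_in_ct > 0:
        label = CHROMOTHRIPSIS
    elif n_del > n_gain and n_del >= params.min_bridges:
        label = CHROMOPLEXY
    elif n_gain > n_del and n_gain >= params.min_bridges:
        label = TEMPLATED_INSERTION
    else:
        label = UNCLASSIFIED

    metrics = {
        **best,
        "n_del_bridges": n_del,
        "n_gain_bridges": n_gain,
        "n_neutral_bridges": n_neutral,
        "n_junctions_in_chromothripsis": n_in_ct,
    }
    return ComplexEvent(
        event_id=candidate.event_id,
        sample_id=candidate.sample_id,
        junction_ids=candidate.junction_ids,
        chroms=candidate.chroms,
        label=label,
        metrics=metrics,
        simple_chain=(label == TEMPLATED_INSERTION and len(candidate.chroms) <= 2),
    )


def call_complex_events(
    junctions: Sequence[Junction],
    cn: Sequence[CNSegment],
    params: ComplexParams = ComplexParams(),
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[ComplexEvent], dict[str, bool]]:
    """End-to-end complex calling for one sample.

    Returns the labeled events plus per-sample flags
    ``has_chromothripsis`` / ``has_chromoplexy`` / ``has_templated_insertion``.
    """
    junctions = [j.canonical() for j in junctions]
    graph = build_junction_graph(junctions, params.w_chain)
    candidates = find_candidates(graph, junctions, params.min_junctions)
    ct_calls = detect_chromothripsis(junctions, cn, params) if junctions else []
    by_id = {j.id: j for j in junctions}
    events = [
        classify_event(c, by_id, cn, ct_calls, params, chrom_lengths)
        for c in candidates
    ]
    flags = {
        "has_chromothripsis": any(e.label == CHROMOTHRIPSIS for e in events),
        "has_chromoplexy": any(e.label == CHROMOPLEXY for e in events),
        "has_templated_insertion": any(
            e.label == TEMPLATED_INSERTION for e in events
        ),
    }
    return events, flags
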