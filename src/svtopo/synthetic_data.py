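"""Seeded synthetic cohorts for end-to-end testing of the pipeline.

The generator emulates the structure of a newly diagnosed multiple-myeloma
whole-genome cohort on a desk-scale toy genome (5 chromosomes x 50 Mb):

* heavy-tailed per-sample SV counts with a ~10% high-burden subpopulation
  (negative-binomial counts; cohort mean 31, high-burden mean 102, the
  medians reported for such cohorts);
* an intra/inter-chromosomal junction mix of roughly 25:6;
* planted complex events, one class per sample by default — chromothripsis
  (clustered breakends over a 2-state copy-number oscillation with LOH),
  chromoplexy (multi-chromosome cycle with deletion bridges) and templated
  insertion (the same topology with gain bridges) — at prevalences
  0.23 / 0.10 / 0.37;
* recurrent super-enhancer-hijack loci: a handful of target TADs each
  receiving TAD-TAD translocations in ~10% of samples, whose resident
  genes are upregulated by ``effect_log2fc`` in carriers.

Simple (non-planted) SVs are emitted copy-neutral so that every deletion
bridge, gain bridge and oscillation in the copy-number profile traces back
to a planted complex event; see the methods note for what this does and
does not exercise.

All randomness flows from ``SimParams.seed`` through one
``numpy.random.Generator``; identical parameters give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from svtopo.io_formats import (
    Breakend,
    CNSegment,
    GeneModel,
    Junction,
    Tad,
    HEAD,
    TAIL,
)

_SIMPLE_ORIENTS = {
    "DEL": (HEAD, TAIL),
    "DUP": (TAIL, HEAD),
    "INV": (HEAD, HEAD),
}


@dataclass(frozen=True)
class SimParams:
    """Study-condition parameters of the synthetic cohort."""

    seed: int
    n_samples: int = 200
    n_chroms: int = 5
    chrom_len: int = 50_000_000
    tad_size: int = 1_000_000
    tad_gap: int = 100_000  # inter-TAD boundary region
    genes_per_tad: int = 3
    sv_mean: float = 31.0  # simple-SV count, baseline samples
    sv_dispersion: float = 10.0  # NB size parameter, baseline samples
    high_burden_mean: float = 102.0
    high_burden_dispersion: float = 10.0
    frac_high_burden: float = 0.10
    frac_inter: float = 6.0 / 31.0  # translocation share of simple SVs
    frac_chromothripsis: float = 0.23
    frac_chromoplexy: float = 0.10
    frac_ti: float = 0.37
    ct_n_breakends: int = 16
    ct_max_gap: int = 450_000  # spacing within a chromothripsis cluster
    chain_n_chroms: int = 3
    n_hijack_tads: int = 8
    carriers_per_tad: int = 20
    effect_log2fc: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    mixed_events: bool = False  # allow several event classes per sample

    def __post_init__(self) -> None:
        for name in ("frac_high_burden", "frac_inter", "frac_chromothripsis",
                     "frac_chromoplexy", "frac_ti"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_chromothripsis + self.frac_chromoplexy + self.frac_ti > 1.0:
            raise ValueError("complex-event fractions sum to more than 1")
        if self.tad_size > self.chrom_len:
            raise ValueError("infeasible geometry: tad_size exceeds chrom_len")


@dataclass(frozen=True)
class PlantedEvent:
    event_type: str  # chromothripsis | chromoplexy | templated_insertion
    chroms: tuple[str, ...]
    junction_ids: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, the recovery-testing oracle."""

    burden_class: dict[str, str]  # sample -> "high" | "low"
    events: dict[str, list[PlantedEvent]]  # sample -> planted events
    gene_effects: dict[str, dict]  # gene -> {"log2fc": float, "carriers": frozenset}
    hijack_tads: list[str] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    params: SimParams
    chrom_lengths: dict[str, int]
    tads: list[Tad]
    genes: list[GeneModel]
    junctions: list[Junction]
    cn_segments: list[CNSegment]
    expression: pd.DataFrame
    truth: SyntheticTruth

    def junctions_of(self, sample_id: str) -> list[Junction]:
        return [j for j in self.junctions if j.sample_id == sample_id]

    def cn_of(self, sample_id: str) -> list[CNSegment]:
        return [s for s in self.cn_segments if s.sample_id == sample_id]


# ---------------------------------------------------------------------------
# CN overlay bookkeeping
# ---------------------------------------------------------------------------

class _CNProfile:
    """Mutable tiling of one (sample, chromosome) with CN states."""

    def __init__(self, length: int):
        self.segments: list[list[int]] = [[0, length, 2, 1]]  # start,end,total,minor

    def overlay(self, start: int, end: int, total: int, minor: int) -> None:
        out: list[list[int]] = []
        for s, e, t, m in self.segments:
            if e <= start or s >= end:
                out.append([s, e, t, m])
                continue
            if s < start:
                out.append([s, start, t, m])
            if e > end:
                out.append([end, e, t, m])
        out.append([start, end, total, minor])
        out.sort()
        self.segments = out


# ---------------------------------------------------------------------------
# Event generators
# ---------------------------------------------------------------------------

def simulate_chromothripsis(
    sample_id: str,
    chrom: str,
    chrom_len: int,
    n_breakends: int,
    max_gap: int,
    rng: np.random.Generator,
    id_start: int,
) -> tuple[list[Junction], list[tuple[int, int, int, int]]]:
    """A clustered shatter: paired breakends over a 2-state CN oscillation.

    Returns junctions plus CN overlays (start, end, total, minor). Segments
    alternate total CN 2 and 1 across the cluster span with minor_cn = 0 on
    the CN-1 segments, so the span carries both the oscillation and the LOH
    the chromothripsis definition demands.
    """
    if n_breakends < 4 or n_breakends % 2:
        raise ValueError("n_breakends must be an even number >= 4")
    gaps = rng.integers(max_gap // 4, max_gap, size=n_breakends - 1)
    span = int(gaps.sum())
    start = int(rng.integers(1_000_000, chrom_len - span - 1_000_000))
    positions = start + np.concatenate([[0], np.cumsum(gaps)]).astype(int)

    shuffled = positions.copy()
    rng.shuffle(shuffled)
    junctions: list[Junction] = []
    for k in range(0, n_breakends, 2):
        p1, p2 = sorted((int(shuffled[k]), int(shuffled[k + 1])))
        svclass = str(rng.choice(["DEL", "DUP", "INV"]))
        o1, o2 = _SIMPLE_ORIENTS[svclass]
        junctions.append(
            Junction(
                id=f"{sample_id}_j{id_start + k // 2}",
                sample_id=sample_id,
                bnd1=Breakend(chrom, p1, o1),
                bnd2=Breakend(chrom, p2, o2),
                svclass=svclass,
            )
        )
    overlays = []
    for k, (a, b) in enumerate(zip(positions, positions[1:])):
        if k % 2 == 0:
            overlays.append((int(a), int(b), 1, 0))  # CN 1 with LOH
        # odd segments stay at the baseline CN 2
    return junctions, overlays


def simulate_chain(
    sample_id: str,
    chroms: Sequence[str],
    chrom_len: int,
    bridge_kind: str,
    rng: np.random.Generator,
    id_start: int,
    n_junctions: int | None = None,
) -> tuple[list[Junction], dict[str, list[tuple[int, int, int, int]]]]:
    """A cyclic multi-chromosome chain with del or gain bridges.

    Each visited chromosome holds one short bridge [p, q); junction i joins
    q on chromosome i to p on chromosome i+1 (cyclically). ``bridge_kind``
    "del" plants CN 1 bridges with LOH (chromoplexy), "gain" plants CN 3
    bridges (templated insertion).
    """
    if len(set(chroms)) < 2:
        raise ValueError("a chain needs at least 2 distinct chromosomes")
    if bridge_kind not in ("del", "gain"):
        raise ValueError("bridge_kind must be 'del' or 'gain'")
    visits = list(chroms)
    if n_junctions is not None:
        if n_junctions < len(chroms):
            raise ValueError("n_junctions must be >= number of chromosomes")
        while len(visits) < n_junctions:
            visits.append(str(rng.choice(list(chroms))))

    anchors = []
    for chrom in visits:
        p = int(rng.integers(2_000_000, chrom_len - 3_000_000))
        q = p + int(rng.integers(100_000, 700_000))
        anchors.append((chrom, p, q))

    total, minor = (1, 0) if bridge_kind == "del" else (3, 1)
    overlays: dict[str, list[tuple[int, int, int, int]]] = {}
    for chrom, p, q in anchors:
        overlays.setdefault(chrom, []).append((p, q, total, minor))

    junctions = []
    n = len(anchors)
    for i in range(n):
        chrom_i, _, q_i = anchors[i]
        chrom_k, p_k, _ = anchors[(i + 1) % n]
        svclass = "TRA" if chrom_i != chrom_k else "INV"
        junctions.append(
            Junction(
                id=f"{sample_id}_j{id_start + i}",
                sample_id=sample_id,
                bnd1=Breakend(chrom_i, q_i, HEAD),
                bnd2=Breakend(chrom_k, p_k, TAIL),
                svclass=svclass,
            ).canonical()
        )
    return junctions, overlays


def _simple_junction(
    sample_id: str,
    chroms: Sequence[str],
    chrom_len: int,
    frac_inter: float,
    rng: np.random.Generator,
    jid: str,
) -> Junction:
    if rng.random() < frac_inter:
        c1, c2 = rng.choice(len(chroms), size=2, replace=False)
        o1 = HEAD if rng.random() < 0.5 else TAIL
        o2 = HEAD if rng.random() < 0.5 else TAIL
        return Junction(
            id=jid,
            sample_id=sample_id,
            bnd1=Breakend(chroms[int(c1)], int(rng.integers(0, chrom_len)), o1),
            bnd2=Breakend(chroms[int(c2)], int(rng.integers(0, chrom_len)), o2),
            svclass="TRA",
        ).canonical()
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    svclass = str(rng.choice(["DEL", "DUP", "INV"]))
    size = int(np.clip(np.exp(rng.normal(np.log(50_000), 1.0)), 1_000, 3_000_000))
    p1 = int(rng.integers(0, chrom_len - size))
    o1, o2 = _SIMPLE_ORIENTS[svclass]
    return Junction(
        id=jid,
        sample_id=sample_id,
        bnd1=Breakend(chrom, p1, o1),
        bnd2=Breakend(chrom, p1 + size, o2),
        svclass=svclass,
    )


def _nbinom(rng: np.random.Generator, mean: float, size_param: float) -> int:
    # numpy parameterizes NB by (n, p) with mean = n (1-p)/p
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def simulate_expression(
    genes: Sequence[GeneModel],
    sample_ids: Sequence[str],
    gene_effects: dict[str, dict],
    params: SimParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Log2 expression: Normal(baseline_mean, noise_sd) plus planted shifts."""
    gene_ids = [g.gene_id for g in genes]
    values = rng.normal(
        params.baseline_mean, params.noise_sd, size=(len(gene_ids), len(sample_ids))
    )
    expr = pd.DataFrame(values, index=gene_ids, columns=list(sample_ids))
    col_pos = {s: i for i, s in enumerate(expr.columns)}
    for gene_id, eff in gene_effects.items():
        idx = [col_pos[s] for s in sorted(eff["carriers"])]
        expr.iloc[expr.index.get_loc(gene_id), idx] += eff["log2fc"]
    return expr


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _make_genome(params: SimParams) -> tuple[dict[str, int], list[Tad], list[GeneModel]]:
    chrom_lengths = {
        f"chr{i + 1}": params.chrom_len for i in range(params.n_chroms)
    }
    tads: list[Tad] = []
    genes: list[GeneModel] = []
    stride = params.tad_size + params.tad_gap
    for chrom, length in chrom_lengths.items():
        k = 0
        for start in range(0, length - params.tad_size + 1, stride):
            tad_id = f"{chrom}_tad{k}"
            tads.append(Tad(tad_id=tad_id, chrom=chrom, start=start,
                            end=start + params.tad_size, source="synthetic"))
            for g in range(params.genes_per_tad):
                frac = 0.2 + 0.6 * (g / max(params.genes_per_tad - 1, 1))
                g_start = start + int(frac * params.tad_size)
                genes.append(
                    GeneModel(
                        gene_id=f"{tad_id}_g{g}",
                        chrom=chrom,
                        start=g_start,
                        end=g_start + 20_000,
                        strand="+" if g % 2 == 0 else "-",
                    )
                )
            k += 1
    return chrom_lengths, tads, genes


def simulate_cohort(params: SimParams) -> SyntheticCohort:
    """Generate a full seeded cohort with ground truth.

    Deterministic given ``params``; all outputs satisfy the package's
    format invariants (canonical junction ordering, tiling CN segments
    covering every breakend, finite expression values).
    """
    rng = np.random.default_rng(params.seed)
    chrom_lengths, tads, genes = _make_genome(params)
    chroms = list(chrom_lengths)
    sample_ids = [f"S{i:03d}" for i in range(params.n_samples)]

    n_high = int(round(params.frac_high_burden * params.n_samples))
    high_set = set(
        rng.choice(params.n_samples, size=n_high, replace=False).tolist()
    )

    p_ct = params.frac_chromothripsis
    p_cpx = params.frac_chromoplexy
    p_ti = params.frac_ti

    truth = SyntheticTruth(burden_class={}, events={}, gene_effects={})
    junctions: list[Junction] = []
    profiles: dict[str, dict[str, _CNProfile]] = {}

    for i, sample_id in enumerate(sample_ids):
        is_high = i in high_set
        truth.burden_class[sample_id] = "high" if is_high else "low"
        truth.events[sample_id] = []
        profiles[sample_id] = {
            c: _CNProfile(chrom_lengths[c]) for c in chroms
        }
        next_id = 0

        # simple, copy-neutral background SVs
        mean, disp = (
            (params.high_burden_mean, params.high_burden_dispersion)
            if is_high
            else (params.sv_mean, params.sv_dispersion)
        )
        n_simple = _nbinom(rng, mean, disp)
        for _ in range(n_simple):
            junctions.append(
                _simple_junction(
                    sample_id, chroms, params.chrom_len, params.frac_inter,
                    rng, f"{sample_id}_j{next_id}",
                )
            )
            next_id += 1

        # planted complex events (one class per sample unless mixed_events)
        u = rng.random()
        classes: list[str] = []
        if params.mixed_events:
            if rng.random() < p_ct:
                classes.append("chromothripsis")
            if rng.random() < p_cpx:
                classes.append("chromoplexy")
            if rng.random() < p_ti:
                classes.append("templated_insertion")
        else:
            if u < p_ct:
                classes = ["chromothripsis"]
            elif u < p_ct + p_cpx:
                classes = ["chromoplexy"]
            elif u < p_ct + p_cpx + p_ti:
                classes = ["templated_insertion"]

        for cls in classes:
            if cls == "chromothripsis":
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                ev_junctions, overlays = simulate_chromothripsis(
                    sample_id, chrom, params.chrom_len,
                    params.ct_n_breakends, params.ct_max_gap, rng, next_id,
                )
                for s, e, t, m in overlays:
                    profiles[sample_id][chrom].overlay(s, e, t, m)
                ev_chroms = (chrom,)
            else:
                picked = rng.choice(
                    len(chroms), size=params.chain_n_chroms, replace=False
                )
                ev_chroms = tuple(chroms[int(c)] for c in picked)
                kind = "del" if cls == "chromoplexy" else "gain"
                ev_junctions, chain_overlays = simulate_chain(
                    sample_id, ev_chroms, params.chrom_len, kind, rng, next_id,
                )
                for chrom, ovs in chain_overlays.items():
                    for s, e, t, m in ovs:
                        profiles[sample_id][chrom].overlay(s, e, t, m)
            junctions.extend(ev_junctions)
            next_id += len(ev_junctions)
            truth.events[sample_id].append(
                PlantedEvent(
                    event_type=cls,
                    chroms=ev_chroms,
                    junction_ids=tuple(j.id for j in ev_junctions),
                )
            )

    # recurrent super-enhancer-hijack loci: TAD-TAD translocations into a
    # handful of target TADs, upregulating their resident genes in carriers
    hijack_counter = {s: 0 for s in sample_ids}
    if params.n_hijack_tads > 0 and params.n_samples >= params.carriers_per_tad:
        picked_tads = rng.choice(
            len(tads), size=min(params.n_hijack_tads, len(tads)), replace=False
        )
        genes_by_tad: dict[str, list[GeneModel]] = {}
        for g in genes:
            genes_by_tad.setdefault(g.gene_id.rsplit("_g", 1)[0], []).append(g)
        for t_idx in picked_tads:
            tad = tads[int(t_idx)]
            truth.hijack_tads.append(tad.tad_id)
            carrier_idx = rng.choice(
                params.n_samples, size=params.carriers_per_tad, replace=False
            )
            carriers = frozenset(sample_ids[int(c)] for c in carrier_idx)
            for sample_id in sorted(carriers):
                # breakend near the TAD start, tail orientation: the
                # retained interval spans nearly the whole target TAD
                pos = tad.start + int(rng.integers(0, params.tad_size // 10))
                partner_candidates = [
                    t for t in tads if t.chrom != tad.chrom
                ]
                partner = partner_candidates[
                    int(rng.integers(0, len(partner_candidates)))
                ]
                ppos = partner.start + int(rng.integers(0, params.tad_size))
                jid = f"{sample_id}_hj{hijack_counter[sample_id]}"
                hijack_counter[sample_id] += 1
                junctions.append(
                    Junction(
                        id=jid,
                        sample_id=sample_id,
                        bnd1=Breakend(tad.chrom, pos, TAIL),
                        bnd2=Breakend(partner.chrom, ppos,
                                      HEAD if rng.random() < 0.5 else TAIL),
                        svclass="TRA",
                    ).canonical()
                )
            for g in genes_by_tad.get(tad.tad_id, []):
                truth.gene_effects[g.gene_id] = {
                    "log2fc": params.effect_log2fc,
                    "carriers": carriers,
                }

    cn_segments = [
        CNSegment(sample_id=s, chrom=c, start=seg[0], end=seg[1],
                  total_cn=seg[2], minor_cn=seg[3])
        for s in sample_ids
        for c in chroms
        for seg in profiles[s][c].segments
    ]

    expression = simulate_expression(
        genes, sample_ids, truth.gene_effects, params, rng
    )

    emitted_ids = {(j.sample_id, j.id) for j in junctions}
    for sample_id, events in truth.events.items():
        for ev in events:
            for jid in ev.junction_ids:
                assert (sample_id, jid) in emitted_ids

    return SyntheticCohort(
        params=params,
        chrom_lengths=chrom_lengths,
        tads=tads,
        genes=genes,
        junctions=[j.canonical() for j in junctions],
        cn_segments=cn_segments,
        expression=expression,
        truth=truth,
    )
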