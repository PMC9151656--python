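"""TAD-disruption expression analysis.

Breakends are mapped to topologically associated domains (TADs); junctions
linking two different TADs define TAD–TAD rearrangements and candidate
neo-TADs (fused domains that can place an enhancer next to a new target
gene). Per TAD the cohort is partitioned into carriers and controls, and
each gene in the TAD is tested for differential expression with a one-way
ANOVA; Benjamini–Hochberg correction runs across all (TAD, gene) tests of
the run. A gene passes when it has >= ``min_cases`` carriers, a median
log2 expression > ``min_median`` in at least one group, and q < ``alpha``.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from svtopo.io_formats import BOUNDARY, NO_TAD, Breakend, GeneModel, Junction, Tad

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TadJunction:
    """A junction annotated with the TADs its two breakends fall in."""

    junction_id: str
    sample_id: str
    tad_a: str  # tad id, or BOUNDARY / NO_TAD sentinel
    tad_b: str

    @property
    def same_tad(self) -> bool:
        return (
            self.tad_a == self.tad_b
            and self.tad_a not in (BOUNDARY, NO_TAD)
        )

    @property
    def is_tad_tad(self) -> bool:
        """True for a rearrangement joining two distinct real TADs."""
        return (
            self.tad_a not in (BOUNDARY, NO_TAD)
            and self.tad_b not in (BOUNDARY, NO_TAD)
            and self.tad_a != self.tad_b
        )

    @property
    def touches_boundary(self) -> bool:
        return BOUNDARY in (self.tad_a, self.tad_b)


@dataclass(frozen=True)
class NeoTad:
    """A fused domain joining retained portions of two TADs."""

    neo_id: str
    sample_id: str
    tad_a: str
    retained_a: tuple[int, int]
    tad_b: str
    retained_b: tuple[int, int]
    genes_ab: frozenset[str]


@dataclass(frozen=True)
class BoundaryContrast:
    gene_id: str
    inside_samples: frozenset[str]
    outside_samples: frozenset[str]
    none_samples: frozenset[str]
    statistic: float
    p: float


class TadIndex:
    """Sorted per-chromosome TAD lookup (binary search, half-open)."""

    def __init__(self, tads: Sequence[Tad]):
        self.by_chrom: dict[str, list[Tad]] = {}
        for t in sorted(tads, key=lambda t: (t.chrom, t.start)):
            self.by_chrom.setdefault(t.chrom, []).append(t)
        self._starts = {
            chrom: [t.start for t in ts] for chrom, ts in self.by_chrom.items()
        }
        self.by_id = {t.tad_id: t for t in tads}

    def assign(self, bnd: Breakend) -> str:
        """TAD id containing the breakend, or a sentinel.

        ``BOUNDARY`` for positions in inter-TAD gaps, ``NO_TAD`` for
        chromosomes without any TADs.
        """
        ts = self.by_chrom.get(bnd.chrom)
        if not ts:
            return NO_TAD
        i = bisect_right(self._starts[bnd.chrom], bnd.pos) - 1
        if i >= 0 and ts[i].start <= bnd.pos < ts[i].end:
            return ts[i].tad_id
        return BOUNDARY


def assign_breakend_to_tad(bnd: Breakend, tads: Sequence[Tad] | TadIndex) -> str:
    index = tads if isinstance(tads, TadIndex) else TadIndex(tads)
    return index.assign(bnd)


def find_tad_rearrangements(
    junctions: Iterable[Junction], tads: Sequence[Tad] | TadIndex
) -> list[TadJunction]:
    """Annotate every junction with the TADs of its breakends."""
    index = tads if isinstance(tads, TadIndex) else TadIndex(tads)
    return [
        TadJunction(
            junction_id=j.id,
            sample_id=j.sample_id,
            tad_a=index.assign(j.bnd1),
            tad_b=index.assign(j.bnd2),
        )
        for j in junctions
    ]


def enumerate_neo_tads(
    tad_junctions: Sequence[TadJunction],
    junctions: Mapping[str, Junction],
    tads: Sequence[Tad] | TadIndex,
    genes: Sequence[GeneModel],
) -> list[NeoTad]:
    """Fused domains implied by TAD–TAD junctions.

    The retained interval of each side follows the breakend orientation:
    a ``head`` breakend keeps [tad.start, pos), a ``tail`` breakend keeps
    [pos, tad.end). ``genes_ab`` collects genes overlapping either retained
    interval.
    """
    index = tads if isinstance(tads, TadIndex) else TadIndex(tads)
    neo: list[NeoTad] = []
    for tj in tad_junctions:
        if not tj.is_tad_tad:
            continue
        j = junctions[tj.junction_id]
        parts = []
        for bnd, tad_id in ((j.bnd1, tj.tad_a), (j.bnd2, tj.tad_b)):
            tad = index.by_id[tad_id]
            if bnd.orient == "head":
                retained = (tad.start, bnd.pos)
            else:
                retained = (bnd.pos, tad.end)
            parts.append((tad_id, retained))
        gene_ids = frozenset(
            g.gene_id
            for g in genes
            for tad_id, (lo, hi) in parts
            if g.chrom == index.by_id[tad_id].chrom and g.start < hi and g.end > lo
        )
        neo.append(
            NeoTad(
                neo_id=f"neo_{tj.sample_id}_{tj.junction_id}",
                sample_id=tj.sample_id,
                tad_a=parts[0][0],
                retained_a=parts[0][1],
                tad_b=parts[1][0],
                retained_b=parts[1][1],
                genes_ab=gene_ids,
            )
        )
    return neo


def group_samples_by_tad(
    tad_junctions: Sequence[TadJunction],
    all_samples: Iterable[str],
) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
    """Per-TAD carrier/control partition of the cohort.

    A sample carries TAD T when it has at least one TAD–TAD junction
    touching T; every other sample is a control for T.
    """
    cohort = frozenset(all_samples)
    carriers: dict[str, set[str]] = {}
    for tj in tad_junctions:
        if not tj.is_tad_tad:
            continue
        for tad_id in (tj.tad_a, tj.tad_b):
            carriers.setdefault(tad_id, set()).add(tj.sample_id)
    return {
        tad_id: (frozenset(c), cohort - c) for tad_id, c in carriers.items()
    }


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_tad_genes(
    expr: pd.DataFrame,
    partition: Mapping[str, tuple[frozenset[str], frozenset[str]]],
    genes_in_tad: Mapping[str, Sequence[str]],
    min_cases: int = 5,
    min_median: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANOVA + BH screen of genes inside rearranged TADs.

    For every (TAD, gene) pair, carriers and controls are compared with a
    one-way ANOVA on log2 expression (two groups, so F = t^2 of the pooled
    t-test). BH runs across all tests in the call. ``passes_filters``
    requires n_carrier >= min_cases, max group median > min_median and
    q < alpha; under-powered genes are still reported, marked failed.
    """
    rows = []
    for tad_id in sorted(partition):
        carriers, controls = partition[tad_id]
        for gene_id in genes_in_tad.get(tad_id, []):
            if gene_id not in expr.index:
                logger.warning("gene %s absent from expression matrix; skipped", gene_id)
                continue
            car = expr.loc[gene_id, sorted(carriers & set(expr.columns))].to_numpy(float)
            ctl = expr.loc[gene_id, sorted(controls & set(expr.columns))].to_numpy(float)
            if car.size == 0 or ctl.size == 0:
                continue
            if np.ptp(np.concatenate([car, ctl])) == 0:
                f_stat, p = 0.0, 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f_stat, p = stats.f_oneway(car, ctl)
                if not np.isfinite(p):
                    f_stat, p = 0.0, 1.0
            rows.append(
                {
                    "tad_id": tad_id,
                    "gene_id": gene_id,
                    "n_carrier": car.size,
                    "n_control": ctl.size,
                    "median_carrier": float(np.median(car)),
                    "median_control": float(np.median(ctl)),
                    "log2fc": float(car.mean() - ctl.mean()),
                    "p_anova": float(p),
                    "f_stat": float(f_stat),
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "tad_id",
            "gene_id",
            "n_carrier",
            "n_control",
            "median_carrier",
            "median_control",
            "log2fc",
            "p_anova",
            "f_stat",
        ],
    )
    if len(result) == 0:
        result["q"] = []
        result["passes_filters"] = []
        return result
    result["q"] = bh_fdr(result["p_anova"].to_numpy())
    result["passes_filters"] = (
        (result["n_carrier"] >= min_cases)
        & (result[["median_carrier", "median_control"]].max(axis=1) > min_median)
        & (result["q"] < alpha)
    )
    return result


def boundary_contrast(
    gene: GeneModel,
    junctions: Iterable[Junction],
    tads: Sequence[Tad] | TadIndex,
    expr: pd.DataFrame,
    flank: int = 2_000_000,
) -> BoundaryContrast:
    """Does expression differ by breakpoint position relative to the gene's
    TAD boundary?

    Samples split three ways: ``inside`` — >=1 breakend inside the gene's
    TAD (precedence for mixed samples); ``outside`` — >=1 breakend within
    ``flank`` bp of the TAD but none inside; ``none`` — the rest. The
    p-value is a Kruskal–Wallis test of the gene's expression across the
    groups.
    """
    index = tads if isinstance(tads, TadIndex) else TadIndex(tads)
    gene_tad = None
    for t in index.by_chrom.get(gene.chrom, []):
        if t.start < gene.end and t.end > gene.start:
            gene_tad = t
            break
    if gene_tad is None:
        raise ValueError(f"gene {gene.gene_id} lies in no TAD")

    inside: set[str] = set()
    near: set[str] = set()
    for j in junctions:
        for bnd in j.breakends:
            if bnd.chrom != gene_tad.chrom:
                continue
            if gene_tad.start <= bnd.pos < gene_tad.end:
                inside.add(j.sample_id)
            elif gene_tad.start - flank <= bnd.pos < gene_tad.start or (
                gene_tad.end <= bnd.pos < gene_tad.end + flank
            ):
                near.add(j.sample_id)
    outside = near - inside
    cohort = set(expr.columns)
    none = cohort - inside - outside

    groups = [
        expr.loc[gene.gene_id, sorted(s & cohort)].to_numpy(float)
        for s in (inside, outside, none)
    ]
    non_empty = [g for g in groups if g.size > 0]
    if len(non_empty) < 2:
        stat, p = float("nan"), 1.0
    else:
        stat, p = stats.kruskal(*non_empty)
    return BoundaryContrast(
        gene_id=gene.gene_id,
        inside_samples=frozenset(inside & cohort),
        outside_samples=frozenset(outside & cohort),
        none_samples=frozenset(none),
        statistic=float(stat),
        p=float(p),
    )
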