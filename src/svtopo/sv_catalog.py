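"""Per-sample SV burden, subgroup comparison, translocation hotspots,
elbow-based high-burden stratification and paired-timepoint event diffing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from svtopo.io_formats import Junction

if TYPE_CHECKING:  # pragma: no cover
    from svtopo.complex_sv import ComplexEvent


@dataclass(frozen=True)
class SampleSVSummary:
    sample_id: str
    n_total: int
    n_intra: int
    n_inter: int
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.n_total != self.n_intra + self.n_inter:
            raise ValueError("n_total must equal n_intra + n_inter")


@dataclass(frozen=True)
class BurdenSplit:
    """High/low SV-burden partition from the elbow of the sorted curve."""

    threshold: float
    high_ids: frozenset[str]
    low_ids: frozenset[str]


def summarize_sample(junctions: Sequence[Junction], sample_id: str) -> SampleSVSummary:
    """Count total, intra- and interchromosomal junctions for one sample."""
    for j in junctions:
        if j.sample_id != sample_id:
            raise ValueError(
                f"junction {j.id} belongs to sample {j.sample_id!r}, "
                f"expected {sample_id!r}"
            )
    n_inter = sum(1 for j in junctions if j.is_interchromosomal)
    n_intra = len(junctions) - n_inter
    return SampleSVSummary(
        sample_id=sample_id,
        n_total=len(junctions),
        n_intra=n_intra,
        n_inter=n_inter,
    )


def compare_burden(
    summaries: Sequence[SampleSVSummary],
    labels: Mapping[str, str],
) -> tuple[float, float]:
    """Kruskal–Wallis test of total SV burden across sample groups.

    Returns (H statistic, p-value). Works for two or more groups; with two
    groups the test is the rank-sum comparison practitioners report as a
    chi-square.
    """
    groups: dict[str, list[int]] = {}
    for s in summaries:
        if s.sample_id in labels:
            groups.setdefault(labels[s.sample_id], []).append(s.n_total)
    if len(groups) < 2:
        raise ValueError(f"need >=2 non-empty groups, got {len(groups)}")
    for name, vals in groups.items():
        if not vals:
            raise ValueError(f"group {name!r} has no samples")
    arrays = list(groups.values())
    if all(arrays[0] == a for a in arrays[1:]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Translocation hotspots
# ---------------------------------------------------------------------------

def bin_translocation_breakends(
    junctions: Iterable[Junction],
    bin_size: int,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Bin both breakends of every translocation along the genome.

    Returns one row per bin with ``n_samples`` (distinct samples with >=1
    TRA breakend in the bin — a sample with five breakends in one bin
    counts once) and ``n_incidences`` (sample-bin incidences before the
    distinct-sample collapse; a junction contributes one incidence per
    breakend).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[tuple[str, int, int]] = []
    index: dict[tuple[str, int], int] = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length, bin_size):
            index[(chrom, start // bin_size)] = len(bins)
            bins.append((chrom, start, min(start + bin_size, length)))

    samples_per_bin: list[set[str]] = [set() for _ in bins]
    incidences = np.zeros(len(bins), dtype=int)
    for j in junctions:
        if j.svclass != "TRA":
            continue
        for bnd in j.breakends:
            if bnd.chrom not in chrom_lengths:
                raise ValueError(f"junction {j.id}: unknown chromosome {bnd.chrom!r}")
            if bnd.pos >= chrom_lengths[bnd.chrom]:
                raise ValueError(
                    f"junction {j.id}: breakend {bnd.chrom}:{bnd.pos} beyond "
                    f"chromosome length {chrom_lengths[bnd.chrom]}"
                )
            i = index[(bnd.chrom, bnd.pos // bin_size)]
            incidences[i] += 1
            samples_per_bin[i].add(j.sample_id)

    return pd.DataFrame(
        {
            "chrom": [b[0] for b in bins],
            "start": [b[1] for b in bins],
            "end": [b[2] for b in bins],
            "n_samples": [len(s) for s in samples_per_bin],
            "n_incidences": incidences,
        }
    )


def call_hotspots(bins: pd.DataFrame, n_cohort: int, alpha: float = 0.05) -> pd.DataFrame:
    """Annotate bins with binomial enrichment p-values and BH q-values.

    The null is a uniform genome-wide rate: each of the ``n_cohort``
    samples hits any given bin with probability (total sample-bin
    incidences) / (n_bins * n_cohort). A bin is a hotspot when q < alpha.
    """
    from svtopo.tad_expression import bh_fdr

    if n_cohort <= 0:
        raise ValueError("n_cohort must be positive")
    out = bins.copy()
    n_bins = len(out)
    total = int(out["n_samples"].sum())
    rate = min(total / (n_bins * n_cohort), 1.0) if n_bins else 0.0
    # one-sided: P(X >= k) for X ~ Binomial(n_cohort, rate); bins at or
    # below the expected count carry no evidence of enrichment (p = 1)
    k = out["n_samples"].to_numpy()
    p = stats.binom.sf(k - 1, n_cohort, rate)
    p = np.where(k <= rate * n_cohort, 1.0, p)
    out["p"] = np.clip(p, 0.0, 1.0)
    out["q"] = bh_fdr(out["p"].to_numpy()) if n_bins else []
    out["is_hotspot"] = out["q"] < alpha
    return out


# ---------------------------------------------------------------------------
# Elbow stratification
# ---------------------------------------------------------------------------

def elbow_split(counts: Mapping[str, int | float]) -> BurdenSplit:
    """Split samples into high/low SV burden at the elbow of the sorted curve.

    Counts are sorted descending; the elbow is the index maximizing the
    perpendicular distance to the chord joining the first and last points
    of the curve (both axes normalized to [0, 1], which makes the split
    invariant to rescaling the counts). Samples with counts strictly above
    the elbow count are high; ties go low. A constant vector yields an
    empty high set.
    """
    if len(counts) < 3:
        raise ValueError("need >=3 samples for an elbow split")
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    values = np.array([v for _, v in items], dtype=float)
    n = len(values)
    if values[0] == values[-1]:
        return BurdenSplit(
            threshold=float(values[0]),
            high_ids=frozenset(),
            low_ids=frozenset(counts),
        )
    x = np.linspace(0.0, 1.0, n)
    y = (values - values[-1]) / (values[0] - values[-1])
    # distance from (x_i, y_i) to the chord through (0, 1) and (1, 0)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    elbow = int(np.argmax(dist))
    threshold = float(values[elbow])
    high = frozenset(s for s, v in counts.items() if v > threshold)
    low = frozenset(counts) - high
    return BurdenSplit(threshold=threshold, high_ids=high, low_ids=low)


# ---------------------------------------------------------------------------
# Paired-timepoint comparison
# ---------------------------------------------------------------------------

def _junctions_match(a: Junction, b: Junction, tol: int) -> bool:
    return (
        a.bnd1.chrom == b.bnd1.chrom
        and a.bnd2.chrom == b.bnd2.chrom
        and abs(a.bnd1.pos - b.bnd1.pos) <= tol
        and abs(a.bnd2.pos - b.bnd2.pos) <= tol
    )


def _events_match(
    e1: "ComplexEvent",
    e2: "ComplexEvent",
    jx1: Mapping[str, Junction],
    jx2: Mapping[str, Junction],
    tol: int,
) -> bool:
    """Two events match when >=50% of the smaller event's junctions have a
    counterpart (both breakends within ``tol``) in the other event."""
    js1 = [jx1[i] for i in e1.junction_ids]
    js2 = [jx2[i] for i in e2.junction_ids]
    small, large = (js1, js2) if len(js1) <= len(js2) else (js2, js1)
    if not small:
        return False
    n_matched = sum(
        1 for a in small if any(_junctions_match(a, b, tol) for b in large)
    )
    return n_matched >= 0.5 * len(small)


def diff_timepoints(
    events_t1: Sequence["ComplexEvent"],
    events_t2: Sequence["ComplexEvent"],
    junctions_t1: Iterable[Junction],
    junctions_t2: Iterable[Junction],
    tolerance: int = 1000,
) -> dict[str, list]:
    """Compare complex events between two timepoints of one patient.

    Returns ``{"stable": [(e1, e2), ...], "gained": [e2, ...],
    "lost": [e1, ...]}``. An event that only grows between timepoints
    (e.g. a two-chromosome chain gaining a third chromosome at relapse)
    is stable, because the matching rule is anchored on the smaller event.
    """
    jx1 = {j.id: j.canonical() for j in junctions_t1}
    jx2 = {j.id: j.canonical() for j in junctions_t2}
    matched2: set[int] = set()
    stable: list[tuple] = []
    lost: list = []
    for e1 in events_t1:
        hit = None
        for i2, e2 in enumerate(events_t2):
            if i2 in matched2:
                continue
            if _events_match(e1, e2, jx1, jx2, tolerance):
                hit = i2
                break
        if hit is None:
            lost.append(e1)
        else:
            matched2.add(hit)
            stable.append((e1, events_t2[hit]))
    gained = [e2 for i2, e2 in enumerate(events_t2) if i2 not in matched2]
    return {"stable": stable, "gained": gained, "lost": lost}
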