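"""Typed genomic records and readers/writers for the external formats.

Every coordinate inside the package is 0-based half-open; conversions from
1-based formats (VCF) happen at read time only. Breakend orientation uses
the vocabulary ``head`` / ``tail``:

* ``head`` — the derivative chromosome retains the sequence to the LEFT of
  ``pos`` (BEDPE strand ``+``);
* ``tail`` — it retains the sequence to the RIGHT of ``pos`` (strand ``-``).

Chromosome names are taken verbatim: ``chr1`` and ``1`` are different
chromosomes unless the caller aliases them explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

HEAD = "head"
TAIL = "tail"

#: breakend landed in an inter-TAD gap
BOUNDARY = "__boundary__"
#: breakend on a chromosome with no TADs at all
NO_TAD = "__no_tad__"

_STRAND_TO_ORIENT = {"+": HEAD, "-": TAIL, "−": TAIL}  # U+2212 minus
_ORIENT_TO_STRAND = {HEAD: "+", TAIL: "-"}

SV_CLASSES = ("DEL", "DUP", "INV", "TRA")


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True, order=True)
class Breakend:
    """One side of a rearrangement junction."""

    chrom: str
    pos: int  # 0-based
    orient: str  # HEAD or TAIL

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("breakend chromosome must be non-empty")
        if self.pos < 0:
            raise ValueError(f"breakend pos must be >= 0, got {self.pos}")
        if self.orient not in (HEAD, TAIL):
            raise ValueError(f"orient must be 'head' or 'tail', got {self.orient!r}")


@dataclass(frozen=True)
class Junction:
    """One structural variant: two oriented breakends in one sample.

    Canonical ordering: intrachromosomal junctions have ``bnd1.pos <=
    bnd2.pos``; interchromosomal ones are ordered by (chrom, pos) so that
    the same physical junction read from different encodings compares equal.
    """

    id: str
    sample_id: str
    bnd1: Breakend
    bnd2: Breakend
    svclass: str
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if self.svclass not in SV_CLASSES:
            raise ValueError(
                f"unknown svclass {self.svclass!r}; accepted: {', '.join(SV_CLASSES)}"
            )
        if self.bnd1.chrom != self.bnd2.chrom and self.svclass != "TRA":
            raise ValueError(
                f"junction {self.id}: interchromosomal junctions must be TRA"
            )

    @property
    def is_interchromosomal(self) -> bool:
        return self.bnd1.chrom != self.bnd2.chrom

    def canonical(self) -> "Junction":
        """Return the junction with breakends in canonical order."""
        k1 = (self.bnd1.chrom, self.bnd1.pos)
        k2 = (self.bnd2.chrom, self.bnd2.pos)
        if k1 <= k2:
            return self
        return Junction(
            id=self.id,
            sample_id=self.sample_id,
            bnd1=self.bnd2,
            bnd2=self.bnd1,
            svclass=self.svclass,
            timepoint=self.timepoint,
        )

    @property
    def breakends(self) -> tuple[Breakend, Breakend]:
        return (self.bnd1, self.bnd2)


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment with total and minor allele copy number.

    ``minor_cn == 0`` with ``total_cn >= 1`` encodes loss of heterozygosity.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"CN segment start must be < end: {self}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError(f"copy numbers must be non-negative: {self}")
        if self.minor_cn > self.total_cn:
            raise ValueError(f"minor_cn must not exceed total_cn: {self}")

    @property
    def has_loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn >= 1


@dataclass(frozen=True)
class Tad:
    """A topologically associated domain interval."""

    tad_id: str
    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"TAD start must be < end: {self}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene start must be < end: {self}")


def _canonical_junctions(junctions: Iterable[Junction]) -> list[Junction]:
    return [j.canonical() for j in junctions]


def _check_unique_ids(junctions: Sequence[Junction]) -> None:
    seen: set[tuple[str, str | None, str]] = set()
    for j in junctions:
        key = (j.sample_id, j.timepoint, j.id)
        if key in seen:
            raise FormatError(
                f"duplicate junction id {j.id!r} in sample {j.sample_id!r}"
            )
        seen.add(key)


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def _infer_svclass(chrom1: str, chrom2: str, orient1: str, orient2: str) -> str:
    if chrom1 != chrom2:
        return "TRA"
    if orient1 == HEAD and orient2 == TAIL:
        return "DEL"
    if orient1 == TAIL and orient2 == HEAD:
        return "DUP"
    return "INV"


def read_sv_bedpe(path: str | Path, default_sample: str = "sample") -> list[Junction]:
    """Read SV junctions from a 10+ column BEDPE file.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1
    strand2 [svclass] [sample]. The breakend position is the start
    coordinate of each side (BEDPE is 0-based). Strand ``+`` maps to
    orientation ``head``, ``-`` to ``tail``. When the svclass column is
    absent it is inferred from chromosomes and orientations.
    """
    path = Path(path)
    junctions: list[Junction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 10:
                raise FormatError(
                    f"{path}:{lineno}: expected >=10 BEDPE columns, got {len(fields)}"
                )
            try:
                chrom1, start1 = fields[0], int(fields[1])
                chrom2, start2 = fields[3], int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[6]
            try:
                orient1 = _STRAND_TO_ORIENT[fields[8]]
                orient2 = _STRAND_TO_ORIENT[fields[9]]
            except KeyError as exc:
                raise FormatError(
                    f"{path}:{lineno}: bad strand {exc.args[0]!r} (expected + or -)"
                ) from exc
            svclass = (
                fields[10]
                if len(fields) > 10 and fields[10] not in (".", "")
                else _infer_svclass(chrom1, chrom2, orient1, orient2)
            )
            if svclass not in SV_CLASSES:
                raise FormatError(
                    f"{path}:{lineno}: unknown svclass {svclass!r}; "
                    f"accepted: {', '.join(SV_CLASSES)}"
                )
            sample = fields[11] if len(fields) > 11 else default_sample
            junctions.append(
                Junction(
                    id=name,
                    sample_id=sample,
                    bnd1=Breakend(chrom1, start1, orient1),
                    bnd2=Breakend(chrom2, start2, orient2),
                    svclass=svclass,
                ).canonical()
            )
    if not junctions:
        logger.warning("no junctions read from %s", path)
    _check_unique_ids(junctions)
    return junctions


def write_bedpe(junctions: Iterable[Junction], path: str | Path) -> None:
    """Write junctions as 12-column BEDPE (svclass + sample appended)."""
    with open(path, "w") as fh:
        for j in _canonical_junctions(junctions):
            fh.write(
                "\t".join(
                    [
                        j.bnd1.chrom,
                        str(j.bnd1.pos),
                        str(j.bnd1.pos + 1),
                        j.bnd2.chrom,
                        str(j.bnd2.pos),
                        str(j.bnd2.pos + 1),
                        j.id,
                        ".",
                        _ORIENT_TO_STRAND[j.bnd1.orient],
                        _ORIENT_TO_STRAND[j.bnd2.orient],
                        j.svclass,
                        j.sample_id,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF (Manta dialect: SVTYPE in {DEL,DUP,INV,BND}, BND mates via MATEID)
# ---------------------------------------------------------------------------

def _parse_bnd_alt(alt: str) -> tuple[str, int, str, str]:
    """Decode a VCF 4.2 breakend ALT string.

    Returns (mate_chrom, mate_pos0, local_orient, mate_orient).

    ``t[p[``  local head, mate tail    (piece right of p joins after t)
    ``t]p]``  local head, mate head
    ``[p[t``  local tail, mate tail
    ``]p]t``  local tail, mate head
    """
    bracket = "[" if "[" in alt else "]" if "]" in alt else None
    if bracket is None:
        raise FormatError(f"not a breakend ALT: {alt!r}")
    local_orient = TAIL if alt.startswith(("[", "]")) else HEAD
    mate_orient = TAIL if bracket == "[" else HEAD
    inner = alt.split(bracket)[1]
    try:
        chrom, pos_s = inner.rsplit(":", 1)
        pos = int(pos_s)
    except ValueError as exc:
        raise FormatError(f"malformed breakend ALT {alt!r}") from exc
    return chrom, pos - 1, local_orient, mate_orient


def read_sv_vcf(path: str | Path, default_sample: str = "sample") -> list[Junction]:
    """Read SV junctions from a Manta-style VCF.

    BND mate pairs (linked by INFO/MATEID) collapse to one TRA junction;
    symbolic ``<DEL>``/``<DUP>``/``<INV>`` alleles expand using POS and
    INFO/END. VCF 1-based positions become 0-based. Unpaired BND records
    are dropped with a warning (real caller output contains them).
    """
    from cyvcf2 import VCF

    path = str(path)
    junctions: list[Junction] = []
    bnd_records: dict[str, tuple] = {}
    n_unpaired = 0

    vcf = VCF(path)
    sample = vcf.samples[0] if vcf.samples else default_sample
    for rec in vcf:
        svtype = rec.INFO.get("SVTYPE")
        if svtype is None:
            continue
        rid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if svtype == "BND":
            bnd_records[rid] = (
                rec.CHROM,
                rec.POS - 1,
                rec.ALT[0],
                rec.INFO.get("MATEID"),
            )
            continue
        if svtype in ("DEL", "DUP", "INV"):
            end = rec.INFO.get("END")
            if end is None:
                raise FormatError(
                    f"{path}: record {rid}: symbolic {svtype} allele missing INFO/END"
                )
            # For DEL the retained flanks are left-of-start and
            # right-of-end; DUP is the reverse; INV is conventionally +/+.
            orients = {
                "DEL": (HEAD, TAIL),
                "DUP": (TAIL, HEAD),
                "INV": (HEAD, HEAD),
            }[svtype]
            junctions.append(
                Junction(
                    id=rid,
                    sample_id=sample,
                    bnd1=Breakend(rec.CHROM, rec.POS - 1, orients[0]),
                    bnd2=Breakend(rec.CHROM, int(end), orients[1]),
                    svclass=svtype,
                ).canonical()
            )
    vcf.close()

    consumed: set[str] = set()
    for rid, (chrom, pos0, alt, mateid) in bnd_records.items():
        if rid in consumed:
            continue
        if mateid is None or mateid not in bnd_records:
            n_unpaired += 1
            continue
        consumed.add(rid)
        consumed.add(mateid)
        mate_chrom, mate_pos0, local_orient, mate_orient = _parse_bnd_alt(alt)
        svclass = "TRA" if chrom != mate_chrom else _infer_svclass(
            chrom, mate_chrom, local_orient, mate_orient
        )
        junctions.append(
            Junction(
                id=rid.rsplit(":", 1)[0] if ":" in rid else rid,
                sample_id=sample,
                bnd1=Breakend(chrom, pos0, local_orient),
                bnd2=Breakend(mate_chrom, mate_pos0, mate_orient),
                svclass=svclass,
            ).canonical()
        )
    if n_unpaired:
        warnings.warn(f"{path}: dropped {n_unpaired} unpaired BND record(s)")
    return junctions


# ---------------------------------------------------------------------------
# CN segments, TADs, genes, expression
# ---------------------------------------------------------------------------

_CN_COLUMNS = ["sample_id", "chrom", "start", "end", "total_cn", "minor_cn"]


def validate_cn_segments(segments: Sequence[CNSegment]) -> None:
    """Check per (sample, chrom) sorted, non-overlapping tiling."""
    by_key: dict[tuple[str, str], list[CNSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"overlapping CN segments in sample {sample!r} on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def read_cn_segments(path: str | Path) -> list[CNSegment]:
    """Read copy-number segments from a headered TSV.

    Columns: sample_id, chrom, start, end, total_cn, minor_cn.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_CN_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing CN columns {sorted(missing)}")
    segments = [
        CNSegment(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            total_cn=int(r.total_cn),
            minor_cn=int(r.minor_cn),
        )
        for r in df.itertuples()
    ]
    validate_cn_segments(segments)
    return sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start))


def write_cn_segments(segments: Iterable[CNSegment], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.sample_id, s.chrom, s.start, s.end, s.total_cn, s.minor_cn)
            for s in segments
        ],
        columns=_CN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_tad_bed(path: str | Path, source: str = "") -> list[Tad]:
    """Read TADs from BED4 (chrom, start, end, tad_id); enforces per-
    chromosome non-overlap (gaps allowed — they are boundary regions)."""
    tads: list[Tad] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            tads.append(
                Tad(
                    tad_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    source=fields[4] if len(fields) > 4 else source,
                )
            )
    tads.sort(key=lambda t: (t.chrom, t.start))
    for a, b in zip(tads, tads[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise FormatError(
                f"{path}: overlapping TADs {a.tad_id} and {b.tad_id} on {a.chrom}"
            )
    return tads


def write_tad_bed(tads: Iterable[Tad], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tads, key=lambda t: (t.chrom, t.start)):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.tad_id}\t{t.source}\n")


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, gene_id, score, strand)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            genes.append(
                GeneModel(
                    gene_id=fields[3],
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5] if len(fields) > 5 else "+",
                )
            )
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a normalized log2 expression matrix (genes x samples).

    First column is gene_id, header row holds sample ids. Duplicate gene
    or sample ids and non-finite values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene id(s) {dups}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample id(s)")
    values = df.to_numpy()
    import numpy as np

    if not np.isfinite(values).all():
        raise FormatError(f"{path}: expression matrix contains non-finite values")
    df.index.name = None
    df.columns.name = None
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")
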