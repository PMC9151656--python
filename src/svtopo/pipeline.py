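"""Pipeline configuration and the ``run-all`` orchestration.

``run_all`` chains ingest -> burden -> complex calling -> TAD expression
and writes TSV tables plus a JSON summary. Outputs are written atomically
(temp file + rename) so an aborted stage never leaves a truncated table,
and identical config + inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from svtopo import complex_sv, io_formats, sv_catalog, tad_expression
from svtopo.complex_sv import ComplexParams

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All input paths and every threshold used by the stages."""

    # inputs
    sv_bedpe: str = ""
    cn_tsv: str = ""
    tad_bed: str = ""
    gene_bed: str = ""
    expr_tsv: str = ""
    chrom_lengths_tsv: str = ""
    out_dir: str = "svtopo_out"
    # thresholds
    w_chain: int = 1_000_000
    min_junctions: int = 3
    min_breakends: int = 10
    ct_window: int = 50_000_000
    min_oscillations: int = 7
    require_loh: bool = True
    bin_size: int = 1_000_000
    min_cases: int = 5
    min_median: float = 2.0
    alpha: float = 0.05
    flank: int = 2_000_000
    tolerance: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w_chain", "min_junctions", "min_breakends", "ct_window",
                     "min_oscillations", "bin_size", "min_cases", "flank",
                     "tolerance"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must lie in [0, 1]")

    @classmethod
    def from_toml(cls, path: str | Path,
                  overrides: Mapping[str, str] | None = None) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw: dict[str, Any] = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if overrides:
            for key, value in overrides.items():
                if key not in known:
                    raise ConfigError(f"unknown override key: {key}")
                current = cls.__dataclass_fields__[key].type
                raw[key] = _coerce(value, getattr(cls(), key))
        return cls(**raw)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    def complex_params(self) -> ComplexParams:
        return ComplexParams(
            w_chain=self.w_chain,
            min_junctions=self.min_junctions,
            min_breakends=self.min_breakends,
            ct_window=self.ct_window,
            min_oscillations=self.min_oscillations,
            require_loh=self.require_loh,
        )


def _coerce(value: str, template: Any) -> Any:
    if isinstance(template, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(template, int):
        return int(value)
    if isinstance(template, float):
        return float(value)
    return value


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chrom, length."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
    return out


def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the JSON-able summary it also writes."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logger.info("thresholds: %s", dataclasses.asdict(config))

    def stage(name, fn):
        t = time.time()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc
        logger.info("stage %s done in %.1fs", name, time.time() - t)
        return result

    junctions = stage("ingest", lambda: io_formats.read_sv_bedpe(config.sv_bedpe))
    cn = stage("ingest_cn", lambda: io_formats.read_cn_segments(config.cn_tsv))
    tads = stage("ingest_tads", lambda: io_formats.read_tad_bed(config.tad_bed))
    genes = stage("ingest_genes", lambda: io_formats.read_gene_bed(config.gene_bed))
    expr = stage("ingest_expr", lambda: io_formats.read_expression_tsv(config.expr_tsv))
    chrom_lengths = stage(
        "ingest_chroms", lambda: read_chrom_lengths(config.chrom_lengths_tsv)
    )

    samples = sorted({j.sample_id for j in junctions} | set(expr.columns))
    by_sample: dict[str, list] = {s: [] for s in samples}
    for j in junctions:
        by_sample.setdefault(j.sample_id, []).append(j)
    cn_by_sample: dict[str, list] = {}
    for seg in cn:
        cn_by_sample.setdefault(seg.sample_id, []).append(seg)

    # --- burden ---
    def _burden():
        summaries = [
            sv_catalog.summarize_sample(by_sample[s], s) for s in samples
        ]
        df = pd.DataFrame(
            [(x.sample_id, x.n_total, x.n_intra, x.n_inter) for x in summaries],
            columns=["sample_id", "n_total", "n_intra", "n_inter"],
        )
        _atomic_write(df, out_dir / "burden.tsv")
        split = sv_catalog.elbow_split({x.sample_id: x.n_total for x in summaries})
        split_df = pd.DataFrame(
            [(s, "high" if s in split.high_ids else "low") for s in samples],
            columns=["sample_id", "burden_class"],
        )
        _atomic_write(split_df, out_dir / "burden_split.tsv")
        return summaries, split

    summaries, split = stage("burden", _burden)

    # --- hotspots ---
    def _hotspots():
        bins = sv_catalog.bin_translocation_breakends(
            junctions, config.bin_size, chrom_lengths
        )
        annotated = sv_catalog.call_hotspots(bins, len(samples), config.alpha)
        _atomic_write(annotated, out_dir / "hotspots.tsv")
        return annotated

    hotspots = stage("hotspots", _hotspots)

    # --- complex events ---
    def _complex():
        params = config.complex_params()
        all_events, all_flags = [], []
        for s in samples:
            events, flags = complex_sv.call_complex_events(
                by_sample[s], cn_by_sample.get(s, []), params, chrom_lengths
            )
            all_events.extend(events)
            all_flags.append({"sample_id": s, **flags})
        ev_df = pd.DataFrame(
            [
                {
                    "event_id": e.event_id,
                    "sample_id": e.sample_id,
                    "label": e.label,
                    "n_junctions": e.n_junctions,
                    "chroms": ",".join(sorted(e.chroms)),
                    "simple_chain": e.simple_chain,
                    **e.metrics,
                }
                for e in all_events
            ]
        )
        _atomic_write(ev_df, out_dir / "complex_events.tsv")
        _atomic_write(pd.DataFrame(all_flags), out_dir / "sample_flags.tsv")
        return all_events, all_flags

    events, flags = stage("complex", _complex)

    # --- TAD expression ---
    def _tad():
        index = tad_expression.TadIndex(tads)
        tjs = tad_expression.find_tad_rearrangements(junctions, index)
        partition = tad_expression.group_samples_by_tad(tjs, expr.columns)
        genes_in_tad: dict[str, list[str]] = {}
        for g in genes:
            tid = tad_expression.assign_breakend_to_tad(
                io_formats.Breakend(g.chrom, g.start, "head"), index
            )
            if tid not in (io_formats.BOUNDARY, io_formats.NO_TAD):
                genes_in_tad.setdefault(tid, []).append(g.gene_id)
        results = tad_expression.test_tad_genes(
            expr, partition, genes_in_tad,
            min_cases=config.min_cases,
            min_median=config.min_median,
            alpha=config.alpha,
        )
        _atomic_write(results, out_dir / "tad_gene_results.tsv")
        by_id = {j.id: j for j in junctions}
        neo = tad_expression.enumerate_neo_tads(tjs, by_id, index, genes)
        neo_df = pd.DataFrame(
            [
                {
                    "neo_id": n.neo_id,
                    "sample_id": n.sample_id,
                    "tad_a": n.tad_a,
                    "retained_a": f"{n.retained_a[0]}-{n.retained_a[1]}",
                    "tad_b": n.tad_b,
                    "retained_b": f"{n.retained_b[0]}-{n.retained_b[1]}",
                    "genes": ",".join(sorted(n.genes_ab)),
                }
                for n in neo
            ]
        )
        _atomic_write(neo_df, out_dir / "neo_tads.tsv")
        if len(results):
            import numpy as np

            volcano = results[["tad_id", "gene_id", "log2fc"]].copy()
            volcano["neg_log10_p"] = -np.log10(
                results["p_anova"].clip(lower=1e-300)
            )
            _atomic_write(volcano, out_dir / "volcano.tsv")
        return results

    tad_results = stage("tad", _tad)

    label_counts = pd.Series([e.label for e in events]).value_counts().to_dict()
    summary = {
        "n_samples": len(samples),
        "n_junctions": len(junctions),
        "high_burden_samples": sorted(split.high_ids),
        "event_counts": {k: int(v) for k, v in sorted(label_counts.items())},
        "n_hotspots": int(hotspots["is_hotspot"].sum()),
        "significant_genes": sorted(
            tad_results.loc[tad_results["passes_filters"], "gene_id"].tolist()
        )
        if len(tad_results)
        else [],
        "runtime_s": round(time.time() - t0, 2),
    }
    tmp = out_dir / "summary.json.tmp"
    # runtime varies between runs; keep it out of the determinism contract
    stable = {k: v for k, v in summary.items() if k != "runtime_s"}
    tmp.write_text(json.dumps(stable, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, out_dir / "summary.json")
    return summary
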