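"""End-to-end orchestration from a single YAML config.

Stage order: de -> modules -> stages -> homeolog -> motifs -> eet ->
traits. Each stage writes its TSVs into the output directory; a manifest
(JSON) records the package version, the config hash, the seed and
per-stage row counts, so a rerun with the same config is byte-comparable.
A failing stage aborts the run with a FAILED marker naming it; earlier
outputs are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import fiberatlas
from fiberatlas import coexpr, diffexpr, eet_detect, homeolog, motif_cre, stages
from fiberatlas.data_io import (
    ExpressionMatrix,
    ValidationError,
    default_motif_library,
    load_expression_matrix,
    load_motif_library,
    load_sample_sheet,
)
from fiberatlas.traits_validation import (
    DEFAULT_CONTROLS,
    correlation_table,
    normalize_ncounter,
)

logger = logging.getLogger("fiberatlas")

STAGE_SEQUENCE = ("de", "modules", "stages", "homeolog", "motifs", "eet", "traits")


@dataclass
class PipelineConfig:
    """Flat configuration mirroring the CLI flags."""

    expr: str = ""
    transcripts: str = ""
    samples: str = ""
    promoters: str = ""
    motifs: str = ""
    ncounter: str = ""
    traits: str = ""
    pairs: str = ""
    out_dir: str = "fiberatlas_out"
    alpha: float = diffexpr.ALPHA_DEFAULT
    lfc: float = diffexpr.LFC_DEFAULT
    beta: float = coexpr.BETA_DEFAULT
    min_module_size: int = coexpr.MIN_MODULE_SIZE_DEFAULT
    zero_tol: float = 0.0
    reps: int = 1000
    seed: int = 0
    skip: tuple = field(default_factory=tuple)
    controls: tuple = DEFAULT_CONTROLS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if isinstance(cfg.skip, (list, tuple)):
            cfg.skip = tuple(cfg.skip)
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest: dict = {
        "version": fiberatlas.__version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in STAGE_SEQUENCE:
        if stage in config.skip:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.monotonic()
        try:
            counts = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            failed_marker.write_text(f"stage {stage} failed: {exc}\n")
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
        elapsed = time.monotonic() - t0
        logger.info("stage %s done in %.2fs", stage, elapsed)
        manifest["stages"][stage] = {"status": "ok", **(counts or {})}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _require(path: str, what: str) -> str:
    if not path:
        raise ValidationError(f"{what} input not configured")
    if not Path(path).exists():
        raise ValidationError(f"{what} file not found: {path}")
    return path


def _load_gene_expr(config: PipelineConfig, state: dict) -> ExpressionMatrix:
    if "gene_expr" not in state:
        state["gene_expr"] = load_expression_matrix(
            _require(config.expr, "expression"), level="gene", unit="fpkm"
        )
        state["sheet"] = load_sample_sheet(_require(config.samples, "sample sheet"))
    return state["gene_expr"]


def _stage_de(config: PipelineConfig, out: Path, state: dict) -> dict:
    expr = _load_gene_expr(config, state)
    table = diffexpr.differential_expression(
        expr, state["sheet"], alpha=config.alpha, tau=config.lfc
    )
    table.to_csv(out / "de.tsv", sep="\t", index=False)
    counts = diffexpr.call_degs(table, alpha=config.alpha, tau=config.lfc)
    state["de"] = table
    return {"rows": len(table), "up": counts.up, "down": counts.down, "ns": counts.ns}


def _stage_modules(config: PipelineConfig, out: Path, state: dict) -> dict:
    expr = _load_gene_expr(config, state)
    de = state.get("de")
    if de is None:
        de = diffexpr.differential_expression(expr, state["sheet"], config.alpha, config.lfc)
    up = de.loc[de["direction"] == "up", "feature_id"].tolist()
    if len(up) < config.min_module_size:
        raise ValidationError(
            f"{len(up)} upregulated genes < min module size {config.min_module_size}"
        )
    # co-expression over the fiber developmental axis (OF samples)
    of_samples = [s for s in state["sheet"].samples_in_group("OF") if s in expr.sample_ids]
    sub = expr.subset(features=up, samples=of_samples).to_log2()
    adj, tom, part = coexpr.network_and_modules(
        sub, beta=config.beta, min_module_size=config.min_module_size
    )
    part.assignments.rename_axis("gene_id").to_csv(out / "modules.tsv", sep="\t")
    if part.eigengenes is not None:
        part.eigengenes.rename_axis("module").to_csv(out / "eigengenes.tsv", sep="\t")
    pd.Series(part.hubs, name="hub_gene").rename_axis("module").to_csv(
        out / "hubs.tsv", sep="\t"
    )
    if part.clades is not None:
        part.clades.rename_axis("module").to_csv(out / "clades.tsv", sep="\t")
    state["partition"] = part
    sizes = part.module_sizes()
    return {
        "genes": int(len(part.assignments)),
        "modules": len(part.modules),
        "unassigned": part.n_unassigned,
        "sizes": {m: int(sizes[m]) for m in part.modules},
    }


def _stage_stages(config: PipelineConfig, out: Path, state: dict) -> dict:
    expr = _load_gene_expr(config, state)
    part = state.get("partition")
    if part is None:
        raise ValidationError("stage profiling needs the modules stage")
    prof = stages.stage_profile(expr, state["sheet"], part)
    prof.to_csv(out / "stage_profile.tsv", sep="\t")
    state["stage_profile"] = prof
    return {"rows": len(prof)}


def _stage_homeolog(config: PipelineConfig, out: Path, state: dict) -> dict:
    expr = _load_gene_expr(config, state)
    pooled = diffexpr.pool_groups(expr, state["sheet"])
    de = state.get("de")
    genes = (
        de.loc[de["direction"] == "up", "feature_id"].tolist()
        if de is not None
        else expr.feature_ids
    )
    table = homeolog.prominence_table(
        pooled.values["OF"], gene_ids=genes, pair_table=config.pairs or None
    )
    table.to_csv(out / "prominence.tsv", sep="\t", index=False)
    tally = table["prominence"].value_counts()
    return {
        "pairs": len(table),
        "unpaired": table.attrs["n_unpaired"],
        "At": int(tally.get("At", 0)),
        "Dt": int(tally.get("Dt", 0)),
    }


def _stage_motifs(config: PipelineConfig, out: Path, state: dict) -> dict:
    from Bio import SeqIO

    path = _require(config.promoters, "promoters")
    promoters = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }
    motifs = (
        load_motif_library(config.motifs) if config.motifs else default_motif_library()
    )
    part = state.get("partition")
    rows = []
    freq_rows = []
    for motif in motifs:
        scans = {
            gid: motif_cre.iupac_scan(seq, motif, gene_id=gid)
            for gid, seq in promoters.items()
        }
        for gid, res in scans.items():
            rows.append(
                {
                    "motif_id": motif.motif_id,
                    "gene_id": gid,
                    "n_sites": res.n_sites,
                    "positions": ",".join(map(str, res.positions)),
                    "strands": "".join(res.strands),
                }
            )
        if part is not None:
            for module in part.modules:
                members = [g for g in part.members(module) if g in scans]
                if not members:
                    continue
                freq = motif_cre.cre_binding_frequency(
                    [scans[g] for g in members], len(motif), len(members)
                )
                freq_rows.append(
                    {"motif_id": motif.motif_id, "module": module, "frequency": freq}
                )
    pd.DataFrame(rows).to_csv(out / "motif_scan.tsv", sep="\t", index=False)
    if freq_rows:
        pd.DataFrame(freq_rows).to_csv(out / "cre_frequency.tsv", sep="\t", index=False)
    return {"motifs": len(motifs), "promoters": len(promoters)}


def _stage_eet(config: PipelineConfig, out: Path, state: dict) -> dict:
    path = _require(config.transcripts, "transcript expression")
    tx = load_expression_matrix(path, level="transcript", unit="fpkm")
    sheet = state.get("sheet")
    if sheet is None:
        sheet = load_sample_sheet(_require(config.samples, "sample sheet"))
    pooled = diffexpr.pool_groups(tx, sheet).to_log2()
    records = eet_detect.detect_eets(pooled, zero_tol=config.zero_tol)
    frame = eet_detect.eet_records_frame(records)
    frame.to_csv(out / "eets.tsv", sep="\t", index=False)
    state["eets"] = frame
    return {"transcripts": len(frame), "eets": int(frame["is_eet"].sum())}


def _stage_traits(config: PipelineConfig, out: Path, state: dict) -> dict:
    counts = pd.read_csv(_require(config.ncounter, "nCounter counts"), sep="\t", index_col=0)
    traits = pd.read_csv(_require(config.traits, "traits"), sep="\t", index_col=0)
    normalized = normalize_ncounter(counts, [c for c in config.controls if c in counts.index])
    expression = np.log2(normalized.drop(index=[c for c in config.controls if c in normalized.index]) + 1.0)
    table = correlation_table(expression, traits)
    table.rename_axis("transcript_id").to_csv(out / "trait_correlation.tsv", sep="\t")
    table.attrs["long"].to_csv(out / "trait_correlation_long.tsv", sep="\t", index=False)
    return {"transcripts": len(table), "traits": table.shape[1]}


_STAGE_FUNCS = {
    "de": _stage_de,
    "modules": _stage_modules,
    "stages": _stage_stages,
    "homeolog": _stage_homeolog,
    "motifs": _stage_motifs,
    "eet": _stage_eet,
    "traits": _stage_traits,
}
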