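"""Chained pipeline runner: scan -> partition -> quant, with a JSON report.

The configuration is a nested mapping (typically loaded from YAML); the
requested stages run in a fixed order and each contributes a summary to
``report.json`` in the output directory.  Stage failures carry the
stage name and the underlying cause.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import genome as gm
from . import scanner as sc
from .departition import DEThresholds, contrast_total, partition_contrasts, read_de_table, write_partition
from .quant import PeptideTable, hi3_table

log = logging.getLogger("ntcascan")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_genome(path: str) -> gm.AnnotatedGenome:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input not found: {p}")
    if p.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        return gm.read_genbank(p)
    return gm.read_fasta(p)


def _stage_scan(cfg: dict, out_dir: Path) -> dict:
    genome = _load_genome(cfg["genome"])
    arch = (
        sc.load_architecture(cfg["arch"]) if cfg.get("arch") else sc.DEFAULT_ARCHITECTURE
    )
    window = int(cfg.get("window", 350))
    loci = cfg.get("loci", "all")
    if loci == "all":
        loci = [f.locus_tag for f in genome.features]
    elif isinstance(loci, str):
        loci = [t.strip() for t in loci.split(",") if t.strip()]
    hits = []
    for tag in loci:
        hits.extend(sc.scan_upstream(genome, tag, arch, window))
    out = out_dir / "hits.tsv"
    sc.hits_to_tsv(hits, genome.id, out)
    log.info("scan: %d hits over %d loci -> %s", len(hits), len(loci), out)
    return {"n_hits": len(hits), "n_loci": len(loci), "out": str(out)}


def _stage_departition(cfg: dict, out_dir: Path) -> dict:
    for key in ("a", "b"):
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"input not found: {cfg[key]}")
    th = DEThresholds(
        fold_cut=float(cfg.get("fold", 1.5)), padj_cut=float(cfg.get("padj", 0.05))
    )
    part = partition_contrasts(read_de_table(cfg["a"]), read_de_table(cfg["b"]), th)
    write_partition(part, out_dir / "departition")
    summary = {
        "cells": list(part.cells()),
        "totals": {"A": contrast_total(part, "A"), "B": contrast_total(part, "B")},
        "discordant_n": len(part.discordant),
    }
    log.info("departition: cells %s", summary["cells"])
    return summary


def _stage_quant_hi3(cfg: dict, out_dir: Path) -> dict:
    path = Path(cfg["peptides"])
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    table = PeptideTable.from_tsv(
        path, cfg["standard_id"], float(cfg.get("standard_amount", 50.0))
    )
    result = hi3_table(table)
    out = out_dir / "hi3.tsv"
    result.to_csv(out, sep="\t", index=False)
    log.info("quant hi3: %d proteins -> %s", len(result), out)
    return {"n_proteins": int(len(result)), "out": str(out)}


_STAGES = {
    "scan": _stage_scan,
    "departition": _stage_departition,
    "quant_hi3": _stage_quant_hi3,
}


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Execute the stages present in ``config`` and write report.json.

    Returns the report.  Rerunning with the same config and seed
    reproduces identical report content.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    for name, fn in _STAGES.items():
        if name not in config:
            continue
        try:
            report["stages"][name] = fn(config[name], out_dir)
        except Exception as exc:  # propagate with stage context
            raise StageError(name, exc) from exc
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
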