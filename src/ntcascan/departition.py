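"""Two-contrast differential-expression classification and Venn partition.

Input tables carry one row per gene with a signed fold change (+k means
k-fold up, -k means k-fold down; |fold| >= 1) and a multiple-testing
adjusted p-value.  A gene is called changed when |fold| strictly exceeds
the fold cutoff AND padj is strictly below the padj cutoff — the
conventions of the study this implements (>1.5-fold, padj < 0.05).
Genes changed in both contrasts but in opposite directions are reported
separately so the six Venn cells stay disjoint.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

Classification = Literal["up", "down", "ns"]


@dataclass(frozen=True)
class DERecord:
    """One gene in one contrast.

    ``signed_fold`` may be NaN/None as an "unexpressed" sentinel; a
    missing ``padj`` (independent-filtering NA) classifies as ns.
    """

    gene_id: str
    signed_fold: float | None
    padj: float | None

    def __post_init__(self) -> None:
        f = self.signed_fold
        if f is not None and not math.isnan(f) and -1 < f < 1:
            raise ValueError(
                f"{self.gene_id}: signed fold {f} in (-1, 1); signed-fold "
                "values have magnitude >= 1 (use NaN for unexpressed)"
            )
        p = self.padj
        if p is not None and not math.isnan(p) and not 0 <= p <= 1:
            raise ValueError(f"{self.gene_id}: padj {p} outside [0, 1]")


@dataclass(frozen=True)
class DEThresholds:
    fold_cut: float = 1.5
    padj_cut: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_cut <= 1:
            raise ValueError("fold cutoff must exceed 1")
        if not 0 < self.padj_cut < 1:
            raise ValueError("padj cutoff must lie in (0, 1)")


@dataclass
class VennPartition:
    """The six disjoint two-contrast cells plus discordant genes."""

    common_up: frozenset[str] = frozenset()
    a_only_up: frozenset[str] = frozenset()
    b_only_up: frozenset[str] = frozenset()
    common_down: frozenset[str] = frozenset()
    a_only_down: frozenset[str] = frozenset()
    b_only_down: frozenset[str] = frozenset()
    discordant: frozenset[str] = frozenset()

    def cells(self) -> tuple[int, int, int, int, int, int]:
        """Cell sizes in the order (common_up, a_only_up, b_only_up,
        common_down, a_only_down, b_only_down)."""
        return (
            len(self.common_up),
            len(self.a_only_up),
            len(self.b_only_up),
            len(self.common_down),
            len(self.a_only_down),
            len(self.b_only_down),
        )

    def changed_genes(self) -> frozenset[str]:
        return (
            self.common_up
            | self.a_only_up
            | self.b_only_up
            | self.common_down
            | self.a_only_down
            | self.b_only_down
            | self.discordant
        )


def signed_fold_from_log2(lfc: float) -> float:
    """DESeq2-style log2 fold change -> signed fold (+k up / -k down)."""
    if lfc is None or math.isnan(lfc):
        return math.nan
    return math.copysign(2.0 ** abs(lfc), lfc) if lfc != 0 else 1.0


def classify_gene(rec: DERecord, th: DEThresholds = DEThresholds()) -> Classification:
    """Classify one gene: strict inequalities on both cutoffs."""
    f, p = rec.signed_fold, rec.padj
    if f is None or math.isnan(f) or p is None or math.isnan(p):
        return "ns"
    if p < th.padj_cut:
        if f > th.fold_cut:
            return "up"
        if f < -th.fold_cut:
            return "down"
    return "ns"


def _classify_table(
    table: Iterable[DERecord], th: DEThresholds
) -> dict[str, Classification]:
    out: dict[str, Classification] = {}
    for rec in table:
        if rec.gene_id in out:
            raise ValueError(f"duplicate gene id within one table: {rec.gene_id}")
        out[rec.gene_id] = classify_gene(rec, th)
    return out


def partition_contrasts(
    table_a: Iterable[DERecord],
    table_b: Iterable[DERecord],
    th: DEThresholds = DEThresholds(),
) -> VennPartition:
    """Assign every gene to exactly one Venn cell.

    Genes absent from one table are treated as ns there; (up, down) /
    (down, up) pairs go to ``discordant`` so the six primary cells stay
    pairwise disjoint.
    """
    cls_a = _classify_table(table_a, th)
    cls_b = _classify_table(table_b, th)
    cells: dict[str, set[str]] = {
        k: set()
        for k in (
            "common_up",
            "a_only_up",
            "b_only_up",
            "common_down",
            "a_only_down",
            "b_only_down",
            "discordant",
        )
    }
    for gene in set(cls_a) | set(cls_b):
        a = cls_a.get(gene, "ns")
        b = cls_b.get(gene, "ns")
        if a == b == "up":
            cells["common_up"].add(gene)
        elif a == b == "down":
            cells["common_down"].add(gene)
        elif a == "up" and b == "ns":
            cells["a_only_up"].add(gene)
        elif a == "ns" and b == "up":
            cells["b_only_up"].add(gene)
        elif a == "down" and b == "ns":
            cells["a_only_down"].add(gene)
        elif a == "ns" and b == "down":
            cells["b_only_down"].add(gene)
        elif "ns" not in (a, b):
            cells["discordant"].add(gene)
    return VennPartition(**{k: frozenset(v) for k, v in cells.items()})


def contrast_total(p: VennPartition, contrast: str) -> int:
    """Number of genes changed in one contrast (A or B).

    Discordant genes are changed in both contrasts and count toward
    both totals.
    """
    if contrast == "A":
        return (
            len(p.common_up)
            + len(p.a_only_up)
            + len(p.common_down)
            + len(p.a_only_down)
            + len(p.discordant)
        )
    if contrast == "B":
        return (
            len(p.common_up)
            + len(p.b_only_up)
            + len(p.common_down)
            + len(p.b_only_down)
            + len(p.discordant)
        )
    raise ValueError(f"contrast must be 'A' or 'B', got {contrast!r}")


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a delimited DE result table (tab or comma, auto-detected).

    Requires a ``gene_id`` column, a ``padj`` column, and either
    ``signed_fold`` or ``log2fc`` (converted via
    :func:`signed_fold_from_log2`).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "padj" not in cols:
        raise ValueError(f"{path}: need gene_id and padj columns, got {list(df.columns)}")
    if "signed_fold" in cols:
        folds = df[cols["signed_fold"]].astype(float)
    elif "log2fc" in cols:
        folds = df[cols["log2fc"]].astype(float).map(signed_fold_from_log2)
    else:
        raise ValueError(f"{path}: need a signed_fold or log2fc column")
    return [
        DERecord(
            gene_id=str(g),
            signed_fold=float(f) if pd.notna(f) else math.nan,
            padj=float(p) if pd.notna(p) else math.nan,
        )
        for g, f, p in zip(df[cols["gene_id"]], folds, df[cols["padj"]])
    ]


def write_partition(p: VennPartition, prefix: str | Path) -> tuple[Path, Path]:
    """Write <prefix>.partition.tsv (gene_id, cell) and <prefix>.summary.json."""
    prefix = Path(prefix)
    tsv = prefix.with_name(prefix.name + ".partition.tsv")
    js = prefix.with_name(prefix.name + ".summary.json")
    cell_names = (
        "common_up",
        "a_only_up",
        "b_only_up",
        "common_down",
        "a_only_down",
        "b_only_down",
        "discordant",
    )
    with open(tsv, "w") as fh:
        fh.write("gene_id\tcell\n")
        for name in cell_names:
            for gene in sorted(getattr(p, name)):
                fh.write(f"{gene}\t{name}\n")
    summary = {
        "cells": dict(
            zip(
                ("common_up", "a_only_up", "b_only_up",
                 "common_down", "a_only_down", "b_only_down"),
                p.cells(),
            )
        ),
        "totals": {"A": contrast_total(p, "A"), "B": contrast_total(p, "B")},
        "discordant_n": len(p.discordant),
    }
    js.write_text(json.dumps(summary, indent=2) + "\n")
    return tsv, js
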