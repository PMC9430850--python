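"""Internal-consistency checks against the study's printed arithmetic.

The published counts used as *inputs* here (gene totals, hypothetical-
protein tallies, the small-ORF length) come from the study's printed
tables; each check recomputes the derived quantity with this package
and compares it to the printed result.
"""

from __future__ import annotations

from dataclasses import dataclass

from .departition import DEThresholds, contrast_total, partition_contrasts
from .genome import cluster_span, intergenic_gap, orf_peptide_length
from .scanner import (
    DEFAULT_ARCHITECTURE,
    attach_minus10,
    find_dyads,
    mismatch_descriptor,
)
from .sites import REPORTED_SITES
from .synthetic import DESimParams, make_de_tables, synthetic_cluster_reconstruction

# printed inputs: (numerator, denominator) count pairs from the study's tables
HYPOTHETICAL_UP = (67, 168)
HYPOTHETICAL_DOWN = (52, 134)
TRANSCRIPTOME_COVERAGE = (2505, 2530)
PROTEOME_COVERAGE = (326, 2530)
SMALL_ORF_BP = 135

# printed results the checks compare against
EXPECTED = {
    "total_A": 862,
    "total_B": 819,
    "hypothetical_up_pct": 39.88,
    "hypothetical_down_pct": 38.81,
    "small_orf_aa": 44,
    "transcriptome_pct": 99,
    "proteome_pct": 13,
    "nrtP_narB_gap": 82,
    "cluster_span": 13300,
}


def percentage(numerator: int, denominator: int, digits: int = 2) -> float:
    return round(100.0 * numerator / denominator, digits)


def venn_summary(seed: int = 0) -> dict:
    """Generate the default two-contrast truth structure, partition it,
    and report cells and per-contrast totals."""
    table_a, table_b, _ = make_de_tables(DESimParams(seed=seed))
    part = partition_contrasts(table_a, table_b, DEThresholds())
    return {
        "cells": part.cells(),
        "total_A": contrast_total(part, "A"),
        "total_B": contrast_total(part, "B"),
    }


def notation_fidelity() -> dict:
    """Re-derive every reported site's deviation annotation.

    Each printed dyad must pass the default mismatch budgets and
    reproduce its printed descriptor exactly; each printed -10 box must
    attach at its printed linker with its printed descriptor.
    """
    arch = DEFAULT_ARCHITECTURE
    failures = []
    n_boxes = 0
    for site in REPORTED_SITES:
        hits = [
            h for h in find_dyads(site.dyad, arch) if h.strand == "+" and h.start == 1
        ]
        if not hits:
            failures.append(f"{site.gene}: dyad {site.dyad} rejected by default budgets")
            continue
        dyad_note = mismatch_descriptor(site.dyad, "dyad", arch)
        if dyad_note != site.dyad_note:
            failures.append(
                f"{site.gene}: dyad note {dyad_note!r} != printed {site.dyad_note!r}"
            )
        if site.minus10 is None:
            continue
        n_boxes += 1
        context = site.dyad + "A" * site.linker + site.minus10
        hit = attach_minus10(hits[0], context, arch)
        if hit.minus10 is None:
            failures.append(f"{site.gene}: -10 box {site.minus10} not attached")
        else:
            if hit.minus10.linker_length != site.linker:
                failures.append(
                    f"{site.gene}: linker {hit.minus10.linker_length} != {site.linker}"
                )
            if hit.minus10.descriptor != site.minus10_note:
                failures.append(
                    f"{site.gene}: -10 note {hit.minus10.descriptor!r} != "
                    f"printed {site.minus10_note!r}"
                )
    return {
        "n_dyads": len(REPORTED_SITES),
        "n_boxes": n_boxes,
        "failures": failures,
        "ok": not failures,
    }


@dataclass
class CheckResult:
    name: str
    value: float
    expected: float
    ok: bool


def study_consistency(seed: int = 0) -> list[CheckResult]:
    """Run every desk-scale arithmetic check and report pass/fail.

    The genome-geometry checks run on the package's clearly-labelled
    synthetic reconstruction of the published cluster layout, not on
    the real contig.
    """
    venn = venn_summary(seed)
    genome, _ = synthetic_cluster_reconstruction(seed)
    cluster = ["cynS", "cnaT", "nirA", "RSS12335", "nitM", "nrtP", "narB"]
    values = {
        "total_A": venn["total_A"],
        "total_B": venn["total_B"],
        "hypothetical_up_pct": percentage(*HYPOTHETICAL_UP),
        "hypothetical_down_pct": percentage(*HYPOTHETICAL_DOWN),
        "small_orf_aa": orf_peptide_length(SMALL_ORF_BP),
        "transcriptome_pct": round(percentage(*TRANSCRIPTOME_COVERAGE, digits=4)),
        "proteome_pct": round(percentage(*PROTEOME_COVERAGE, digits=4)),
        "nrtP_narB_gap": intergenic_gap(genome, "nrtP", "narB"),
        "cluster_span": cluster_span(genome, cluster),
    }
    results = [
        CheckResult(name, values[name], EXPECTED[name], values[name] == EXPECTED[name])
        for name in EXPECTED
    ]
    fidelity = notation_fidelity()
    results.append(
        CheckResult("notation_fidelity", int(fidelity["ok"]), 1, fidelity["ok"])
    )
    return results
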