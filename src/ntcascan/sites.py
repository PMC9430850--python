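"""Reported NtcA sites of *Synechococcus* sp. WH7803.

The published promoter survey for this strain lists eight dyad sites
upstream of nitrogen-assimilation genes, seven of them with an attached
-10 box, each annotated with its deviation from the GTA-N8-TAC / TAN3T
consensus and its distance upstream of the gene's translational start
site ("tss" in this strain's literature).  They serve as the reference
inputs for notation-fidelity checks and for deriving the strain-level
consensus.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReportedSite:
    gene: str
    dyad: str
    linker: int | None  # spacer (bp) between dyad and -10 box, None if no box
    minus10: str | None
    distance: int  # bp upstream of the gene's translational start site
    distance_kind: str  # how the publication anchors the distance
    dyad_note: str  # deviation annotation as printed ('' = canonical)
    minus10_note: str


REPORTED_SITES: tuple[ReportedSite, ...] = (
    ReportedSite(
        gene="nrtP",
        dyad="GTAGCGATTGCAAC",
        linker=22,
        minus10="TGCAAT",
        distance=125,
        distance_kind="identified",
        dyad_note="TAC changed to AAC",
        minus10_note="TAN_3_T changed to TGN_3_T",
    ),
    ReportedSite(
        gene="nrtP",
        dyad="GTAACAACGGCTAC",
        linker=22,
        minus10="TGTGAT",
        distance=198,
        distance_kind="identified",
        dyad_note="",
        minus10_note="TAN_3_T changed to TGN_3_T",
    ),
    ReportedSite(
        gene="narB",
        dyad="GTGACCTACCTCAC",
        linker=21,
        minus10="TTGGAT",
        distance=304,
        distance_kind="identified",
        dyad_note="GTA and TAC changed to GTG and CAC, respectively",
        minus10_note="TAN_3_T changed to TTN_3_T",
    ),
    ReportedSite(
        gene="nirA",
        dyad="GTTCGAACTGCTAC",
        linker=22,
        minus10="AAAACT",
        distance=142,
        distance_kind="identified",
        dyad_note="GTA changed to GTT",
        minus10_note="TAN_3_T changed to AAN_3_T",
    ),
    ReportedSite(
        gene="nitM",
        dyad="GTCACGGCCGTCAC",
        linker=24,
        minus10="CACCAT",
        distance=200,
        distance_kind="identified",
        dyad_note="GTA and TAC changed to GTC and CAC, respectively",
        minus10_note="TAN_3_T changed to CAN_3_T",
    ),
    ReportedSite(
        gene="cynS",
        dyad="GTGACTGCGTGAAC",
        linker=23,
        minus10="TGGCAT",
        distance=127,
        distance_kind="identified",
        dyad_note="GTA and TAC changed to GTG and AAC, respectively",
        minus10_note="TAN_3_T changed to TGN_3_T",
    ),
    ReportedSite(
        gene="cnaT",
        dyad="GTTCAGCCAGCAAC",
        linker=22,
        minus10="TCTGGT",
        distance=213,
        distance_kind="centered",
        dyad_note="GTA and TAC changed to GTT and AAC, respectively",
        minus10_note="TAN_3_T changed to TCN_3_T",
    ),
    ReportedSite(
        gene="cnaT",
        dyad="GTATCAACGACTAC",
        linker=None,
        minus10=None,
        distance=57,
        distance_kind="placed",
        dyad_note="",
        minus10_note="",
    ),
)
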