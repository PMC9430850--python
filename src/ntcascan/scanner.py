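"""Detection of NtcA-activated promoter architectures.

The canonical NtcA-binding site in cyanobacteria is a palindromic dyad,
GTA-N8-TAC: two 3-base arms separated by eight unconstrained bases.  An
NtcA-*activated promoter* additionally carries a Pribnow-like -10 box
(consensus TAN3T) 21-24 bp downstream of the dyad, replacing the -35
element of a sigma-70 promoter.  Reported sites routinely deviate from
the consensus by a base or two, so the scanner searches with a
per-element mismatch budget and annotates deviations in the notation
used in the cyanobacterial literature ("GTA and TAC changed to GTG and
CAC, respectively").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .genome import (
    VALID_BASES,
    AnnotatedGenome,
    GenomeRegion,
    reverse_complement,
    upstream_region,
)

IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class MotifArchitecture:
    """Parameters of the dyad + spaced -10 box promoter architecture.

    Defaults are the tightest values consistent with every site reported
    for *Synechococcus* WH7803: at most one mismatch per dyad arm, at
    most one mismatch over the three constrained -10 positions, and a
    21-24 bp linker between the dyad and the -10 box.
    """

    arm5: str = "GTA"
    arm3: str = "TAC"
    internal_n: int = 8
    max_mismatch_per_arm: int = 1
    minus10_consensus: str = "TANNNT"
    max_minus10_mismatch: int = 1
    linker_range: tuple[int, int] = (21, 24)
    minus10_required: bool = False

    def __post_init__(self) -> None:
        if self.internal_n < 0:
            raise ValueError("internal spacer length must be >= 0")
        if self.linker_range[0] > self.linker_range[1]:
            raise ValueError("linker range min exceeds max")
        if self.max_mismatch_per_arm < 0 or self.max_minus10_mismatch < 0:
            raise ValueError("mismatch budgets must be >= 0")

    @property
    def dyad_length(self) -> int:
        return len(self.arm5) + self.internal_n + len(self.arm3)

    @property
    def minus10_length(self) -> int:
        return len(self.minus10_consensus)


DEFAULT_ARCHITECTURE = MotifArchitecture()


@dataclass(frozen=True)
class Minus10Match:
    sequence: str
    linker_length: int
    mismatches: int
    descriptor: str


@dataclass(frozen=True)
class GeneContext:
    locus_tag: str
    distance_upstream_end: int
    distance_upstream_center: float


@dataclass(frozen=True)
class PromoterHit:
    """One detected dyad site, optionally with an attached -10 box.

    ``start``/``end`` are 1-based inclusive coordinates of the dyad in
    the scanned sequence (or the parent contig after ``scan_upstream``);
    ``dyad_sequence`` reads 5'->3' on ``strand``.
    """

    start: int
    end: int
    strand: str
    dyad_sequence: str
    arm_mismatches: tuple[str, ...] = ()
    arm5_mismatches: int = 0
    arm3_mismatches: int = 0
    minus10: Minus10Match | None = None
    gene: GeneContext | None = None

    @property
    def total_mismatches(self) -> int:
        n = self.arm5_mismatches + self.arm3_mismatches
        if self.minus10 is not None:
            n += self.minus10.mismatches
        return n

    @property
    def descriptor(self) -> str:
        """Combined deviation annotation in the literature's notation."""
        parts = [p for p in self.arm_mismatches if p]
        if self.minus10 is not None and self.minus10.descriptor:
            parts.append(self.minus10.descriptor)
        return _join_descriptor_parts(parts)


@dataclass
class ConsensusSummary:
    """Per-position base counts over accepted sites and the derived consensus."""

    dyad_counts: list[dict[str, int]]
    minus10_counts: list[dict[str, int]]
    n_sites: int
    n_minus10: int

    @property
    def dyad_consensus(self) -> str:
        return "".join(_majority(c) for c in self.dyad_counts)

    @property
    def minus10_consensus(self) -> str:
        return "".join(_majority(c) for c in self.minus10_counts)


def _majority(counts: dict[str, int]) -> str:
    if not counts:
        return "N"
    top = max(counts.values())
    tied = frozenset(b for b, c in counts.items() if c == top)
    if len(tied) == 1:
        return next(iter(tied))
    return IUPAC_CODES.get(tied, "N")


def _join_descriptor_parts(parts: list[str]) -> str:
    """Join element descriptors as the literature prints them.

    A both-arms part already ends in ", respectively" and takes a comma
    before the following "and".
    """
    out = ""
    for part in parts:
        if not out:
            out = part
        elif out.endswith("respectively"):
            out += ", and " + part
        else:
            out += " and " + part
    return out


def _mismatch_count(observed: str, consensus: str) -> int:
    """Mismatches at constrained (non-N consensus) positions; an N in the
    observed sequence never counts as a match."""
    return sum(
        1 for o, c in zip(observed, consensus) if c != "N" and o != c
    )


def _compress_n_runs(pattern: str) -> str:
    """Render a pattern with internal N runs in subscript style: TANNNT -> TAN_3_T."""
    out = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "N":
            j = i
            while j < len(pattern) and pattern[j] == "N":
                j += 1
            run = j - i
            out.append("N" if run == 1 else f"N_{run}_")
            i = j
        else:
            out.append(pattern[i])
            i += 1
    return "".join(out)


def mismatch_descriptor(
    observed: str,
    consensus_label: str,
    arch: MotifArchitecture = DEFAULT_ARCHITECTURE,
) -> str:
    """Deviation annotation for one element, in the literature's notation.

    ``consensus_label`` is ``"dyad"`` (the full 14-mer) or ``"minus10"``.
    An exact match yields the empty string.  Single-arm deviations read
    "TAC changed to AAC"; both arms deviating reads "GTA and TAC changed
    to GTG and CAC, respectively"; -10 deviations keep the unconstrained
    positions as N: "TAN_3_T changed to TGN_3_T".
    """
    if consensus_label == "dyad":
        if len(observed) != arch.dyad_length:
            raise ValueError(
                f"observed dyad length {len(observed)} != {arch.dyad_length}"
            )
        obs5 = observed[: len(arch.arm5)]
        obs3 = observed[-len(arch.arm3) :]
        dev5 = obs5 != arch.arm5
        dev3 = obs3 != arch.arm3
        if dev5 and dev3:
            return (
                f"{arch.arm5} and {arch.arm3} changed to {obs5} and {obs3}, "
                "respectively"
            )
        if dev5:
            return f"{arch.arm5} changed to {obs5}"
        if dev3:
            return f"{arch.arm3} changed to {obs3}"
        return ""
    if consensus_label == "minus10":
        cons = arch.minus10_consensus
        if len(observed) != len(cons):
            raise ValueError(
                f"observed -10 length {len(observed)} != {len(cons)}"
            )
        pattern = "".join(
            o if c != "N" else "N" for o, c in zip(observed, cons)
        )
        if pattern == cons:
            return ""
        return (
            f"{_compress_n_runs(cons)} changed to {_compress_n_runs(pattern)}"
        )
    raise ValueError(f"unknown consensus label: {consensus_label!r}")


def _dyad_hit_at(
    window: str, pos: int, strand: str, arch: MotifArchitecture
) -> PromoterHit | None:
    """Build a hit for a strand-oriented window starting at 1-based ``pos``."""
    n5 = len(arch.arm5)
    n3 = len(arch.arm3)
    mm5 = _mismatch_count(window[:n5], arch.arm5)
    if mm5 > arch.max_mismatch_per_arm:
        return None
    mm3 = _mismatch_count(window[-n3:], arch.arm3)
    if mm3 > arch.max_mismatch_per_arm:
        return None
    descriptors = []
    obs5, obs3 = window[:n5], window[-n3:]
    if obs5 != arch.arm5 or obs3 != arch.arm3:
        descriptors.append(mismatch_descriptor(window, "dyad", arch))
    return PromoterHit(
        start=pos,
        end=pos + arch.dyad_length - 1,
        strand=strand,
        dyad_sequence=window,
        arm_mismatches=tuple(descriptors),
        arm5_mismatches=mm5,
        arm3_mismatches=mm3,
    )


def find_dyads(
    sequence: str, arch: MotifArchitecture = DEFAULT_ARCHITECTURE
) -> list[PromoterHit]:
    """All dyad windows on both strands within the per-arm mismatch budget.

    Hits are sorted by leftmost coordinate, then strand (+ before -),
    then total mismatch count.  Since the consensus dyad is its own
    reverse complement, a perfect site is reported once per strand.
    """
    sequence = sequence.upper()
    bad = set(sequence) - VALID_BASES
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    w = arch.dyad_length
    hits: list[PromoterHit] = []
    for i in range(len(sequence) - w + 1):
        window = sequence[i : i + w]
        fwd = _dyad_hit_at(window, i + 1, "+", arch)
        if fwd is not None:
            hits.append(fwd)
        rev = _dyad_hit_at(reverse_complement(window), i + 1, "-", arch)
        if rev is not None:
            hits.append(rev)
    hits.sort(key=lambda h: (h.start, h.strand, h.total_mismatches))
    return hits


def attach_minus10(
    dyad_hit: PromoterHit,
    sequence: str,
    arch: MotifArchitecture = DEFAULT_ARCHITECTURE,
) -> PromoterHit:
    """Scan 3' of a dyad hit for the best qualifying -10 box.

    Each linker length in ``arch.linker_range`` is tried; the candidate
    with the fewest mismatches wins, ties going to the shortest linker.
    The hit is returned unchanged when no candidate is within budget —
    absence of a -10 box is a valid state (an NtcA-*binding site* that
    is not a recognizable NtcA-*activated promoter*).
    """
    sequence = sequence.upper()
    m = arch.minus10_length
    best: Minus10Match | None = None
    for linker in range(arch.linker_range[0], arch.linker_range[1] + 1):
        if dyad_hit.strand == "+":
            s = dyad_hit.end + linker + 1  # 1-based start of the box
            if s + m - 1 > len(sequence):
                continue
            candidate = sequence[s - 1 : s + m - 1]
        else:
            e = dyad_hit.start - linker - 1  # 1-based end of the box
            if e - m + 1 < 1:
                continue
            candidate = reverse_complement(sequence[e - m : e])
        mm = _mismatch_count(candidate, arch.minus10_consensus)
        if mm > arch.max_minus10_mismatch:
            continue
        if best is None or mm < best.mismatches:
            best = Minus10Match(
                sequence=candidate,
                linker_length=linker,
                mismatches=mm,
                descriptor=mismatch_descriptor(candidate, "minus10", arch),
            )
    if best is None:
        return dyad_hit
    return dataclasses.replace(dyad_hit, minus10=best)


def _to_parent_coords(
    hit: PromoterHit, region: GenomeRegion
) -> PromoterHit:
    """Map a region-local hit onto the parent contig."""
    if region.strand == "+":
        return dataclasses.replace(
            hit,
            start=region.start + hit.start - 1,
            end=region.start + hit.end - 1,
        )
    return dataclasses.replace(
        hit,
        start=region.end - hit.end + 1,
        end=region.end - hit.start + 1,
        strand="-" if hit.strand == "+" else "+",
    )


def scan_upstream(
    genome: AnnotatedGenome,
    locus_tag: str,
    arch: MotifArchitecture = DEFAULT_ARCHITECTURE,
    window: int = 350,
) -> list[PromoterHit]:
    """Scan a gene's upstream region for promoter architectures.

    Runs :func:`find_dyads` then :func:`attach_minus10` over the
    coding-strand-oriented upstream region, fills in gene-relative
    distances, and maps coordinates back onto the contig.

    Two distances are reported because the literature mixes conventions:
    ``distance_upstream_end`` counts the bases between the 3'-most base
    of the reported element (-10 box when present, else dyad) and the
    start codon; ``distance_upstream_center`` locates the dyad center,
    where the base immediately before the start codon is position 1
    (a 14-bp dyad abutting the start codon is centered at 7.5).
    """
    if window < arch.dyad_length:
        raise ValueError(
            f"window {window} shorter than dyad length {arch.dyad_length}"
        )
    region = upstream_region(genome, locus_tag, window)
    local_hits = [
        attach_minus10(h, region.sequence, arch)
        for h in find_dyads(region.sequence, arch)
    ]
    if arch.minus10_required:
        local_hits = [h for h in local_hits if h.minus10 is not None]
    lr = region.length
    out = []
    for h in local_hits:
        if h.strand == "+" and h.minus10 is not None:
            gene_ward_end = h.end + h.minus10.linker_length + arch.minus10_length
        else:
            gene_ward_end = h.end
        ctx = GeneContext(
            locus_tag=locus_tag,
            distance_upstream_end=lr - gene_ward_end,
            distance_upstream_center=lr + 1 - (h.start + h.end) / 2,
        )
        out.append(
            dataclasses.replace(_to_parent_coords(h, region), gene=ctx)
        )
    out.sort(key=lambda h: (h.start, h.strand, h.total_mismatches))
    return out


def load_architecture(path) -> MotifArchitecture:
    """Load a :class:`MotifArchitecture` from a YAML mapping.

    Keys mirror the dataclass fields; absent keys keep their defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(MotifArchitecture)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown architecture keys: {sorted(unknown)}")
    if "linker_range" in data:
        data["linker_range"] = tuple(data["linker_range"])
    return MotifArchitecture(**data)


def hits_to_tsv(hits: list[PromoterHit], contig: str, path) -> None:
    """Write hits as a TSV with one row per detected site."""
    cols = (
        "locus_tag\tcontig\tstart\tend\tstrand\tdyad_seq\tdyad_mm\tlinker\t"
        "minus10_seq\tminus10_mm\tdist_end\tdist_center\tdescriptor\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for h in hits:
            m10 = h.minus10
            gene = h.gene
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        gene.locus_tag if gene else ".",
                        contig,
                        h.start,
                        h.end,
                        h.strand,
                        h.dyad_sequence,
                        h.arm5_mismatches + h.arm3_mismatches,
                        m10.linker_length if m10 else ".",
                        m10.sequence if m10 else ".",
                        m10.mismatches if m10 else ".",
                        gene.distance_upstream_end if gene else ".",
                        gene.distance_upstream_center if gene else ".",
                        h.descriptor or ".",
                    )
                )
                + "\n"
            )


def hits_to_bed6(hits: list[PromoterHit], contig: str, path) -> None:
    """Write dyad intervals as BED6 (0-based half-open, noted in header)."""
    with open(path, "w") as fh:
        fh.write("# BED6: 0-based half-open coordinates\n")
        for h in hits:
            name = h.gene.locus_tag if h.gene else "dyad"
            fh.write(
                f"{contig}\t{h.start - 1}\t{h.end}\t{name}\t"
                f"{h.total_mismatches}\t{h.strand}\n"
            )


def build_consensus(hits: list[PromoterHit]) -> ConsensusSummary:
    """Per-position base tallies and majority consensus over accepted sites.

    Ties at a position are rendered as the IUPAC ambiguity code of the
    tied bases.  -10 tallies cover only the hits that carry a box.
    """
    if not hits:
        raise ValueError("cannot build a consensus from zero sites")
    dlen = len(hits[0].dyad_sequence)
    dyad_counts: list[dict[str, int]] = [dict() for _ in range(dlen)]
    for h in hits:
        if len(h.dyad_sequence) != dlen:
            raise ValueError("hits have inconsistent dyad lengths")
        for i, b in enumerate(h.dyad_sequence):
            dyad_counts[i][b] = dyad_counts[i].get(b, 0) + 1
    with_box = [h for h in hits if h.minus10 is not None]
    mlen = len(with_box[0].minus10.sequence) if with_box else 0
    minus10_counts: list[dict[str, int]] = [dict() for _ in range(mlen)]
    for h in with_box:
        for i, b in enumerate(h.minus10.sequence):
            minus10_counts[i][b] = minus10_counts[i].get(b, 0) + 1
    return ConsensusSummary(
        dyad_counts=dyad_counts,
        minus10_counts=minus10_counts,
        n_sites=len(hits),
        n_minus10=len(with_box),
    )
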