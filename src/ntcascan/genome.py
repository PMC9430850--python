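"""Genome sequence + annotation model and coordinate arithmetic.

All coordinates are 1-based and fully inclusive (GenBank convention).
Distances relative to a gene are measured to the first base of its start
codon — in marine picocyanobacterial promoter work the "tss" reference
point is the *translational* start site, not a mapped transcription start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (CDS) on a contig, 1-based inclusive coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    gene_name: str | None = None
    compound: bool = False  # True when a join() location was flattened

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.locus_tag}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """A contig sequence with its strand-aware gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dupes = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"duplicate locus tags: {dupes}")
        for f in self.features:
            if f.start < 1 or f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.locus_tag} [{f.start},{f.end}] outside "
                    f"sequence [1,{len(self.sequence)}]"
                )
        self._by_tag = {f.locus_tag: f for f in self.features}

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, locus_tag: str) -> GeneFeature:
        try:
            return self._by_tag[locus_tag]
        except KeyError:
            raise KeyError(f"unknown locus tag: {locus_tag!r}") from None

    def slice(self, start: int, end: int) -> str:
        """Plus-strand sequence of [start, end], 1-based inclusive."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValueError(f"invalid slice [{start},{end}]")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class GenomeRegion:
    """A coding-strand-oriented slice of a contig.

    ``sequence`` is the parent slice, reverse-complemented when
    ``strand == '-'`` so it always reads 5'->3' on the strand of interest.
    """

    parent_id: str
    start: int
    end: int
    strand: str
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("region sequence length inconsistent with coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read the first record of a GenBank flat file.

    CDS features are captured with locus_tag (falling back to /gene then
    /protein_id), 1-based inclusive coordinates and strand.  Compound
    (join) locations are flattened to their bounding interval with a
    warning — they are rare in bacterial annotation and irrelevant here.
    """
    path = Path(path)
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise ValueError(f"{path}: no GenBank records found") from None
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(record.seq) == 0:
        raise ValueError(f"{path}: record {record.id} has no sequence")
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        tag = (
            quals.get("locus_tag", [None])[0]
            or quals.get("gene", [None])[0]
            or quals.get("protein_id", [None])[0]
        )
        if tag is None or tag in seen:
            continue
        seen.add(tag)
        compound = len(feat.location.parts) > 1
        if compound:
            warnings.warn(
                f"CDS {tag}: compound location flattened to bounding interval",
                stacklevel=2,
            )
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(
            GeneFeature(
                locus_tag=tag,
                start=start,
                end=end,
                strand=strand,
                gene_name=quals.get("gene", [None])[0],
                compound=compound,
            )
        )
    return AnnotatedGenome(id=record.id, sequence=seq, features=features)


def read_fasta(path: str | Path) -> AnnotatedGenome:
    """Read the first FASTA record as an unannotated genome."""
    path = Path(path)
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ValueError(f"{path}: no FASTA records found") from None
    return AnnotatedGenome(id=record.id, sequence=str(record.seq).upper())


def upstream_region(
    genome: AnnotatedGenome, locus_tag: str, length: int
) -> GenomeRegion:
    """The ``length`` bases immediately 5' of a gene's start codon.

    The returned sequence is oriented on the coding strand, so its last
    base is always the base immediately before the start codon.  Regions
    running off the contig edge are truncated and flagged.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    feat = genome.feature(locus_tag)
    if feat.strand == "+":
        start = max(1, feat.start - length)
        end = feat.start - 1
        if end < start:
            raise ValueError(f"{locus_tag}: no upstream sequence (gene at contig edge)")
        truncated = start > feat.start - length
        seq = genome.slice(start, end)
    else:
        start = feat.end + 1
        end = min(len(genome), feat.end + length)
        if end < start:
            raise ValueError(f"{locus_tag}: no upstream sequence (gene at contig edge)")
        truncated = end < feat.end + length
        seq = reverse_complement(genome.slice(start, end))
    return GenomeRegion(
        parent_id=genome.id,
        start=start,
        end=end,
        strand=feat.strand,
        sequence=seq,
        truncated=truncated,
    )


def intergenic_gap(
    genome: AnnotatedGenome, upstream_locus: str, downstream_locus: str
) -> int:
    """Bases between the end of one CDS and the start codon of the next.

    Both genes must lie on the same strand; the gap is measured in
    transcription order and is negative for overlapping genes.
    """
    up = genome.feature(upstream_locus)
    down = genome.feature(downstream_locus)
    if up.strand != down.strand:
        raise ValueError(
            f"{upstream_locus} and {downstream_locus} are on opposite strands; "
            "intergenic gap is defined for co-oriented genes only"
        )
    if up.strand == "+":
        return down.start - up.end - 1
    return up.start - down.end - 1


def cluster_span(genome: AnnotatedGenome, loci: Sequence[str]) -> int:
    """Bounding-interval span (bp) of a set of >=2 gene features."""
    if len(loci) < 2:
        raise ValueError("cluster span needs at least two loci")
    feats = [genome.feature(t) for t in loci]
    return max(f.end for f in feats) - min(f.start for f in feats) + 1


def orf_peptide_length(orf_length: int) -> int:
    """Length (aa) of the peptide encoded by an ORF of ``orf_length`` bp.

    The stop codon is not translated, so a 135-bp ORF encodes a
    44-residue peptide.
    """
    if orf_length < 6:
        raise ValueError(f"ORF of {orf_length} bp is shorter than start+stop codons")
    if orf_length % 3:
        raise ValueError(f"ORF length {orf_length} is not a multiple of 3")
    return orf_length // 3 - 1


def features_to_tsv(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as TSV (locus_tag, start, end, strand), 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("locus_tag\tstart\tend\tstrand\n")
        for f in features:
            fh.write(f"{f.locus_tag}\t{f.start}\t{f.end}\t{f.strand}\n")


def features_to_bed6(
    features: Iterable[GeneFeature], contig: str, path: str | Path
) -> None:
    """Write features as BED6 (0-based half-open, noted in the header)."""
    with open(path, "w") as fh:
        fh.write("# BED6: 0-based half-open coordinates\n")
        for f in features:
            fh.write(
                f"{contig}\t{f.start - 1}\t{f.end}\t{f.locus_tag}\t0\t{f.strand}\n"
            )


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write the genome and its CDS features as a GenBank flat file."""
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description="",
        annotations={"molecule_type": "DNA"},
    )
    for f in genome.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1),
                type="CDS",
                qualifiers={"locus_tag": [f.locus_tag]}
                | ({"gene": [f.gene_name]} if f.gene_name else {}),
            )
        )
    SeqIO.write(record, str(path), "genbank")


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        SeqRecord(Seq(genome.sequence), id=genome.id, description=""),
        str(path),
        "fasta",
    )
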