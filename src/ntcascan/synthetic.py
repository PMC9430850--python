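"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is a pure function of its parameter object: the same
seed yields byte-identical output.  Randomness comes from numpy's PCG64
generator, recorded in the emitted truth metadata so fixtures are
portable.  The genomic background is i.i.d. with configurable GC
(default 0.60, matching the organism the defaults emulate); no Markov
structure is modelled.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .departition import DERecord
from .genome import AnnotatedGenome, GeneFeature, reverse_complement
from .quant import PeptideTable
from .scanner import DEFAULT_ARCHITECTURE, MotifArchitecture

_RNG_NAME = "numpy PCG64"


@dataclass(frozen=True)
class PlantedSite:
    contig: str
    start: int  # 1-based inclusive genome coordinates of the dyad
    end: int
    strand: str
    dyad_seq: str
    minus10_seq: str | None
    linker: int | None
    arm_mm: int
    minus10_mm: int
    target_locus: str
    distance: int  # bases between the element 3' end and the start codon


@dataclass
class TruthSet:
    """Ground truth emitted by every generator."""

    planted_sites: list[PlantedSite] = field(default_factory=list)
    de_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    protein_fmol: dict[str, float] = field(default_factory=dict)
    expression_ratios: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_sites": [dataclasses.asdict(s) for s in self.planted_sites],
            "de_labels": self.de_labels,
            "protein_fmol": self.protein_fmol,
            "expression_ratios": self.expression_ratios,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_sites=[PlantedSite(**s) for s in payload["planted_sites"]],
            de_labels=payload["de_labels"],
            protein_fmol=payload["protein_fmol"],
            expression_ratios=payload["expression_ratios"],
            meta=payload["meta"],
        )


# ---------------------------------------------------------------------------
# genomes with planted promoter architectures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimParams:
    """Background genome + planted-site layout.

    One site is planted per target gene (round-robin), inside the
    gene's upstream clearance so a default scanning window always
    covers it.  ``arm_mismatches`` / ``minus10_mismatches`` give the
    requested degeneracy of every planted site.
    """

    seed: int
    length: int = 10_000
    gc_content: float = 0.60
    n_genes: int = 5
    gene_length: int = 600
    upstream_clearance: int = 300
    n_sites: int = 3
    arm_mismatches: int = 0
    minus10_mismatches: int = 0
    with_minus10: bool = True
    arch: MotifArchitecture = DEFAULT_ARCHITECTURE
    contig_id: str = "synth_contig"

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.length < 20 * self.arch.dyad_length:
            raise ValueError("genome too short for site planting")


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def _mutate(rng: np.random.Generator, element: str, n_mm: int, positions: list[int]) -> str:
    """Introduce n_mm mismatches at randomly chosen allowed positions."""
    if n_mm > len(positions):
        raise ValueError("more mismatches requested than constrained positions")
    chosen = rng.choice(len(positions), size=n_mm, replace=False)
    seq = list(element)
    for idx in chosen:
        pos = positions[idx]
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def _make_site(
    rng: np.random.Generator, params: GenomeSimParams
) -> tuple[str, str | None, int | None, int, int]:
    """Returns (dyad, minus10 or None, linker or None, arm_mm_total, minus10_mm)."""
    arch = params.arch
    arm5 = _mutate(rng, arch.arm5, min(params.arm_mismatches, arch.max_mismatch_per_arm),
                   list(range(len(arch.arm5))))
    arm3 = _mutate(rng, arch.arm3, min(params.arm_mismatches, arch.max_mismatch_per_arm),
                   list(range(len(arch.arm3))))
    spacer = "".join(_random_sequence(rng, arch.internal_n, params.gc_content))
    dyad = arm5 + spacer + arm3
    arm_mm = sum(a != b for a, b in zip(arm5, arch.arm5)) + sum(
        a != b for a, b in zip(arm3, arch.arm3)
    )
    if not params.with_minus10:
        return dyad, None, None, arm_mm, 0
    cons = arch.minus10_consensus
    constrained = [i for i, c in enumerate(cons) if c != "N"]
    filled = "".join(
        c if c != "N" else "ACGT"[rng.integers(4)] for c in cons
    )
    box = _mutate(
        rng, filled, min(params.minus10_mismatches, arch.max_minus10_mismatch), constrained
    )
    m10_mm = sum(box[i] != cons[i] for i in constrained)
    linker = int(rng.integers(arch.linker_range[0], arch.linker_range[1] + 1))
    return dyad, box, linker, arm_mm, m10_mm


def make_genome(params: GenomeSimParams) -> tuple[AnnotatedGenome, TruthSet]:
    """I.i.d. background genome with genes and planted promoter sites.

    Genes alternate strand and each keeps ``upstream_clearance`` bases
    of intergenic space on its 5' side; planted elements sit inside
    that clearance at a recorded distance from the start codon.
    """
    rng = np.random.default_rng(params.seed)
    slot = params.upstream_clearance + params.gene_length
    needed = 100 + params.n_genes * slot + 100
    if needed > params.length:
        raise ValueError(
            f"cannot pack {params.n_genes} genes with {params.upstream_clearance} bp "
            f"clearance into {params.length} bp (needs {needed})"
        )
    if params.n_sites > params.n_genes:
        raise ValueError("at most one planted site per gene")
    seq = _random_sequence(rng, params.length, params.gc_content)
    features = []
    for i in range(params.n_genes):
        slot_start = 100 + i * slot + 1
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start = slot_start + params.upstream_clearance
            end = start + params.gene_length - 1
        else:
            start = slot_start
            end = start + params.gene_length - 1
        features.append(
            GeneFeature(
                locus_tag=f"gene_{i + 1:04d}", start=start, end=end, strand=strand
            )
        )
    planted: list[PlantedSite] = []
    arch = params.arch
    for i in range(params.n_sites):
        feat = features[i]
        dyad, box, linker, arm_mm, m10_mm = _make_site(rng, params)
        element = dyad if box is None else dyad + "".join(
            _random_sequence(rng, linker, params.gc_content)
        ) + box
        max_d = params.upstream_clearance - len(element) - 5
        distance = int(rng.integers(10, max_d))
        if feat.strand == "+":
            elem_end = feat.start - 1 - distance
            elem_start = elem_end - len(element) + 1
            seq[elem_start - 1 : elem_end] = list(element)
            dyad_start, dyad_end = elem_start, elem_start + arch.dyad_length - 1
        else:
            elem_start = feat.end + 1 + distance
            elem_end = elem_start + len(element) - 1
            seq[elem_start - 1 : elem_end] = list(reverse_complement(element))
            dyad_start, dyad_end = elem_end - arch.dyad_length + 1, elem_end
        planted.append(
            PlantedSite(
                contig=params.contig_id,
                start=dyad_start,
                end=dyad_end,
                strand=feat.strand,
                dyad_seq=dyad,
                minus10_seq=box,
                linker=linker,
                arm_mm=arm_mm,
                minus10_mm=m10_mm,
                target_locus=feat.locus_tag,
                distance=distance,
            )
        )
    genome = AnnotatedGenome(
        id=params.contig_id, sequence="".join(seq), features=features
    )
    truth = TruthSet(
        planted_sites=planted,
        meta={"rng": _RNG_NAME, "seed": params.seed, "generator": "make_genome"},
    )
    return genome, truth


def perfect_match_probability(gc: float, arch: MotifArchitecture = DEFAULT_ARCHITECTURE) -> float:
    """Per-(window, strand) probability of a zero-mismatch dyad under an
    i.i.d. background with the given GC content (closed form)."""
    p_base = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    p = 1.0
    for b in arch.arm5 + arch.arm3:
        p *= p_base[b]
    return p


# ---------------------------------------------------------------------------
# two-contrast differential-expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DESimParams:
    """Two-contrast DE truth structure.

    Defaults reproduce the overlap structure of the nitrogen-response
    study this package emulates: 2,505 expressed genes, contrast A
    (starvation vs. ammonium) with 440 up / 422 down, contrast B
    (nanomolar nitrate vs. ammonium) with 420 up / 399 down, sharing
    395 up and 371 down.  True effect magnitudes are log-uniform over
    [1.6, 300] — the span of fold changes the study reports.
    """

    seed: int
    n_genes: int = 2505
    up_a: int = 440
    up_b: int = 420
    up_common: int = 395
    down_a: int = 422
    down_b: int = 399
    down_common: int = 371
    fold_range: tuple[float, float] = (1.6, 300.0)
    ns_fold_max: float = 1.5
    de_padj_max: float = 0.049
    gene_prefix: str = "g"

    def __post_init__(self) -> None:
        if self.up_common > min(self.up_a, self.up_b):
            raise ValueError("up overlap exceeds a marginal up count")
        if self.down_common > min(self.down_a, self.down_b):
            raise ValueError("down overlap exceeds a marginal down count")
        changed = (
            self.up_a + self.up_b - self.up_common
            + self.down_a + self.down_b - self.down_common
        )
        if changed > self.n_genes:
            raise ValueError(f"{changed} changed genes exceed n_genes={self.n_genes}")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def make_de_tables(
    params: DESimParams,
) -> tuple[list[DERecord], list[DERecord], TruthSet]:
    """Two DE result tables with a controlled Venn overlap of true labels.

    Label assignment is deterministic (by gene index); fold changes and
    padj values are drawn so that every true up/down gene clears both
    cutoffs (|fold| >= 1.6, padj <= 0.049) and every ns gene fails the
    fold cutoff, making truth recovery exact for the default thresholds.
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"{params.gene_prefix}{i + 1:05d}" for i in range(params.n_genes)]
    labels: dict[str, dict[str, str]] = {g: {"A": "ns", "B": "ns"} for g in genes}
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor : cursor + n]
        cursor += n
        return block

    for g in take(params.up_common):
        labels[g] = {"A": "up", "B": "up"}
    for g in take(params.up_a - params.up_common):
        labels[g] = {"A": "up", "B": "ns"}
    for g in take(params.up_b - params.up_common):
        labels[g] = {"A": "ns", "B": "up"}
    for g in take(params.down_common):
        labels[g] = {"A": "down", "B": "down"}
    for g in take(params.down_a - params.down_common):
        labels[g] = {"A": "down", "B": "ns"}
    for g in take(params.down_b - params.down_common):
        labels[g] = {"A": "ns", "B": "down"}

    def build_table(contrast: str) -> list[DERecord]:
        records = []
        lo, hi = params.fold_range
        for g in genes:
            lab = labels[g][contrast]
            if lab == "ns":
                mag = rng.uniform(1.0, params.ns_fold_max)
                sign = 1.0 if rng.integers(2) else -1.0
                records.append(
                    DERecord(g, sign * mag, float(rng.uniform(0, 1)))
                )
            else:
                mag = float(_log_uniform(rng, lo, hi, 1)[0])
                sign = 1.0 if lab == "up" else -1.0
                padj = float(np.exp(rng.uniform(math.log(1e-8), math.log(params.de_padj_max))))
                records.append(DERecord(g, sign * mag, padj))
        return records

    table_a = build_table("A")
    table_b = build_table("B")
    truth = TruthSet(
        de_labels=labels,
        meta={"rng": _RNG_NAME, "seed": params.seed, "generator": "make_de_tables"},
    )
    return table_a, table_b, truth


def de_records_to_tsv(records: list[DERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsigned_fold\tpadj\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.signed_fold:.6g}\t{r.padj:.6g}\n")


# ---------------------------------------------------------------------------
# peptide-intensity tables with a spiked internal standard
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteomicsSimParams:
    """Peptide intensities proportional to true protein amount.

    Each protein carries three quantifiable unique peptides (the exact
    Hi3 complement); multiplicative log-normal noise with the given CV
    is applied per peptide.  The internal standard's peptides are
    emitted at exactly the spike-equivalent intensity.
    """

    seed: int
    n_proteins: int = 100
    peptides_per_protein: int = 3
    noise_cv: float = 0.2
    fmol_range: tuple[float, float] = (1.0, 1000.0)
    standard_id: str = "STD_PHOSB"
    standard_amount: float = 50.0
    response_factor: float = 1e4


def make_peptide_table(
    params: ProteomicsSimParams,
) -> tuple[PeptideTable, TruthSet]:
    rng = np.random.default_rng(params.seed)
    sigma = math.sqrt(math.log(1 + params.noise_cv**2)) if params.noise_cv > 0 else 0.0
    rows = []
    fmol_truth: dict[str, float] = {}
    for i in range(params.n_proteins):
        pid = f"prot_{i + 1:04d}"
        fmol = float(
            _log_uniform(rng, params.fmol_range[0], params.fmol_range[1], 1)[0]
        )
        fmol_truth[pid] = fmol
        for j in range(params.peptides_per_protein):
            noise = math.exp(rng.normal(0.0, sigma)) if sigma else 1.0
            rows.append(
                (pid, f"pep_{i + 1:04d}_{j + 1}", params.response_factor * fmol * noise, True)
            )
    for j in range(3):
        rows.append(
            (
                params.standard_id,
                f"pep_std_{j + 1}",
                params.response_factor * params.standard_amount,
                True,
            )
        )
    df = pd.DataFrame(rows, columns=["protein_id", "peptide_id", "intensity", "unique"])
    table = PeptideTable(
        df=df, standard_id=params.standard_id, standard_amount=params.standard_amount
    )
    truth = TruthSet(
        protein_fmol=fmol_truth,
        meta={"rng": _RNG_NAME, "seed": params.seed, "generator": "make_peptide_table"},
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables under stated amplification efficiencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrSimParams:
    """Ct values back-computed from true expression ratios.

    The reference gene is generated with ratio 1 (constant expression);
    Gaussian cycle noise of the given sigma is added to every Ct.
    """

    seed: int
    true_ratios: tuple[tuple[str, float], ...] = (("RSS12335", 238.82),)
    e_target: float = 2.0
    e_ref: float = 2.0
    ct_noise: float = 0.0
    n_replicates: int = 3
    ref_gene: str = "rnpB"
    base_ct: float = 20.0
    control_condition: str = "control"
    sample_condition: str = "sample"

    def __post_init__(self) -> None:
        for e in (self.e_target, self.e_ref):
            if not 1 < e <= 2:
                raise ValueError(f"efficiency {e} outside (1, 2]")


def make_qpcr(params: QpcrSimParams) -> tuple[pd.DataFrame, TruthSet]:
    rng = np.random.default_rng(params.seed)
    rows = []

    def emit(gene: str, condition: str, clean_ct: float, eff: float) -> None:
        for rep in range(1, params.n_replicates + 1):
            noise = rng.normal(0.0, params.ct_noise) if params.ct_noise > 0 else 0.0
            rows.append((gene, condition, rep, clean_ct + noise, eff))

    emit(params.ref_gene, params.control_condition, params.base_ct - 2.0, params.e_ref)
    emit(params.ref_gene, params.sample_condition, params.base_ct - 2.0, params.e_ref)
    ratios: dict[str, float] = {}
    for gene, ratio in params.true_ratios:
        if ratio <= 0:
            raise ValueError(f"true ratio for {gene} must be positive")
        ratios[gene] = ratio
        sample_ct = params.base_ct - math.log(ratio) / math.log(params.e_target)
        emit(gene, params.control_condition, params.base_ct, params.e_target)
        emit(gene, params.sample_condition, sample_ct, params.e_target)
    df = pd.DataFrame(
        rows, columns=["gene", "condition", "replicate", "ct", "efficiency"]
    )
    truth = TruthSet(
        expression_ratios=ratios,
        meta={"rng": _RNG_NAME, "seed": params.seed, "generator": "make_qpcr"},
    )
    return df, truth


# ---------------------------------------------------------------------------
# synthetic reconstruction of the published cluster geometry
# ---------------------------------------------------------------------------


def synthetic_cluster_reconstruction(seed: int = 0) -> tuple[AnnotatedGenome, TruthSet]:
    """SYNTHETIC stand-in for the WH7803 nitrate-assimilation region.

    The real contig is not bundled; this generator builds a random
    background carrying gene features that reproduce the *published
    geometry* of the cluster — 82 bp between the end of nrtP and the
    start codon of narB, 6,000 bp separating nirA from the nrtP/narB
    pair, a 13,300 bp overall span, and a 135 bp small ORF between nirA
    and nitM — and plants each reported promoter element upstream of
    its gene at its printed distance (treated uniformly as the
    element-end-to-start-codon distance).  Gene order, strandedness and
    intra-gene sequence are synthetic choices, not annotation facts.
    """
    from .scanner import _mismatch_count
    from .sites import REPORTED_SITES

    arch = DEFAULT_ARCHITECTURE
    rng = np.random.default_rng(seed)
    length = 16_000
    seq = _random_sequence(rng, length, 0.60)
    features = [
        GeneFeature("cynS", 872, 1300, "+", gene_name="cynS"),
        GeneFeature("cnaT", 1400, 2400, "+", gene_name="cnaT"),
        GeneFeature("nirA", 3001, 4561, "+", gene_name="nirA"),
        GeneFeature("RSS12335", 4620, 4754, "+", gene_name="RSS12335"),
        GeneFeature("nitM", 4800, 5600, "+", gene_name="nitM"),
        GeneFeature("nrtP", 10562, 11995, "+", gene_name="nrtP"),
        GeneFeature("narB", 12078, 14171, "+", gene_name="narB"),
    ]
    by_tag = {f.locus_tag: f for f in features}
    planted: list[PlantedSite] = []
    for site in REPORTED_SITES:
        feat = by_tag[site.gene]
        if site.minus10 is None:
            element = site.dyad
        else:
            linker_seq = "".join(_random_sequence(rng, site.linker, 0.60))
            element = site.dyad + linker_seq + site.minus10
        elem_end = feat.start - 1 - site.distance
        elem_start = elem_end - len(element) + 1
        if elem_start < 1:
            raise RuntimeError("reconstruction layout error")
        seq[elem_start - 1 : elem_end] = list(element)
        planted.append(
            PlantedSite(
                contig="synthetic_WH7803_cluster",
                start=elem_start,
                end=elem_start + len(site.dyad) - 1,
                strand="+",
                dyad_seq=site.dyad,
                minus10_seq=site.minus10,
                linker=site.linker,
                arm_mm=_mismatch_count(site.dyad[:3], arch.arm5)
                + _mismatch_count(site.dyad[-3:], arch.arm3),
                minus10_mm=0
                if site.minus10 is None
                else _mismatch_count(site.minus10, arch.minus10_consensus),
                target_locus=site.gene,
                distance=site.distance,
            )
        )
    genome = AnnotatedGenome(
        id="synthetic_WH7803_cluster", sequence="".join(seq), features=features
    )
    truth = TruthSet(
        planted_sites=planted,
        meta={
            "rng": _RNG_NAME,
            "seed": seed,
            "generator": "synthetic_cluster_reconstruction",
            "synthetic": True,
        },
    )
    return genome, truth
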