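# Methods

## Promoter-architecture model

The scanner models the NtcA-activated promoter of cyanobacteria as a
two-element architecture on one strand:

```
5'-[arm5]-N{internal_n}-[arm3]---linker---[-10 box]-3'
     GTA      N8           TAC   21-24 bp    TAN3T
```

* The **dyad** (default `GTA-N8-TAC`, 14 bp) is matched with an
  independent mismatch budget per arm (default ≤ 1). The spacer is
  unconstrained. The consensus dyad is its own reverse complement, so
  a perfect site is reported once per strand; overlapping and nested
  hits are all reported, with deterministic ordering (coordinate, then
  strand `+` before `-`, then total mismatches).
* The **−10 box** (default `TAN3T`, 6 bp) is searched 3′ of the dyad at
  every linker length in the configured range (default 21–24 bp, the
  range observed across the reported sites). The best candidate is the
  one with the fewest mismatches over the three constrained positions
  (budget ≤ 1); ties go to the shortest linker. A dyad without a
  qualifying box is a valid NtcA-*binding site* that is not a
  recognizable NtcA-*activated promoter*; setting `minus10_required`
  suppresses such hits.
* `N` in the scanned sequence never counts as a match (conservative).
* Mismatch budgets and linker range are the tightest values consistent
  with every site reported for *Synechococcus* WH7803; all are
  configurable through `MotifArchitecture`.

Deviation descriptors follow the literature's phrasing exactly:
single-arm changes read `TAC changed to AAC`, double-arm changes read
`GTA and TAC changed to GTG and CAC, respectively`, and −10 changes
keep unconstrained positions as `N` (`TAN_3_T changed to TGN_3_T`).
When elements are combined, a part ending in "respectively" takes a
comma before the joining "and", matching how such annotations are
printed.

### Distance conventions

The literature anchors site positions inconsistently ("identified …
bp upstream", "centered … bp upstream", "placed … bp upstream"), so
two distances are exposed rather than guessing a single convention:

* `distance_upstream_end` — bases strictly between the 3′-most base of
  the *reported element* (−10 box when present, else dyad) and the
  first base of the start codon;
* `distance_upstream_center` — position of the dyad center, where the
  base immediately before the start codon is position 1 (a 14-bp dyad
  abutting the start codon is centered at 7.5).

All gene-relative distances reference the **translational** start site:
in this strain's literature "tss" denotes the start codon, not a mapped
transcription start.

### Coordinates

1-based, fully inclusive everywhere internally (GenBank convention);
BED exports are 0-based half-open and say so in their header. Compound
(`join`) GenBank locations are flattened to their bounding interval
with a warning — they are rare in bacterial annotation and irrelevant
to upstream scanning. Intergenic gaps are measured in transcription
order (downstream start − upstream end − 1) and go negative for
overlapping genes, which preserves the arithmetic identities the tests
rely on.

## Differential-expression partition

Classification uses strict inequalities exactly as the emulated study
states them: up iff `signed_fold > 1.5` and `padj < 0.05`; down
symmetric. The canonical effect representation is the signed fold
(+k/−k); `signed_fold_from_log2` converts DESeq2-style log2 fold
changes. Missing `padj` (independent-filtering NA) classifies as ns.
Genes changed in opposite directions across the two contrasts are kept
out of the six Venn cells (which must stay pairwise disjoint) and
reported as `discordant`; per-contrast totals include them, since such
genes are genuinely changed in both contrasts.

## Assay formulas

* **Pfaffl**: `ratio = E_t^(Ct_ctrl − Ct_sample) / E_ref^(Ct_ctrl −
  Ct_sample)`; ΔCt is control − sample so that higher expression in the
  sample gives a ratio above 1. Efficiencies must lie in (1, 2].
* **Hi³**: amount = mean of the top-3 unique-peptide intensities,
  scaled by the same statistic of a spiked standard of known amount
  (default 50 fmol). The mean (not sum) variant is used; ties at rank 3
  resolve by peptide id for determinism. Two unique peptides are the
  floor (warned); one is an error.
* **Total-abundance normalization** scales each sample so per-sample
  totals equal the across-sample mean total — a documented stand-in
  for proprietary "normalize to all proteins" corrections, whose exact
  statistic is not public.
* **Spectrophotometry**: Beer–Lambert throughout. Phycoerythrin uses
  the hexamer coefficient ε₅₄₂ = 2.15×10⁶ M⁻¹cm⁻¹. The 2-oxoglutarate
  assay converts the A₃₄₀ decrease to NADPH oxidized with
  ε = 6,220 M⁻¹cm⁻¹ (standard literature value, configurable) and a
  1:1 NADPH:2-OG stoichiometry; volumes are explicit litres, no
  implicit unit coercion.

## Synthetic generators

Each generator is a pure function of its parameter dataclass; the seed
feeds numpy's PCG64 generator, named in the emitted truth metadata.

* **Genomes** (`make_genome`): i.i.d. background at configurable GC
  (default 0.60, typical of the emulated organism). Genes alternate
  strand, each with ≥ 300 bp of upstream clearance; one site per target
  gene is planted at a recorded distance with the requested number of
  arm/−10 mismatches. An i.i.d. background is adequate for
  recall/false-positive calibration but does not reproduce the
  dinucleotide structure or repeat content of real genomes — planted-
  site recall on these fixtures does not bound false-discovery rates
  on real sequence.
* **DE tables** (`make_de_tables`): label assignment is deterministic;
  defaults encode the emulated study's structure (2,505 genes; 440/422
  changed in contrast A, 420/399 in contrast B, overlaps 395 up and
  371 down). True effects are log-uniform over [1.6, 300] (the span of
  reported fold changes) with padj drawn below 0.049; ns genes get
  |fold| ≤ 1.5 with uniform padj. p-values are generated directly
  rather than via a count model: the fixtures test the partition
  logic, not the DE test itself.
* **Peptide tables** (`make_peptide_table`): three quantifiable unique
  peptides per protein — the exact Hi³ complement, chosen so the
  estimator is exercised without top-k-of-many selection bias, which
  is a known upward-bias mode of Hi³ on larger peptide complements and
  a documented limitation of these fixtures. Intensities are
  proportional to true fmol (log-uniform over [1, 1000]) with
  median-unbiased log-normal noise at the requested CV; the standard's
  peptides are exact.
* **Ct tables** (`make_qpcr`): Ct values are back-computed from true
  ratios under the stated efficiencies (reference gene at ratio 1),
  with optional Gaussian cycle noise; default triplicates are averaged
  before ratio computation.

### Cluster reconstruction

`synthetic_cluster_reconstruction` is a labelled synthetic stand-in
for the WH7803 nitrate-assimilation region: it reproduces the
*published geometry* — the 82 bp nrtP→narB gap, the 6,000 bp
nirA-to-nrtP separation, the 13,300 bp overall span and the 135 bp
small ORF — and plants each reported promoter element at its printed
distance (all distances treated uniformly as element-end distances).
The 6,000 bp separation and 13,300 bp span are end-to-start and
bounding-interval measurements respectively; the publication does not
state its endpoints, so these are this package's conventions, checked
for internal consistency only. Gene order, strandedness and intra-gene
sequence are synthetic choices. Geometry checks on this object verify
the coordinate arithmetic, not the real annotation; verifying against
the real record requires downloading the accession.

## Problem sizes and numerical choices

The default verification workloads are chosen to be desk-scale: the
scanner/oracle equivalence suite uses 1,000 random sequences of up to
500 bp; recall and false-positive calibration use 100 seeded 6-kb
genomes (false positives compared against the closed-form i.i.d.
expectation at mismatch budget 0, within 3 binomial σ); Pfaffl
recovery uses 1,000 simulated experiments at σ = 0.2 cycles (median
estimate within 15% of truth); Hi³ error is pooled over 5 × 100
proteins at CV 0.2 (median relative error < 10%). Consensus ties are
rendered as IUPAC ambiguity codes; all tie-breaks (hit ordering,
linker choice, top-3 selection) are deterministic so that identical
seeds give byte-identical outputs.

## Known limitations

* No position-weight-matrix or thermodynamic scoring — detection is
  budgeted mismatch counting by design, mirroring how the emulated
  analysis defined sites.
* The scanner reports all qualifying windows; no masking or merging of
  overlapping hits.
* Venn-partition totals depend on upstream DE results being
  per-contrast tables with unique gene ids; no attempt is made to
  reconcile conflicting duplicates.
* The assay layer implements quantification formulas only: no standard
  curves, spectral processing, or peptide identification.
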