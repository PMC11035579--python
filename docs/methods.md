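# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `dogtcr` package. Everything quantitative below is
computed by the test suite or the analysis drivers; nothing is asserted
that the code does not itself produce.

## Coordinate and sequence conventions

All coordinates are 0-based, half-open. Sequences are stored 5'→3' in
transcript (mRNA) orientation; the genomic strand of the TRB locus is a
loader concern only. V segments are assumed to be in-frame V-REGION
coding sequence without a leader (IMGT V-REGION convention); J segments
are J-REGION coding sequence whose frame is implied by the located
anchor motif.

## Reference model

Segments carry an IMGT-style functional class (functional / ORF /
pseudogene) and explicit defect records (`in_frame_stop`, `frameshift`,
`noncanonical_RSS`, `nonconserved_motif`). CDR3 anchors are located by
deterministic surrogates for the IMGT positions:

- **V cysteine**: the 3'-most in-frame TGT/TGC within the final 15
  codons; absence is flagged `nonconserved_motif`, not fatal.
- **J motif**: the last [FW]-G-X-G occurrence in any reading frame of
  the J translation; the motif's frame defines the J frame.

The 10x 5' cDNA template is assembled in transcript order as
R1 adapter · 16×N cell barcode · 10×N UMI · 13-nt TSO · V · (D) · J · C,
with component offsets recorded so a primer-design step could target the
C region. The default R1 adapter is the 22-nt Illumina TruSeq read-1
primer site; the TSO value is a placeholder 13-mer, configurable.
C-REGION sequences are accepted pre-spliced; the loader does not splice.

### The synthetic default reference

`dogtcr.refdata` generates a deterministic synthetic reference (seeded,
fixed) whose *structure* — not nucleotide content — mirrors a curated
canine locus: 12 functional V and 10/8 functional J per chain, two TRB D
segments, one C per chain, one ORF J lacking the [FW]GXG motif
(`TRAJ52`), and three defective segments modeled on the documented
canine cases:

- `TRBV19`: in-frame TAG at amino-acid position 104 (FR3); a single
  germline T→C turns it into CAG (Gln).
- `TRAV9-2`: in-frame TGA at position 45 (G→C corrects it to TCA, Ser)
  plus a 1-nt deletion at position 57 that breaks the frame; the
  corrected donor germline differs from the reference by 8 SNVs and one
  frame-restoring single-base insertion — 9 differences in total.
- `TRBJ1-3`: stop codon in the second 5' codon of the J, removable only
  by junctional trimming.

V segments are 108 codons with the Cys at codon 105 of 108 (9-nt 3'
tail, so the default maximum trim of 8 nt can never destroy the anchor);
J segments are 17 codons with the motif at codon 9. These geometries are
design choices that keep anchor survival deterministic at the default
trimming model; real loci vary more.

## Repertoire simulator

The generator emulates the data-generating process at contig level:

- **Clonality profiles.** `polyclonal`: uniform masses over `n_clones`
  (default: one per cell, so most observed clones are singletons).
  `oligoclonal`: expanded clones at fractions (0.10, 0.05, 0.03) —
  the treated-melanoma regime, whose reported top clonotypes average
  ~9% — over a polyclonal background. `monoclonal`: one clone at 0.88 —
  the T-zone-lymphoma regime. The background can optionally decay as a
  power law (`background_decay`), reflecting the decaying clone-size
  spectra of real repertoires; the default is uniform.
- **Rearrangement.** Segment choice is weighted (default: uniform over
  functional segments only); trimming per end is truncated-geometric
  (p = 0.25, max 8 nt) and nontemplated insertions are
  truncated-geometric in length (p = 0.25, max 12 nt) with uniform ACGT
  composition; TRB inserts a doubly-trimmed D between two insertion
  tracts. No generative model for these is published for dog; the values
  are declared assumptions that produce CDR3 lengths spanning roughly
  5–24 aa, and they are exposed in the configuration.
- **Truth.** Every contig records its components, CDR3 and productivity
  computed by positional bookkeeping (not by the annotator); tests hold
  this truth against an independent translate-and-scan oracle.
- **Clone founders** are resampled until both chains are productive, so
  all cells of a clone share identical productive CDR3 sets before
  pairing noise; non-productive rearrangements are exercised through
  direct `simulate_rearrangement` draws, which do not enforce
  productivity.
- **Pairing noise.** Per cell i.i.d. over
  {single_pair, tra_only, trb_only, extra_tra, extra_trb, extra_both};
  the default preset is the v2-protocol taxonomy
  (.698/.025/.157/.066/.033/.021), with the v1 preset
  (.309/.202/.409/.023/.054/.003) and a clean preset also provided.
  "Extra" chains re-draw the junction on the founder's segments and are
  resampled until productive, emulating a second rearranged allele.
- **UMIs** per chain are 1 + Poisson draws with medians near the
  reported per-chain UMI medians (TRA ≈ 7, TRB ≈ 13); bookkeeping only.
- **Barcodes** are sequential distinct 16-mers (barcode correction is
  out of scope). An optional per-base substitution `error_rate` degrades
  emitted contigs after truth is recorded; the default is 0.
- Determinism: (config, seed) fully determines every output byte.

### Germline and rescue planting

Three mechanisms can be planted: (a) a stop-correcting germline SNV in
selected donors only (auto-derived from the defect record); (b) an
explicit multi-edit donor consensus (SNVs + frame-restoring insertion);
(c) junctional correction, implemented as a minimum J trim that removes
a junction-proximal stop (requested for a defect outside the 12-nt
junction window → error). Donors without a corrective variant simply
never produce productive rearrangements of the segment, so its usage is
carrier-restricted without any special-casing.

## Contig annotator

Candidates are short-listed per contig by infix edit distance (edlib)
and rescored with local Smith–Waterman (match +2, mismatch −2, gap open
−4, gap extend −1; score floor 40; biopython's PairwiseAligner). Ties
break by higher identity then lexicographically smaller key, and are
flagged. The chain is inferred from the best V; a V/J chain conflict
flags the contig and excludes it from clonotyping. D segments are not
assigned. Anchors are mapped through the alignment onto the contig;
for V references whose own frame is broken (an annotated frameshift, or
no usable Cys anchor), the cysteine is instead located on the contig in
the contig's V frame — the fallback production annotators use, and the
reason corrected TRAV9-2-like transcripts still receive CDR3s when
annotated against the *universal* (defective) reference. Productivity
re-derives the definitional rule from the alignment; on error-free
simulated data the annotator reproduces the generative truth exactly
(tested at 2,000 cells), and agreement degrades monotonically as
substitution errors are added.

## Clonotype analytics

- Diversity is computed over all clonotyped cells by default
  (paired and unpaired clonotypes); `paired_only` restricts the
  frequency vector, since the corresponding summary metric is
  conventionally named *paired* clonotype diversity and its exact
  denominator is ambiguous. Both modes are provided.
- Rank bins are {1}, {2–5}, {6–10}, {11–100}, {101–1000}, {>1000}; only
  the first two boundaries are conventional, the rest are declared
  choices. Ranking ties break deterministically.
- `pairing_summary` weights each clonotype once by default; a
  `by="cell"` mode weights by member cells. The cell-level mode is the
  one that recovers an i.i.d. per-cell pairing process exactly —
  clonotype-level fractions are biased whenever two same-category cells
  collapse into one clonotype.
- Downsampling draws `n_target` cells with replacement (defaults
  n_perm = 100, n_target = 1,850, the smallest-sample convention) and
  averages bin fractions and diversity across permutations.
  **Limitation:** rank-binned fractions are only downsampling-stable
  when repertoire mass sits in clonotypes that remain well represented
  at `n_target`. For flat polyclonal repertoires dominated by
  singletons, tail-bin mass is a function of sample size and *no*
  estimator makes the binned fractions concordant; the concordance test
  therefore uses a clonally dominated (lymphoma-like) sample, where
  agreement is within 0.005 absolute. Inverse Simpson itself is far less
  size-sensitive in the clonal regimes where it is interpreted.
- The usage matrix counts unique barcodes per segment and V×J
  combination; a cell may count toward several segments. The coverage
  census reports observed/known per chain × class × functional class.

## Pseudogene rescue

Per clonotype using a defective segment, the (majority) consensus is
aligned glocally to the segment (unit-cost edit alignment, edlib);
differences are enumerated in segment coordinates with indels
left-normalized. A difference is a **donor (germline) variant** if
present in ≥ 90% of that donor's clonotypes using the segment (≥ 2
clonotypes) and outside the junction window (V 3'-terminal 12 nt / J
5'-terminal 12 nt; configurable). A defect is **corrected** when ≥ 90%
of examined clonotypes lack it in the observed sequence (stop codon
altered or removed; frame restored by a net non-3-multiple indel balance
outside the junction window), else **retained**; segments without
covering clonotypes are **not_covered**. The mechanism is
`germline_shared` when every correcting difference is donor-shared in
every donor with usage, `junctional` when correcting differences are
junction-window-confined and vary between clonotypes, else `unresolved`.
Re-annotation policy: *functional* when all defects are corrected in
≥ 2 donors and usage reaches ≥ 100 productive cells or ≥ 50 clonotypes;
a *donor-specific note* when corrected in exactly one donor (more
individuals needed); otherwise no change. The 90% thresholds, window
width and usage floors are declared policy, chosen to tolerate rare
noise while keeping the three planted mechanisms cleanly separable; the
tests recover all three (and the carrier restriction) in 20/20 seeds.

With the default zero-error simulator, clonotype members are identical
and the consensus step is trivial; under sequencing error it degrades to
a majority vote over identical-length members, which is not a full MSA.

## Expansion phenotype

Cells are *expanded* when their clonotype exceeds 1% of all cells
(strict inequality, over the whole sample; a per-cell-type restriction
is applied after labeling). Markers: activation {CD38, GZMA, GZMK,
MKI67}, exhaustion {CTLA4, HAVCR2, NFATC1, NR4A1, NR4A2, NR4A3, PDCD1,
PRDM1, TCF7, TIGIT, TOX, TOX2} (the default 16-gene test panel), plus
effector-memory {CCL5, ZEB2, GZMK} and naive {LEF1, TCF7, CCR7} panels
for labeling. Tests are two-sided Wilcoxon rank-sum on log_e(x+1)
normalized values (per-gene z-scaling is display-only and not applied
before testing; whether to test scaled values is genuinely open, so it
is configurable by passing a scaled table). The Bonferroni factor is the
number of markers actually tested in the run; missing markers are
reported, not counted. The synthetic expression generator draws
N(μ_g, 1) log-scale values with μ_g ~ U(0.5, 2), clipped at 0, and adds
planted shifts to the expanded group — it models none of the count
overdispersion, sparsity or cell-type structure of real scRNA data, so
passing tests demonstrate calibration and power of the testing machinery,
not robustness to real-data pathologies. Under label permutation the
family-wise error stays within Monte-Carlo range of the 5% bound; a
+1.0 log-shift at 500 vs 500 cells is detected with adjusted p ≪ 0.05.

## Problem sizes

The default test run simulates up to 10,000 cells for pairing recovery,
2,000 cells for exact annotator recovery, 100 seeded runs of the
three-profile clonality spectrum (5,000–8,000 cells each), a 6,000-cell
downsampling comparison, 20 seeded five-donor rescue studies (60 cells
per donor), and 200 permutation nulls for the phenotype calibration.
These sizes were chosen so each check is statistically decisive (3σ
binomial margins; coupon-collector coverage) at desk scale.

## Known limitations

- The reference is synthetic: segment content, divergence between
  segments and defect positions are modeled, not copied from IMGT, so
  segment-confusability is easier than in real data where related V
  families can be near-identical.
- No read-level model: FASTQ emission, UMI collapsing, assembly,
  barcode correction and primer artifacts are out of scope; contigs are
  emitted directly.
- D segments are simulated but never called by the annotator.
- Germline inference is a shared-fraction surrogate, not a
  reconstruction of any production tool's donor-reference logic.
- Clonotype merging across samples and germline-aware cross-individual
  repertoire comparison are out of scope.
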