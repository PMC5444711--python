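# Methods

`pignstab` implements the computational chain of an expression-aberration /
genomic-instability analysis in MDS and AML with myelodysplasia-related
changes (AML-MRC): instability-panel scoring of expression cohorts,
splice-junction-based partial intron-retention detection with
protein-truncation prediction, GPI-anchor-protein (GPI-AP) deficiency
frequency estimation from selective colony assays, paired variant-profile
comparison, and expression/protein aberration classification. A synthetic
data module generates inputs with the statistical structure each stage
assumes, so the whole pipeline runs and is tested without downloads.

## Instability-panel scoring (`pignstab.panels`)

**Model.** A cohort is a log2-scale gene-by-sample matrix with per-sample
MDS subtype labels (Control, RA, RARS, RAEB1, RAEB2). Risk stratification
is binary and a pure function of subtype — {Control, RA, RARS} are low
risk, {RAEB1, RAEB2} high risk — with a `subtype` 5-class option.

**Panel score.** For a gene panel (the packaged CIN70 chromosomal
instability signature, or the GPI-anchor biosynthesis panel), rows are
z-scored (population convention, divisor *n*; zero-variance rows dropped
with a warning) and the per-sample score is the first principal component
of the panel submatrix with samples as observations. PC1's sign is
ambiguous in any PCA; it is fixed so the scores correlate non-negatively
with the per-sample mean panel z-score, making the sign of the reported
cross-panel correlation reproducible. Cross-panel association is the
Pearson correlation of the two score vectors, with a two-sided p-value
from the t distribution on *n* − 2 degrees of freedom.

**Panel membership.** The packaged CIN70 list (70 symbols) is a curated
reconstruction of the published chromosomal-instability signature with
symbols updated to current HGNC nomenclature; the historical list's tail
contains anonymous clone identifiers, so a handful of slots are filled
with canonical mitotic/CIN signature genes. The GPI panel (25 symbols) is
likewise a reconstruction: the PIG-family biosynthesis genes plus GPAA1
and the PGAP remodeling genes. Both are plain text files and can be
replaced via `--panel`.

**Permutation importance.** Gene importance for risk prediction is the
classical random-forest mean decrease in accuracy (MDA): a forest of
decision trees (bootstrap sampling with replacement, `sqrt(p)` features
per split, unlimited depth, 500 trees by default) is grown on the panel
submatrix; for each tree, out-of-bag accuracy is compared with accuracy
after permuting one gene's out-of-bag values, and the per-tree
differences are averaged (unscaled). The trees are scikit-learn
`DecisionTreeClassifier`s; the bootstrap and the OOB permutation
importance are implemented here because scikit-learn's forest API does
not expose per-tree OOB permutation. Rank 1 is the largest MDA; ties
break by panel gene order. All randomness derives from one integer seed.

**Heat map.** The display matrix groups columns by subtype in risk order
(stable within subtype) and orders rows by average-linkage hierarchical
clustering on 1 − Pearson-correlation distance.

## Partial intron-retention detection (`pignstab.retention`)

**Evidence model.** A partial intron retention leaves a splice junction
with one endpoint at an annotated exon boundary and the other strictly
inside the adjacent intron; the transcript keeps the intron fragment
between that internal endpoint and the retained splice site. Junctions
are classified against a gene model as `annotated`,
`partial_retention_5prime` / `_3prime` (defined in transcription
orientation; minus-strand genes are mirrored), `exon_skip`, `intronic`,
or `other`. `intronic` junctions (both ends inside one intron) are
reported but never turned into retention events, since a
doubly-internal junction does not abut an exon boundary.

**Coordinates.** Internally, all positions are 1-based inclusive genomic
coordinates; a junction is stored by its flanking exonic bases
(donor = last exonic base upstream, acceptor = first exonic base
downstream, donor < acceptor). Dialect conversion is centralized in the
reader: STAR `SJ.out.tab` gives first/last intronic bases (donor = first
− 1, acceptor = last + 1); BED12 blocks are 0-based half-open.

**Calling.** Junctions classified as partial retentions become events if
they carry at least `min_reads` unique reads (default 2) and their
fragment length lies in `[min_len, max_len]` (defaults 1 and intron
length − 1). Identical events are merged with summed read support. The
detection thresholds are exposed because the evidence-based caller is a
reconstruction: the original events were established by cloning and
sequencing, with junction files inspected for corroboration.

**Consequence prediction.** The aberrant transcript is the spliced exon
sequence with the retained fragment inserted at its exon/intron boundary
(minus-strand genes reverse-complemented; a coordinate map records each
transcript base's genomic origin). Translation runs from the annotated
start codon to the first stop. A retention of length *N* shifts the
reading frame iff *N* mod 3 ≠ 0; an in-frame retention with no internal
stop extends the protein by *N*/3 residues. A stop is premature (PTC)
when the resulting protein is shorter than the reference protein plus
any in-frame insertion. NMD sensitivity uses the 50-nt rule — a PTC more
than 50 nt upstream of the last exon-exon junction marks the transcript
as a likely nonsense-mediated-decay substrate; the flag is advisory, as
the rule is a heuristic. Protein masses are average (not monoisotopic)
residue masses plus one water, via Biopython, reported in kDa —
appropriate for comparison against gel-estimated sizes.

## GPI-AP deficiency frequency (`pignstab.gpi`)

In a proaerolysin-selection colony-forming-cell (CFC) assay, only
GPI-AP-deficient clones form colonies under selection. The per-replicate
deficiency frequency is the ratio of plating efficiencies,

    f = (colonies_selective / cells_plated_selective)
        / (colonies_control / cells_plated_control),

the standard mutant-frequency estimator for selective clonogenic assays;
the exact historical calculation is described only in a cited reference,
so the estimator is a single swappable function. Values above 1 (possible
under sampling noise at high frequencies) are clipped to 1 with a
warning; zero control colonies are an error (plating efficiency
undefined). Replicates are summarized as median plus min-max range, and
populations are compared as ratios of medians (`fold_over`), optionally
against the normal-population background frequency of 0.002%
(a named constant, configurable).

## Paired variant-profile comparison (`pignstab.variants`)

Two Sanger-derived variant lists from paired cell populations (e.g.
leukemic vs non-leukemic cells of one patient, TP53 exons 2-11) are
compared by: (i) global sequence identity — pairwise global alignment
with match +1, mismatch 0, linear gap −1, identity = matches over
alignment columns with gaps counting as mismatches (the alignment scheme
is a package choice; the source analysis reports a single identity
percentage without one); (ii) mutation rate per kbp = 1000 × n / L over
the sequenced region length; (iii) the conserved-alteration intersection,
matching on exact (position, ref, alt) with no fuzzy indel matching;
(iv) coding-consequence classification by mutate-and-translate on the CDS
(substitutions → synonymous / non-synonymous with `p.<ref><codon><alt>`
notation, single-base deletions → frameshift `p.<ref><codon>fs`, codon
number = ceil(CDS position / 3)); and (v) a pooled-variance two-sample
t-test on per-amplicon rates, with an explicit error on degenerate
zero-variance input. SIFT impact annotations are carried through as
data, never computed. The three conserved TP53 alterations ship as a
packaged CSV fixture.

## Aberration classification (`pignstab.aberration`)

Relative expression is the delta-delta-Ct method at 100% efficiency:
fold = 2^−ΔΔCt. A patient shows the *aberrant expression pattern* when
transcript output is elevated but protein is absent. The default
operational rule keys on protein absence and records the fold-vs-
threshold status in the call's `basis`: in the packaged 48-patient
cohort, the 15/35 headline count equals the protein-absent count, yet
one protein-absent patient has fold 0.398 — the verbal definition and
the printed count disagree at the margin. A `--strict` mode requires
fold ≥ threshold (default 2.0) as well, yielding 14/35 on the packaged
table. Patients lacking protein status or fold are `indeterminate`.
Cohort summaries count total, protein-determined, aberrant,
protein-absent, complex-karyotype, and TP53-deleted patients.

## Synthetic data (`pignstab.simulate`)

**Expression cohorts.** Each sample carries a latent instability factor
z = shift(subtype) + N(0, 1). A panel gene's expression is
μ_i + sign(panel) · λ_i · z + N(0, σ), with baseline μ_i ~ N(8, 1)
(log2 scale), loading λ_i ~ U(0.5, 1), and a per-panel sign; background
genes are baseline plus noise. A single shared latent factor with
opposite panel signs is the simplest structure that reproduces both a
subtype-dependent instability heat map and a negative cross-panel PC1
correlation. The generator does not emulate probe-level effects,
normalization artifacts, batch structure, or gene-gene correlation
beyond the single factor, so passing tests demonstrate estimator
correctness under the stated model, not robustness to microarray
technical structure.

**Calibrated preset.** The packaged preset emulates the reference cohort
design: group sizes 11/18/19/9/9 (n = 66), latent shifts (0, 0.8, 0.8,
3.0, 3.0) rising with risk, CIN70 with sign +1 and the GPI panel with
sign −1. The noise level was fixed by a pre-build sweep (200 replicates
per candidate) so the mean cross-panel PC1 Pearson r at n = 66 is ≈
−0.41, the calibration target; the frozen value is σ = 5.75. Under this
calibration each gene's marginal signal is weak by construction, so the
MDA *ranking* of near-tied loadings (U(0.5, 1) order statistics differ
by a few percent) is unstable across replicates; what is recoverable —
and what the tests assert — is the positive association between a gene's
generating loading and its importance, pooled across replicates. A
stable top-3 placement of a single designated gene, as observed in real
data, is not reproducible under this generating model and is checked in
the optional real-accession script instead.

**Toy genes.** Exon/intron structures are generated with canonical GT..AG
dinucleotides at every splice site (transcription orientation), a CDS
starting ATG at a configurable offset in the first exon and ending at a
generated in-frame TAA in the last exon, with no internal stops. Intron
interiors are drawn from {C, G} so that any retained fragment is free of
in-frame stop codons: retention consequences are then governed by frame
arithmetic, which is what the round-trip tests exercise; frameshift PTCs
still arise naturally downstream in the shifted exon frame. Minus-strand
genes are built in transcript space and mirrored onto the forward
strand.

**Junctions, colonies, variants.** Junction files contain one annotated
junction per intron plus one novel junction per requested retention, the
internal endpoint placed fragment-length nt inside the intron. CFC
counts are binomial per replicate: selective colonies ~
Binomial(cells, f × e) and control colonies ~ Binomial(cells, e), with
plating efficiency e; medians and ranges are the only published
summaries, so no overdispersion is modeled. Paired variant profiles are
shared ∪ private unions, with the packaged conserved alterations as the
default shared set; the default private counts (23 and 26 over 2,300 bp)
put the total per-kbp rates at the scale reported for the sequenced
region (the underlying real counts are unpublished, so the printed rates
are not exactly recomputable).

## Numerical choices and degenerate inputs

- PC1 via SVD of the centered sample-by-gene matrix; explained-variance
  fraction from squared singular values.
- Importance ties break deterministically by panel gene order; identical
  seeds give bit-identical rankings.
- Frequencies above 1 clip with a warning; zero control colonies,
  zero-length regions, empty sequences, and zero pooled variance with
  unequal means raise errors naming the problem.
- Junction files are validated line-by-line; malformed lines report
  their line number.
- All generators take one explicit integer seed; no global RNG state.

## Problem sizes in the tests and acceptance script

The statistical checks use 200 cohort replicates (n = 66) for the
cross-panel correlation, 1000 binomial replicates for the CFC estimator,
retention round-trips over all fragment lengths 1-200 (tests) and 11-142
(acceptance script), 100 random matrices for the PC1 oracle, and 20
forest seeds for the separability oracle — sizes chosen so each check's
Monte-Carlo error is well inside its tolerance while the whole suite
runs in well under a minute of compute per check.

## Known limitations

- Panel membership files are reconstructions (see above); analyses of
  real cohorts should substitute a vetted list where available.
- The retention caller requires junction evidence; retentions visible
  only in exon-spanning coverage (no novel junction) are out of scope,
  as are PSI quantification and splice-site strength models.
- The NMD flag is the 50-nt heuristic, not a degradation model.
- Identity percentages depend mildly on the alignment scoring scheme;
  the packaged scheme is documented above and fixed.
- The aberration rule's strict/default duality reflects a genuine
  definitional tension in the underlying cohort table; both counts are
  computed rather than adjudicated.
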