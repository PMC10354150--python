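# Methods

This note documents the models, numerical choices and limitations behind
`deamscan`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement problem

A deaminase expressed in a bacterial host edits the genome at rates far
below the raw sequencing error rate, so its genome-wide target preference
cannot be read from ordinary alignments. Rolling-circle consensus
sequencing solves this: genomic fragments of 90–120 bp are circularised and
amplified into tandem concatemers, so one read carries 2–4 independent
observations of every fragment position, and intra-read voting suppresses
sequencing error quadratically (or better) in the per-base error rate. The
package reimplements that consensus analysis plus the three satellite
analyses such an experiment rests on — motif/context spectra, in-vitro deamination
kinetics, and resistance-assay statistics.

## Synthetic data as the experimental conditions

`syndata` generates every pipeline input with ground truth. The defaults
encode the experimental conditions this kind of assay runs under;
quantities that such protocols leave open are package choices, fixed once
and documented here.

* **Reference**: i.i.d. bases at a configurable GC fraction (default 0.5,
  close to the ~0.508 of an E. coli genome), circular by choice of the
  caller. Length is an experiment parameter; the genome-scale experiments
  use 100 kb rather than 4.6 Mb so that desk-scale runs keep the same
  per-site statistics at ~1/46 of the cost.
* **Mutation model**: per-type per-site probabilities with triplet-context
  multipliers, keyed by the collapsed (focal-C/A) context representation.
  Matching a G/T site through the reverse complement of its top-strand
  triplet enforces strand symmetry *by construction*: a minus-strand TCG
  hit appears as G→A inside top-strand 5'CGA3'. The editing-motif model
  (`MutationModel.motif_model`) confines C→T to TCG and A→G to GAA.
* **Reads**: one fragment (uniform length 90–120 bp, uniform start,
  wrapping on circular genomes), a uniform random phase, tandem-tiled to
  the read length (default 300 bp — a merged pair of 150 bp mates with a
  ~300 bp insert, giving ~3 copies per fragment). Errors are i.i.d.
  substitutions (no indels, PCR duplicates or GC bias — the downstream
  tally counts substitutions only). Base qualities follow a two-state model
  (Q30 / Q10 with default 2% low-quality bases) so the Q<20 masking rule
  has work to do; qualities are assigned independently of the error
  process, i.e. they carry no extra information about which bases are
  wrong.
* **Sequencing depth** is not a property of the protocol and is therefore
  an explicit experiment parameter everywhere; the recovery experiments size
  the read number so the expected count of observed edited sites reaches a
  stated target (≥500 for the headline recovery run).
* **Molecules** stand in for genome copies in a culture and mutate
  independently; there is no lineage (jackpot) structure in the consensus
  arm. Jackpot-like dispersion enters only through the Poisson fluctuation
  simulator, which itself ignores late-mutation clustering — it draws
  resistant counts as Poisson(frequency × viable cells), which is what the
  frequency estimator (not a Luria–Delbrück rate estimator) assumes.

Passing tests on these data show the *computational* pipeline recovers
what was injected; they cannot show robustness to real-data features that
are deliberately not modelled (indels, coverage bias, chimeric reads,
contamination).

## Consensus calling

Reads with mean Phred < 20 are dropped; individual bases below Q20 are
masked but keep the read (fastp-style cleaning specifies only a Q20
threshold, not which of the two behaviours; both knobs are exposed in
`QCParams`). The repeat period is the self-offset
p ∈ [90, 120] minimising the read-vs-shifted-read mismatch fraction over
unmasked pairs, accepted when that fraction ≤ 0.1 with ≥ 25 comparable
bases; ties go to the smaller period; otherwise the read abstains. Voting
is per template position (read positions mod p): plurality wins, count
ties are broken by summed Phred, remaining ties and positions with fewer
than `min_copies` (default 2) unmasked observations are called N.
Partial trailing copies vote — with 300 bp reads over 90–120 bp fragments
they are the norm, so `min_copies` applies per position, not per read.
The consensus never sees the reference. The consensus "quality" string
encodes the support count capped at Q40; downstream code uses counts, not
Phred semantics.

## Placement of circular consensi

Folding returns the fragment *rotated by the read's phase*, so a consensus
is a cyclic string, not a genome substring. Placement therefore: (i) seeds
with exact 21-mers of the doubled consensus on both strands against a
k-mer index of the reference; (ii) for each seeded diagonal scores all 2p
rotation windows of the tripled consensus by mismatch count (ungapped, Ns
excluded; any p consecutive positions of the tripled cyclic string cover
each template position exactly once); (iii) accepts the unique minimum-
mismatch window if its mismatches are ≤ 5% of comparable bases.

Two boundary subtleties are handled explicitly:

* **Slide degeneracy.** When the reference base just 5' of a fragment
  equals the fragment's last base, the cyclic consensus matches two (or
  more) windows offset by one; the data genuinely cannot decide where the
  fragment boundary lies. Equal-score windows on one strand within a
  period of each other are merged: the placement is anchored at the
  smallest start and the boundary positions not shared by every member are
  excluded from observation. This choice makes the pipeline exactly
  equivariant under reverse complementation of reference plus reads (the
  shared core is mirror-invariant), which the test suite checks for exact
  equality of spectrum and context tables. Equal-score windows elsewhere
  abstain as ambiguous.
* **N-dense consensi.** min_copies=3 plus quality masking can scatter Ns
  densely enough that no clean 21-mer seed exists; such consensi abstain
  (`no_placement`) and are counted in the run report, never silently
  dropped.

The vectorised batch path (`place_batch`) resolves the typical case with
three disjoint seed offsets (at most one can straddle the rotation
boundary) and falls back to the exhaustive single-read function for rows
with N-broken seeds, multi-hit k-mers, or wide tie sets; tests assert the
two paths produce identical tallies.

## Tally and spectrum

Coverage uses interval difference-arrays; base counts start as
coverage × reference one-hot and are corrected sparsely at mismatch and
excluded positions, which is exactly equivalent to naive per-base
accumulation (tested) at a fraction of the cost. At every site the base
counts sum to the coverage; N and excluded-boundary observations are
removed from both numerator and denominator.

Spectrum frequencies are per coverage-weighted *site-observation* (the
usual wording, "sites analysed", does not distinguish per-site from
per-site-observation; the denominator is the latter here and the output
says so). Context tables cover the two transition
types; the default denominator is the total
C+G (or A+T) site-observation count, identical across the 16 rows, with
`per-context` denominators available as an option. Edge sites of a linear
reference lack a flank and are excluded from context tables only; on a
circular reference (no edges) the 16 context numerators partition the type
numerator exactly, and the tests check the partition there. Group
comparisons use one-way ANOVA with Tukey's HSD exactly (no extra FDR
layer), plus a seeded label-permutation p-value (≥10⁴ shuffles) as an
internal cross-check; the degenerate zero-within-variance case is resolved
deterministically (p = 1 if groups are identical, 0 otherwise) rather than
returning NaN.

## Kinetics

Fraction deaminated is cleaved / (cleaved + uncleaved) band intensity.
Each replicate time course is fit by bounded nonlinear least squares to
F(t) = P·(1 − e^(−kt)) with k ≥ 0 and P ∈ (0, 1]; the initial k comes from
the slope of the two earliest nonzero points divided by the plateau guess
(max observed fraction), and solver tolerances are tightened to 1e-13 so a
noiseless round trip recovers k to ~1e-6 relative. The plateau is fitted
by default because a bare "single exponential" specification does not fix
it; `fix_plateau` forces it (and the choice is recorded in the output).
Fitting substrate decay e^(−kt) instead of rise to plateau would give the
identical k_app, so nothing hinges on that choice.
k_app is the mean over replicate fits and its SEM is across replicates
(the convention for independent bench replicates), not the
covariance-matrix SE of a pooled fit; an all-zero course short-circuits to
k = 0 with a `no_signal` flag. Fold ratios expose both rounding modes
because such ratios are conventionally quoted both as integer folds
("sixfold") and one-decimal folds ("5.3-fold").

Substrate annotation uses a single-hairpin model: exhaustive search over
all registers for the longest contiguous Watson–Crick stem closing a loop
of ≥3 bases (no wobble pairs, no multiloops — all in-scope substrates are
designed single hairpins or linear oligos). Ties prefer the longer stem,
then the outermost register. A sequence is `hairpin` when the stem-loop
span covers at least half the oligo, `mixed` when a stem exists but most of
the sequence is outside it (the hairpin-plus-linear designs), else
`linear`. The default target base is the caller's index, else the unique
single-occurrence base (the linear designs), else the third loop base (the
hairpin designs). Cleavage read-outs: EndoV cuts the second phosphodiester
bond 3' of deoxyinosine (5' fragment = target + 1 nt); UDG + NaOH breaks
the strand at the abasic site (5' fragment = target − 1 nt); the two
always differ by 2 nt, and fragments that would be empty or full-length
raise an edge-case error.

## Assay statistics

Per-culture frequency = resistant colonies / (viable cells × dilution
factor); groups are summarised by the median. The two-tailed Wilcoxon
rank-sum comparison uses exact enumeration when both groups have ≤ 10
cultures and the normal approximation with mid-rank tie correction
otherwise; the tests check the exact branch against brute-force
enumeration of all assignments for group sizes ≤ 8. Clone classification
requires gap-free equal-length alignment, returns None for identical
sequences, and treats multiple substitutions as an error under the default
strict mode (selection designs expect exactly one hit per clone). Codon
labels use the wild-type residue letter, residue_offset + codon index, and
the lowercase wild-type codon, reproducing the "S512 (tct)" style on toy
genes. Structure classes (loop/stem/linear) are inputs, not predictions —
the original annotations came from an external folding server, and folding
gene-scale DNA is out of scope.

## Experiment sizes

The full-scale experiments (`deamscan.experiments`) use: 100 kb genome,
2000 molecules, TCG C→T at 1e-4 per site per molecule, and a read count
sized for ≥550 expected observed events (~1.7 M reads) for spectrum
recovery; 20 kb and 100 k reads at 1% error for the false-positive floor;
1100 fixed-100 bp-fragment reads (≥10⁵ consensus bases) per error rate for
the majority-vote bound; 5 kb and 800 reads for the exact
reverse-complement invariance check; 200 replicates per rate constant for
kinetics recovery. These sizes keep each experiment's Monte-Carlo error
several-fold below the tolerance it is checked against.

## Known limitations

* Substitution-only error and mutation model; no indel-tolerant period
  detection or placement.
* Paired-end mates are folded as independent reads (no mate co-folding).
* Placement abstains on N-dense consensi rather than using spaced or
  shorter seeds; abstentions are reported.
* The slide-degeneracy exclusion discards a fraction of a base per read on
  average; numerator and denominator are affected symmetrically.
* No mutational-signature decomposition, no real-genome annotation, no
  Luria–Delbrück rate estimation (the frequency estimator is deliberate).
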