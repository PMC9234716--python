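# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Sequence curation

Length filtering operates on gap-stripped residue counts with *inclusive*
bounds (300 and 1000 survive): the filter is described in the field as
removing sequences "larger than" / "shorter than" the bounds, so the
bounds themselves pass. Redundancy collapse is a greedy sweep in input
order: a sequence is dropped iff its alignment identity to an
already-kept sequence strictly exceeds 0.90 (">90%" is strict; a pair at
exactly 0.90 survives). Identity counts matches over columns where
neither sequence is gapped. The greedy rule is order-dependent in *which*
representative it keeps, but the guarantee that no kept pair exceeds the
threshold is order-independent, and the operation is idempotent. Manual
curation steps with no stated criterion — "obviously incomplete"
sequences, poor-aligning segments — are deliberately not guessed at; an
optional column-occupancy mask (`mask_high_gap_columns`, drop columns
with > 50% gaps) is provided as a clearly-labeled approximation and is
not part of the default path.

## Clade-contrast scan

The screen's informal criterion — conserved in the foreground clade,
either completely or in physicochemical character, but divergent in the
background — is operationalized with two thresholds and a fixed six-class
residue scheme:

| class | residues |
|---|---|
| aliphatic | A V L I M C |
| aromatic | F W Y |
| positive | K R H |
| negative | D E |
| polar | S T N Q |
| special | G P |

Histidine is grouped as positive, cysteine as aliphatic, and G/P are
isolated because their backbone behaviour matches no side-chain group.
This scheme is the single source of truth for both the generator and the
scan, so "class-conserved" means the same thing when planting and when
detecting.

Defaults: foreground conservation ≥ 0.90, background match ≤ 0.20,
foreground gap fraction ≤ 0.50, mode `either` (a column passes if the
full identity criterion *or* the full class criterion accepts). The
source screen reports no numeric thresholds, so these are the package's
operating point; every one is exposed in `ScanConfig`, and the generator
exposes `within_class_noise` precisely so users can stress-test the
thresholds rather than trusting one operating point. Consequences of the
definitions: gaps are excluded from conservation numerators and
denominators; an all-gap column for a clade is an error, distinct from a
score of zero; the ambiguity code X counts toward denominators but can
never be a consensus or match anything; a column whose background is
entirely gapped cannot demonstrate divergence and is skipped; a passing
column at which the reference is gapped is dropped with a logged warning
rather than silently renumbered. Candidate positions use the ungapped
numbering of the reference sequence counted from its initiator
methionine.

Mutation proposal: the target is the modal background residue when it
reaches frequency ≥ 0.5 among ungapped background residues ("the
equivalent residue of channels outside the clade"), otherwise alanine;
if the nominal target equals the reference residue the proposal also
falls back to alanine. When the reference residue is itself alanine and
the background is heterogeneous, the rule degenerates to an identity
"mutation" (e.g. A109A); the rule is left as stated rather than inventing
a secondary target.

Vicinal grouping is single linkage at ≤ 2 residues with runs split
greedily left-to-right into groups of at most three, matching the
practice of mutating up to three neighbouring candidates together.

## Structure mapping

A candidate is interfacial if the minimum distance from its atoms to any
atom of a different chain is within the cutoff. The default mode is Cα
with an 8 Å cutoff; a heavy-atom mode with a 5 Å contact cutoff is
available. Cα is the default because the intended inputs are homology
models built at low template identity, where side-chain placement is
unreliable but backbone positions are comparatively robust. All other
chains count as potential partners (under C3 symmetry the two neighbours
are equivalent); the closest is reported. No numeric definition of
"lining" a pocket exists in the source literature, so the cutoff is a
documented default, not a claim. Pockets are single-linkage clusters of
interfacial residues under pairwise Cα distance ≤ 12 Å; chain copies of
the same residue merge into one residue-number set, and each pocket
reports its linkage diameter. Distances use a k-d tree; a brute-force
all-pairs implementation is kept as the test oracle. PDB input reads the
first model only, takes altloc 'A'/blank, and rejects insertion codes
with a clear message. Flags are monotone in the cutoff and invariant
under rigid-body motion (tested with 100 seeded random rotations plus
translations).

## Electrophysiology statistics

**Sign convention.** Inward currents are stored negative; all summary
statistics are computed on magnitudes.

**Peak extraction.** Baseline is the median of the 1 s preceding the
application window (median, not mean, to resist transients); the peak is
the in-window extremum of baseline-subtracted current, sign preserved.
Windows shorter than 3 samples and traces without a full baseline
segment are errors.

**Hill fits.** Per recording, least squares of
`I = Imax / (1 + 10^(nH·(log10 EC50 − log10 c)))` — the Hill equation
parameterized in log10 concentration, which conditions the optimizer far
better than fitting EC50 on the molar scale across µM-to-nM regimes.
Bounds: log10 EC50 within [min conc ÷ 100, max conc × 100], nH in
[0.3, 10], Imax > 0. Initialization: Imax from the largest response,
log10 EC50 from linear interpolation of the half-max crossing, nH = 1.
Non-convergence is reported via a flag with the optimizer message, never
silently. The Hill coefficient is fitted, not fixed, and is always
reported. Summary statistics are the mean ± SEM (and median) of
per-recording EC50s; a separate display fit to the per-concentration
mean of normalized responses mirrors figure practice but is never used
for the summary numbers.

**Batch normalization.** Peaks are divided by the same-batch mean
maximal-concentration response of the reference construct, independently
per batch (recording day), so day-to-day expression differences cancel;
a batch without a reference recording is an error naming the batch.

**Potency ratio.** Per-recording |I(sub-max)|/|I(max)| on the same
oocyte, then mean ± SEM across recordings. Recordings whose maximal
response falls below the noise floor (3× baseline SD by default,
configurable) are excluded and counted.

**Fold-enhancement.** Per-recording |peak_b|/|peak_a| for the paired
conditioning protocol (test pulse after conditioning alone vs after
conditioning plus peptide), mean ± SEM. A control pulse below the noise
floor is *not* dropped — that would censor exactly the strongest
enhancements — instead the fold is computed against the floor and the
recording flagged. The proton test stimulus enters Hill machinery through
the pH ↔ concentration adapter (c = 10^−pH); the desensitizing
conditioning pH is a configuration value defaulting to 7.0.

**Mutant classification.** Two stages. (1) A one-sample two-sided t-test
of raw response amplitudes against zero; a construct that fails at both
test concentrations is `no_response` and never enters the ratio
comparison (interpreting a ratio of two noise values would be
meaningless). A t-test was chosen over a CI criterion; the two are
equivalent at matched α but the t-test states its p-value. (2) Remaining
constructs' ratios enter a one-way ANOVA frame (pooled variance) and are
compared to wild type with Dunnett's many-to-one procedure. The
comparison is one-sided (lower) by default: the classification scheme
distinguishes only *reduced* potency, lumping "significantly greater"
with "unchanged", so a lower-tailed familywise test at α = 0.05 is the
decision-theoretically matching procedure and makes the null rate of
`reduced` calls equal α (verified at 0.05 ± 0.01 over 10,000 null
simulations). A two-sided alternative is available. Critical values come
from a seeded Monte-Carlo simulation of the Dunnett max-statistic null
(shared control mean and shared pooled-variance χ² generate the
correlation structure; ≥ 50,000 draws, cached per design); a closed-form
cross-check against an independent multivariate-t implementation is part
of the test suite.

## Synthetic data: what it emulates, and what it does not

**Alignments.** Planted specificity-determining columns are identical
across the foreground (with optional within-class substitution noise)
while every background residue is drawn from a *different*
physicochemical class; all other columns are iid draws from a per-column
background profile (uniform by default) for both clades, so they carry no
clade signal. Redundant duplicates and out-of-length-window sequences are
appended as curation fodder and flagged in the truth record. Deliberately
**not** simulated: phylogenetic autocorrelation. Background columns are
iid across sequences given the profile, which matches the scan's
column-wise logic — the scan does not model tree structure either — but
means passing tests say nothing about the false-positive behaviour that
shared ancestry induces in real alignments (a clade of closely related
background sequences can mimic divergence patterns no iid model
produces).

**Trimers.** Cα-only, C3-symmetric by construction: chain A is built and
rotated by 120° and 240°. Non-pocket residues stack at twice the
interface radius from the symmetry axis (closest inter-chain approach
2√3 ≈ 3.5 interface radii); pocket residues sit near the axis in a
separate z band where each lies within the interface radius of its
rotational image on the adjacent chain. The generator re-verifies its own
separation guarantees and raises if they cannot be met. This is a
geometric oracle, not a protein: no secondary structure, no side chains,
no realistic bond lengths.

**Dose-response and traces.** Peaks follow the Hill model with
*multiplicative* Gaussian noise (default 5%), because oocyte responses
scale with expression level; additive noise would misrepresent the
error structure the fitter faces. Note one consequence: a ratio of two
noisy peaks has expectation ≈ true ratio × (1 + σ²), a +0.25% bias at 5%
noise — far below the SEM at realistic n, but visible in very large
simulations. Traces are biexponential — (1 − e^(−t/τ_act)) rise, optional
e^(−t/τ_des) decay rescaled so the analytic extremum at
t* = τ_act·ln(1 + τ_des/τ_act) equals the requested peak — with white
Gaussian sample noise; no filtering artifacts, leak currents or
series-resistance errors are simulated, and no Markov gating kinetics.
Paired-protocol generators add lognormal between-oocyte amplitude
scatter (σ = 0.2–0.3) so the paired statistics are exercised against
realistic expression variation. Default concentration ladder: 30 nM to
100 µM in half-log steps.

## Orchestration and reproducibility

A single pipeline seed fans out to per-stage seeds by fixed offsets, so
any stage can be re-run alone and reproduce its output bit-identically.
The manifest records seed, full configuration and per-stage outputs;
every number in the human-readable tables is derivable from the manifest.
Stages with missing optional inputs are marked skipped; any failure
halts with the stage name and cause.

Problem sizes used by the test and acceptance runs — 200 recordings for
EC50 recovery, 14 paired recordings for the potency ratio, 7 for
enhancement, 20 + 50 sequences × 560 columns with 43 planted columns for
the scan, a 3 × 560-residue trimer with 6 planted interface residues,
10,000 replicates for the type-I calibration of the Dunnett stage — are
the package's chosen benchmark conditions: they mirror the replication
scales of the experimental setting they emulate while keeping a full run
in the seconds-to-minutes range.

## Known limitations

- The scan's thresholds are an operating point, not the (unpublished)
  criterion of any particular study; exact reproduction of a specific
  published candidate count is out of reach from thresholds alone.
- Identity-based redundancy collapse is greedy, not an optimal set cover;
  permuting the input can change which representative survives.
- The interface detector knows nothing about solvent accessibility or
  pocket volume; "interfacial" is purely a distance statement.
- `no_response` classification depends on the configurable noise floor;
  very small true responses are indistinguishable from silence at low n.
- The pH adapter treats activity coefficients as 1 (concentration =
  10^−pH).
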