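# peptidegate

Comparative screening of peptide-gated DEG/ENaC ion channels: from a
clade-labeled multiple sequence alignment to a ranked list of
clade-specific candidate residues, their structural context at
inter-subunit interfaces of the trimeric channel, and the
electrophysiological statistics used to test the resulting mutants.

## Who this is for

Molecular physiologists and channel evolution researchers asking the
question: *which amino acid residues make one clade of a channel
superfamily sensitive to a peptide agonist that the rest of the
superfamily ignores?* The canonical setting is the FMRFamide-gated sodium
channel (FaNaC) family inside the degenerin/epithelial sodium channel
(DEG/ENaC) superfamily: FaNaCs are gated by the neuropeptide FMRFamide,
their Wamide-gated relatives (WaNaCs) by Trp-amide peptides, while
acid-sensing ion channels (ASICs) are merely *modulated* by RFamides.
The package implements the comparative arm of such a study as a tested,
reusable pipeline, with a synthetic-data module that supplies
ground-truth-annotated inputs for every stage.

## The method

1. **Curation** — sequences shorter than 300 or longer than 1000 residues
   are removed (bounds inclusive), and sequences >90% identical to an
   already-kept sequence are collapsed to one representative.
2. **Clade-contrast scan** — every alignment column is scored for
   conservation within the foreground clade (complete identity, or shared
   physicochemical class under a fixed six-class scheme) versus divergence
   in the background. A column is a candidate iff foreground conservation
   ≥ 0.90 and at most 20% of background residues match the foreground
   consensus (defaults; both exposed). Candidates are reported in the
   ungapped numbering of a reference sequence, grouped when vicinal
   (within 2 residues, groups of ≤ 3), and each gets a proposed mutation:
   the background consensus residue when one reaches frequency 0.5,
   alanine otherwise.
3. **Structure mapping** — candidates are mapped onto a trimeric
   structure; a residue is interfacial if its Cα lies within 8 Å of an
   adjacent subunit, and interfacial residues are clustered into pockets
   by single-linkage at 12 Å.
4. **Functional statistics** — per-recording Hill fits
   `I = Imax·c^nH/(c^nH + EC50^nH)` aggregated as mean ± SEM; the paired
   sub-maximal/maximal potency ratio (e.g. I₃µM/I₃₀µM); mutant
   classification against wild type (no_response / reduced /
   unchanged_or_greater) via a zero-response t-test followed by a
   Monte-Carlo Dunnett many-to-one comparison inside a one-way ANOVA
   frame; and the paired conditioning-protocol fold-enhancement
   |peak_b|/|peak_a| used for peptide modulation of proton-gated currents.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/03_hill_fitting.py` simulates five oocyte recordings at
a planted EC50 of 3.4 µM with 5% multiplicative noise and fits each one:

```
planted EC50: 3.40 µM
fitted  EC50: 3.81 ± 0.32 µM (mean ± SEM, n = 5)
fitted  nH:   0.97
  rec_001: EC50  4.77 µM, nH 0.87, Imax 5.47 µA
  ...
```

The fitted mean lies within ~1.3 SEM of the planted value — the scatter is
what five recordings at 5% noise genuinely support. Similarly,
`python examples/02_interface_mapping.py` builds a 3×560-residue toy
trimer with six planted interface residues and prints:

```
interfacial residues: [231, 281, 288, 316, 447, 529]
pocket: residues [231, 281, 288, 316, 447, 529] (linkage diameter 8.9 Å)
```

i.e. the detector recovers exactly the planted inter-subunit pocket.

The same operations are available from a thin CLI (`peptidegate
fixtures|curate|scan|map-structure|fit-dr|ratio|classify|enhance|run`);
`peptidegate fixtures --seed 7 --out fix/` writes a complete synthetic
study (alignment, clade table, trimer PDB, dose-response tables, paired
traces) with its ground truth in `truth.json`, and `peptidegate run
--config pipeline.yaml` executes the whole screen into a single
reproducible JSON manifest.

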