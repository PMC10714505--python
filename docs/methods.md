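# Methods

## The frequentmer model

Each sample's metagenome is reduced to a presence set of k-mers: all
length-k windows (step 1, forward orientation, windows containing N
skipped) over its single-end reads, keeping the distinct k-mers whose
total within-sample count is at least 2. The singleton filter is the
method's only error control — a k-mer observed once in a sample is far
more likely to be a sequencing error than a real, recurrent feature of
that microbiome, and a substitution error virtually never produces the
same novel k-mer twice within one sample.

Over a training split with m control and l patient samples, the cohort
index counts, for every observed k-mer, the number of *distinct*
samples per cohort containing it (read-level multiplicity never enters).
A control frequentmer of recurrency r satisfies `n_control ≥ r` and
`n_patient = 0`; a patient frequentmer symmetrically. The absence
condition makes the two catalogs disjoint by construction and makes the
catalogs shrink monotonically as r grows; both properties are asserted
in the test suite, together with exact agreement against a brute-force
per-k-mer membership scan.

Derivation is performed independently inside each cross-validation
fold, from that fold's training samples only. Held-out samples never
influence which k-mers become features; the test split is used solely
to measure how often training-derived frequentmers reappear (recovery),
in which cohort they reappear (majority vote; ties are left
unassigned, since an equal split carries no label information), and how
well a classifier built on them generalises.

## Encoding and storage

k-mers are packed two bits per base (A=0, C=1, G=2, T=3, leftmost base
most significant), so the default k=16 fits one 32-bit word; arrays use
uint64 to support any k ≤ 32. Reverse-complement canonicalisation is
**off** by default — the derivation is defined on forward-strand
presence — but `canonical=True` maps each window to
min(code, revcomp(code)) for libraries where strand is arbitrary.
Per-sample sets are stored sorted in fixed-width binary (`.kset`,
ceil(2k/8) bytes per record), which lets the index be built either
vectorised in memory or by a heap-based multiway merge whose memory is
bounded by the number of open streams; both backends are contractually
identical and tested as such.

## Classification

Features are binary presence indicators — X[i,j] = 1 iff feature k-mer
j is in sample i's retained set — in a fixed column order (control
block then patient block, each ascending by code) so coefficients are
comparable across runs. By construction every training control sample
is zero on all patient-frequentmer columns and vice versa; test samples
may violate this, and that violation is exactly the signal.

Models: L2-penalised logistic regression with inverse regularisation
strength C = 0.01 and an iteration cap of 2000 (deterministic,
interpretable coefficients), and an XGBoost classifier with
max_depth = 11, gamma = 0.3, eta = 0.2, alpha = 6 (seeded). PCA uses
column-mean centring without unit-variance scaling — the minimal
standard choice for a binary matrix — reporting up to 90 components.
Feature reduction ranks features by absolute logistic coefficient
(ties broken by k-mer code, ascending, for reproducibility) and refits
on the top N of the *same* split; with N equal to the full feature
count this reproduces the full model bit-for-bit, which the acceptance
suite checks. Per-fold ranking is the default; coefficient averaging
across folds is used only for selecting the global top/bottom-100
frequentmers handed to read traceback. Evaluation reports both the
pooled AUC over concatenated fold scores and the mean of per-fold AUCs
(with mean ± 1.96·sd/√folds as the CI), plus a confusion matrix at the
0.5 probability threshold; degenerate single-class test folds are
excluded from per-fold AUCs with a warning.

## Exposure subgroups

For a binary covariate on patients (e.g. viral infection, high alcohol
intake), a subset-specific frequentmer must be present in at least r
exposure-positive patients and absent from every exposure-negative
patient *and* every control — i.e. it is always a patient frequentmer
whose support lies entirely in the positive subgroup. Patients with
unknown status are excluded (not assumed negative), with a warning.
Profile similarity uses the Jaccard index over per-sample frequentmer
sets, with J(∅,∅) = 0 by convention (flagged in the report). The
within-group and cross-group Jaccard distributions are compared with a
Welch two-sample t-test; pairs straddling two groups have no natural
matching, so a paired test is offered only as an opt-in mode that
requires an explicit pair list.

## The synthetic generator

`SyntheticCohortSpec` emulates the structure the method exploits: all
samples draw reads from a shared background pool (the common
microbiome), and cohort-specific marker sequences are planted into a
Bernoulli(prevalence) subset of their cohort. Defaults, chosen once as
a small but realistic screen: 30 patients + 30 controls; five 10 kb
background references; ten patient and five control markers of 100 bp
(the patient excess mirrors the asymmetry typical of disease cohorts);
prevalence 0.5; 2,000 reads of 100 bp per sample (~4× background
coverage); substitution error rate 0.5%; three reads per included
marker so marker k-mers survive the singleton filter even with errors.

Background references are treated as circular, like bacterial
chromosomes: read starts are uniform over all positions with
wrap-around. With linear references the terminal k-mers receive
systematically low coverage, and their stochastic dropout can make a
genuinely shared k-mer look cohort-exclusive — an artefact of the
simulator, not of the method. Markers are rejection-sampled until
their k-mer sets are disjoint from the background (including the
circular junction k-mers) and from each other, so each marker k-mer's
cohort support equals the marker's inclusion pattern and recovery can
be scored exactly. An explicit inclusion-override matrix lets tests
force a marker into exactly n samples rather than relying on Bernoulli
tails. Everything, including emitted FASTQ bytes, is reproducible from
the spec seed.

What the simulator does **not** model: indels, realistic community
abundance and strain variation, GC bias, quality scores, or any overlap
between marker and background sequence. Passing tests therefore show
that the derivation, absence accounting and classification machinery
are correct under controlled signal — not that any particular real
cohort is separable, which depends on the biology.

## Problem sizes and numerical choices

The default test suite and the acceptance study run the simulator at
the scales above (60 samples, ~120 k windows per sample), where the
whole pipeline completes in seconds; smaller variants (10–24 samples,
2–4 kb backgrounds) are used for exhaustive property checks against
brute-force oracles. Recurrency thresholds are accepted on any grid
with r ≥ 1; r = 1 is allowed but warned about, since it degenerates to
mere group-absence. The patient share of a catalog is reported as
n_patient / (n_patient + n_control), null when the catalog is empty.
Test-set fold-enrichment ratios return infinity when frequentmers are
detected exclusively in their own cohort (a zero denominator), which
the clean simulator regularly produces; summary scripts therefore
prefer the underlying per-sample detection counts. Thread count never
affects results: every stage is deterministic and single-pass.

## Known limitations

- Exact absence is a hard constraint: one stray read containing a
  k-mer in the wrong cohort removes it from the catalog. This is the
  method's definition, but it makes catalogs sensitive to
  contamination at scale.
- The streaming index backend trades speed for bounded memory (pure
  Python merge); very large cohorts would warrant a compiled merge.
- Substitution-only error simulation; indel-heavy platforms would need
  a different generator.
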