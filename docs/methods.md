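# Methods

## The problem

Bacterial microcompartments (BMCs) are protein organelles: a polyhedral
shell of pfam00936 hexamers (BMC-H, the circularly permuted BMC-H^p, and
the tandem-domain trimers BMC-T^s / BMC-T^sp / BMC-T^dp) capped by
pfam03319 pentamers (BMC-P), encapsulating a metabolic core — typically a
signature enzyme producing an aldehyde intermediate plus aldehyde/alcohol
dehydrogenases and a phosphotransacetylase.  The genes sit together in an
operon-like locus, so a locus can be *typed*: its component inventory and
gene order are characteristic of functional BMC types (carboxysomes, EUT,
PDU, GRM, SPU, ...).  bmctyper identifies BMC components in ordered protein
sequence data with profile HMMs, fingerprints candidate loci, compares them
against a reference registry, and calls the BMC type by majority vote over
type-specific profile matches.

## Profile HMMs and the built-in scorer

**Estimation.**  A profile is built from an aligned protein family.
Alignment columns with gap fraction ≤ 0.5 become match states (a column
gapped in exactly half the rows is kept).  Match emissions are observed
residue frequencies with a +1/20 pseudocount per residue; a single insert
emission vector is shared by all insert states; per-state transitions
(M→M/I/D, I→M/I, D→M/D) are counted from each row's gap structure with +1
smoothing per outcome.  I→D and D→I events fall outside the Plan7 topology
and are not counted.  Estimation is deterministic and invariant to row
order.  Non-standard residues (B, J, O, U, X, Z) contribute no emission
counts but do count as residues for the gap structure.

**Scoring.**  The built-in scorer needs no external binary.  It computes

    bitscore = log2( P_forward(seq | profile) / P(seq | background) )

by the forward algorithm over a multihit local Plan7-style search
configuration:

* flanking states N/C/J emit with the background on their self-loops; all
  loop and move probabilities are 0.5;
* uniform local entry B→M_k with probability 1/L;
* a local exit M_k→E with probability ε = 0.05 folded multiplicatively
  into each non-final match state's core transitions; the last match state
  and D_L exit to E with probability 1;
* the null model emits every residue from the background (uniform 1/20 by
  default, overridable per library).

Because flanking states emit with the null's own background, flank
emissions cancel in the ratio; each flanked residue costs only the 0.5
loop probability (1 bit).  Non-standard residues are emitted at 1/20 by
every state *and* by the null, contributing zero bits.  All recurrences
run in natural-log space (numba-JIT kernels, with a pure-Python fallback
carrying identical semantics).

A hit is accepted at bitscore ≥ 20 bits by default (configurable per
profile and per library).  The threshold is intentionally simple and
deterministic; no E-value calibration is attempted.  Envelope coordinates
and the domain count are taken from the Viterbi traceback: `n_domains` is
the number of B→M entries on the optimal path, the envelope spans the
first to last core-emitted residue.  Tandem BMC-T recognition is
nevertheless delegated to profile identity (T profiles are trained on
full-length tandem sequences); `n_domains` is reported as metadata only.

**Verification.**  On every profile of length ≤ 3 against queries of
length ≤ 5, the forward probability is checked against exhaustive
enumeration of all state paths of the same configured machine (relative
agreement demanded at 1e-9; observed ~1e-15).  Forward ≥ Viterbi holds by
construction and is asserted property-style.

## Fingerprints, similarity, and type calling

A locus fingerprint is the ordered list of best-hit profile names (one
best profile per protein, maximal bitscore, ties broken lexicographically;
unassigned proteins are excluded).  Similarity between fingerprints blends

* **inventory**: Jaccard index of the label sets, and
* **order**: the maximal fraction of aligned label matches over all
  integer offsets, searching the second fingerprint both forward and
  reversed (operons occur on either strand), normalised by the longer
  length,

as `S = α·inventory + (1−α)·order` with α = 0.5.  S is symmetric, bounded
in [0, 1], and equals 1 on identical fingerprints.  Ties between offsets
prefer the forward orientation and the smallest offset, making reports
deterministic.  Against a reference registry, each type is scored by its
best example fingerprint and the top 5 are reported.  Loci are clustered
single-linkage: connected components of the graph with edges at
similarity ≥ 0.6.

The BMC type is called by majority vote over the BMC-type labels of all
typed assignments (shell and enzymes; a shell-only vote mode is a flag).
A unique modal type with ≥ 50% of the votes is assigned with confidence
modal/total; anything else is ambiguous (ties always are).  A locus with
no shell-role assignment is `no_shell` regardless of enzyme votes.  When a
call is ambiguous, the types of signature-enzyme matches are listed
separately as a functional hint.

## Candidate loci in whole proteomes

Input order is trusted as genome order (the input contract); no
coordinates are parsed from headers.  Each shell hit expands to
±12 genes (the default window), windows are closed intervals on gene
indices (0-based internally, 1-based in reports), and overlapping *or
touching* windows merge — a single operonic run should not split.  Merging
is idempotent and independent of hit enumeration order.

## Reference registry

The shipped registry enumerates the 68 types/subtypes of the published BMC
classification (carboxysomes; EUT1/EUT2A–K/EUT3; PDU1A–D/PDU2–4;
GRM1A–GRM6; SPU1–7; CUT1–4; PVM/PVM2/PVM3; RMM1–3; ACI; ETU1–2; MUF1–6;
MIC1–6; BUF1–6).  Its example fingerprints are synthetic placeholders (one
color per type in a canonical role order), labelled as such in the data
file; they give the registry a complete, loadable shape until real locus
fingerprints are substituted.  Registry files are a documented single-file
TSV; per-type sequence sets round-trip through FASTA export.  Per-family
sequence summaries reduce to count, length min/mean/max and isoelectric
point min/mean/max (Henderson–Hasselbalch bisection, Biopython's
Bjellqvist pKa set); sequence logos are out of scope.

## Synthetic fixture worlds

The generator emulates the *shape* of BMC data, not its biophysics: per
synthetic type, one family per role (six shell classes, a signature
enzyme, an AldDh), each family a fixed random 28-residue motif between
8-residue random flanks, 6 sequences with ≤ 10% (default 5%) per-position
substitution noise — equal-length members, so the raw family is its own
ungapped training alignment.  Loci follow a canonical role order (14 shell
+ 2 enzyme genes at the default 20-gene length) with up to two adjacent
swaps and ~20% random bystander genes.  One numpy Generator stream per
world seed makes regeneration bit-identical.  Family sequences are split:
the first ⌈half⌉ trains profiles, loci draw only from the held-out half,
so classification benchmarks never score training sequences.

Corruption modes produce the failure cases: `shuffle` permutes gene order
(votes are order-free, so the vote table is unchanged); `drop_shell`
removes all shell genes (`no_shell` by construction); `mix_types` replaces
half the shell genes (rounded up) *and* the typed enzyme genes with
same-role counterparts from the other types, donors cycling.  Replacing
shell genes alone cannot reliably break a majority once enzymes vote
(the home type retains ⌊S/2⌋+E of S+E votes ≥ 50%), so the corruption also
reassigns the enzyme votes; with donors cycling, no donor accumulates a
majority either, and the call is robustly ambiguous.

What passing these tests shows — and does not.  Synthetic families are
far cleaner than real BMC families: motifs are independent across types,
indels are absent, and bystanders are random sequence.  Perfect recovery
here validates the pipeline's plumbing, determinism, and decision rules,
not its sensitivity on diverged real families; real-world accuracy is
bounded by profile quality and the 20-bit threshold.

## Numerical and design choices

* Bitscore threshold 20 bits; similarity α = 0.5; majority 0.5 with a
  unique-mode requirement; clustering threshold 0.6; window 12; top-k 5;
  cascading diagrams wrap at 10 genes per row.  All are configurable; the
  defaults are the documented contract.
* The exit probability ε = 0.05 keeps local alignments long enough to
  span whole motifs while still permitting envelope truncation.
* Full-sequence forward scores decide acceptance and best-hit ranking
  (not per-domain scores); per-domain reporting is metadata.
* Exact score ties between profiles break lexicographically; offset ties
  prefer forward orientation, then the smaller offset.
* Degenerate inputs are rejected with named diagnostics: empty MSAs,
  ragged rows, all-gap columns, empty sequences, duplicate FASTA ids,
  empty libraries/registries.
* Library serialization prints floats with `repr`, so save→load is exact
  and re-runs are byte-identical.  HMMER3/f import clips stored zero
  probabilities to 1e-9 and renormalises to satisfy the strict-positivity
  invariant; import goes through pyhmmer, export is validated by
  re-parsing.
* Benchmarks in the test suite and acceptance script use worlds of 10
  types × 8 loci × 20 genes (the reference recovery condition) and
  smaller 3–6-type worlds for corruption and CLI checks; these sizes keep
  the whole suite to a few minutes while exercising 80-profile × 1600-
  protein searches.

## Known limitations

* No E-value statistics; bit thresholds do not adapt to profile length.
* The similarity order component counts exact label matches only; related
  but distinct profiles contribute nothing (recalibration would be needed
  if a graded label-similarity definition were adopted).
* Satellite loci are not detected separately: each merged window is one
  candidate locus.
* The default registry's example fingerprints are placeholders; closest-
  type rankings against it are structural, not biological, until real
  fingerprints are loaded.
* DNA input, six-frame translation, and strand awareness are out of
  scope; input order must be genome order.
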