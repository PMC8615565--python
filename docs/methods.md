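# Methods

## Logical formalism and update semantics

Components take integer activity levels 0..`max_level` (1 for Boolean, 2
for ternary components).  A rule is an ordered list of
(target level, condition) pairs; conditions are formulas over threshold
atoms (`X` for level ≥ 1, `X:2` for level ≥ 2) under NOT/AND/OR.  On
update a component adopts the **highest** target level whose condition
holds, 0 otherwise.  This highest-satisfied-level convention is what lets
the IKK complex report level 2 whenever the CD40/TRAF6 arm is active, even
if the BCR/CBM arm (level 1) fires simultaneously — required for the LZ2
and PC attractors, where both arms are on and NF-κB must reach level 2.

The update scheme is synchronous, but it is used only to *define*
fixpoints (f(s) = s), which are identical under any update scheme.  All
eight wild-type attractors are fixpoints, so trajectory dynamics, cyclic
attractors, trap spaces and asynchronous semantics are deliberately out of
scope.

Inputs (BCR, CD40, IL21/4) are environment, not dynamics: they are held at
an externally supplied level, and every analysis conditions on one of the
eight input combinations.  Three combinations — T-cell help without BCR
engagement — are flagged non-physiological and excluded from patient
analysis, because CD40/IL21 signals presuppose antigen presentation by the
B cell.

## Fixpoint enumeration and its oracle

`enumerate_fixpoints` first pins inputs and clamps, then propagates
constants: any component whose regulators are all pinned is itself pinned
at its rule value, iterated to closure.  Only the residual, cyclically
interdependent components (in the GC model: MYC, BCL6, BLIMP1, AID, BCL2 —
the BCL6/BLIMP1 double-negative loop and its readouts, ≤ 32 combinations)
are scanned exhaustively; a candidate is kept when every free component
already sits at its target level.  This is exact: pinned components are
forced to those values in *every* fixpoint consistent with the
conditioning, so the reduced scan enumerates precisely the fixpoints of
the full space.  The test suite verifies this equivalence against an
independent brute-force scan of all 2^16·3^3 = 1,769,472 states of the GC
model (own evaluator, early-exit state test) and against 50 random clamp
sets.  Fixpoints are reported in lexicographic order of the state vector
for deterministic output.

## The GC model

Multi-regulator rules are written exactly as in the README's rule table;
single-regulator components copy their sole regulator (SYK = BCR,
BTK = BCR, RAF = BTK, CBM = BTK, TRAF6 = CD40, STAT = IL21/4,
NF-κB = IKKc level, IRF4 = NF-κB level).  Two structural choices deserve
note:

* **IκB is not an explicit component.**  The core network writes NF-κB as
  directly following IKKc; the biological IKKc ⊣ IκB ⊣ NF-κB double
  inhibition is collapsed into one activation.  Lesions in IκB-family
  genes (NFKBIE) are instead handled in the *mapping table* as an
  inhibiting edge onto NF-κB.
* **IRF4 mirrors the NF-κB level.**  Low/transient IRF4 (level 1) opens
  the BCL6 window (`IRF4:1 ∧ ¬IRF4:2`); sustained high IRF4 (level 2,
  CD40-driven) closes it and enables BLIMP1.  No IRF4 regulators besides
  NF-κB are modeled.

Stage identity is read off the markers MYC, BCL6, BLIMP1, BCL2 only; AID
is computed and reported (it marks the dark zone) but excluded from
pattern equality, from the oncogenicity criteria and from the 'no marker'
treatment surrogate.  Stage ids are the binary encoding of
(BCR, CD40, IL21/4) plus one, so LZ1 = 1, Pre-GC = 5, DZ = 6, LZ2 = 7,
PC = 8.

## Genotype → clamp mapping

Only strong events are interpreted: non-synonymous mutations, structural
variants, and high-grade copy-number gains/losses.  Gains are GOF and
losses LOF of the gene; mutations/SVs are GOF for oncogenes and LOF for
tumor suppressors; an inhibiting gene→component edge inverts the
direction.  GOF clamps to the component's maximal level — ternary
components therefore jump to level 2, which is why receptor-arm lesions
(TLR2, MYD88) produce strong constitutive NF-κB.  The default table
contains the 29 genes whose mapping is documented for this model; it is a
deliberate subset of the full curated driver list used on the original
cohort, which was never published, so cohort-level counts from that study
are not reproduction targets here.

When one component collects both GOF and LOF clamps the LOF wins and the
conflict is recorded on the perturbation set and in the cohort report.
Rationale: for the genes modeled here, loss of the protein is epistatic to
activating point mutations; determinism matters more than the choice, and
the conflict is always surfaced.

## Patient profiles, oncogenicity, NF-κB classes

A patient model is the wild-type network plus genotype clamps.  Its
profile evaluates the five physiological stages; a stage whose input
combination contradicts an input clamp (CD79B ⇒ BCR = 1 vs LZ1's BCR = 0)
is *lost*, which is distinct from a stage with zero fixpoints.  "Changed
vs wild type" is decided at marker-pattern level (the four stage markers),
with full-state deltas retained for inspection.

Oncogenicity flags: (i) abnormal combination — BCL6 co-active with MYC
and/or BCL2 in any reachable attractor; (ii) wrong stage — BCL6 outside
DZ or MYC outside Pre-GC/LZ2; (iii) PC loss — stage lost *or* its
attractor lacks BLIMP1 (a genotype like EZH2-driven BLIMP1 silencing
keeps the PC input but abolishes plasma-cell commitment); (iv) LZ1 loss —
stage lost or any marker active in the no-signal state, i.e. escape from
the selection checkpoint.  A model is oncogenic if any flag is set.

NF-κB dependency is a five-way class, assigned by a fixed cascade
(first match wins): **independent** when the genotype clamps MYC or BCL6
active (marker output no longer responds to NF-κB); **inactive** when
NF-κB (or IKKc, its sole driver) is clamped off; **level2**/**level1**
when the model shows constitutive NF-κB of that level in its minimal
reachable input condition (clamped inputs at their clamp, all other
receptors off); **unperturbed** otherwise.  The minimal-reachable-input
rule covers receptor-level lesions: a CD79B-driven model has no zero-input
state, and its BCR-on baseline gives constitutive level-1 NF-κB, grouping
it with the level-1 class — consistent with treating BCR-perturbed models
as level-1 models in the inhibitor analysis.  The cascade order was fixed
once: marker-gene GOF must dominate (a BCL6-driven model with an
additional TLR2 lesion is still NF-κB independent), and an explicit NF-κB
LOF must dominate the constitutive-level test.

## Drug simulation

Each inhibitor clamps its target to 0; drug clamps are applied after and
therefore override genotype clamps on the same component (Venetoclax
silences amplified BCL2), while lesions downstream of the target escape
(an IRF4 GOF escapes Bortezomib).  Response is scored by the 'no marker'
surrogate — the count and fraction of reachable stages whose attractor has
all four markers off — standing in for apoptosis, which the network does
not model.  Lost stages leave the denominator.  Regimen ranking sorts by
no-marker stages, then fewer total active markers, then smaller regimens,
then lexicographic drug order.  The default candidate set is the seven
blocks: none, BTKi, NFKBi, PI3Ki, BCL2i, PI3Ki+BCL2i, NFKBi+BCL2i.

## Synthetic cohort

The generator emulates the statistical shape of a large DLBCL cohort, not
any real dataset: per-patient lesion counts of 1 + Poisson(2) truncated to
[1, 10]; genes drawn without replacement with weight 1 per mappable gene
and weight 3 for BCL2, making BCL2 the clearly most frequent lesion;
cell-of-origin labels ABC/GCB/unclassified at 0.40/0.45/0.15; alteration
classes at mutation 0.60 / high gain 0.25 / high loss 0.10 / SV 0.05,
except BCL2, which is amplified in ABC and mutated (0.7) or
SV-rearranged (0.3) in GCB tumors, mirroring the subtype split of BCL2
lesions.  These weights are free parameters of the generator, chosen once
and documented here; they are not estimates of published frequencies.  An
optional noise fraction (default 0) adds filterable records — silent or
low-grade events, or known DLBCL drivers outside the mapping table
(TP53, KMT2D, ...) — to exercise the filter.  All draws come from one
`numpy` generator seeded explicitly, so identical spec + seed gives
byte-identical tables.

What passing tests on this cohort do **not** show: real lesion
co-occurrence structure, subclonality, variant-level effect heterogeneity,
or the composition of the unpublished curated gene list — so cohort-level
fractions computed here characterize the generator's conditions, not the
original patient cohort.

Nine fixture genotypes reproduce the worked patient models (131, 73, 29,
47, 34, 60, 85, 27, 92).  Where the narrative names the alteration class
it is used; where it is silent the class is recorded as `sv` (any
high-impact class maps to the same clamp for those genes).  The model-29
STAT lesion is taken as GOF via STAT3: only active STAT suppresses ERK and
yields the described BCL6+BCL2 co-activity in Pre-GC and DZ.

## Problem sizes and numerical notes

The conditioned enumeration touches ≤ 32 residual states per stage, so a
full patient profile costs ~1 ms; the acceptance script analyzes a
500-patient synthetic cohort plus all fixtures in about a second, and the
brute-force oracle sweep of all 1.77 M states runs in a few seconds.
Report files are long-format TSV with fixed column order and `\n` line
endings, byte-stable under write→read→write.  Degenerate inputs are
handled explicitly: a network with no components has the empty state as
its unique fixpoint; a pure negative self-loop has none; clamp levels and
rule thresholds are validated against `max_level` at construction.

## Known limitations

No apoptosis/p53 arm, no non-canonical NF-κB, no BIM or survival
crosstalk; inhibition is all-or-none (no dose); perturbed ternary
components always adopt the extreme level (a GOF cannot produce
constitutive level-1 NF-κB); the mapping table ignores variant-level
annotation; and cyclic attractors, if a modified model had any, would be
invisible to a fixpoint-only analysis.
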