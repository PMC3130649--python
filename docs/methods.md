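# Methods

## The typing problem

Each assay in the panel is a TaqMan endpoint genotyping reaction for one
biallelic Y-chromosome variant: two hydrolysis probes, one per allele,
labelled with VIC and FAM. After PCR, the released fluorescence of the
two dyes is read once per well, so a well is a point in (VIC, FAM)
intensity space. Y-chromosome markers are hemizygous in males — one
chromosome, one allele — so a successful assay shows at most **two**
allele clusters (never a dual-high heterozygote cluster) plus a
background cluster near the origin containing the no-template controls
(NTCs) and any well that failed to amplify. Plates follow the OpenArray
layout: 24 wells per assay, 22 samples and 2 NTCs.

## Panel and tree

The packaged panel (`yplex/data/panel_openarray121.tsv`) describes 128
designed assays, 121 active and 7 failed, each with its haplogroup
label, ancestral/derived allele tokens (indel tokens kept verbatim;
shorthand indels such as "2-bp del" are encoded as `ref`/`del` or
`ref`/`ins` two-state assays), dye orientation, published per-marker
call rate, and redundancy group. Two groups of built-in controls exist:
M145 and M203 both define the DE branch, and M9a/M9b interrogate the
same K-defining SNP with swapped dye assignments.

The haplogroup tree is built from the labels themselves. YCC
nomenclature nests subhaplogroups by extending the parent label, so the
parent of a label is its **longest proper prefix** present in the panel
or skeleton, tolerating gaps (`I1b1` attaches to `I1` when no `I1b`
assay exists). Joins the prefix rule cannot express are supplied by a
child→parent skeleton table and always win over prefix parsing:
compound haplogroups (`CT`→`Y`, `DE`→`CT`, `IJ`→`F`, `NO`→`K`), major
branches under their compounds (`D`/`E`→`DE`, `I`/`J`→`IJ`, ...), and
multi-digit siblings (`J2a10`, `J2a11`, `J2a13`→`J2a`, which the prefix
rule would misplace under `J2a1`). A purely alphabetic label with no
resolvable prefix (a major haplogroup such as a lone `A`) hangs off the
root; any other unresolvable label is a hard error. The root is fixed
at `Y`, displayed as the paragroup `Y*`. `CF` is not carried (no assay
types it), so `C` and `F` attach directly to `CT`; only panel-relevant
nodes exist. Markers with a `.2`-style variant designation (SRY10831.2,
P37.2, P41.2) mark recurrent mutations; the panel types a single
placement of each, and recurrence is recorded only as a node annotation.

**Distinguishable classes.** Every marker-defined node contributes one
genotype-distinguishable outcome (its starred paragroup when typed
descendants remain, the bare node when terminal in the panel), plus the
all-ancestral root paragroup. On the packaged panel: 121 active assays,
two redundant pairs → 119 marker-defined labels → **120** classes. Other
counting conventions exist (e.g. excluding the root class); the count is
exposed with an `include_root` switch rather than asserted as a single
canonical number.

## Allele calling

Intensities are arbitrary units, so each assay is first normalised by
its per-assay maximum and log1p-transformed; calls are therefore
invariant under any common positive rescaling of an assay's wells. The
partition is centroid-based:

1. **Background anchor.** The background centroid is the mean of the NTC
   wells (≥1 required; missing NTCs are an error). Wells within
   `signal_threshold` (default 0.25 in normalised log space) of it carry
   no signal; if no well does, the assay failed on this plate and every
   sample well is a no-call.
2. **Allele seeds.** Among signal wells, the most FAM-dominant and most
   VIC-dominant points seed the allele clusters. Two clusters are fitted
   only when the seeds dominate *opposite* dye axes and are at least 0.2
   apart; same-side seeds mean a single allele cloud (e.g. an assay where
   every sample carries the same allele) whose spread along its minor
   axis must not be split into two pseudo-clusters.
3. **Refinement.** k-means (scikit-learn, fixed init at the seeds, one
   start) refines the 2–3 centroids.
4. **Cluster validity.** An allele cluster is accepted only if its
   centroid is further from the background centroid than 3× the larger
   of the two clusters' scatters; this rejects noise-driven
   pseudo-clusters when a whole assay sits at background (empty wells),
   which max-normalisation would otherwise inflate into signal.
5. **Labelling.** Each accepted allele cluster is labelled by its
   dominant dye axis, and the dye is mapped to ancestral/derived through
   the marker's dye map — dye-swapped assays (M9b) therefore decode
   correctly with no special casing.
6. **Abstention.** A sample well is a no-call when it falls in the
   background cluster, when its nearest/second-nearest centroid distance
   ratio exceeds the no-call margin (default 0.7), or when it is a
   signal well beyond 3 cluster-SDs of *both* allele centroids (the
   dual-high case the hemizygous model forbids). Called wells carry a
   positive margin (second-nearest minus nearest distance); no-calls
   carry margin 0. NTC wells are always labelled `ntc`, never an allele.

The margin and thresholds are declared package decisions; the
instrument vendor's calling algorithm is proprietary and this geometry
is the simplest one consistent with a three-cluster endpoint read.

## Assignment, conflicts, resolution

Derived alleles accumulate along a lineage, so an error-free profile's
derived set equals the marker set of one root-to-node path. Profiles
are checked against every node's path with **missing calls treated as
uninformative**: a path is acceptable when no called marker contradicts
it (no ancestral call on the path, no derived call off it). Compatible
profiles are assigned to the deepest node whose own defining marker is
derived — assignment never reaches deeper than direct evidence, so a
sample whose terminal marker dropped out is placed one level up rather
than guessed. The all-ancestral profile is the root paragroup `Y*`. A
node with typed descendants, all ancestral or missing, is displayed
starred (`G*`); a node terminal in the panel is displayed bare.

Before assignment, redundancy groups are consolidated: agreeing members
collapse to one state; a disagreeing pair is downgraded to no-call for
both members (the branch stays assignable at reduced resolution, and
the discordance is reported); a single called member is used and
flagged partially supported.

**Single-false-positive resolution.** For an incompatible profile, each
derived call in turn is reverted to ancestral and compatibility
re-tested. Exactly one workable reversion → the sample is assigned on
the corrected profile with that marker recorded as eliminated
(`resolved`). Zero or ≥2 workable reversions → `unresolved`; at most one
elimination is ever applied and ties are never broken by guessing.
Reversion is to ancestral rather than no-call because a false positive's
true state is ancestral; on this panel the two choices give identical
compatibility outcomes.

**Known blind spot.** A false positive on a marker whose node is a
*direct child* of the sample's true node creates no incompatibility: the
call is clean but one level too deep. This is inherent to tree-based
checking, not an implementation limit; the test suite asserts the
behaviour rather than hiding it. A false positive deeper down (skipping
an intermediate marker) *is* caught via the ancestral-on-path violation.

## QC

Call rate = 100 × called / denominator per marker (or per sample), with
samples that produced zero calls (loading failures) excluded from
denominators by default (`exclude_empty`); pass rate = active/designed
assays; concordance = percent agreement over (sample, marker) pairs
called in both the observed and reference sets. All reported
percentages are rounded half-up to one decimal, matching the panel
table's precision. On the packaged table: mean call rate 96.4%, minimum
84.8% (L23), pass rate 94.5%.

## Simulator

Truth haplogroups are drawn uniformly over marker-defined nodes (or
from explicit weights/labels); the truth genotype is derived on every
lineage marker and ancestral elsewhere, which guarantees pre-error
compatibility. Independent Bernoulli processes then apply per-marker
dropout (→ N), false positives (A→D) and false negatives (D→A); a
configurable number of samples is forced all-N to emulate empty wells.
Plates render each (assay, well) from the Gaussian class of its
genotype: background mean (0.1, 0.1) SD 0.05; allele clusters (1.0,
0.2)/(0.2, 1.0) SD 0.08 on the allele's reporting dye, all in
normalised units scaled by a per-assay uniform(8000, 32000) factor and
clipped at zero. Default separation between class means is ≥11 SD —
a clean endpoint read. All draws flow from one integer seed through
`numpy` `Generator`s (seed streams split per stage and plate), so fixed
configurations reproduce byte-identical outputs.

What the simulator does **not** model: assay-correlated errors (probe
cross-hybridisation families), intensity drift within a plate,
partial-amplification smears between clusters, or Ct-domain kinetics.
Passing simulation tests therefore demonstrates the correctness of the
calling geometry and the assignment logic under the stated error model,
not robustness to every failure mode of real fluorescence data.

## Problem sizes and defaults

The standing experiment sizes are the package's own: 18-sample control
cohorts for end-to-end concordance (one plate, matching the size of a
typical reference-sample set), 500-sample cohorts for assignment
accuracy, 22 samples per plate. The accuracy experiment sets each
marker's dropout to 1 − its published call rate; under the
no-deeper-than-evidence rule the expected exact-node accuracy is then
approximately the mean call rate (≈96–97%): when a node's sole defining
marker drops out, the sample is placed at its parent paragroup — an
on-path, one-level-shallow call, never an off-branch error. The
experiment asserts that every miss is an ancestor of the truth.

## Limitations

- Resolution is capped at the panel: branches with no assay (A, B,
  subclades of C, D, K, M, N, O, P, Q, T beyond those typed) collapse
  into their nearest typed ancestor's paragroup.
- No probabilistic posterior over haplogroups and no imputation of
  missing genotypes; abstention is preferred to guessing throughout.
- The cluster caller assumes endpoint (single-read) data in a long-form
  CSV; instrument-native binary exports are out of scope.
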