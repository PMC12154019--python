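# Methods

## Chemotype classification

The working statistic is `x = log10(%THC / %CBD)` on percent dry-weight
contents.  Contents below a floor (default **0.001% w/w**, the smallest
content the reference survey reports; effectively a detection limit) are
clamped to the floor before taking the ratio, and the clamping is flagged
on the call.  Classification uses fixed cutoffs, `x > 0 → I`,
`−1 < x ≤ 0 → II`, `x ≤ −1 → III`; both cutoffs are parameters.  Reported
ranges are rounded half-away-from-zero to 2 d.p. (so −1.085 → −1.09),
matching the convention of the survey literature.

The packaged 85-sample reference table reproduces its published chemotype
column 85/85 under these cutoffs.  Its published log-ratio column, however,
was evidently computed from unrounded quantitation data: recomputing from
the printed %THC/%CBD columns matches the printed log column within 0.005
for 67 of 85 rows, with the largest deviations where %CBD is printed at
one significant figure (e.g. a printed 2.301 against log10(0.488/0.002) =
2.387, consistent with a true CBD near 0.0024).  The package always reports
values recomputed from its inputs.

A clustering route mirrors heatmap-based grouping: samples are points
(log10 %THC, log10 %CBD) after flooring, agglomerated with complete
linkage under Euclidean distance (scipy), and cut at a requested k.
On the reference table this recipe — like the equivalent R
`hclust`/`pheatmap` computation — does **not** reproduce the three
chemotype groups at k = 3: the ~10 drug-type samples whose CBD sits at the
detection floor (log10 = −3) split off before the intermediate and fiber
groups separate, and the smallest chemotype-pure cut is k = 4.  The
"three clear clusters" reading of such heatmaps is a visual one.  The
fixed-cutoff rule is therefore the default classification method; the
clustering result (merge history and partition) is exposed for inspection
rather than used for calling.

## In-silico ARMS PCR

Binding is scored by mismatch counting, not thermodynamics, because the
emulated readout is binary band presence on an agarose gel.  A primer
footprint qualifies iff its 3′-terminal window (default **1 base**) matches
exactly (IUPAC-compatibly) and the remaining positions carry at most a
fraction (default **0.10**) of mismatches.  Both strands are scanned;
coordinates are 1-based inclusive.  Products form for every convergent
plus/minus site combination up to a length cap (default 3000 nt), spanning
5′ end of the upstream primer to 5′ end of the downstream primer.  A band
is "present" iff some product lies within a size tolerance (default
**±10%**, roughly agarose resolution) of the pair's expected size.

The engine is primer-agnostic (assays are YAML configs); the shipped
fixture assay is engineered so the four marker reactions give exactly
their nominal sizes on matching templates: THCASd 384 bp, CBDASf 346 bp,
and internal controls THCASint 291 bp and CBDASint 169 bp.  The THCAS
discriminating primer is the reverse primer (3′ base on position 1349 read
from the minus strand) so the 384-bp product fits inside the 1635-nt CDS;
the CBDAS discriminating primer is a forward primer ending on position
645.  Only the 3′-terminal base distinguishes active from inactive
templates, so toggling that one template base toggles the band (the ARMS
property, under test).

## Genotype coding

Dominant-marker logic: THCAS target band present → `T`, absent → `t`;
CBDAS target band present → `D`, absent → `d`; composites `Td → I`,
`TD → II`, `tD → III`.  The fourth combination `td` is reported as
*undetermined* rather than guessed (both synthases apparently inactive is
never observed in the survey).  An absent internal control makes a
negative target call untrustworthy; the default policy still calls the
lowercase allele but flags `internal_control_failed` (the survey itself
retained such a sample as `t`), while `strict=True` returns `no_call`.

## ORF integrity and activity

A gene copy is **active** iff (a) its end-gap-free affine alignment to the
intact reference contains no internal indel of length not divisible by 3,
and (b) its translation from position 1 to the first stop reaches at least
**0.90** of the reference protein length.  Alignment scoring: match +1,
mismatch −1, and a gap of length L costs 4 + L (i.e. open −4, extend −1),
via Biopython's `PairwiseAligner` with free terminal gaps; tests require
score equality with an exhaustive dynamic-programming oracle on short
sequences.  Terminal gaps never count as indels (truncated sequencing is
not a frameshift).  Activity here is purely sequence-structural: catalytic
point substitutions that kill activity without disturbing the frame are
out of scope, so a structurally "active" allele can be enzymatically dead;
such conflicts surface as QC flags, not resolutions.

## Phylogenies

Published analyses of this kind use MAFFT alignments and maximum
likelihood (TIM1+G/TIM1+I, 1000 bootstraps).  This package deliberately
substitutes a simpler, fully deterministic stack, because the scientific
surface being reproduced is **clade composition**, not likelihoods:

* star-progressive alignment around the first input sequence, built on
  the pairwise affine aligner above ("once a gap, always a gap");
* p- or JC69 distances over mutually ungapped columns,
  `d = −(3/4)·ln(1 − 4p/3)`, with pairs at p ≥ 0.75 flagged saturated
  and capped (default cap 5.0);
* canonical neighbor joining (Q-criterion, Studier–Keppler updates),
  ties broken on the lexicographically smallest pair of cluster labels,
  negative branch lengths clamped to zero — NJ recovers additive matrices
  exactly, which is the oracle test;
* column-resampling bootstrap with a seeded generator; supports are the
  fraction of replicate trees containing each internal bipartition.

On synthetic panels the pooled gene tree (one leaf per gene copy) shows
the four expected groups — active THCAS (drug + intermediate), inactive
THCAS (fiber), active CBDAS (intermediate + fiber), inactive CBDAS
(drug) — each with bootstrap support ≥ 0.9 at 100 replicates, and in the
per-sample concatenated data the intermediate group lies between the drug
and fiber groups (its mean distance to each is smaller than the
drug–fiber distance).

## Synthetic panel generator

The generator emulates the survey's structure, not its biology in detail.
Defaults: 70 drug / 11 intermediate / 4 fiber samples; one random
ancestral CDS per panel for THCAS (1635 nt, the real CDS length) with the
CBDAS ancestor (1632 nt) derived from it at **0.16 substitutions/site**
(real THCAS/CBDAS are ~84% identical, which keeps cross-gene alignments
and distances meaningful); active and inactive allele lineages of each
gene separated by a further **0.02/site** (real active and inactive
synthase alleles differ at dozens of sites — with only the functional
changes, per-sample noise would swamp the allele split and no clade could
be supported); per-sample background substitutions at **0.002/site**.
Functional coordinates — the SNPs (1349/1349-codon, 645), primer
footprints, start/stop codons, the engineered premature-stop codon
(placed at ~60% of the THCAS CDS so truncation is unambiguous under the
0.90 rule) and the CBDAS deletion window at position 153 — are protected
from all mutations, and substitutions never create in-frame stops, so the
engineered activity states are exactly the truth labels.  Which SNP base
is "active" is arbitrary and configurable (defaults: G at THCAS 1349,
C at CBDAS 645); only generator/assay consistency matters.  A 6-bp
deletion is accepted by config for completeness but is in-frame (no
frameshift) and flagged as such.

Cannabinoid contents are drawn **independently and uniformly** per
chemotype (the survey reports only observed ranges, no distribution).
The survey's raw marginal ranges overlap across classes when sampled
independently (its low-THC drug samples never co-occur with its high-CBD
drug samples, but independent draws would combine them), so the defaults
are survey-like ranges trimmed to be linearly separable at the cutoffs:
drug THC 0.3–3.7 / CBD 0.001–0.16, intermediate THC 0.7–1.7 / CBD
1.8–6.5, fiber THC 0.06–0.15 / CBD 1.6–3.0 (% w/w).  A guard rejects any
configuration whose ranges could cross the cutoffs, so generated classes
are separable by construction — passing chemotype tests on synthetic data
therefore demonstrates correctness of the statistic and cutoffs, not
real-world separability, which only the packaged survey table speaks to.

What the generator does **not** emulate: chromatograms or quantitation
noise, heterozygosity (the marker coding is dominant), linkage between
cannabinoid content and sequence beyond the class labels, catalytic-site
variation, and real accession sequences.

## Problem sizes and determinism

Sequence-level tests run on a 10-sample panel (4/3/3) with 100 bootstrap
replicates; classification and concordance tests use the full 85-row
reference table and a survey-sized 70/11/4 synthetic panel.  Every
stochastic step takes an explicit seed (panel generation, bootstrap), and
a panel is a pure function of its config, so identical configs yield
byte-identical artifacts; `cannatype full` writes a manifest recording
seed and parameters sufficient to regenerate its output directory exactly.

## Known limitations

* Fixed-cutoff chemotype calls at the class boundaries depend on the
  flooring value when a content is below detection.
* The in-silico PCR engine has no thermodynamic model; primers that fail
  in practice for Tm/ΔG reasons will not fail here.
* The clustering route does not reproduce published visual groupings on
  the reference table (see above) and is not used for calling.
* ML/Bayesian inference, rate heterogeneity and model selection are out
  of scope; JC69+NJ is a documented simplification.
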