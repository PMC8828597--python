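# Methods

## Model and assumptions

The analysis treats a set of tissues/fluids as a fixed, undirected,
connected network of "lipid stations". The bundled adult-mouse preset is a
star: liver—serum plus serum—{right brain, cerebellum, heart, adipose},
with liver declared as biosynthetic origin and serum as transport hub; a
neonate preset uses whole brain and omits adipose. Topology is fully
user-configurable (compartment list + edge list in the run config), and
CNS sub-compartments are deliberately *not* connected to each other in the
presets — nothing in the model requires or forbids it, so the conservative
choice is no edge.

Inputs are wide per-compartment, per-group abundance matrices (samples ×
lipid variables, non-negative intensities) from direct-infusion MS, with
variables named in shorthand species nomenclature `CLASS(C:D)`. The
analysis is presence-based and descriptive: it assumes the upstream
normalisation made intensities comparable within a table, and it never
fits a statistical model to the intensities.

## Presence rule

A variable is present in a compartment for a group when
`(# samples with value > 0) / (# samples) >= threshold`, default 0.66.
The threshold is applied literally as a fraction (so 33/50 = 0.66 passes)
rather than as 2/3. Presence is computed per group, the only reading that
yields group-specific binary lists. Missing cells count as non-detection
(zero), the convention of DIMS exports; `strict_missing=True` rejects them
instead. Presence is monotone in the threshold and invariant to positive
rescaling; both are property-tested.

## Traffic categories

Per phenotype, every present variable receives exactly one category:
A (all compartments), U (exactly one), B (≥ 2 but not all, with at least
one adjacent pair among the presence compartments), other-shared (≥ 2
non-adjacent compartments). The four categories partition the present
variables; classification is checked against direct enumeration of every
presence subset of the six-compartment network.

Two genuinely open choices, both exposed as switches:

* Variables in > 2 compartments with an adjacent pair default to B with
  *all* sharing edges reported; `strict_pairs_only=True` restricts B to
  exactly-two-compartment patterns.
* The uni-/bidirectional label on B-types: with a declared origin, sharing
  confined to edges whose endpoints differ in hop-distance from the origin
  is labelled unidirectional (consistent with outbound traffic), otherwise
  bidirectional. The label is interpretive and never affects counts.

TG-derived glyceride assessment: for each present DG (MG), candidate TG
parents are all compositions `child + one (two) fatty acids` drawn from a
pool, default even-chain 14:0–22:6 as commonly observed in mouse;
observed parents are the candidates present in the same compartment. The
composition arithmetic (carbons and double bonds add) is the whole model;
sn-positions and acyl identities are out of scope.

## Switch Analysis

Two phenotypes' lists in a scope are aligned over the canonical ordering
of their union (class vocabulary order, then carbons, then double bonds,
then raw name — a deterministic total order). J = |∩|/|∪|. The p-value
uses a fixed-margins null: both lists placed uniformly at random over the
aligned universe with their sizes fixed, under which the intersection size
K is hypergeometric; since J is strictly increasing in K at fixed margins,
p = P(J ≤ J_obs) = P(K ≤ k_obs), computed exactly (the hypergeometric CDF
is the finite summation over feasible intersection sizes). This null
reproduces the documented limiting behaviours — disjoint lists of
substantial size give p ≈ 0, near-coincident lists give large p — and is
verified against exhaustive enumeration of all fixed-size subset
placements for every universe size up to 12. The null universe is the
class-scoped aligned list, not the whole lipidome. Reported tables round J
and p to 2 d.p.; full precision is kept on the result objects. No
multiple-testing correction is applied across scopes.

## Abundance Analysis

margin change = x̄_E − x̄_C (intensity units);
ENFC = log10(x̄_E/x̄_C) / sqrt((a² + b²)/2), dimensionless. The relative
errors a, b default to coefficients of variation (sample SD with ddof=1
over the mean) — the only dimensionless spread that keeps the denominator
commensurate with a log ratio and ENFC invariant under common rescaling;
`error_model="sem"` substitutes SEM/mean. ENFC is undefined (reported
missing with a reason, never silently dropped) when either mean is ≤ 0 or
both errors are 0. The control group is always the denominator.

Pre-steps, both default-on and configurable: per-mille normalisation of
each sample row (relative abundance), and exclusion of variables failing
the presence call in either group (avoids ratios of noise). ENFC
antisymmetry, zero-at-equal-means and scale invariance are verified
exhaustively over a grid of means {0.1, 1, 10} × CVs {0.1, 0.3, 0.5}.

SUSP datasets pair the per-variable ENFC of two comparisons in one
compartment; variables with a defined ENFC in both comparisons are shared
points, the rest are unique to their side, and the three sets partition
the variables with any defined ENFC. Rendering (scatter + axis rugs, SVG)
is a presentation choice; the CSV export is layout-independent.

## Synthetic data generator

The generator emulates a four-group DIMS study. Per lipid class and
category it plants a core of variables shared by all groups plus
per-group extras, which fixes every pairwise between-group overlap to the
core size by construction (a counts-plus-overlap constructor validates
feasibility). Planted A variables are positive in all compartments, U in
one, B on one edge's endpoints, other-shared on a non-adjacent pair; all
tables of an ionisation mode share one column panel and absent cells are
exact zeros, matching the strictly-positive presence rule. Intensities
are lognormal with a per-variable CV drawn from 0.1–0.5 (typical DIMS
dispersion) around a per-(variable, compartment) base mean shared by all
groups, so unit effect sizes give ENFC ≈ 0; per-group (optionally
per-class) multiplicative effects shift means; a dropout rate zeroes
individual cells. All randomness flows from one explicit seed.

The default design's A-type TG and PC core/extra counts reproduce the
worked-example list sizes and overlaps (TG 29:35 sharing 28, PC 32:23
sharing 21); the other categories and classes are set to magnitudes
typical of a ~500-variable panel. Default 8 samples per group (a typical
mouse cohort); the test suite and acceptance script generate at 3–4
samples per group, which is sufficient because recovery at dropout 0 is
exact for any sample count.

What the generator does *not* emulate: correlated variables, censored
low-signal noise (absences are exact zeros), batch effects, isotope
overlap, or class-dependent ionisation efficiency. Passing round-trip
tests therefore shows the pipeline's logic is correct, not that real-data
presence calls are noise-free; on real data the 66 % rule is the noise
control.

## Numerical and degenerate-input choices

Empty universe → J and p raise (undefined similarity) rather than return
a sentinel; empty scopes are omitted from reports. All-zero sample rows
stay zero under per-mille normalisation. Ordering ties fall back to the
raw header text so isomeric annotations never collide. CSV outputs are
byte-deterministic for fixed config and inputs; the run manifest (config
hash, package version, timestamp) is the only non-deterministic output.

## Known limitations

The exact original definition of the p-value's "order of the binary
list" statistic is not recoverable; the hypergeometric null is this
package's documented choice, isolated behind `jtc_p_value`. Ionisation
mode is carried as metadata (TGs from positive-mode, PCs from
negative-mode tables by convention) but the package does not deduplicate
variables measured in both modes. Flux direction and magnitude are out of
scope; B-type direction labels are interpretive only.
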