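# Methods

This note records the models implemented in `fps`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
generators do and do not emulate.

## Dose–response model and protection factors

A residue's unoxidized fraction is modelled as a single exponential in
dose, `1 − F(d) = exp(−S·d)`, with `F = area_ox / (area_ox + area_unox)`
compiled from matched LC-MS peaks.  The protection factor is `PF = S / IR`
with `IR` the residue type's intrinsic hydroxy-radical reactivity; `logPF`
is base-10 by default (`log_base` switches it).  The shipped IR table
contains only the two published values on this scale (K = 2.2, D = 0.42);
other residue types must be supplied by the user — the package refuses to
guess, since IR scales differ between dosimetry conventions.

**Fitting.**  When every `F < 1` the fit is a weighted linear regression
through the origin in `ln(1 − F)` space — exact for a pure exponential and
stable on sparse dose grids.  With per-point standard errors available the
weights are `1/SE²` with the delta-method transform `SE[ln(1−F)] =
SE[F]/(1−F)`; otherwise uniform.  Saturated points (`F = 1`, log-space
undefined) trigger a nonlinear least-squares fit of the exponential itself,
seeded with the slope of the unsaturated points.  `S` is constrained
non-negative; its standard error comes from the weighted residual variance
(linear path) or the fit covariance (nonlinear path).  Technical replicates
are averaged per dose first, with `SE = SD/√n`.

**Matching.**  Identifications are matched to peaks within `rt_tol`
(default 0.5 min) and `mz_tol` (default 0.02 Th); both are flags, since
instrument resolutions vary.  All matched areas — co-eluting peaks, all
charge states — are summed.  The per-residue unoxidized denominator is the
unmodified-peptide area **plus** the oxidized areas of the peptide's other
residues: the oxidized fraction at site *i* must condition on that site
only, the standard footprinting convention.  An identification with no peak
at a dose invalidates that dose for the residues it informs rather than
silently contributing zero.  Residues never observed as an oxidation site
are reported as "not detected", not as `F = 0`.

## SASA and the Log(PF) calibration

SASA uses the Shrake–Rupley rolling-probe algorithm (probe 1.4 Å, 1000
Fibonacci points per atom, single-element van-der-Waals radii), summed over
sidechain heavy atoms (Cα for glycine) because hydroxy-radical chemistry
and the hydrogen-bond analysis are both sidechain phenomena;
`sidechain_only=False` gives whole-residue values.  Waters, ions and
hydrogens are excluded from the surface computation; occlusion by all
protein chains is included.  Altloc conflicts resolve to the
highest-occupancy conformer.

The calibration is ordinary least squares of `logPF` on SASA over a
user-supplied calibration list (in practice non-polar M/F/W/Y residues,
whose oxidation tracks bulk exposure).  The band is the pointwise
confidence interval **for the mean response** at the requested level
(default 95%): `ŷ(x) ± t·s·√(1/n + (x−x̄)²/Sxx)`.  A prediction-interval
mode exists (`prediction=True`) for classifying single new observations;
the mean-response band is the default because the classification boundary
is meant to demarcate the fitted relation itself.  A residue is
`anomalous_low` iff its `logPF` is strictly below the lower band at its
SASA.  Activation deltas are computed per shared residue index (so
engineered substitutions at a position compare positionally) as
`Δ = state_A − state_B`, with per-group mean ± SD (SD with `ddof=1`).

## Hydrogen-bond networks

Nodes are residue sidechains (one node per residue) and waters.  The
donor/acceptor atom set is enumerated per residue type (Arg NE/NH1/NH2,
Lys NZ, His ND1/NE2, Asp/Glu carboxylate O, Asn/Gln amide N/O, Ser/Thr/Tyr
hydroxyl O, Trp NE1, Cys SG, water O).  An edge joins two nodes when any
atom pair is within `d_max` (default 3.5 Å); parallel atom contacts
collapse to one edge keeping the closest pair.  Crystal structures usually
lack hydrogens, so the 60° angle criterion applies only when hydrogen
positions exist in the file — distance-only behaviour is reproducible and
avoids guessing protonation.  Model 1 only for multi-model files.

Betweenness is the raw (unnormalized) shortest-path count of the standard
definition, computed with unit edge weights; disconnected pairs contribute
zero and a normalized option exists for cross-graph comparison.  Waters
with no partner inside the cutoff are absent from the graph but still
counted by `count_waters`, which assigns each water to the chain of its
nearest protein atom when a per-chain count is requested.  Group statistics
report mean ± SD of centrality per label; the detected/undetected ratio
propagates the two group-mean standard errors, and the merged-network mode
reports mean ± SD of per-structure ratios.

## Contact frustration

Contacts are residue pairs with sidechain-centroid distance ≤ 6.5 Å and
sequence separation ≥ 2.  The burial classifier counts residue centroids
within 6.5 Å of the contact midpoint: ≥ 6 neighbors → `direct`, fewer →
`water_mediated` (an exposed environment leaves room for bridging water);
contacts beyond the direct cutoff but within an optional longer reach are
`long`.  The neighbor threshold is a package default chosen to separate a
fully ringed contact from an isolated surface pair; no published value
exists for it.

The frustration index z-scores the native pair energy against decoys that
re-draw both residue identities uniformly over the 20 amino acids with
geometry fixed; the denominator is the population SD of the decoy set.
Exhaustive mode enumerates all 400 ordered identity pairs and is
seed-independent; sampled mode requires ≥ 100 decoys and a seed.  Under
this sign convention positive indices are energetically stressed contacts
(note the widely used frustration index has the opposite sign; the
classification defaults `hi = 0.78`, `lo = −1.0` are the conventional
magnitudes transposed to this convention and are configuration, not
measurements).  The default pair potential —
`E(a,b) = −h_a·h_b/10 + q_a·q_b` on the Kyte–Doolittle hydropathy scale
with unit charges for D/E/K/R and 0.5 for His — is a deliberately simple,
fully documented stand-alone choice; the potential argument accepts any
callable over ordered type pairs, and because the index is a z-score all
results are invariant under affine rescaling of the potential, which the
tests enforce.

## Real-valued evolutionary trace

Column entropy is Shannon entropy in nats over the 20 amino acids; gaps
are excluded from the counts, an all-gap column is reported missing, and an
all-gap group contributes zero.  The tree is cut into successive
partitions by opening internal nodes root-first (ordered by distance from
the root, ties by smallest descendant leaf label; a node only after its
parent), giving 1 … N−1 groups on binary trees.  The score is

    rvET_i = 1 + Σ_partitions w_node(n) Σ_groups w_group(n) · s_i(group)

with both weights defaulting to `1/n` for a partition of `n` groups (both
are pluggable callables).  Invariant columns score exactly 1; scores never
fall below 1.  Ranking takes the `floor(f·ncols)` lowest scores, ties
broken by lower column index.  Branch substitutions use Fitch small
parsimony — at multifurcations the states shared by the most children are
kept, which reduces to intersection-else-union on binary nodes — with
deterministic tie resolution (alphabetically smallest state) on the
top-down pass.  When no tree is given, a neighbor-joining tree from
p-distances is built as a convenience; it is a generic reconstruction, not
a curated phylogeny.

## Synthetic data

The generators produce every input format the toolkit reads, with a truth
table alongside; identical parameters and seed give byte-identical files
(canonical row order, fixed float format).

* **Dose series** emulate a titration at 8 dose points
  (0–2 dose units, geometric-ish spacing chosen to resolve decay rates
  across two orders of magnitude of PF), total ion current 1000 area units
  per dose split between the oxidized and unoxidized form, Gaussian area
  noise of `sigma × 1000` (default sigma 0.02, a few-percent area error
  typical of integrated LC-MS peaks), areas clipped at zero.  Each planted
  residue gets its own peptide with distinct RT and m/z; the oxidized form
  is shifted +15.9949/z Th.
* **Toy structures** place residues and waters at explicit coordinates:
  a Ser–water–Asp bridge, a serine hub with up to six octahedrally placed
  waters (waters 3.0 Å from the hub, > 3.5 Å from each other, so the
  hydrogen-bond graph is an exact star), a buried-vs-surface contact pair
  at equal distance, and small SASA test articles.  Plans that put atoms of
  different residues closer than 1 Å are rejected.
* **Alignments** hit per-column entropy targets by solving a one-vs-rest
  composition family for the mixing parameter and assigning integer counts
  by largest remainder, then shuffling the assignment across sequences
  (seeded); realized entropy is within 0.05 nats of target at 200
  sequences.  Clade columns fix one residue per half of the leaf order,
  which under the balanced tree makes the column change state on exactly
  the root edge.  Trees are balanced-binary or star with unit branch
  lengths.

What the generators do **not** emulate: chromatographic peak-shape
artifacts, isotope envelopes and charge-state interference; crystallographic
refinement noise, altlocs and partial occupancies; realistic amino-acid
substitution processes (columns are i.i.d. given the plan, except clade
columns).  Tests passing on these fixtures therefore validate the
algorithms and their contracts, not instrument- or crystal-specific
robustness.

## Problem sizes and tolerances

Parameter-recovery checks use 200 replicates per condition over
PF ∈ {0.1, 1, 10} at sigma 0.02 (median relative error < 5%).  Betweenness
is verified exactly against exhaustive path enumeration on 50 random graphs
of ≤ 8 nodes; SASA against a 10⁵-point Monte-Carlo surface sampler within
3%; sampled decoy frustration against exhaustive enumeration within 3
delta-method standard errors (`SE(z) = √((1+z²/2)/n)`); OLS slope CI
coverage over 1000 replicates against a 93% floor.  Exact-arithmetic
checks (entropy closed forms, rvET = 1 on invariant columns, Fitch counts
vs exhaustive parsimony) use tolerances at machine precision.

## Known limitations

* The default contact potential is qualitative; quantitative frustration
  work should supply a statistical contact-energy table via the
  `potential` argument.
* Hydrogen-bond detection is distance-based on heavy atoms unless the
  structure is protonated; no geometry-aware donor typing is attempted.
* `PF = S/IR` rises with oxidation rate as defined; users comparing with
  literature using the inverse convention (`IR/S`) should negate `logPF`.
* The rvET grouping convention (root-first node opening) is one of several
  used in the evolutionary-trace literature; scores are comparable within
  a run, not across tools.
* Water assignment to chains is by nearest protein atom, with no symmetry
  expansion of the crystal lattice.
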