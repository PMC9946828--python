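# Methods

This note documents the models and procedures implemented in `famhal`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions.

## 1. Geometry and discretization

Every residue pair (i, j) is described by six features computed from
backbone atoms plus Cβ: the Cβᵢ–Cβⱼ distance d; the dihedral
ω = (Cαᵢ, Cβᵢ, Cβⱼ, Cαⱼ); the directional dihedrals
θ→ = (Nᵢ, Cαᵢ, Cβᵢ, Cβⱼ) and θ← (i, j swapped); and the directional
planar angles φ→ = (Cαᵢ, Cβᵢ, Cβⱼ) and φ←.  This is the standard
distogram coordinate system of trRosetta-style predictors, adopted
because the framework's oracle contract is written for exactly such
networks.  Dihedrals follow the IUPAC sign convention (verified against
Biopython and mdtraj) and are reported in (−180°, 180°], planar angles
in [0°, 180°], all interfaces in degrees.

Virtual Cβ atoms (always for glycine, and whenever a Cβ is missing) are
placed from N/Cα/C with ideal internal coordinates Cα–Cβ 1.522 Å,
N–Cα–Cβ 110.4°, C–N–Cα–Cβ −122.5° — the conventional ideal-geometry
values.

The default `BinSpec` has 36 distance bins of 0.5 Å over [2 Å, 20 Å),
24 bins of 15° for ω and θ, 12 bins of 15° for φ, mirroring the common
distogram discretization; it is fully configurable because published
restraint sets do not always state their binning.  Each channel carries
one extra *no-contact* bin: pairs with d ≥ 20 Å occupy it in every
channel, so "these residues are apart" is itself an observable state
rather than missing data.  Binning is half-open [lower, upper), with
+180° assigned to the last angular bin and sub-2 Å distances clamped
into bin 0 (they do not occur in plausible backbones).

## 2. Family restraints and region classification

Given a family alignment, columns with gap fraction ≤ 0.3 are
*conserved*; conserved runs shorter than 3 columns are demoted to
*variable*.  Both thresholds are configurable: families differ in how
cleanly loops align, and no single rule is canonical.  Variable
segments receive loop-length bounds (observed minimum − 1, observed
maximum + 1), clamped at zero — one residue of slack beyond what the
family exhibits.

Restraints are stored per *alignment-column* pair, not per residue
pair, so insertions and deletions in loops never invalidate them.  For
each unordered conserved-column pair and channel, the observed bins of
all members in which both columns are resolved are counted, a
pseudocount ε is added to every bin, and the histogram normalized.
ε defaults to 1/K (K = bins in the channel), a Laplace-flavoured choice
that keeps every KL and cross-entropy term finite while washing out
under even a handful of observations.  Pooling histograms (rather than
fitting smoothed densities) is the simplest estimator consistent with
the categorical loss space; with ε = 0 and a single member the profile
degenerates to one-hot, which the tests exploit.

Only conserved–conserved pairs enter the profile.  Pairs touching a
variable column belong to the confidence term's domain.

## 3. Predictor contract, surrogate and background

A predictor maps a sequence to normalized categorical distributions
over the bins for every ordered residue pair, deterministically.  Real
networks are expected to be wrapped as registered adapters; their d and
ω channels are symmetrized by averaging if needed.  No network
inference is part of this package.

The shipped surrogate interpolates between a family template and an
uninformative distribution:

    P_ij = s · onehot(template geometry at mapped pair) + (1 − s) · U
    s    = logistic(κ · mean per-position compatibility)

where U is uniform and the compatibility of a query position is a score
table entry for the amino acid at the mapped template position
(unmapped positions contribute 0).  Conserved segments map 1:1 to the
template; loop residues map proportionally into the template loop;
loops longer than the template's are left unmapped so their pairs stay
uninformative.  Using the *uniform* distribution as the diffuse
component (rather than the empirical background) avoids circularity,
because the background is itself defined over predictor outputs.

The background is operational: the mean prediction over uniformly
random sequences (default 100) of the given lengths, pooled over all
pairs per channel, floored at 1e-8 and renormalized.  Optional
stratification by sequence-separation bands (|i−j| < 6, 6–11, ≥ 12) is
available but off by default; whether published backgrounds stratify is
ambiguous, and the toggle records that ambiguity.

## 4. The loss

* **Restraint term**: channel-weighted mean over conserved pairs of the
  cross-entropy −Σ_b R_b ln P_b (prediction floored at 1e-8).
  Cross-entropy rather than KL(R‖P): the two differ by the entropy of
  the fixed profile, so minimizer and move deltas are identical and the
  reported value is cheaper and monotone in the same sense.
* **Confidence term**: −(mean over variable pairs of KL(P ‖ B)).  The
  direction is prediction-against-background — confidence is how far
  the prediction has moved *away* from the average — and minimizing the
  total maximizes that divergence.
* Total = w_r · restraint + w_c · confidence, defaults w_r = w_c = 1,
  channel weights 1, all in nats.  No relative weighting is asserted as
  canonical; they are config.

Both terms are *means*, not sums, over their pair sets.  This is a
deliberate bias-removal choice: insertion/deletion moves change pair
counts, and sums would let the sampler shrink loops merely to shrink
the loss scale.

## 5. The sampler

Moves: substitution (uniform non-frozen position, uniform different
letter), insertion (uniform non-maxed loop, uniform slot, uniform
letter) and deletion (uniform non-minimal loop, uniform position), with
kind probabilities (0.85, 0.075, 0.075) renormalized over the currently
legal kinds.  Conserved positions keep their alignment columns across
indels; frozen positions — the stand-in for designed hydrogen-bond
networks that must survive design — are addressed by column and never
mutated.  Acceptance is Metropolis, min(1, exp(−ΔL/T)).

The default schedule is geometric, T = 0.02 → 0.0002 over 2,000 steps.
The scale is set relative to the loss: a single conserved-position
mismatch in the planted toy problem changes the total loss by ≈ 0.045
nats, so T starts at about half that magnitude (bad moves are accepted
often enough to escape local arrangements early) and ends two orders of
magnitude below it (the end of the run is effectively greedy).  A
temperature protocol only means anything relative to typical ΔL, which
is oracle-dependent; all schedule parameters are config.

One predictor call is made per proposal, with a cache keyed by
(sequence, loop lengths) to absorb re-proposals.  All randomness flows
through one seeded generator in a fixed draw order (kind, move draws,
then the acceptance uniform only for uphill moves), so trajectories are
byte-reproducible given (seed, config, inputs).  The best state is the
first iteration achieving the minimal total.

## 6. Synthetic data: what it emulates and what it does not

`make_toy_family` builds members as torsion-space chains (helix
−57/−47, strand −139/135, loop −75/145, ideal bond geometry) sharing
conserved segments, with loop lengths drawn per member and Gaussian
coordinate jitter (default 0.05 Å) on all atoms.  The emitted alignment
encodes the loop-length differences exactly as gaps.  This captures the
*structure* of the problem — conserved segments with consistent
pairwise geometry, loops of variable length, an alignment coupling
members to columns — but not real-family properties: no compact
tertiary packing or hydrophobic core, no realistic loop conformations,
no alignment errors, no structural divergence beyond jitter, and
jitter breaks exact bond geometry (harmless to the pairwise features
it feeds).  Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted optima, not that the defaults
would hallucinate well against a real predictor on a real family.

The planted problems (18-mer conserved region: helix 10 + loop 2–4 +
strand 8, six members) use compatibility scores +1 at the planted
letter, −1 otherwise, 0 on loop positions, with κ = 3.  These values
were chosen analytically: the planted optimum's mixture coefficient
s ≈ 0.93 stays below the regime where the restraint term's −ln(1 − s)
growth on loop-length-split pairs would overtake the confidence gain,
so the planted sequence is genuinely the loss minimizer (the
constructor verifies this against 1,000 random sequences and raises
otherwise).

The *synthetic design model* (117 residues, Arg65, a DTZ-named hetero
group with N1 exactly 4.2 Å from Arg65 CZ, chain mass 13.9 kDa at
3 s.f.) is a stand-in for inspecting a real luciferase design model;
every one of those properties is a construction input.  Inspecting it
validates the utilities (parsing, mass bookkeeping, selections,
distances), nothing about any deposited structure.  The "centre of the
arginine guanidinium" is taken as the CZ atom, which is the centroid of
the three guanidinium nitrogens by construction.

## 7. Numerical conventions and edge cases

* Coordinates in Å; user-facing residue numbers 1-based (PDB
  convention); internal indices 0-based half-open.
* Altloc policy: highest occupancy, ties alphabetical; residues ordered
  by (number, insertion code).
* Chain mass: average-isotopic residue masses plus one water; kDa
  reported to 3 significant figures.
* KL: q floored at 1e-8 and renormalized; 0·ln 0 = 0; p may contain
  exact zeros (one-hot profiles are common).
* Empty variable-pair sets give confidence 0 with a logged notice.
* Profile files are versioned JSON; bin-count mismatches and unknown
  versions are distinct errors.

## 8. Problem sizes

The default test and acceptance workloads use 6-member families of
19–22 residues, 2,000-step anneals over 20 seeds, 10⁵-draw binomial
contract checks and a 60,000-step fixed-temperature chain on the
enumerable 2×2 sequence space.  These sizes give the statistical
checks 3σ–4σ headroom while keeping a full run around a minute.

## 9. Known limitations

* The surrogate's loop mapping distributes length changes across
  multiple loops proportionally by template loop length; with several
  loops its position mapping can disagree with the sampler's actual
  loop assignment for the same total length.  Single-loop toys avoid
  this; a real-network adapter would not have the issue (it sees only
  the sequence).
* Restraint pooling treats members as independent observations; no
  redundancy weighting.
* `classify_regions` is gap-fraction-only; columns that are gap-free
  but structurally divergent still classify conserved (families should
  be curated upstream, or the truth annotation supplied directly).
* PDB output is minimal (ATOM/HETATM/TER/END, single chain, no altlocs
  or anisotropic records); mmCIF is out of scope.
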