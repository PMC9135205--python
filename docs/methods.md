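# Methods

## The model in brief

phagevolve treats a small linear phage genome as a *parameter file*, not a
nucleotide sequence: an ordered set of protein-coding genes plus point
regulatory elements (promoters, terminators, RNase cleavage sites) placed
in the regulatory regions between genes, each with a continuous strength.
The simulator maps this genotype to a stochastic transcript time-course;
the evolutionary engine searches genotype space for architectures whose
time-courses match a user-supplied target.

## Genome geometry

A genome with *M* genes has *M* + 1 regulatory regions of `spacer_length`
(default 50) nt: region 0 upstream of gene 1, region *i* between genes *i*
and *i* + 1, region *M* downstream of the last gene. Coordinates are
1-based and inclusive, derived deterministically from gene lengths and the
spacer; there is a single strand and transcription runs left to right only.
Elements are points that consume no sequence. Within a region they sit at
fixed fractions of the spacer — terminator at 0.2, promoter at 0.5,
cleavage site at 0.8 — so a terminator stops transcripts arriving from
upstream *before* the co-located promoter, and the cleavage site lies
inside transcripts initiated at that promoter. This ordering is what makes
the promoter–terminator and promoter–cleavage-site co-occurrence motifs
expressible. At most one element of each kind may occupy a region.
Promoters and cleavage sites in the final region are legal but effectively
inert (transcripts initiated there contain no gene); a terminator there
merely shortens full-length transcripts by part of a spacer.

The canonical starting genotype for evolution is *M* genes with a single
promoter in region 0 at the insertion-default strength 10⁶ (exposed as an
argument for exploring other moderate starting strengths).

## The expression simulator

The simulator is an exact-in-distribution discrete-event engine over the
union of binding, elongation, termination, cleavage and degradation
processes, tracking every polymerase and every transcript molecule
individually.

Kinetic parameters (all configurable; defaults in parentheses):

- `n_polymerases` (4): fixed pool of host polymerases; they never degrade.
- `pol_footprint` (35 nt): exclusion length on the template. The 30 nt
  ribosome footprint is reserved for the translation hook (below).
- `pol_speed` (40 nt/s): mean elongation rate per nucleotide.
- `binding_scale` (2.5 × 10⁻⁸ per strength·molecule·s): converts promoter
  strength × free-polymerase count into a binding propensity. With the
  default promoter strength 10⁶ and 4 free polymerases this gives a 0.1/s
  initiation propensity per promoter.
- `k_deg_nascent` (10⁻⁵/s): degradation-initiation propensity at an
  original (nascent) 5' end; `deg_fold` (1000) multiplies it at cleaved
  ends; `deg_speed` (20 nt/s) is the exonuclease front speed.
- `horizon` (300 s) and `sample_interval` (5 s): the simulated five-minute
  infection and the sampling grid shared with targets.

The upstream simulation platform this model is patterned after does not
publish all of its internal rate constants, so these defaults are this
package's own calibration, chosen to put a three-gene genome with default
element strengths in the regime of tens of transcripts per gene within the
five-minute horizon. No numerical parity with any other simulator is
claimed; the mechanistic contract (propensity forms, footprints, the
1000-fold cleaved-end acceleration, whole-genome availability from t = 0)
is the specification.

Mechanics:

- **Binding.** Each promoter's waiting time is exponential with propensity
  `strength × free × binding_scale`, redrawn whenever the free count
  changes (exact, by memorylessness). A binding attempt on an occluded
  promoter (any polymerase footprint within 35 nt) is rejected and
  redrawn — standard thinning. To bound event counts for very strong
  promoters the retry wait has a floor of half a footprint-transit time
  (≈ 0.44 s); this only delays binding after clearance by a fraction of the
  occlusion window itself.
- **Elongation.** Per-nucleotide exponential steps at `pol_speed` are
  batched: the jump to the next landmark (element position, gene end,
  genome end, or the exclusion boundary behind the leading polymerase) is
  drawn as an Erlang (gamma) waiting time, which is exactly the sum of the
  per-nucleotide steps. A polymerase whose landmark is the exclusion
  boundary blocks there and is replanned when the leader moves. When a new
  polymerase binds just downstream of one in mid-jump, the upstream jump is
  truncated and redrawn from its last committed position — a conservative
  rewind that can only briefly slow a polymerase reading through an
  internal promoter region.
- **Termination.** Crossing a terminator resolves a single Bernoulli draw
  with success probability equal to the terminator strength (not a rate):
  release or read-through, once per passage.
- **Cleavage.** Every transcribed, intact site on any molecule (nascent or
  released) carries an exponential clock with propensity equal to its
  strength. Firing splits the molecule at the site; the downstream
  fragment keeps the polymerase (if still attached), acquires a cleaved 5'
  end and a fresh degradation clock at `deg_fold × k_deg_nascent`;
  remaining site clocks are redrawn (exact, memoryless). The fired site is
  consumed.
- **Degradation.** Once initiated at a 5' end, the front advances
  deterministically at `deg_speed`, destroying a coding sequence when it
  reaches its first nucleotide and cleavage sites as it passes; the
  molecule dies when the front passes its 3' end. The front can never
  overtake a polymerase at default speeds (20 < 40 nt/s); if configured
  otherwise, destruction of a not-yet-finished gene is still handled
  correctly (the gene never counts).
- **Counting.** Gene *k*'s count at a sample time is the number of
  molecules whose copy of gene *k* is fully transcribed and not yet
  destroyed, whether or not the molecule is released. Counting nascent
  full-length copies is a deliberate choice; partially transcribed genes
  never count.

With a fixed seed the trajectory is bit-reproducible: a single generator
drives all draws and simultaneous events are ordered by scheduling
sequence. Replicate means use seeds spawned deterministically from a
master seed.

Translation is a disabled no-op hook: the model carries the ribosome
footprint parameter but analyses transcript abundances only.

## Fitness and the design criterion

The distance between a simulated time-course *y* and a target *Y* on a
shared grid of *T* times and *M* genes is

    RMSE_k    = sqrt( Σ_t [y_k(t) − Y_k(t)]² / T )
    RMSE_norm = Σ_k RMSE_k / (M · Ȳ_k)

with each gene's RMSE divided by *M* times that gene's mean target
abundance — implemented exactly in this per-gene-normalized form, which
makes the distance invariant under joint rescaling of both time-courses
and requires every Ȳ_k > 0 (target generators enforce this). A design is
*successful* when RMSE_norm ≤ 0.1, threshold inclusive.

Three fitness maps are provided: Fermi `1/[exp(βr) + 1]` (the default;
f = 1/2 at r = 0), exponential `exp(−βr)`, and linear `−βr`. For the
linear map, whose values are non-positive, the origin–fixation ratio is
formed after adding a configurable positive offset (default 2) — a
package-level decision, since the ratio rule is otherwise undefined there;
the shift is monotone and preserves the acceptance ordering.

## The evolutionary engine

One mutation is proposed *every* generation, drawn uniformly from the
complete enumeration: one *add* per empty (kind, region) slot (at the
kind's insertion default), one *remove* and one *modify* per existing
element. Modify multiplies the strength by a Normal(1, 0.1) draw, redrawn
until the product is in bounds (only the multiplier is redrawn, not the
action or slot). Mutant genotypes are evaluated as the element-wise mean
of `replicates` (default 10) independently seeded simulations; the
resident's cached evaluation is reused by default (re-evaluating it each
generation is available as an option). Acceptance follows the
origin–fixation rule with Ne = 1000 and one uniform draw per generation,
consumed even when acceptance is certain, so trajectories are reproducible
draw-for-draw.

The annealing schedule keeps β = 10⁻³ for the first tenth of the run
(nearly neutral exploration), rises linearly to 1.1 over the middle eight
tenths, and to 1.3 over the final tenth; run lengths other than 5000
generations scale the phase boundaries proportionally. The returned state
carries both the final resident and the best-ever genotype (lowest
evaluated RMSE_norm seen); reporting favours the best-ever value, with the
resident also available since either reading of "final pattern" can be
wanted.

## Arrangement search, pruning, diversity

- **Arrangements.** All *M*! assignments of genome genes to target genes
  are enumerated in lexicographic order and each is evolved independently;
  the assignment minimizing the mean final RMSE_norm across its replicate
  runs wins, ties broken by enumeration order. Beyond 5 genes the
  factorial enumeration must be explicitly opted into; a fixed order is
  the practical choice there.
- **Pruning.** Starting from a successful genome, each element's removal is
  evaluated (fresh derived seeds, replicate mean); removals that keep
  RMSE_norm ≤ 0.1 are candidates and the one with the smallest
  post-removal distance is applied, repeating to a fixed point. "Least
  impact" is read as smallest post-removal distance; smallest *change* in
  distance is available as `criterion="delta_rmse"`. Ties break by
  (region, kind). The greedy procedure deliberately ignores epistasis.
  Near the 0.1 boundary, pruning decisions inherit evaluation noise; the
  guarantees (success of the pruned genome, idempotence) hold under the
  run's own seed policy.
- **Diversity.** Successful, pruned genomes are reduced to fingerprints —
  the sorted set of (kind, region) pairs, strengths ignored — and the
  census of fingerprint counts is summarised by Shannon entropy in bits
  (scipy's entropy with base 2). H bits ≈ 2^H effectively distinct
  architectures.

## Synthetic targets: what they do and do not cover

Target generators produce linear ramps, ramp-then-plateau curves (the
signature of a production/degradation steady state) and cross-over
patterns, plus a positive control obtained by simulating a known
architecture — the one class of target guaranteed to have an exact
solution. Ten named presets approximate the qualitative shapes studied
with this method; they are parametric stand-ins, not measured data, and
are sized for the tens-of-transcripts regime of the default kinetics.
Decreasing or oscillatory abundances are deliberately out of scope: the
regulatory vocabulary here cannot shut genes off. Passing tests on these
targets demonstrates the design loop works where solutions exist and has
the documented qualitative behaviour (plateaus need cleavage sites;
terminators attenuate downstream genes); it does not establish that any
particular real phage pattern is reachable, nor calibrate rate constants
against experimental data.

## Problem sizes and numerical choices

The full-scale experiment this method supports (50 replicate runs × 5000
generations × 10 simulations per evaluation, per pattern and arrangement)
is cluster-scale. The test suite and the acceptance script instead
exercise the identical code paths at desk scale, the package's chosen
reference conditions: the positive-control loop runs 1000 generations with
3 replicates per evaluation and 3 run seeds (~5 s per run), which reliably
reaches the ≤ 0.1 success criterion on the control target; property checks
use 50–100-replicate means, and the analytic birth-process check uses a
deliberately weak-binding configuration (4000 short simulations) so that
polymerase-pool depletion and promoter occlusion are negligible relative
to Monte-Carlo error.

Numerical details worth knowing: simultaneous heap events resolve in
scheduling order (deterministic); the occluded-binding retry floor is
`pol_footprint / (2 · pol_speed)`; degradation-initiation clocks far
beyond the horizon are scheduled and never fire (cheap, exact); replicate
averaging can make counts fractional; evaluations near the success
threshold are noisy at small replicate counts — the replicate-mean noise
floor for the default 3-gene regime sits around 0.05–0.1 RMSE_norm with
3-replicate evaluations, which is why best-ever values below the
threshold, rather than every evaluation, define success at desk scale.

## Known limitations

- No translation/protein dynamics, no ribosome traffic, no host-resource
  competition beyond the fixed polymerase pool, no phage-encoded
  polymerases.
- No nucleotide sequences: element strengths are abstract rate constants;
  mapping a design onto standardized parts is outside the model.
- Genes cannot overlap or reorder during evolution (arrangement search
  relabels targets instead).
- The mean-strength modification kernel (Normal(1, 0.1)) makes very large
  strength excursions slow; multi-order-of-magnitude promoter retuning
  takes many accepted modifications.
- Exact parity with any external simulator's default kinetics is not
  claimed; conclusions are about the model as parameterised here.
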