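# phagevolve

Design tool for small phage-like genomes: given a target gene-expression
time-course, it evolves the *architecture* of a linear genome — the
placement and strengths of promoters, transcriptional terminators and RNase
cleavage sites — until stochastic simulations of the genome reproduce the
target. No regulatory proteins or feedback circuits are involved: all
dynamics come from the balance of transcription initiation, termination
read-through, transcript cleavage and directional degradation.

It is intended for computational/synthetic biologists exploring what
expression dynamics (ramps at different rates, plateaus, cross-overs in the
abundance ranking of genes) are reachable with this minimal regulatory
vocabulary, and which genome layouts realise them.

## Model

**Genotype.** A genome with *M* genes (150 nt each by default) has *M* + 1
regulatory regions (upstream of gene 1, between consecutive genes,
downstream of gene *M*). Each region holds at most one promoter, one
terminator and one cleavage site, in fixed 5'→3' order terminator →
promoter → RNase site. Strengths are bounded: promoters in [10⁵, 10¹³]
(insertion default 10⁶), terminators in [0, 1] (default 0.2, the
termination probability per passage), cleavage sites in [0, 1] (default
5 × 10⁻³, the per-second cleavage propensity once transcribed).

**Phenotype.** A discrete-event, single-molecule simulator tracks a pool of
4 host RNA polymerases (footprint 35 nt) over a 300 s infection: binding
with propensity `strength × free_pols × binding_scale`, elongation at
40 nt/s with footprint exclusion, Bernoulli termination at terminators,
stochastic cleavage of transcribed sites, and 5'→3' exonucleolytic
degradation that initiates 1000× faster at cleaved 5' ends than at nascent
ones and proceeds at 20 nt/s. The per-gene transcript count *y_k(t)* —
molecules whose coding sequence is fully transcribed and intact — is
sampled every 5 s.

**Objective.** Distance to the target *Y_k(t)* is a normalized RMSE,

    RMSE_k    = sqrt( Σ_t [y_k(t) − Y_k(t)]² / T )
    RMSE_norm = Σ_k RMSE_k / (M · Ȳ_k),    Ȳ_k = Σ_t Y_k(t) / T

with RMSE_norm ≤ 0.1 defining a successful design. Fitness is the Fermi
function `f = 1/[exp(β · RMSE_norm) + 1]` (exponential and linear declines
are also available).

**Search.** An origin–fixation loop: each generation proposes one mutation
drawn uniformly from the full enumeration (add an element to any empty
slot, remove or modify any existing one; modifications multiply the
strength by an in-bounds Normal(1, 0.1) draw), evaluates the mutant as the
mean of replicate simulations, and accepts with

    P_accept = 1              if f' ≥ f
             = (f'/f)^(2·Ne)  if f' < f,     Ne = 1000.

Selection strength β is annealed: 10⁻³ for the first 10% of generations,
linearly rising to 1.1 over the middle 80% and to 1.3 over the final 10%
(500 / 4000 / 500 for a 5000-generation run).

Post-processing: greedy pruning of elements whose removal keeps the design
successful, exhaustive gene-to-target arrangement search (*M*! assignments),
and the Shannon entropy `H = −Σ_i (n_i/n) log₂(n_i/n)` (bits) of the
pruned architecture fingerprints found by replicate runs.

## Worked example

`examples/evolve_to_target.py` evolves a genome from a single-promoter
start toward a target simulated from a known control architecture
(promoters in regions 0 and 1, terminators in regions 2 and 3, a cleavage
site in region 1):

```
generations: 600
acceptance rate: 0.13
final resident normalized RMSE: 0.0781
best-ever normalized RMSE:      0.0711 (success)

best architecture found:
  terminator  region 0  strength 0.2
  promoter    region 0  strength 1.11531e+06
  promoter    region 1  strength 862630
  rnase_site  region 1  strength 0.00478764
  ...
```

The best genome reproduces the target within 7% of mean target abundance
per gene — a success under the ≤ 0.1 criterion — and, as typically
happens, its architecture is similar but not identical to the one that
generated the target. The other example scripts show plain simulation
(`simulate_architecture.py`), pruning plus diversity entropy
(`prune_and_diversity.py`), and arrangement search
(`gene_arrangements.py`).

The same workflows are scriptable from a shell via the thin CLI:

```sh
phagevolve make-target --preset positive-control --out target.csv --seed 1
phagevolve evolve --target target.csv --out evolved.yaml --generations 1000 --seed 1
phagevolve prune --genome evolved.yaml --target target.csv --out minimal.yaml
```

Every command writes a `*.manifest.json` recording options, seeds and the
package version.

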