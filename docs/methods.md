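# Methods

`samdrift` simulates the evolution of gene regulatory networks (GRNs) that
pattern a two-dimensional model of the plant shoot apical meristem (SAM),
and provides the measurement tools used to study developmental system
drift (DSD): conservation of regulatory interactions along ancestral
lineages, functional-network pruning, interaction importance, network
divergence, robustness assays, and a generic analysis relating conserved
non-coding sequence (CNS) complements to organ-level expression.

## The model

### Genome and GRN

A genome is an ordered sequence of genes and transcription-factor binding
sites (TFBSs).  Each gene encodes one transcription factor (TF) of a fixed
type; each TFBS binds one TF type and regulates the nearest downstream
gene with a sign w ∈ {−1, +1} and a Hill constant H.  The 14 TF species
fall into functional classes: types 0–1 diffuse between cells; types 2–3
act on directly neighbouring cells only (receptor–ligand-like); types 8–9
are monomers that can heterodimerize into type 7, which itself cannot be
transcribed; types 4, 5, 6, 10, 11 are cell-autonomous; and types 12–13
are the fitness genes whose spatial pattern is under selection (12 for the
organizing centre, OC; 13 for the central zone, CZ).  The type-level GRN
of a genome is the set of (regulator, target, sign) triples; TFBS copy
numbers are retained separately for the quantitative adjacency variant.

### Tissue

Development runs on fixed 130-cell templates (40 cells in the desk
preset).  The domain is a parabolic dome y ∈ [0, h − 0.01 x²],
x ∈ [−61, 61], with h = 0.01·61² = 37.21 so the profile meets the base at
the domain edge.  (The printed form of the domain is degenerate at x = 0;
this canonicalization puts the apex at y ≈ 37.2, which places the zone
boxes below at the apex, where the figures show them.)  Cell centres start
as uniform random points, are spread by 500 overdamped steps of a spring
relaxation (springs of potential U = ½k(l − l_r)² between Delaunay
neighbours, recomputed each step; l_r defaults to √(domain area / n);
a constant-magnitude inward force of 10 returns escaped cells — the
boundary term's stated purpose is containment, so it is implemented as a
restoring penalty on the penetration depth), then regularized by 2000
Lloyd iterations of the Voronoi diagram.  Voronoi polygons are clipped to
the dome; areas A_c and shared-edge lengths ω_ck come from the clipped
polygons.  Zones are assigned by centroid-in-box tests (CZ: |x| < 15,
y > 28; CZ∩OC: |x| < 15, 24 ≤ y ≤ 28; OC: |x| < 15, 16 ≤ y ≤ 24), and the
epidermal L1 layer is the set of cells whose polygon has an edge on the
curved dome surface (the flat base is excluded by default).

### Development

Per cell c, mRNA of gene copy g and protein of TF species p follow the
chemical Langevin equations

    dG = (τ − αG) dt + √τ dW₁ − √(αG) dW₂
    dP = (υ − βP + s·L1 + (D_p/A_c) Σ_k ω_ck (P_k − P_c)) dt
         + √υ dW₃ − √(βP) dW₄

with translation rate υ = G (gene copies of the same product type sum into
one protein species), transcription rate τ = τ_max T²/(T² + 1) where
T = max(0, Σᵢ θᵢ) and each TFBS contributes θ = w P²/(P² + H²).  Cell–cell
TF types read the edge-length-weighted mean concentration of the
neighbours instead of the local one.  The heterodimer is assumed at
binding equilibrium: each step the monomer totals are partitioned by
solving (P₈ − d)(P₉ − d) = K_d d in closed form; free monomers bind
monomer TFBSs, the dimer concentration binds dimer TFBSs.  Development
starts from TF type 4 at concentration 100 in every cell, with TF type 0
produced constitutively at rate 10 in L1 cells, and runs to t = 500
(t = 100 in the desk preset).

Numerics: Euler–Maruyama with dt = 0.1 (0.2 desk).  The production and
decay Wiener increments are independent; per step their sum is realized
as one Gaussian with the summed variance, which is the same distribution
at a third of the random-number cost.  Concentrations are clamped at 0
after each step (they are physical).  Gaussians come from a 128-layer
ziggurat over an xorshift64* stream seeded per development — the
evolutionary experiments draw ~10⁹ variates, and this is an order of
magnitude faster than a library generator inside the compiled kernel.
The whole step loop is a single numba kernel; with noise off it reduces
to the deterministic Euler scheme, which the test suite checks against a
closed-form relaxation (1e-6) and an independent `solve_ivp` integration
of the same rate laws (1e-4 relative).

### Fitness and selection

At integer sample times in two windows ([201, 250] and [451, 500] at full
scale; [41, 50] and [91, 100] desk) each cell contributes

    CZ:    +100·Pcz/(Pcz+100) − 50·Poc/(Poc+200)
    CZ∩OC: + 50·Pcz/(Pcz+100) + 50·Poc/(Poc+100)
    OC:    +100·Poc/(Poc+100) − 50·Pcz/(Pcz+200)
    other: − 50·Poc/(Poc+200) − 50·Pcz/(Pcz+200)

with a saturation cap: if the zone-correct protein exceeds 400 the cell
contribution is exactly 100 (for overlap cells, either protein; the cap
is applied per time point, and the literal reading — the cap overrides
the misexpression penalty — is the default, with the positive-term-only
variant available as a configuration switch).  Total fitness is
F = max(0, Σ/(n_cells · n_samples)) ∈ [0, 100].  Note the zone boxes
cover a minority of the dome, and "other" cells can only lose points, so
the attainable maximum of F is 100 · n_zone/n_cells (≈ 20); reported
fitness values should be read on that scale.  Parents are drawn with
probability F_i/ΣF_j (uniformly when every fitness is 0, and in control
runs, which may also skip development entirely).

### Mutation

Each element receives at most one event per offspring: genes — deletion,
duplication, τ_max change, α change; TFBSs — deletion, duplication, H
change, sign flip, bound-type redraw.  Genome-level events: de novo TFBS
emergence (a fresh random TFBS at a uniform position), whole-genome
duplication (the element sequence is appended with a copy of itself; no
ploidy), and changes to the diffusion and dimer association/dissociation
constants.  Continuous parameters mutate by adding N(0, σ²) and clamping
to the parameter's bounds.  Every event record fully describes its edit,
so ancestral genomes are reconstructed by replaying events rather than
stored per generation.

### Parameter defaults

The quantitative parameter table of the original study conditions was not
available; the defaults below were chosen once on the stated grounds and
are all configurable.

| parameter | default | grounds |
|---|---|---|
| τ_max | 5, bounds [0, 10] | mRNA steady state τ/α ≈ 50, protein ≈ 500: spans the fitness half-saturations (100–200) and the cap (400) |
| α | 0.1, bounds [0.01, 1] | mRNA lifetime ~10 time units |
| β (fixed) | 0.1 | protein lifetime ~10; not mutable (only α is listed as mutable) |
| H | init/prior U[1, 500], σ = 25 | brackets the typical concentration scale |
| D (types 0, 1) | 1.0, bounds [0, 5] | gradient length of a few cell diameters |
| association / dissociation | 1 / 10 (K_d = 10) | appreciable but partial dimerization at ~10-unit monomer levels |
| L1 production | 10 (TF type 0) | L1 steady level s/β = 100 |
| initial condition | TF type 4 at 100 everywhere | the named classes are "one TF uniformly distributed" + "a diffusible TF in L1"; ids configurable |
| initial TFBSs per gene | uniform 0–2 | sparse initial wiring; the initialization distribution is exposed as configuration |
| per-element event rates | 1e-3 per class | keeps the majority of offspring mutation-free |
| TFBS deletion | 2e-3 | exceeds duplication so the neutral TFBS equilibrium, de_novo/(del − dup) = 25 sites, sits near the initial complement |
| de novo emergence | 2.5e-2 per offspring | the inflow of a 1e-3 per-element event at the initial genome size; a literal per-element insertion rate is self-amplifying (longer genomes spawn more insertions) and grows genomes exponentially |
| whole-genome duplication | 1e-4 per offspring | rare macro-mutation |

## Presets and problem sizes

`default` is the full-scale configuration (130-cell tissues, 1000
individuals, 50 000 generations, 1000 templates) — cluster-scale.
`control` removes selection ("random reproduction"), `noise_off` switches
the integrator to its deterministic limit, `reduced_grn` restricts the
gene complement to 2 diffusing + 2 cell–cell + 2 cell-autonomous + 2
fitness genes.

`desk` is the package's desktop-scale preset: 40-cell tissues, 100
individuals, development to t = 100 (dt 0.2, 20 fitness samples), a pool
of 8 templates, and per-event mutation probabilities ×10 (generation
compression ~50k → ~10³ keeps the mutation supply per unit of
evolutionary search comparable; whole-genome duplication is not scaled —
repeated doublings within a short run would distort the conditions).
The shipped experiments use desk-scale runs of 50–100 individuals and
600–800 generations with 3 seeds.  At this scale adaptation is
early-stage: selected runs reliably lift the best fitness an order of
magnitude above the generation-0 noise floor (a few points on the
0–100 scale), develop interactions conserved for hundreds of
generations (absent from matched controls), and show the
robustness/divergence signatures — but they do not approach the
fitness plateau that full-scale runs reach after tens of thousands of
generations.  Passing desk-scale tests therefore demonstrates the
machinery and the direction of every effect, not the asymptotic state.

## Analyses

* **Conservation**: for the ancestral line of the fittest final
  individual, maximal runs of consecutive presence of each type-level
  interaction; one generation of absence resets a run.  The conserved set
  uses a cutoff chosen from the matched control run's maximum
  conservation time (5000 generations at full scale).
* **Pruning**: greedy single-element deletion; each candidate is scored
  as mean fitness over 5 developments; the best deletion is accepted
  while it stays within 5 fitness points of the reference; ties break to
  the earliest genome position.
* **Importance**: I = (1/R) Σ (F₀ − F_r)/F₀ over R (default 500)
  developments with every TFBS copy realizing the interaction deleted;
  negative raw values (fitness gains) are clamped to [0, 1] for reporting
  and logged raw.
* **Divergence**: networks are rewritten as Boolean activating and
  inhibiting adjacency matrices (rows targets, columns regulators);
  d(X, Y) = Σ|X − Y| / Σ(X + Y) per sign (0 for two empty matrices), and
  div = the mean of the two — the most conservative, purely qualitative
  comparison.  Curves along clone lineages are reported as full-network
  vs common ancestor, conserved-set vs CA, and conserved-set between
  clones, with medians and IQRs across clones.
* **Robustness**: offspring of a focal genome generated by the standard
  mutation operator and developed once each, partitioned by whether any
  mutation was applied: the mutated partition probes mutational
  robustness (U-shaped when evolved), the unmutated one developmental
  robustness (tight).  The test suite summarizes shape with Sarle's
  bimodality coefficient (> 5/9 indicates bimodality).

## CNS / expression analysis

The rewiring analysis is generic over three delimited-text inputs: a CNS
table (cns_id, orthogroup, species, gene; one gene belongs to one
orthogroup, (cns_id, gene) unique), an expression matrix (genes × organs,
variance-stabilized counts), and a rooted newick species tree.  Presence
profiles tally, per orthogroup, how many CNSs show each species-presence
pattern; a pattern is flagged as a loss when it is not the leaf set of
any clade of the tree.  Gene pairs are compared by the Jaccard index of
their CNS sets — the similarity formula is not named in the source
analysis; Jaccard matches both stated anchor points (0 disjoint,
1 identical) and is the field default; two empty sets score 1 (logged) —
against the Pearson distance (1 − r) of their organ-expression vectors.
Ortholog/paralog labels are user input.  The synthetic generator builds
all three inputs with controlled overlap (family CNS pools with a shared
fraction and per-species losses) and controlled expression correlation
(equicorrelated Gaussian organ profiles plus noise), so the DSD
signature — disjoint CNS sets at low expression distance — can be
constructed on demand.  What the fixture does not emulate: realistic CNS
length/position metadata, phylogenetic correlation of losses, organ-level
mean-variance structure of counts; conclusions about real Conservatory /
RNA-seq data require the real tables, read through the same interface.

## Reproducibility

One global seed expands through `numpy.random.SeedSequence` into named
component streams (tissue, initialization, development, mutation,
selection, analysis); development kernels receive 31-bit child seeds.
Checkpoints store genomes, generation index, the lineage log and the
exact bit-generator states, so a resumed run is identical to an
uninterrupted one.

## Known limitations

* Euler–Maruyama is first-order: quantitative trajectories carry O(dt)
  bias, and the Langevin ensemble mean departs from the ODE path where
  Hill responses are strongly convex (Jensen bias of fluctuations around
  low concentrations).
* The fitness scale is compressed (see above): the attainable maximum is
  set by the zone fraction of the tissue, so absolute fitness values are
  not comparable across tissues with different zone fractions.
* Desk-scale evolution shows early adaptation only; slow phenomena
  (plateau robustness drift, turnover of deeply conserved interactions
  over 10⁴–10⁵ generations) need full-scale runs on a cluster.
* At desk scale the first adaptive strategies found are noise-exploiting
  (expression ignited by stochastic fluctuation; the same genome scores 0
  with noise off), so fitness is weakly heritable and both mutated and
  unmutated offspring distributions keep a heavy zero mode.  The mutated
  partition is already bimodal, but the unmutated clones are not yet the
  tighter distribution — that robustness contrast belongs to mature
  full-scale genotypes, and the corresponding dynamics test documents
  this by failing at desk scale.
* Cells never grow, divide or move during development, and within-genome
  position of a TFBS has no effect beyond nearest-downstream-gene
  assignment.
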