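# Methods

## Scope and model

`plk1net` models a PLK1-centred genomic-instability regulatory network as a
deterministic mass-action reaction system. The pipeline has five stages —
core-gene delimitation, network construction, ODE simulation, perturbation
scenario analysis, and circuit-level expression clustering — and a
synthetic-data module that can supply every input, so the whole pipeline is
exercisable without any external download.

Model assumptions, in the package's own terms:

- **No cell dilution.** Concentrations are not diluted by growth or
  division; the model describes one averaged cell over one cycle.
- **Constant genes.** Gene species are boundary species with zero
  derivative: genes, and any species declared free-form, are assumed
  available at sufficient concentration. A gene's initial concentration is
  the quantity perturbation scenarios rescale.
- **Well-mixed, transport-free.** All reactions are global; no
  compartments.
- **Pure mass action.** Every rate law is `k · Π reactantˢ · Π modifier`.
  Regulatory influences that are not structural (binding, modification) are
  encoded so this stays true: a positive transcriptional regulator enters
  the target's transcription as an extra multiplicative modifier; a
  negative regulator catalyses first-order removal of the target's mRNA
  (or of the target itself when it has no mRNA). No Hill or
  Michaelis–Menten terms are generated, and the SBML reader refuses
  non-mass-action kinetic laws.

## Construction rules

1. Curated records are typed: protein–protein, protein–complex,
   protein–small-molecule, protein–process. Binding records pooling into
   the same complex become one association reaction over the distinct
   subunits. Protein→process records produce a cumulative *phenotype*
   species catalytically; phenotypes are never consumed, so their
   trajectories are non-decreasing by construction. Records with neither a
   mappable mechanism nor a sign are excluded and logged, mirroring the
   curation rule that entities without a clear positive/negative influence
   are dropped.
2. Modification records (phosphorylation, dephosphorylation,
   ubiquitination, acetylation) create the modified target form once —
   however many enzymes target the same state — plus one catalysed state
   transition per enzyme. Dephosphorylation requires an existing
   phosphorylated form; otherwise construction fails loudly rather than
   inventing a species.
3. Central-dogma expansion gives every unmodified, non-free-form protein a
   gene, an mRNA, a transcription and a translation reaction. Complexes on
   the direct-synthesis list (cohesin, APC/C, condensin I, MCM, the
   polymerase and pore complexes, …) get a lumped gene + mRNA and a single
   direct-synthesis step instead of per-subunit synthesis and assembly.
   The lumped mRNA keeps the gene and mRNA populations in exact 1:1
   correspondence — an invariant the tests enforce — while still skipping
   subunit-level synthesis. Modified forms never receive synthesis.
4. Degradation closure gives every protein and complex form exactly one
   first-order degradation. mRNAs are also degraded: with constant genes,
   an undegraded mRNA grows without bound, so mRNA turnover is required
   for any steady state to exist. This deliberately extends the
   protein-only closure rule; it is the package's boundedness choice.
   Genes and phenotypes never degrade.
5. Merging unifies species by canonical id (kind prefix + symbol +
   modification suffix) and reactions by (type, reactants, products,
   modifiers), keeping the first-seen rate constant and warning on
   conflicts. Construction is deterministic: identical inputs give
   byte-identical SBML.

## Parameters and units

Concentrations are µM, time is hours; a rate constant has units
h⁻¹·µM^(1−order). Default constants by reaction type (all overridable, and
superseded by curated values wherever one is known): transcription 1.0 h⁻¹,
translation 1.0 h⁻¹, degradation 0.5 h⁻¹, state transition 1.0 µM⁻¹h⁻¹,
association 0.5 µM⁻ⁿh⁻¹, direct synthesis 1.0 h⁻¹. These are
order-of-magnitude-neutral placeholders chosen so the basic motifs have
O(1) µM steady states; they carry no literature claim. Initial conditions:
genes 1.0 µM (homogeneous basal expression), free-form proteins 5.0 µM,
everything else 0.

## Numerics

Integration uses LSODA (stiff-capable, automatic switching) with
rtol 10⁻⁶ / atol 10⁻⁹, sampled at the 151 interval boundaries of the
150 × 0.28 h grid. The "integration steps per interval" setting is a solver
hint, not a fixed step grid — contract-level agreement (closed forms,
matrix exponentials, moiety conservation), not bit-reproduction of any
particular solver, is the target, and the tests assert it at 10⁻⁶–10⁻¹²
depending on the property. Output concentrations within 10× atol of zero
are clipped to zero. Steady state is declared at the first output interval
where max over non-phenotype species of |dC/dt| / max(C, 10⁻⁶ µM) drops
below 10⁻³ h⁻¹; phenotype species accumulate by design and are excluded.
The criterion values are package choices — only the outcome (settling near
the cell-cycle end) is externally meaningful.

## Scenarios, affected species, synergy

The default grid rescales the initial concentration of the three hub knobs
(*cdk1*, *plk1*, the lumped *cohesin* gene) and their joint triple by
0.01, 0.1, 10 and 100 — sixteen scenarios, Sce1…Sce16, perturbing initial
concentrations only, never rate constants. A species is *affected* when
|log2(scenario/baseline)| ≥ log2 1.5 at the evaluation interval (85, the
cell-cycle endpoint — not the 42 h horizon end) or its time-averaged
absolute relative deviation ≥ 0.2; both thresholds are configurable
because the underlying notion of a "noticeable" change is qualitative.
Perturbed species are excluded from their own report. Directional synergy
perturbs each partner in turn and thresholds the effect on the other's
readout with the same rule, yielding NONE / one-way / two-way verdicts.

## Clustering

Circuit-restricted log2 fold-change submatrices (cancer × gene) are split
into two groups by agglomerative clustering with Euclidean distance and
Ward linkage — the convention behind heatmap-with-dendrogram displays —
with seeded k-means as an alternative. Cluster 2 is defined as the
higher-mean cluster (the predominantly overexpressed cancers), which makes
labels comparable across circuits. Missing entries are imputed as 0 ("no
change") for distance computation only. Concordance between two
assignments is the best-label-permutation agreement fraction, with the
discordant cancers named. A spread-free submatrix yields an arbitrary but
deterministic split flagged `degenerate`.

## Synthetic data: what it does and does not emulate

The generators reproduce the *structural* features the pipeline's logic
depends on: hub proteins with several-fold-median degree, neighbouring
processes sharing a tunable fraction of members, a minority of edges
carrying enzymatic mechanisms, log-uniform rate constants, Bernoulli
expression calls at high probability with planted low-expression genes
(standing in for gene families invisible to poly-A RNA-seq), and planted
two-cluster log2FC structure with Gaussian noise and optional sign-flipped
"mixed" genes. They do **not** emulate the literature-specific topology,
curated rate constants, or realistic degree distributions of the real
network — so passing tests demonstrate that the pipeline's rules, numerics
and detection logic are correct, not that any particular biological
conclusion transfers to real data. Every generator is a pure function of
(seed, spec); each draws from a substream keyed by the generator's name, so
adding one generator never shifts another's output.

The circuit fixtures (CPC, MCC, APCC, CASCADE2, FULL_DEMO) are small,
hand-coded reaction models of the three PLK1 circuits with
literature-shaped wiring: CPC assembly with PLK1-catalysed BIRC5
phosphorylation and the PLK1→FOXM1→AURKB transcriptional arm; MCC assembly
from BUB1B/BUB3/CDC20/MAD2 with PLK1 phosphorylation of BUB1B, KIF2C and
CDC20 and MCC inhibition of APC/C; and the APC/C–FBXO5–PTTG1–separase–
cohesin axis, including direct first-stage cohesin removal by PLK1.
Fixture turnover is set to 1.0 h⁻¹ so even species that drain to zero
(free-form enzymes, sequestered subunits) settle well inside the
85-interval cell-cycle window. FULL_DEMO merges the three circuits through
their shared PLK1 / CDC20 / APC/C nodes; at 69 species it is a
demonstration network, roughly one-tenth the scale of a full curated
model, and the problem sizes used throughout the test suite and the
acceptance script (8–80 proteins per synthetic network, 100 replicates for
stochastic rates) were chosen at that demonstration scale.

## Open design choices made

- **Expression threshold semantics.** The 75 % panel fraction is applied
  as a ceiling on the count, but the shipped pipeline default uses an
  absolute override of 16 of 20 cancer types; both rules are expressible
  because the fraction rule and the applied count disagree at panel size
  20 (ceil gives 15).
- **Degree counting.** A species' degree counts distinct curated records
  (parallel edges from different processes each count), not distinct
  partners; protein→process records count toward the protein only.
- **Unsourced dephosphorylation.** No implicit phosphatase is invented; a
  dephosphorylation record without a curated source enzyme cannot be
  expressed, and one whose target was never phosphorylated is an error.
- **Inhibition encoding.** Catalysed mRNA removal was chosen over
  sequestration or divisive rate terms to keep every law mass action.

## Known limitations

- No stochastic simulation, parameter estimation, bifurcation or global
  sensitivity analysis; the model is exploratory and deterministic.
- Default rate constants are placeholders; conclusions about timing or
  magnitudes on real networks require curated constants.
- Affected-species thresholds are conventions; different thresholds change
  counts, though the directionality results (one-way synergy, monotone
  propagation) are threshold-robust in the fixtures.
- Survival analysis on patient-level data is out of scope; clustering
  operates on supplied log2FC matrices only.
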