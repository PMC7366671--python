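# Methods

## Step algebra

A duplex is represented by its top strand; strand B is the reverse
complement, with per-strand 1-based numbering so that pair index *i*
couples A:*i* with B:*L*+1−*i*.  A dinucleotide step is indexed by the
position *p* of its 5′ top-strand base; the dyad of a palindrome maps
step *p* to step *L*−*p*, and the central step of an even-length
palindrome (*p* = *L*/2) is its own image.  Step identity is the
equivalence class of a dinucleotide under reverse complementation,
canonically named by the lexicographically smaller member (class
{TG, CA} → id `CA`).  Display strings follow the field's `XY/WZ`
convention with a fixed alias table (`TG/CA`, `GG/CC`, `GA/TC`, …);
the parser accepts either strand order, since published usage is
inconsistent (`CC/GG` vs `GG/CC`).  Exhaustive enumeration gives 10
classes: 4 self-complementary singleton orbits and 6 doubletons.

## Panel inference

Observations are per-duplex: an ordinal affinity (7-level scale
none < very-weak < weak < medium < medium-strong < strong <
very-strong — the panel's labels compared only ordinally, never
numerically), optional directly resolved sites, and optional observed
stoichiometry.  The engine applies, in order:

1. **Exclusion.** Every step contained in a zero-affinity duplex is
   excluded *absolutely* — if a step supported even weak binding, a
   duplex exposing it would show some complexed fraction.  Exclusions
   are independent of other verdicts, so the exclusion set is final
   after one pass.
2. **Direct and unique attribution.** Directly resolved sites become
   binders (`direct`); a positive duplex whose candidate set
   (contained steps minus exclusions) is a singleton establishes that
   step (`unique_attribution`).  Neither depends on other positive
   verdicts, so one pass is stable.
3. **Dominant attribution.** A remaining positive duplex containing at
   least one established binder is attributed to the binder with the
   highest current affinity estimate (ties → smaller canonical id).
   Crucially this yields *no* evidence, positive or negative, about
   co-present non-binder steps — they stay undetermined.  The phase is
   iterated Jacobi-style: every pending observation is resolved
   against the same snapshot of affinity estimates, the element-wise
   maxima are applied at once, and the loop repeats until the
   estimates stop changing.  Because estimates only increase on a
   finite ordinal scale the iteration terminates, and because no step
   depends on list order the result is permutation-invariant (verified
   over randomized permutations).

A binder's affinity estimate is the maximum affinity over observations
attributed to it.  Positive observations with an empty candidate set
raise an inconsistency error naming the duplex; a step both excluded
and attributed raises a contradiction error.  Every verdict carries an
evidence list (rule, duplex codename) for audit.

**Stoichiometry.** A central singleton site admits one ligand per
duplex (1:1).  A dyad-related pair of sites admits double occupancy
(1:2) when the two cavities do not overlap and are at least `min_gap`
steps apart; `min_gap` defaults to 2, a neighbor-exclusion-like
spacing — no experimental spacing rule is available, so the parameter
is exposed.  (In an even-length palindrome dyad-paired sites are
automatically non-overlapping; the overlap check guards non-standard
inputs.)

**Spectral forms.** With minor-groove intercalation of an asymmetric
aromatic system, 'up' and 'down' ligand orientations are generally
distinguishable (2 NMR forms per site), but at the centre of a
palindrome the dyad makes them equivalent (1 form).  The argument
needs the dyad, so non-palindromic duplexes are rejected.

## Restraint compilation

NOE contact tables are parsed with the fixed grammar
`<ligand_proton><strand>-<residue><atom>` (e.g. `LH3B-A5H1'` = ligand
proton LH3 to strand-B A5 H1′).  A configurable catalog assigns each
ligand proton to the aromatic ring system (LH3, LH4, LH7, LH9, LH10)
or the aliphatic sidechain (LH15, LH17, LH18).  Only aromatic-proton
peaks are compiled into restraints: the sidechain reorients on the
simulation timescale and its NOEs are not jointly satisfiable by one
conformation.  Crosspeaks superimposed in the spectrum are merged into
a single restraint carrying several atom pairs under one restraint
index (averaged-distance semantics) rather than duplicated — one
merged pair in the packaged table, giving 18 restraints for the
d(CCCTAGGG)₂ complex and 13 for d(CGATATCG)₂.

Intensity classes map to bounds through a calibration table.  Without
an internal relaxation standard, crosspeak volumes support only
class-level calibration, so the defaults are the conventional NOE
classes strong/medium/weak → upper₁ = 3.5/4.5/6.0 Å, lower = 1.8 Å
(van der Waals contact), upper₂ = upper₁ + 1.0 Å (start of the linear
penalty tail); all overridable.  The force constant defaults to
1000 kJ·mol⁻¹·nm⁻² for every restraint.

Watson–Crick restraints hold the donor–acceptor heavy-atom pairs of
retained base pairs: G·C → N1–N3, N2–O2, O6–N4; A·T → N1–N3, N6–O4,
with bounds 2.7–3.1 Å (upper₂ 3.3 Å) from canonical B-DNA hydrogen-
bond geometry.  The default exclusion rule drops the two terminal
pairs, whose imino protons exchange too quickly to be observed; the
rule is a parameter (any predicate over pair index).  Counts follow
3·#GC + 2·#AT over retained pairs.

Bounds are Å internally; the GROMACS writer converts to nm and needs
an atom-descriptor → topology-index map, failing loudly with the list
of unmapped descriptors.  The CSV dialect round-trips exactly.

## Chemical-shift perturbation

Δδ = δ(bound) − δ(free), downfield positive; reports carry both signed
and absolute values.  The free (symmetric) duplex may be assigned as a
single "sym" strand, matched to both strands of the complex, whose
symmetry breaking doubles the resonances.  Matching is on (residue,
atom, nucleus); unmatched assignments (e.g. partially assigned
H4′/H5′/H5″) are listed, never imputed.  ¹H and ³¹P channels never mix
in one aggregate.  Methyls are one `CH3` pseudo-atom; H2′/H2″ stay
distinct.

Localization scores step position *p* as the mean over residues
{*p*, *p*+1} on both strands of the per-residue aggregate of |Δδ|
(default: max over the residue's atoms; mean available).  The
aggregation rule is a reporting choice, hence config-exposed.  Ties
break toward the central position and a tied top pair flags the
ranking ambiguous.

## Superposition and clustering

Kabsch superposition via SVD of the cross-covariance with determinant
correction, so reflections are forbidden; selections of fewer than 3
atoms or collinear selections raise a geometry error.  RMSD matrices
superpose every frame pair on the fit mask (no reference-frame
shortcut); a separate score mask may re-evaluate the fitted RMSD on a
sub-selection, e.g. central residues 3–6 plus the ligand, isolating
the contribution of floppy termini.

Daura clustering counts, per round, each unassigned frame's unassigned
neighbors within the cutoff; the frame with the most neighbors founds
a cluster with them (itself included) and is removed.  Ties break
toward the lowest frame index — the original method leaves this open,
and a fixed rule makes the partition platform-independent.  The cutoff
has no defensible default and is a required parameter.  Note that the
number of clusters is *not* monotone in the cutoff for this greedy
scheme on arbitrary dissimilarity matrices (a smaller cutoff can
reshuffle the greedy choices); only the limits are guaranteed (cutoff
above every distance → one cluster, below every positive distance →
all singletons).

Ensembles are read and written as MODEL-delimited multi-model PDB
(chains A/B = DNA strands, chain L residue `LIG` = ligand), to PDB's
native 10⁻³ Å precision.

## Synthetic generators

All generators are seeded and deterministic; each returns the hidden
truth next to the observable output.

* **Panels.** Observed affinity = max of the planted per-class
  affinities over the duplex's steps, misclassified by ±1 level with
  probability ε (default 0).  The binding site is disclosed as a
  direct site only when the maximum is attained by a unique class
  occupying the duplex centre — the condition under which a single
  well-resolved complex makes the site readable from 1D spectra.
  With ε = 0 the generator is an exact right-inverse of the inference
  engine on the binder set whenever each planted binder is uniquely
  attributable somewhere in the panel.
* **Helix scaffold and NOE tables.** An idealized B-form scaffold
  (rise 3.4 Å, twist 36°/step) carries a handful of pseudo-protons per
  residue at schematic radii; strand B runs antiparallel across the
  dyad.  The geometry is deliberately schematic — it emulates
  inter-proton distance *structure*, not real coordinates.  Ligand
  pseudo-atoms are planted in a step cavity; every ligand–DNA proton
  pair under 6.0 Å emits a peak classified by thresholds
  ≤3.2 strong / ≤4.2 medium / ≤6.0 weak, chosen strictly inside the
  compiler's default calibration windows so that every compiled
  restraint provably contains its true distance.  Placements closer
  than 1.8 Å to any DNA proton are rejected as unphysical.
* **Shift tables.** Free shifts come from a fixed per-atom-type
  baseline (aromatic H ≈ 7–8 ppm, H1′ ≈ 5–6 ppm, …); the values are
  cosmetic since only differences matter.  Binding adds
  m·exp(−d/λ)·(random sign) + Normal(0, σ) per atom, d = residue
  distance to the planted step, independently on the two strands.
  Defaults m = 0.5 ppm, λ = 1 residue, σ = 0.05 ppm emulate a strong,
  tightly localized perturbation over a realistic assignment noise
  floor (m/σ = 10).
* **Ensembles.** k base conformers = scaffold + fixed random
  deformation fields of per-atom RMS amplitude Δ (default 2.0 Å);
  frames add isotropic jitter σ_in (default 0.3 Å per coordinate) and
  an independent random rigid motion, so cluster recovery *must*
  superpose first.  Separability requires Δ > 2√2·σ_in (enforced).
  Frame counts per conformer follow the weights by largest-remainder
  apportionment, shuffled in time: composition is exact, so occupancy
  recovery measures clustering fidelity rather than multinomial
  sampling noise.

## What passing tests do and do not show

The generators share the analysis' own idealizations: hard intensity
thresholds, exponential perturbation decay, isotropic Gaussian
conformer spread, noiseless step content.  Passing recovery tests
therefore demonstrates internal consistency and correctness of the
algorithms under their stated models — not robustness to spin
diffusion, peak overlap, assignment errors, anisotropic motions, or
non-Watson–Crick structure, none of which the generators emulate.
MD-derived quantities (cluster occupancies and RMSDs of real
trajectories) depend on trajectories this package does not produce;
clustering is validated against an exhaustive reference
implementation and planted ensembles instead.

## Problem sizes

Default verification sizes: 500 randomized ≤8-frame matrices for the
clustering cross-check, 200-frame planted ensembles (~125 atoms) for
occupancy recovery, 100 seeded shift-table simulations for
localization accuracy, 100 panel permutations for order independence.

## Known limitations

Palindromic duplexes only (spectral-form counting is undefined without
the dyad); no r⁻⁶ volume quantitation; no torsion/planarity
restraints; trajectory input limited to multi-model PDB; exclusion is
absolute by design and cannot express affinity-dependent detection
thresholds.
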