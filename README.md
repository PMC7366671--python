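# stepspec

Sequence-specificity analysis of DNA intercalation at dinucleotide-step
resolution.

Planar aromatic drugs intercalate between two stacked Watson–Crick base
pairs — a *dinucleotide step*, written 5′-XY-3′/5′-WZ-3′ (shorthand
`XY/WZ`).  Because a duplex is double-stranded, the 16 dinucleotides
collapse into 10 step classes under reverse complementation, four of
them self-complementary (AT/AT, TA/TA, CG/CG, GC/GC).  NMR titrations
of an intercalator against a panel of short palindromic duplexes ask:
*which* of the 10 steps does the ligand prefer, and how strongly?

`stepspec` is written for NMR spectroscopists and molecular modellers
running such panels.  It provides:

- **Step algebra** (`stepspec.duplex`) — palindrome validation,
  canonical step enumeration, dyad-orbit analysis of positioned sites.
- **Panel inference** (`stepspec.inference`) — a deterministic engine
  turning per-duplex observations (ordinal affinity, NMR-resolved
  sites, stoichiometry) into per-step verdicts.  A duplex with *no*
  detectable binding excludes every step it contains; a positive
  duplex whose only non-excluded step is one candidate establishes a
  binder; positive duplexes containing an established binder are
  attributed to the strongest one, leaving co-present steps open.
  Site-symmetry arguments then predict admissible duplex:ligand
  stoichiometries (a central site admits 1:1 only; dyad-related
  off-centre sites also admit 1:2) and the number of distinguishable
  NMR forms (orientational 'up'/'down' degeneracy collapses at the
  dyad centre).
- **Restraint compilation** (`stepspec.restraints`) — NOESY crosspeak
  tables → flat-bottom distance restraints (aromatic-proton filter,
  superimposed-peak merging, intensity→bound calibration), plus
  Watson–Crick hydrogen-bond restraints (3 per G·C, 2 per A·T,
  terminal pairs excluded), serialized to GROMACS
  `[ distance_restraints ]` or CSV.
- **Chemical-shift perturbation** (`stepspec.csp`) — Δδ = δ(bound) −
  δ(free) profiles on independent ¹H and ³¹P channels, with step-site
  localization by per-residue |Δδ| aggregation.
- **Ensemble clustering** (`stepspec.cluster`) — Kabsch superposition,
  masked RMSD matrices and Daura (GROMOS) greedy clustering of
  multi-model PDB conformer ensembles, with occupancy reporting.
- **Synthetic data** (`stepspec.synth`) — seeded generators for every
  input above, each returning its hidden ground truth.

## Worked example

The packaged panel fixture (`stepspec.restraints.packaged_panel()`)
holds 13 palindromic duplexes, codenamed D1–D13, with their observed
relative affinities and NMR-resolved sites.  Running the inference
engine:

```sh
stepspec infer src/stepspec/data/table2.csv
```

prints

```
step     status         affinity       confidence
AA/TT    undetermined   -              -
GT/AC    undetermined   -              -
AG/CT    undetermined   -              -
AT/AT    excluded       -              -
TG/CA    binder         medium-strong  unique_attribution
GG/CC    excluded       -              -
CG/CG    binder         weak           unique_attribution
GA/TC    excluded       -              -
GC/GC    undetermined   -              -
TA/TA    binder         very-strong    direct

binder ranking: TA/TA > TG/CA > CG/CG
```

Reading: the null duplex D6 = d(GGGATCCC)₂ showed no intercalation, so
all three of its steps (GG/CC, GA/TC, AT/AT) are excluded outright.
TA/TA was resolved directly in three complexes (`direct`).  After the
exclusions, D5 = d(CCCATGGG)₂ leaves TG/CA as its only candidate
(`unique_attribution`), as does D1 for CG/CG.  Four steps only ever
co-occurred with a stronger binder and stay `undetermined`.

Compiling the packaged NOE contact table for the d(CCCTAGGG)₂ complex:

```sh
stepspec restraints noe src/stepspec/data/table1.csv --complex D3L
```

yields 18 restraints (19 aromatic-proton peaks, one superimposed pair
merged), e.g.

```
index,atom1,atom2,lower,upper1,upper2,force_constant,provenance
1,ligand:LH3,dna:B:A5:H1',1.8,6.0,7.0,1000.0,D3L:row1:LH3B-A5H1'
2,ligand:LH3,dna:B:A5:H8,1.8,6.0,7.0,1000.0,D3L:row2:LH3B-A5H8
3,ligand:LH3,dna:B:T4:H1',1.8,4.5,5.5,1000.0,D3L:row3:LH3B-T4H1'
```

— a weak crosspeak becomes bounds 1.8–6.0 Å (hard wall 7.0 Å) with
force constant 1000 kJ·mol⁻¹·nm⁻², a medium one 1.8–4.5 Å, and so on.
The same fixture gives 13 restraints for the d(CGATATCG)₂ complex, and
`stepspec restraints wc` adds 14/16 Watson–Crick restraints for the
two octamers with terminal pairs excluded.

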