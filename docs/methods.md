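# Methods

## The problem

Heparin/heparan sulfate (Hp/HS) oligosaccharides are linear, highly anionic
chains of alternating glucosamine (GlcN) and uronic-acid (GlcA/IdoA) residues
joined by 1→4 glycosidic bonds. Docking them against protein surfaces is
notoriously hard: a typical chain carries 12–60 rotatable bonds (di- to
decasaccharide), and the binding sites are shallow, cationic and
solvent-exposed, so fully flexible searches drown in conformational space
while fully rigid searches cannot adapt to the pocket. Crystallographic
surveys, however, show that the glycosidic torsions Φ/Ψ cluster within about
±30° of a small number of minima — two for UA→GlcN linkages, around
(−80°, −100°) and (−80°, 65°), and one for GlcN→UA, around (80°, −145°).

glycodock implements the protocol family built on this observation:

* **rigid** — glycosidic torsions fixed at their input values;
* **semi-rigid** — glycosidic torsions sampled from a bounded, bell-shaped
  probability histogram (±30° by default) centered on a chosen value;
* **flexible** — glycosidic torsions free over the full circle.

Substituent torsions (sulfates, carboxylate, N-acetyl) are always free; ring
puckers never move during search.

## Torsion conventions

For a 1→x linkage with bridging oxygen Ox on the acceptor residue,
Φ = O5–C1–Ox–Cx and Ψ = C1–Ox–Cx–C(x−1) (heavy-atom crystallographic
convention, tag `O5-C1-Ox-Cx`). Angles are signed per the standard
right-handed (IUPAC) torsion convention — cross-checked against
`Bio.PDB.vectors.calc_dihedral` — and wrapped to (−180°, 180°]. Residues are
numbered 1-based from the reducing end, so linkage "2→1" joins the reducing
end to the penultimate residue. All angle averaging is circular; deviations
are reported as magnitudes in [0°, 180°].

## Ring puckers

Cremer–Pople coordinates (Q, θ, φ) are computed over the ring order
O5, C1…C5, with the mean-plane normal oriented so that a counterclockwise
ring reads back the out-of-plane displacements it was built with. Labels:
θ ≤ 45° → 4C1, θ ≥ 135° → 1C4, equatorial band with φ within ±30° of 150°
(the skew azimuth for this atom ordering) → 2SO, otherwise "other"; rings
with Q < 0.1 Å are flagged planar. The windows are configurable
(`PuckerWindows`); the skew azimuth is a convention tied to the O5-first
ordering and is documented rather than universal.

## Rotatable-bond bookkeeping

A bond is rotatable when it is an acyclic single bond between heavy atoms
whose endpoints both have at least two heavy neighbours. This excludes,
automatically, hydroxyl C–O bonds, sulfate S–O(terminal) bonds and
carboxylate C=O bonds, and it never includes ring bonds. With the canonical
minimal substituent complement — GlcN(NS,6S) with a 3-O-sulfated reducing
terminus (the rare antithrombin-type motif) and IdoA(2S) — the tally under
the flexible regime is exactly 6n for an n-mer: 12, 24, 36, 48, 60 for
n = 2…10. In the per-residue donor attribution (each linkage's Φ and Ψ
charged to the donor residue), a uronic acid contributes 5 and a glucosamine
7 rotatable bonds.

## Torsional histograms

`build_histogram` produces a normalized probability vector over 1° bins with
zero weight outside a circular window [center − w, center + w]. The default
shape is a raised cosine, weight ∝ cos²(πΔ/2w) — exactly zero outside the
window, matching the hard ±30° reading of the survey data; a truncated
Gaussian (sd = w/2) and a flat shape (the flexible regime's implicit prior at
w = 180°) are options. Sampling is inverse-CDF (bin by weight, uniform
within the bin, clipped to the support), so a sample can never leave the
window. Bimodal UA→GlcN defaults are an equal-weight mixture of two bounded
bells; the survey literature does not constrain the mixture weights.
Distribution files are a plain-text format of this package (header + one
"angle weight" line per bin, full float precision, exact round-trip).

## The surrogate dock score

The commercial scoring function used in the experiments this package
emulates is proprietary, so glycodock defines its own documented additive
surrogate (higher is better):

* **H-bond term** — cationic receptor N donors vs ligand O acceptors; full
  weight at ≤ 3.0 Å tapering to zero at 3.5 Å, times an angular factor on
  the donor antecedent angle (full ≥ 150°, zero ≤ 120°). Each donor carries
  one proton, so its contribution saturates at its best acceptor.
* **Electrostatics** — 332·qiqj/(4r²) kcal/mol (distance-dependent
  dielectric ε = 4r), clamped at ±10 per pair; the favorable part enters
  the total.
* **Dispersion/repulsion** — 6–12 potential on vdW radii, ε = 0.2, with the
  repulsive part capped at 10 per pair (soft clash).
* **Internal strain** — the same capped repulsion over ligand atom pairs
  ≥ 4 bonds apart.

Weights (8, 2, 0.5 on the attractive terms; 1 on each penalty) put a
well-docked synthetic complex in the ~40–150 range per disaccharide of
contact, so the conventional score/RMSD selectivity threshold of 50 remains
meaningful on this scale. Formal charges: sulfates −1 and carboxylates −1
spread equally over the group's S/C and terminal oxygens, free amines +1,
Arg/Lys +1 and Asp/Glu −1 on protein side chains, His neutral by default.
Sulfate terminal oxygens carry the carboxylate-oxygen surrogate type
(`O.co2`). Hydrogens are not modelled; all metrics and scores are
heavy-atom quantities.

## The genetic algorithm

A chromosome is (translation, unit quaternion, one absolute torsion target
per rotatable bond). Decoding applies torsions along a spanning tree rooted
at the reducing end (rigid fragments stay internally undistorted), then
rotates about the template centroid and translates; translations are bounded
by the docking-site bounding box + 2 Å. The GA is generational with
tournament selection (k = 2), one-point crossover over the gene vector
(probability 0.9; the quaternion crosses as one gene so it stays
normalized), per-gene mutation (probability 0.1; translations N(0, 1 Å) with
occasional uniform resampling, orientations small rotations with occasional
full resampling, free torsions uniform, bounded torsions resampled from
their histogram, fixed genes untouched) and single-individual elitism. A
"genetic operation" is one offspring construction + evaluation; the run
stops after exactly `n_operations` of them (the initial random population is
evaluated separately, so `n_operations=0` returns the best random start).

The best archive entries of each run then receive a deterministic **local
refinement** (the memetic step): pattern search over the rigid-body genes on
a shrinking schedule with rotation pivots at the ligand center and both
chain ends (so an elongated chain can rock about a contact point); a jump
scan over the characteristic near-degeneracies of a quasi-helical polymer in
a complementary groove (end-to-end flips about the pose's principal axes and
±one-disaccharide register shifts along the chain axis), each candidate
rigid-polished before comparison; and a torsion sweep from coarse rotamer
steps (120°) down to 3°, with bounded genes clipped to their histogram
support. Semi-rigid bounds are therefore hard invariants of the entire
search, not statistical tendencies.

Replicate orchestration mirrors the triplicate/top-2 protocol: replicate r
reseeds at base_seed + r, the single best pose of each GA run is pooled, and
the top-2 highest-scoring distinct poses (0.25 Å deduplication; ties broken
by replicate/run order) are retained — six analysis poses per system at the
defaults.

## Pose-consistency metrics

All RMSDs are computed in place (no superposition): docked and native poses
share the receptor frame, and aligning first would erase exactly the
translational error being measured.

* RMSD_AVERAGE — mean native-vs-pose RMSD over the analysis set (default);
  an alternative rmsd-to-centroid mode (RMSD to the coordinate-averaged
  pose) is provided for sensitivity analysis.
* RMSD_LOWEST — the single best native-vs-pose RMSD.
* RMSD_INTRAPOSE — mean RMSD over all unordered pose pairs (15 for six
  poses), reported absent (not zero) for a single pose.

A set *recapitulates* when RMSD_AVERAGE ≤ 2.5 Å and is *consistent* when
RMSD_INTRAPOSE ≤ 2.5 Å; consistent-but-not-recapitulated sets flag
convergence to a non-native site. The threshold is configuration, surfaced
in every report header, with an optional per-length scaling hook (off by
default). Symmetry handling, when enabled, permutes the equivalent terminal
oxygens within each sulfate (3!) and carboxylate (2) group of one pose to
minimize the RMSD; groups are disjoint, so each is minimized independently
and the result equals the exhaustive minimum. Per-linkage torsional
deviations are |circular mean over poses − native|, for Φ and Ψ separately,
plus across-linkage means. The selectivity ratio is mean score /
RMSD_AVERAGE (∞ when the RMSD is 0; never selective when the mean score is
negative), with the selective flag at ratio ≥ 50.

## Synthetic study systems

The fixture generator emulates the prepared co-complex systems:

* **Chains** — idealized pyranoses built by inverting the Cremer–Pople
  transform (Q = 0.57 Å chairs; 4C1 for GlcN/GlcA, 1C4 or 2SO for IdoA),
  substituents at tetrahedral/trigonal positions with standard bond lengths,
  residues joined by exact NeRF construction so every planned Φ/Ψ
  re-measures to < 0.01°. A deterministic greedy sweep over substituent
  torsions (30° grid, glycosidic torsions untouched) removes the steric
  clashes any rule-based placement leaves behind.
* **Receptors** — rigid grooves of Arg/Lys-like pseudo-residues: a cationic
  NZ placed 2.8 Å along the S→O (or C→O) bond of an anionic ligand group,
  its CZ/CB antecedents behind it, plus a four-carbon steric collar around
  the approach vector, carved so that candidate collar atoms contacting the
  planted ligand are omitted. Pocket tightness scales how many anionic
  groups receive a site (1.0 → all, 0 → none within reach). The planted
  pose is then relaxed to a local optimum of the actual dock score
  (substituent torsions + rigid body only), the way a crystal conformation
  sits at a minimum of the physical energy; the standard tight fixture uses
  an aperiodic sulfation pattern so the groove has a single unambiguous
  register.
* **Decoys** — translations (ground-truth RMSD = |t| exactly), planted
  torsion offsets (known per-linkage Δψ) and mixed perturbations.
* **Corpora** — chains with torsions drawn from wrapped normals around the
  class centers, for curation/recovery tests.

What passing tests on these fixtures show — and what they do not: the
machinery (regime bounds, metric identities, retention bookkeeping,
recovery on a well-posed groove) is exercised end to end, but toy grooves
have perfect charge complementarity, no waters, no receptor flexibility and
no crystal-packing effects, so success rates here do not predict
performance on real protein co-complexes.

## Problem sizes and defaults

Publication-scale searches (100 GA runs × 10,000 operations, triplicate)
are one flag away (`full_scale_ga_config`), but the package's own
experiment presets are desk-scale, chosen so the full property surface runs
on a single CPU: the six-fixture benchmark uses 3 runs × 800 operations per
replicate (population 50) and the planted-pose recovery experiment 3 runs ×
1,000. At these settings the benchmark reproduces the qualitative protocol
ordering (rigid and semi-rigid recapitulation ≥ flexible; flexible mean
|Δψ| far above the semi-rigid bound of 30°) and the tight tetrasaccharide
fixture recovers its planted pose (symmetry-corrected RMSD_LOWEST ≤ 2.5 Å)
in ≥ 90% of seeded repeats.

## Numerical choices and degenerate inputs

* Wrap convention (−180°, 180°] everywhere; bin edges half-open.
* Colinear atom triples raise a degenerate-geometry error from the dihedral.
* Near-planar rings (Q < 0.1 Å) classify as "other" with a planar flag.
* Score distances are floored at 0.5 Å; per-pair electrostatic and
  repulsive contributions are clamped/capped as described, so no pose has
  an infinite finite-geometry score (poses far outside the site box return
  a −∞ sentinel and are rejected).
* Pose deduplication at 0.25 Å; score ties break lexicographically by
  (replicate, run) so rankings are deterministic.
* All randomness flows from numpy `SeedSequence`s derived from the single
  job seed; replicate r uses base_seed + r.

## Known limitations

* The surrogate score is not calibrated to any physical binding free energy;
  only its ordering behavior on the synthetic systems is meaningful.
* The protein is rigid and unhydrated; His protonation is a configuration
  flag, not a prediction.
* The GA does not reproduce any commercial engine's island model or
  operator weights; 10,000 operations per run is the configurable default.
* Curation reports KDE modes as candidate histogram centers but does not
  assert a mode count; mode detection beyond KDE peaks is out of scope.
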