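# Methods

This note documents the models, parameter defaults, numerical choices and
limitations behind `amine_profiler`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Chemistry model

The chemistry tables (`data/chemistry.yaml`, version 1) assign every
canonical ribonucleotide, deoxyribonucleotide and amino acid its donor
hydrogens and acceptor atoms. Lone-pair bookkeeping follows elementary
valence chemistry: each oxygen acceptor holds two lone pairs, each
unprotonated ring nitrogen one. The exocyclic amine nitrogen (A N6, C N4,
G N2) is a two-hydrogen donor and *never* an acceptor because its lone
pair is delocalized into the aromatic ring.

The capacity counting convention treats each nucleotide as an internal
chain residue carrying a 5'-phosphate with both nonbridging oxygens plus
the bridging O5', plus O4', O3' and (RNA) O2' — six backbone/sugar oxygens
— with no terminal hydroxyl protons. Under this convention the four
canonical ribonucleotides together carry 62 acceptor lone pairs and 12
polar hydrogens, a better-than-5:1 acceptor excess.

Amino-acid side-chain acceptors (Asp/Glu carboxylates, Asn/Gln carbonyls,
Ser/Thr/Tyr hydroxyls, His ring nitrogens) follow standard chemistry and
can be switched off (`include_sidechain_acceptors=False`); the backbone
carbonyl O, generalized as `AA(O)`, is unaffected by the toggle. Modified
residues are deliberately absent: unknown codes raise `UnknownResidue`
rather than guessing a chemistry, and atoms of unknown residues are never
acceptor candidates.

## Structure normalization and protonation

Structures are read with gemmi. One model is retained (an IFE's model
number, else the first), and one altloc per atom site — highest occupancy,
ties broken by altloc character order; the paper trail for both policies is
kept in the structure metadata since neither choice is externally imposed.
All hydrogens present in the file are stripped before any measurement.

Amine hydrogens are then placed analytically: both in the base plane, N–H
= 1.01 Å, H–N–H = 120°, symmetric about the C→N axis (equivalently 120° to
the C–N bond), one cis and one trans to the first ring anchor (A: N1 via
C6; C: N3 via C4; G: N1 via C2). Placement is exact arithmetic on the
anchor coordinates, hence bit-deterministic. Residues that cannot be
protonated are excluded *as data*, with reasons recorded: missing amine N,
missing anchor atoms, a degenerate anchor geometry, or a covalent
modification (any foreign heavy atom within 1.2 Å of the N). The number of
exclusions is reported in the survey manifest but never asserted against
external counts, which are tool-version dependent.

Canonical residues are always treated as polymer-eligible even when entity
records are too sparse for gemmi to classify them — synthetic files
exercise this path; waters, ions and ligands are not in the tables and are
excluded both by the polymer flag and by acceptor lookup.

## H-bond calling and classification

Candidates are acceptor-capable polymer atoms within **4.1 Å** of the
amine nitrogen (the prescreen must cover the 2.5 Å acceptance distance
plus the 1.01 Å N–H bond). The parent residue's *base-moiety* atoms are
excluded; its own sugar/phosphate atoms remain candidates, since a
2'-hydroxyl or phosphate of the same residue is a chemically meaningful
acceptor. The `exclude_parent_residue` toggle drops the whole residue for
sensitivity analysis.

Both hydrogens are measured against every candidate (distance H→acceptor;
angle N–H–acceptor at the H). A bond passes at **≤ 2.5 Å and ≥ 140°**.
Classification:

* 0 passing bonds → **non**;
* passing bonds on one hydrogen only (1, 2 or ≥3 of them → scenarios 1, 3,
  4) → **single** — multifurcation does not use the amine's second valence;
* both hydrogens passing but only one distinct acceptor (scenario 2) →
  **single**;
* both hydrogens passing with ≥ 2 distinct acceptor atoms → **dual**
  (scenario 5; 7 with a bifurcated hydrogen; 6 with a shared acceptor).

Scenarios 2 and 6 are representable but unreachable under the default
criteria: a grid scan over all acceptor positions within 2.5 Å of both
hydrogens shows the smaller of the two N–H–acceptor angles never exceeds
≈ 120°, well short of 140° (`max_min_shared_acceptor_angle`). The fixture
generator therefore raises `InfeasibleScenario` for them.

For a dual amine's **acceptor pair**, each hydrogen contributes its
greatest-angle passing acceptor. When both hydrogens elect the same atom,
the assignment falls back to the distinct-atom combination maximizing the
summed angle — the greatest-angle rule alone can collide, and the fallback
preserves the two-acceptor definition of duality. Pairs are canonically
ordered by label for counting; a same-residue flag records whether both
acceptors belong to one residue.

Canonical GC pairs are called when *both* G(N2)→C(O2) and C(N4)→G(O6)
bonds pass. The geometry heat map keeps, per amine–acceptor pair, only the
measurement set with the greater angle, and excludes the four canonical
pair types (A(N6)–U(O4), C(N4)–G(O6), G(N2)–C(O2), G(N2)–C(N3)) *from the
histogram only* — classification never excludes them. Default bins are
0.05 Å × 2°, chosen to resolve the population edge that motivates the
criteria.

## Burial descriptors

**SASA** is Shrake–Rupley sphere-point sampling implemented here directly:
100 golden-spiral points per atom, probe 1.40 Å, Bondi-style van der Waals
radii (N 1.55, O 1.52, C 1.70, P 1.80, S 1.80; fallback 1.70), on the
hydrogen-free structure. A lone nitrogen gives the closed form
4π(1.55+1.40)² ≈ 109.36 Å² exactly; the test suite cross-checks whole
structures against Biopython's independent implementation. Point count and
radii are configuration, recorded in output metadata.

**Shell densities** count polymer heavy atoms (the central N included)
within r ≤ 7.5 Å (ROI 1) and 7.5 < r ≤ 12.5 Å (ROI 2), both outer
boundaries closed, divided by the exact sphere/shell volumes (1.767 nm³
and 6.414 nm³). The 7.5 Å boundary corresponds to the spatial extent of a
base triple around a central amine.

## Torsions

χ is the glycosidic dihedral O4'–C1'–N9–C4 (purines) / O4'–C1'–N1–C2
(pyrimidines), reported in (−180, 180] with the stable atan2 formulation.
*syn* means χ strictly inside (−90°, 90°); the *minor-population* flag uses
the (−20°, 130°) display window — a presentation convention, not a
histogram-valley definition. Missing atoms yield an explicit undefined,
never zero.

η = C4'(i−1)–P(i)–C4'(i)–P(i+1) and θ = P(i)–C4'(i)–P(i+1)–C4'(i+1),
mapped to [0, 360). A torsion is undefined at chain termini and across
chain breaks; continuity requires O3'(i−1)–P(i) ≤ 2.5 Å (when O3' is
absent, a C4'(i−1)–P(i) virtual distance under 7 Å substitutes). Region
boxes are inclusive: A-form η ∈ [145, 190], θ ∈ [190, 245] (reading the
published inequality chain as a range); Location 1 η ∈ [43, 72], θ ∈
[151, 180]; Location 2 η ∈ [295, 324], θ ∈ [14, 43].

## Fragment clustering

Fragments are 6×5-nt windows: strand 1 holds the residue of interest at
position 3 of 6 (two upstream, three downstream — an asymmetry motivated by
the S-motif geometry; offsets are configurable), strand 2 the base-pairing
partner ±2. Each nucleotide is coarse-grained to five atoms (P, C4', N9,
C2, C6 for purines; P, C4', N1, C2, C4 for pyrimidines), 55 points per
complete fragment; incomplete fragments are rejected, never padded.

Pairwise distances are minimal superposition RMSDs (Kabsch SVD with a
determinant guard — proper rotations only, so enantiomers do not collapse
to zero). Average-linkage agglomerative clustering runs on the precomputed
matrix; cutoffs are scanned in 0.05 Å steps from the first value forming a
cluster of ≥ 4 members to the integer below the maximum distance, scoring
Silhouette (precomputed metric), Calinski–Harabasz and Davies–Bouldin at
each step. CH and DB require a vector embedding, for which the RMSD-matrix
rows stand in; they are diagnostics only — the reported cutoff is the
Silhouette optimum (ties to the smaller cutoff). Each cluster's
representative superposes all members onto the cluster medoid, averages
the coordinates, and returns the member with the smallest RMSD to that
average (ties to the lowest index). Linkage and the medoid frame are
configurable because no external convention fixes them.

## Statistics

Linear descriptors (SASA, densities) use pairwise two-sided Wilcoxon
rank-sum tests — exact enumeration for tie-free samples up to n = 50,
tie-corrected normal approximation otherwise (scipy) — with
Benjamini–Hochberg adjustment within one family per figure-panel analogue
(all pairwise comparisons passed in one call).

Circular χ distributions use Watson's two-sample U², computed with a
tie-aware pooled-CDF formulation that is invariant under a common rotation
of both samples. Because the test is calibrated against tabulated critical
values (0.152 / 0.187 / 0.268 at α = 0.10 / 0.05 / 0.01, Stephens'
asymptotic points, shipped as data), it reports a p-value *range*, and no
FDR adjustment is applied to ranges. A seeded permutation p-value
(reassignment of pooled angles) is available as the exact oracle and is
computed automatically below 8 observations per group
(`SmallSampleWarning`). The acceptance script verifies the null rejection
rate at the 0.05 critical value over 2000 replicates of n = 100 uniform
samples.

## Synthetic structures

The fixture generators produce every input the tests need, offline and
bit-reproducibly (same spec + seed → identical file):

* **Geometry probes** place acceptors on the exact (distance, angle) cone
  around an idealized amine hydrogen — acceptance-criterion edges can be
  hit to 1e-6 before file rounding (PDB files carry 3 decimals; assertions
  over round-tripped files use a 2e-3 Å tolerance).
* **Duplexes** combine planar polygon-geometry base templates (regular
  hexagon/pentagon rings, exocyclic substituents on outward bisectors)
  paired by least-squares alignment of the defining Watson–Crick H-bonds,
  with a helically parametrized backbone (rise 2.81 Å, twist 32.7°) solved
  numerically so that interior pseudotorsions land at (167°, 217°), the
  center of the A-form box, and per-residue O4' placement yields χ = −160°
  (anti). Sugar atoms between the measured ones are plausibility filler:
  the fixtures are idealized, not physically relaxed, and no measured
  quantity depends on the filler geometry.
* **Noncanonical pairs** (sheared GA, trans AA Hoogsteen) position the
  partner base so the named acceptor sits at ideal geometry for one
  hydrogen, with the second acceptor (O2' or OP1) placed for the other —
  reproducing the signature dual-donation patterns G(N3)/N(O2') and
  A(N7)/N(NPO) with same-residue acceptors.
* **Pseudotorsion chains** grow the P/C4' virtual-bond chain by natural
  extension (NeRF), so interior residues carry *exact* requested (η, θ) —
  including the Location boxes, which a uniform helix cannot reach (a
  40,000-sample scan over helical parametrizations finds no solution
  there; those conformations are kinked, which is the scientific point of
  the Locations).
* **Planted fragment sets** draw random-walk 6×5 templates re-sampled
  until pairwise RMSD ≥ 8 Å, then add Gaussian coordinate noise (default
  σ = 0.3 Å) per member.

What passing on these fixtures does *not* show: real structures have
experimental coordinate error, modified residues, alternate conformations
and crystal contacts; the fixtures pin the geometry and logic of the
pipeline, not the biological distributions. Full-dataset survey numbers
require downloading the pinned representative-set entries and are
reproducible with `amine-profiler survey --rep-set ... --local-dir ...`
when those files are present.

## Problem sizes used by the bundled runs

The test suite and acceptance script use 6–12-bp duplexes, 50 random
~300–500-atom structures for the index-vs-exhaustive check, 20–30
fragments per clustering run and 2000 replicates for null calibration —
sizes chosen so the full pipeline exercises every code path while the
suite stays interactive.

## Known limitations

* Donors are the exocyclic amines of standard A/C/G residues only;
  modified nucleotides are skipped as donors and (by default) as acceptors.
* Only the asymmetric unit is analyzed; no biological-assembly expansion
  or symmetry mates.
* Protonation states are fixed (no pKa prediction, tautomers or charged
  bases).
* The acceptor-side inventory (non-amine donors), π-stacking and metal
  coordination are out of scope.
* Watson U² p-ranges are bracketed by a three-level critical table; use
  the permutation mode when a point p-value is needed.
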