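# Methods

`polyprot` implements the structural-analysis toolchain used to characterise
a multi-domain retroviral polyprotein — concretely the prototype foamy virus
(PFV) protease–reverse transcriptase (PR-RT), a single 751-residue chain
carrying an aspartyl protease (PR), a protease C-terminal extension
(PR-CTE), the four polymerase subdomains (fingers, palm, thumb, connection)
and the RNase H domain.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic fixtures do and do not
demonstrate.

## Structure model and conventions

Structures are parsed with gemmi (PDB and mmCIF) into a minimal
chain/residue/atom hierarchy.  Author residue numbering is the only
coordinate system: for PFV PR-RT it runs 1..751 from the PR N-terminus
through RNase H, and no renumbering is ever performed.  Conventions applied
everywhere:

* **Alternate locations** — all conformers are kept on parse, but geometry
  and surface calculations use only the highest-occupancy conformer (ties
  broken by altloc letter, so 'A' wins).  Single-conformer analysis matches
  what interface-analysis servers do by default.
* **Hydrogens** — ignored.  The deposited models (~2.9–3.0 Å) carry none;
  every analysis is heavy-atom.
* **Waters** — excluded from polymer chains and hetero sites.
* **Hetero sites** — ions and ligands (e.g. the crystallographic Ca²⁺ bound
  at the RNase H active site) are held apart from the polymer, so domain
  groups never silently absorb them.

The PDB writer emits fixed-column v3.3; a write→read round trip reproduces
the model to the format's 10⁻³ Å precision, which bounds how exactly any
file-mediated pipeline result can be reproduced in memory.

## Domain map

The default PFV PR-RT partition is PR 1–100, PR-CTE 101–145, fingers
146–228 ∪ 260–290, palm 229–259 ∪ 291–367, thumb 378–449, connection
450–590, RNase H 593–751.  The fingers subdomain is annotated in the
structure from residue 144, which would overlap PR-CTE (ends 145); because
the interface table needs a disjoint partition, the default map starts
fingers at 146 and the as-annotated map (`literal_pfv_map`) ships alongside
with its overlap reported by the validator rather than silently resolved.
Residues 368–377 (palm→thumb) and 591–592 (connection→RNase H) are linkers:
they belong to no interface group, which makes the buried-surface matrix a
strict domain-pairwise decomposition.  Feature sites (PR catalytic triad
DSG 24–26, polymerase motif YVDD 314–317, catalytic aspartates 254/316/317,
primer grip 355–368, RNase H carboxylate triad 601/648/671) are annotations
on top of the partition, not partition members — the primer grip in
particular overlaps the palm range and must not be double-counted.

## Superposition and structural alignment

Rigid superposition is the Kabsch least-squares fit via SVD, with the
reflection corrected through the sign of the smallest singular value so the
rotation is always proper; RMSD = √(Σ‖Rpᵢ+t−qᵢ‖²/n).  Collinear point sets
(covariance rank < 2) are rejected as degenerate.  Two modes are reported
for structure-vs-structure comparisons: all-common-Cα without outlier
rejection, and an iterative trim (drop pairs beyond mean + 2 σ of per-pair
deviation, ≤ 5 cycles).  Published pairwise RMSDs rarely state the trimming
policy, so both numbers bracket the plausible conventions and neither is
asserted as "the" value.

Cross-protein comparisons at low sequence identity (retroviral proteases
are typically < 30% identical) use a combinatorial-extension-style
sequence-independent alignment: all 8-residue windows of both Cα traces are
compared by intra-window distance-matrix similarity, mutually consistent
window pairs are chained greedily, the chain seeds a Kabsch fit, and
pairing is refined by iterative nearest-neighbour reassignment within 5 Å.
On noiseless transformed copies this recovers the planted transform to
round-off; on genuinely different folds the result depends (as for all such
tools) on the fragment length and cutoffs, which are therefore explicit
parameters.

## Clashes, contacts, metal sites

Steric overlap between two atoms is r_vdw(A) + r_vdw(B) − d with a single
shipped Bondi-type radius set (C 1.70, N 1.55, O 1.52, S 1.80 Å, plus ions);
radii are data, not configuration, so results are reproducible.  Overlap
≥ 0.4 Å counts as a clash and ≥ 0.6 Å as serious, consistent with common
steric-validation practice.  Self-mode excludes intra-residue pairs and
sequence-adjacent backbone pairs (covalently bonded neighbours).  Neighbour
enumeration uses a k-d tree with a radius bound of 2·r_max − threshold and
is exact — the test suite asserts set equality with brute-force all-pairs
on random fixtures.

Polar contacts are a distance-only hydrogen-bond proxy: the minimal
N/O–N/O heavy-atom distance per residue pair, cutoff 3.5 Å, no angle term
(no protons exist to define one at this resolution).  Metal coordination
lists protein N/O atoms within 3.2 Å of a named hetero-site ion, sorted by
distance; on the deposited native structure this recovers the RNase H
carboxylates chelating the buffer-derived Ca²⁺.

## Solvent accessibility and buried surface

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å): per-atom area is the unoccluded point
fraction × 4π(rᵢ+probe)².  The spiral is fixed, not randomly rotated, so
every number is bit-reproducible; the cost is a small deterministic bias
for very small exposed caps, which is why closed-form comparisons on thin
spherical caps use a finer point set (the convergence test shows totals
move < 1% between 960 and 9600 points on compact fixtures).  Exactly
coincident equal-radius atoms (a degenerate fixture case) are collapsed so
the union of two coincident spheres scores one sphere's area.

Buried surface between disjoint groups A, B is
BSA = SASA(A) + SASA(B) − SASA(A∪B), with isolated-group SASA computed on
coordinates taken verbatim from the parent model (no re-packing), matching
how domain interfaces are fed to interface servers.  Because servers differ
on whether the printed number is this total ΔASA or its half, the interface
table reports **both** conventions ("buried-total" and "interface-half")
and never silently picks one; pairs burying < 10 Å² are reported as
no-contact (the dash entries of a domain-interface table).

The interaction free-energy estimate is a transparent atomic-solvation-
parameter model, ΔG = Σ σ(element)·ΔASA(atom), with Eisenberg–McLachlan-type
magnitudes (σ_C = −16, σ_S = −21, σ_N = σ_O = +6 cal mol⁻¹ Å⁻²; negative =
burial favourable).  Thermodynamic interface servers add hydrogen-bond and
salt-bridge terms from an unpublished parameterisation, so only the sign of
an interface's ΔG and the rank order across interfaces are claimed — never
magnitudes.

## Two-fold protease dimer modelling

Retroviral PRs are active only as C2 homodimers.  `build_twofold_dimer`
places two copies of a monomer onto the two chains of a homodimer template:
guide Cα atoms (default the PR core, residues 10–99; the disordered PR
N-terminus 1–9 is excluded) are paired to each template chain by the
sequence-independent alignment and fitted by Kabsch.  The copy-1→copy-2
relative transform yields the dimer axis by screw decomposition (rotation
angle from the trace, axis from the symmetric eigenproblem, axis point from
the least-squares solution of (I−R)p = t⊥); an accepted two-fold has a
rotation angle within [170°, 190°].  No energy minimisation or side-chain
repacking is performed — instead the inter-copy clash report quantifies the
steric strain the placement leaves, with overlap ≥ 0.6 Å treated as
significant.  Reporting clashes rather than relaxing them keeps the model's
quality honest and auditable.

## Instability index and saturation scanning

The instability index of a sequence s of length L is
II = (10/L) Σᵢ DIWV(sᵢ, sᵢ₊₁), using the published 20×20 dipeptide
instability weight table (shipped as data with a SHA-256 fingerprint; the
test suite cross-checks the whole implementation against Biopython's
independent ProtParam route).  II < 40 classifies a sequence stable; the
boundary value 40 itself is classified unstable.  The saturation scan
evaluates all L×19 single substitutions; since a substitution at position i
touches only the (i−1,i) and (i,i+1) dipeptides, each variant is scored
incrementally from the wild-type dipeptide sum, and the tests prove the
incremental path exactly equal to full recomputation.  Hotspots are ranked
by the most negative achievable ΔII, ties broken by ascending position.
This is the engineering procedure that flags destabilising positions in a
polyprotein construct and motivates stabilising substitutions (for PFV
PR-RT: H507D and S584K, combined with C280S into the crystallisable triple
mutant; the construct's index, computed on the 751-residue sequence, sits
just under the stability threshold at 39.75).

## Synthetic fixtures: what they show and what they do not

The generators produce: two-pseudo-atom sphere pairs whose SASA/BSA are
known in closed form (spherical caps); ideal Cα helices (rise 1.5 Å, twist
100°, radius 2.3 Å, giving the canonical ~3.8 Å Cα spacing); two compact
Gaussian domain clouds (σ = 4 Å, 20 residues each) whose burial decreases
monotonically with centre separation; exact C2 dimers built by a 180°
rotation about a chosen axis; octahedral metal sites; uniform random clouds
for grid-vs-brute-force property tests; and sequences hill-climbed to a
target instability index.  All generators are deterministic given their
parameters and seed (PCG64; the seed is written into fixture headers), and
pseudo-atoms use element C so radius lookups work — they are geometric test
bodies, not chemical models.

Passing on these fixtures demonstrates algorithmic correctness (closed-form
agreement, exact grid/brute-force equivalence, exact transform recovery,
incremental/full-scan identity, byte-level pipeline determinism).  It does
not demonstrate agreement with experimentally deposited structures: those
files are too large to ship as text fixtures and must be fetched (see
`data/deposited/README.md`); `scripts/reproduce_deposited.py` then runs the
full reproduction — residue counts, the mutant-vs-native superposition, the
domain interface matrix under both conventions, the Ca²⁺ site, and the
dimer-model-vs-HIV-1-PR alignment.

## Numerical choices and degenerate inputs

* Sphere sampling n = 960 by default; desk checks against thin analytic
  caps use up to 9600.  Sampling noise tolerance for "zero burial" is 1 Å².
* Kabsch requires ≥ 3 non-collinear pairs; the dimer builder requires ≥ 20
  aligned guide pairs per template chain.
* Fragment alignment: 8-mers, seed tolerance 1.5 Å mean distance-matrix
  difference, 5 Å refinement cutoff, ≤ 10 refinement cycles.
* Hotspot ties break by ascending position; altloc ties by letter;
  clash pairs sort by decreasing overlap.
* Problem sizes in the default test run are deliberately modest (clouds of
  500–1000 atoms, 50-mer scan sequences, 30-residue helices): they are the
  smallest sizes at which the properties under test are non-trivial, and
  they keep the whole suite fast enough to run on every change.

## Known limitations

* Solvent-excluded (molecular) surface, curvature and shape complementarity
  are out of scope; only solvent-accessible areas are computed.
* ΔG estimates carry sign/rank information only.
* Polar contacts have no angular term and will over-count near-miss
  geometries that a full hydrogen-bond model would reject.
* The dimer builder does not regularise geometry; a model with many serious
  clashes is reported as such, not repaired.
* The sequence-independent alignment is a compact re-implementation of the
  fragment-seeding idea, adequate for protease-scale traces; it is not a
  drop-in replacement for mature CE/TM-align implementations on hard,
  repetitive, or domain-swapped cases.
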