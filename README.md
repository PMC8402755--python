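# polyprot

Domain-resolved structural analysis of retroviral polyproteins.

Retroviral enzymes are synthesised as multi-domain polyprotein precursors.
The foamy-virus protease–reverse transcriptase (PFV PR-RT) is a striking
case: a single 751-residue chain carrying the protease (PR, active only as
a C2-symmetric homodimer), a protease C-terminal extension, the four
polymerase subdomains (fingers, palm, thumb, connection) and the RNase H
domain, all of which must rearrange for the enzyme's activities.
Characterising such a chain means asking quantitative structural questions:
how much surface is buried between each pair of (sub)domains, and how
strong are those interfaces; how similar are two crystal forms; can a
catalytically competent protease dimer be modelled without steric
collapse; and can the construct itself be engineered for stability from
sequence alone.  `polyprot` implements that toolchain as a tested library
plus a thin CLI, for structural biologists working on polyproteins and
multi-domain enzymes.

## What it computes

* **Structure I/O** — PDB/mmCIF parsing (gemmi) into an author-numbered
  chain/residue/atom model; fixed-column PDB writing; range selections like
  `"A:450-590,A:593-751"`.
* **Domain maps** — the PFV PR-RT seven-domain partition (with catalytic
  feature sites) plus user maps from plain-text configs; per-residue
  annotation and per-domain atom groups with coverage reporting.
* **Superposition** — Kabsch SVD fit (reflection-corrected),
  RMSD = √(Σ‖Rpᵢ+t−qᵢ‖²/n), plain and 2σ-trimmed; sequence-independent
  fragment-seeded Cα alignment for low-identity comparisons.
* **Surfaces** — Shrake–Rupley SASA on a deterministic golden-spiral point
  set; pairwise inter-domain buried surface
  BSA = SASA(A)+SASA(B)−SASA(A∪B) under both the buried-total and
  interface-half conventions; atomic-solvation ΔG estimates
  ΔG = Σ σ(element)·ΔASA (sign and rank order only).
* **Geometry checks** — van der Waals clash reports (overlap ≥ 0.4 Å;
  serious ≥ 0.6 Å), distance-based polar contacts, metal-coordination
  spheres.
* **Dimer modelling** — placement of two monomer copies on a protease
  homodimer template, recovery of the two-fold axis by screw decomposition,
  inter-copy clash assessment instead of energy minimisation.
* **Stability engineering** — dipeptide instability index
  II = (10/L)·Σ DIWV(sᵢ,sᵢ₊₁), exhaustive L×19 saturation scanning with
  provably exact incremental evaluation, hotspot ranking and variant
  application (`"C280S/H507D/S584K"`).

## Worked example

Everything below runs on synthetic inputs with known answers — no
downloads.

```python
from polyprot import synthetic, select_atoms, buried_surface, saturation_scan
from polyprot.surfaces import sphere_pair_bsa
from polyprot.dimer_model import build_twofold_dimer

# Two 1.7 A carbon spheres 3.1 A apart: burial has a closed form
pair = synthetic.make_sphere_pair(1.7, 3.1)
bsa, half = buried_surface(select_atoms(pair, "A:1-1"), select_atoms(pair, "B:1-1"))
print(f"buried area: {bsa:.1f} A^2 (analytic {sphere_pair_bsa(1.7, 3.1):.1f})")

# Saturation scan of a 100-mer generated near the stability threshold
seq = synthetic.sequence_with_target_ii(39.75, tol=0.5, length=100, seed=7)
scan = saturation_scan(seq)
print(f"II = {scan.ii_wild:.2f}")
print(scan.top_hotspots(3).to_string(index=False))

# Two-fold dimer from an exact C2 template, with clash accounting
helix = synthetic.make_ideal_helix(30)
template = synthetic.make_c2_dimer(helix, axis=(0, 0, 1), point=(2.5, 0, 0))
dimer = build_twofold_dimer(helix, template, guide_range="1-30")
print(f"rotation angle: {dimer.rotation_angle:.3f} deg, "
      f"clashes: {dimer.clash.count}, serious: {dimer.n_serious_clashes()}")
```

Output:

```
buried area: 60.5 A^2 (analytic 60.4)
II = 39.71
 rank  position wild  best_delta_ii best_substitution
    1        99    P         -7.828                 Q
    2        66    A         -5.902                 Q
    3        90    P         -5.550                 G
rotation angle: 180.000 deg, clashes: 12, serious: 12
```

The buried area agrees with the spherical-cap closed form to sampling
precision; the scan's hotspot table says position 99 (a proline) is the
single most stabilising substitution site, lowering the index by 7.8 units
if mutated to glutamine; and the dimer builder recovers the planted 180°
axis exactly while reporting the 12 inter-copy overlaps this deliberately
tight template plants.

The same operations run from the shell:

```
polyprot fixtures helix --out helix.pdb
polyprot sasa helix.pdb
polyprot annotate structure.pdb --map pfv_default
polyprot interfaces structure.pdb --convention both
polyprot superpose a.pdb b.pdb --trim
polyprot dimer monomer.pdb --template dimer_template.pdb --out dimer.pdb
polyprot run config.json          # full pipeline -> TSV + summary.json bundle
```

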