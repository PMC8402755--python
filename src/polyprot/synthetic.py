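"""Synthetic structures and sequences with analytically known properties.

Every generator is deterministic given its parameters (and seed, where one
is used); randomized fixtures use ``numpy.random.Generator(PCG64(seed))``
and the seed is recorded in the emitted PDB header when a fixture is written
to disk.  Pseudo-atom fixtures use element "C" so that radius lookups work —
they are geometric test bodies, not chemical models.

The generators cover every analysis stage: sphere pairs with closed-form
buried area (surfaces), ideal helices (superposition, clashes, I/O), compact
two-domain clouds with burial monotone in separation (interface tables),
exact C2 dimers (symmetric dimer modelling), octahedral metal sites
(coordination detection), random clouds (grid-vs-brute-force property
tests), and sequences hill-climbed to a target instability index
(stability classification).
"""

from __future__ import annotations

import numpy as np

from .structure_io import Atom, Residue, StructureModel, write_structure
from .domains import DomainMap
from .geometry import rotation_about_axis
from .stability import DIWV, STANDARD_AA, instability_index


def _pseudo_residue(number: int, coords, name: str = "ALA", atom_name: str = "CA",
                    element: str = "C") -> Residue:
    return Residue(number=number, name=name,
                   atoms=[Atom(name=atom_name, element=element, coords=np.asarray(coords, float))])


def make_sphere_pair(radius: float, separation: float) -> StructureModel:
    """Two carbon pseudo-atoms on the x axis, one per chain (A and B).

    The pair's SASA and buried area are known in closed form (spherical
    caps); see :func:`polyprot.surfaces.sphere_pair_bsa`.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    return StructureModel(
        id=f"sphere_pair_r{radius}_d{separation}",
        chains={
            "A": [_pseudo_residue(1, (0.0, 0.0, 0.0))],
            "B": [_pseudo_residue(1, (separation, 0.0, 0.0))],
        },
    )


def make_ideal_helix(n: int, rise: float = 1.5, twist_deg: float = 100.0,
                     helix_radius: float = 2.3, chain: str = "A",
                     start_number: int = 1) -> StructureModel:
    """C-alpha trace of an ideal alpha-helix (~3.8 Å consecutive Cα spacing).

    Self-clash-free at the default overlap threshold.
    """
    if n < 4:
        raise ValueError("need at least 4 residues for a helix")
    residues = []
    for i in range(n):
        theta = np.radians(twist_deg * i)
        coords = (helix_radius * np.cos(theta), helix_radius * np.sin(theta), rise * i)
        residues.append(_pseudo_residue(start_number + i, coords))
    return StructureModel(id=f"helix{n}", chains={chain: residues})


def make_two_domain(separation: float, seed: int = 0, n_per_domain: int = 20,
                    spread: float = 4.0) -> tuple[StructureModel, DomainMap]:
    """Two compact random clouds whose buried area decreases with separation.

    The two domains are independently sampled centred clouds (so they are
    structurally distinct), with the second placed ``separation`` Å along x
    (centre-to-centre); only the separation varies between fixtures of the
    same seed, so burial is a monotone function of ``separation`` alone.
    Residues 1..n are domain D1, n+1..2n are D2, one carbon pseudo-atom each.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(np.random.PCG64(seed))
    cloud1 = rng.normal(scale=spread, size=(n_per_domain, 3))
    cloud1 -= cloud1.mean(axis=0)
    cloud2 = rng.normal(scale=spread, size=(n_per_domain, 3))
    cloud2 -= cloud2.mean(axis=0)
    residues = [ _pseudo_residue(i + 1, cloud1[i]) for i in range(n_per_domain) ]
    shifted = cloud2 + np.array([separation, 0.0, 0.0])
    residues += [ _pseudo_residue(n_per_domain + i + 1, shifted[i]) for i in range(n_per_domain) ]
    model = StructureModel(id=f"two_domain_sep{separation}_seed{seed}",
                           chains={"A": residues})
    domain_map = DomainMap(segments={
        "D1": [(1, n_per_domain)],
        "D2": [(n_per_domain + 1, 2 * n_per_domain)],
    })
    return model, domain_map


def make_c2_dimer(monomer: StructureModel, axis=(0.0, 0.0, 1.0),
                  point=(0.0, 0.0, 0.0)) -> StructureModel:
    """Exact two-fold dimer: chain B is chain(s) of ``monomer`` rotated 180°
    about the given axis through ``point``.

    The chain A → chain B transform is an exact 180° rotation, so its matrix
    trace is −1 and the dimer-builder must recover the axis to round-off.
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-8:
        raise ValueError("axis must be a unit vector")
    point = np.asarray(point, dtype=float)
    R = rotation_about_axis(axis, 180.0)
    t = point - R @ point
    chains = {}
    src = monomer.chains[monomer.first_chain()]
    chains["A"] = [
        Residue(number=r.number, name=r.name, insertion_code=r.insertion_code,
                atoms=[Atom(name=a.name, element=a.element, coords=a.coords.copy(),
                            occupancy=a.occupancy, b_factor=a.b_factor,
                            alt_loc=a.alt_loc, is_hetero=a.is_hetero)
                       for a in r.atoms])
        for r in src
    ]
    chains["B"] = [
        Residue(number=r.number, name=r.name, insertion_code=r.insertion_code,
                atoms=[Atom(name=a.name, element=a.element, coords=R @ a.coords + t,
                            occupancy=a.occupancy, b_factor=a.b_factor,
                            alt_loc=a.alt_loc, is_hetero=a.is_hetero)
                       for a in r.atoms])
        for r in src
    ]
    return StructureModel(id=f"{monomer.id}_c2", chains=chains)


def make_metal_site(ion: str = "CA", distance: float = 2.4) -> StructureModel:
    """Octahedral toy metal site: one hetero ion with six oxygen ligands at
    ``distance`` Å along ±x, ±y, ±z (each ligand its own residue)."""
    directions = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    ], dtype=float)
    residues = [
        _pseudo_residue(i + 1, d * distance, name="ASP", atom_name="OD1", element="O")
        for i, d in enumerate(directions)
    ]
    model = StructureModel(id=f"metal_site_{ion}", chains={"A": residues})
    model.hetero_sites.append(
        (ion, Atom(name=ion, element=ion, coords=np.zeros(3), is_hetero=True))
    )
    return model


def make_random_cloud(n: int, seed: int, box: float = 20.0) -> StructureModel:
    """``n`` carbon pseudo-atoms uniform in a cube of side ``box`` Å
    (one residue per atom), for grid-vs-brute-force property tests."""
    rng = np.random.default_rng(np.random.PCG64(seed))
    coords = rng.uniform(0.0, box, size=(n, 3))
    residues = [_pseudo_residue(i + 1, coords[i]) for i in range(n)]
    return StructureModel(id=f"cloud{n}_seed{seed}", chains={"A": residues})


def write_fixture(model: StructureModel, path, seed: int | None = None):
    """Write a fixture as PDB, recording the generator seed in the header."""
    remarks = [f"SYNTHETIC FIXTURE {model.id}"]
    if seed is not None:
        remarks.append(f"GENERATOR SEED {seed}")
    return write_structure(model, path, remarks=remarks)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

class TargetUnreachableError(RuntimeError):
    """Hill climb could not reach the requested instability index."""


def sequence_with_target_ii(
    target: float,
    tol: float = 0.5,
    length: int = 100,
    seed: int = 0,
    max_iter: int = 20000,
) -> str:
    """Random sequence hill-climbed to instability index ``target`` ± ``tol``.

    Stochastic single-substitution hill climb, deterministic given
    ``seed``; raises :class:`TargetUnreachableError` after ``max_iter``
    proposals rather than returning an out-of-band sequence.
    """
    if length < 2:
        raise ValueError("need length >= 2 for a non-trivial dipeptide sum")
    rng = np.random.default_rng(np.random.PCG64(seed))
    aas = list(STANDARD_AA)
    seq = list(rng.choice(aas, size=length))
    ii = instability_index("".join(seq))
    if abs(ii - target) <= tol:
        return "".join(seq)
    for _ in range(max_iter):
        pos = int(rng.integers(length))
        new_aa = aas[int(rng.integers(20))]
        if new_aa == seq[pos]:
            continue
        old_aa = seq[pos]
        seq[pos] = new_aa
        new_ii = instability_index("".join(seq))
        if abs(new_ii - target) < abs(ii - target):
            ii = new_ii
            if abs(ii - target) <= tol:
                return "".join(seq)
        else:
            seq[pos] = old_aa
    raise TargetUnreachableError(
        f"|II - {target}| <= {tol} not reached in {max_iter} proposals (best {ii:.2f})"
    )


def min_homodipeptide() -> tuple[str, float]:
    """(residue, weight) of the minimal-weight homodipeptide in the table."""
    best = min(STANDARD_AA, key=lambda a: DIWV[a][a])
    return best, DIWV[best][best]
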