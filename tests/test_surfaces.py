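import numpy as np
import pytest

from polyprot import buried_surface, delta_g_estimate, interface_table, sasa, select_atoms
from polyprot.surfaces import (
    SOLVATION_SIGMA,
    SasaParams,
    golden_spiral_points,
    sphere_pair_bsa,
    sphere_sasa,
)
from polyprot import synthetic


def groups_of_pair(model):
    return select_atoms(model, "A:1-1"), select_atoms(model, "B:1-1")


def test_golden_spiral_is_quasi_uniform():
    pts = golden_spiral_points(960)
    assert pts.shape == (960, 3)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    assert np.linalg.norm(pts.mean(axis=0)) < 0.01


def test_single_atom_sasa_is_exact_sphere_area():
    """One carbon, probe 1.4: every sphere point is exposed, so the result is
    exactly 4*pi*(1.7+1.4)^2 ~ 120.76 A^2."""
    m = synthetic.make_sphere_pair(1.7, 100.0)
    res = sasa(select_atoms(m, "A:1-1"))
    assert res.total == pytest.approx(sphere_sasa(1.7), rel=5e-3)
    assert res.total == pytest.approx(120.76, abs=0.05)


@pytest.mark.parametrize(
    "d, n_points",
    [(1.0, 960), (2.0, 960), (3.1, 960), (4.5, 9600)],
)
def test_two_sphere_burial_matches_cap_formula(d, n_points):
    """Each overlapping sphere loses cap area 2*pi*R*h, h = R - d/2.

    Small caps (large d) carry few sample points, so the finer point set is
    used where the cap covers only a few percent of the sphere.
    """
    m = synthetic.make_sphere_pair(1.7, d)
    ga, gb = groups_of_pair(m)
    bsa, half = buried_surface(ga, gb, SasaParams(n_points=n_points))
    exact = sphere_pair_bsa(1.7, d)
    assert bsa == pytest.approx(exact, rel=0.01)
    assert half == pytest.approx(bsa / 2.0)


def test_far_spheres_bury_nothing():
    m = synthetic.make_sphere_pair(1.7, 50.0)
    bsa, _ = buried_surface(*groups_of_pair(m))
    assert abs(bsa) < 1.0


def test_coincident_spheres_union_is_one_sphere():
    m = synthetic.make_sphere_pair(1.7, 0.0)
    ga, gb = groups_of_pair(m)
    union = sasa(ga + gb).total
    assert union == pytest.approx(sphere_sasa(1.7), rel=5e-3)


def test_per_atom_bounded_and_total_consistent(rng):
    cloud = synthetic.make_random_cloud(60, seed=7, box=10.0)
    g = select_atoms(cloud)
    res = sasa(g)
    R = 1.7 + 1.4
    assert np.all(res.per_atom >= 0.0)
    assert np.all(res.per_atom <= 4 * np.pi * R * R + 1e-9)
    assert res.total == pytest.approx(res.per_atom.sum())


def test_point_count_convergence():
    """960 vs 9600 points on a 100-atom cloud: totals agree within 1%."""
    cloud = synthetic.make_random_cloud(100, seed=5, box=12.0)
    g = select_atoms(cloud)
    coarse = sasa(g, SasaParams(n_points=960)).total
    fine = sasa(g, SasaParams(n_points=9600)).total
    assert coarse == pytest.approx(fine, rel=0.01)


def test_sasa_occlusion_matches_brute_force():
    """Tree-pruned neighbour occlusion equals all-pairs occlusion exactly."""
    cloud = synthetic.make_random_cloud(80, seed=9, box=10.0)
    g = select_atoms(cloud)
    params = SasaParams(n_points=240)
    fast = sasa(g, params).per_atom

    coords, radii = g.coords(), np.full(len(g), 1.7 + params.probe_radius)
    sphere = golden_spiral_points(params.n_points)
    brute = np.empty(len(g))
    for i in range(len(g)):
        pts = coords[i] + radii[i] * sphere
        others = [j for j in range(len(g)) if j != i]
        d2 = ((pts[:, None, :] - coords[others][None, :, :]) ** 2).sum(-1)
        buried = (d2 < radii[others][None, :] ** 2).any(1)
        brute[i] = (1 - buried.mean()) * 4 * np.pi * radii[i] ** 2
    assert np.allclose(fast, brute, atol=1e-9)


def test_complex_sasa_never_exceeds_sum_of_parts():
    for sep in (2.0, 6.0, 12.0):
        model, dmap = synthetic.make_two_domain(sep, seed=21)
        from polyprot import domain_atom_groups

        groups, _ = domain_atom_groups(model, dmap)
        sa = sasa(groups["D1"]).total
        sb = sasa(groups["D2"]).total
        sab = sasa(groups["D1"] + groups["D2"]).total
        assert sab <= sa + sb + 1.0


def test_burial_symmetric_and_monotone_in_separation():
    values = []
    for sep in (4.0, 8.0, 16.0):
        model, dmap = synthetic.make_two_domain(sep, seed=11)
        from polyprot import domain_atom_groups

        groups, _ = domain_atom_groups(model, dmap)
        ab, _ = buried_surface(groups["D1"], groups["D2"])
        ba, _ = buried_surface(groups["D2"], groups["D1"])
        assert ab == pytest.approx(ba, abs=1e-9)
        values.append(ab)
    assert values[0] > values[1] > values[2]


def test_overlapping_groups_rejected(two_domain):
    model, dmap = two_domain
    g = select_atoms(model, "A:1-20")
    with pytest.raises(ValueError):
        buried_surface(g, g)


def test_interface_table_consistency(two_domain):
    model, dmap = two_domain
    report = interface_table(model, dmap)
    from polyprot import domain_atom_groups

    groups, _ = domain_atom_groups(model, dmap)
    bsa, half = buried_surface(groups["D1"], groups["D2"])
    assert report.bsa.loc["D1", "D2"] == pytest.approx(bsa)
    assert report.bsa.loc["D2", "D1"] == pytest.approx(bsa)
    assert report.interface_area.loc["D1", "D2"] == pytest.approx(half)
    assert np.isnan(report.bsa.loc["D1", "D1"])
    assert report.row_sum("D1") == pytest.approx(bsa)
    tsv = report.to_tsv("buried-total")
    assert tsv.splitlines()[0] == "domain\tD1\tD2"


def test_interface_table_needs_two_groups(helix20):
    from polyprot.domains import DomainMap

    with pytest.raises(ValueError):
        interface_table(helix20, DomainMap(segments={"only": [(1, 20)]}))


def test_no_contact_pairs_masked():
    model, dmap = synthetic.make_two_domain(40.0, seed=2)
    report = interface_table(model, dmap)
    assert report.bsa.loc["D1", "D2"] < report.no_contact_bsa
    assert "-" in report.to_tsv("buried-total").splitlines()[1].split("\t")[2]


def test_delta_g_zero_for_distant_groups():
    m = synthetic.make_sphere_pair(1.7, 50.0)
    assert delta_g_estimate(*groups_of_pair(m)) == pytest.approx(0.0, abs=0.02)


def test_delta_g_apolar_pair_is_sigma_times_bsa():
    """Pure-carbon contact: dG = sigma_C x BSA, i.e. favourable (negative)."""
    m = synthetic.make_sphere_pair(1.7, 3.1)
    ga, gb = groups_of_pair(m)
    bsa, _ = buried_surface(ga, gb)
    dg = delta_g_estimate(ga, gb)
    assert dg == pytest.approx(SOLVATION_SIGMA["C"] * bsa, rel=1e-9)
    assert dg < 0


def test_biotite_cross_check():
    """Independent Shrake-Rupley implementation agrees on a random cloud."""
    import biotite.structure as biotite_struct

    cloud = synthetic.make_random_cloud(50, seed=13, box=10.0)
    g = select_atoms(cloud)
    mine = sasa(g, SasaParams(n_points=1000)).total

    arr = biotite_struct.AtomArray(len(g))
    arr.coord = g.coords().astype(np.float32)
    arr.element = np.array(["C"] * len(g))
    arr.res_id = np.arange(1, len(g) + 1)
    arr.atom_name = np.array(["CA"] * len(g))
    arr.res_name = np.array(["ALA"] * len(g))
    arr.chain_id = np.array(["A"] * len(g))
    theirs = float(
        biotite_struct.sasa(
            arr, probe_radius=1.4, point_number=1000, vdw_radii=np.full(len(g), 1.7)
        ).sum()
    )
    assert mine == pytest.approx(theirs, rel=0.02)
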