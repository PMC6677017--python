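"""Probe models, RSCC, real-space refinement and the 21 features."""

import gemmi
import numpy as np
import pytest

from solventscope.features import (FeatureVector, ProbeModel, atom_contact_type,
                                   extract_cc, extract_ed, gaussian_width,
                                   model_density, peak_volume, probe_rscc,
                                   real_space_refine, rscc)
from solventscope.structures import Atom, DensityGrid, Peak, StructureModel

CELL = gemmi.UnitCell(20, 20, 20, 90, 90, 90)


def _probe_grid(probe, center, resolution=2.0, n=40, edge=20.0, kind="two_fofc"):
    """Grid synthesized from the probe itself (the construction oracle)."""
    els, xyz = probe.atoms_at(center)
    ax = np.arange(n) * edge / n
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    sigma = gaussian_width(resolution)
    v = model_density(els, xyz, pts, sigma).reshape(n, n, n)
    g = DensityGrid(kind, v, gemmi.UnitCell(edge, edge, edge, 90, 90, 90))
    return g.standardize()


# --- rscc -------------------------------------------------------------------

def test_rscc_trivials():
    a = np.array([1.0, 2.0, 3.0, 2.5])
    assert rscc(a, a) == pytest.approx(1.0)
    assert rscc(a, -a) == pytest.approx(-1.0)
    assert rscc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)   # affine invariance


def test_rscc_degenerate_region():
    with pytest.raises(ValueError, match="degenerate"):
        rscc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# --- model density ----------------------------------------------------------

def test_model_density_peaks_at_atom():
    pts = np.array([[0, 0, 0], [0.5, 0, 0], [1.5, 0, 0]])
    v = model_density(["O"], np.zeros((1, 3)), pts, sigma=0.8)
    assert v[0] > v[1] > v[2]


def test_sulfate_integrates_more_than_water():
    ax = np.linspace(-4, 4, 33)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    ew, xw = ProbeModel("water").atoms_at(np.zeros(3))
    es, xs = ProbeModel("sulfate").atoms_at(np.zeros(3))
    assert model_density(es, xs, pts, 0.8).sum() > model_density(ew, xw, pts, 0.8).sum()


def test_rscc_invariant_to_amplitude_scaling():
    rng = np.random.default_rng(0)
    m = rng.normal(size=100)
    o = rng.normal(size=100)
    assert rscc(2.0 * m, o) == pytest.approx(rscc(m, o), abs=1e-12)


def test_sulfate_geometry_is_ideal():
    _, xyz = ProbeModel("sulfate").atoms_at(np.zeros(3))
    s, os_ = xyz[0], xyz[1:]
    for o in os_:
        assert np.linalg.norm(o - s) == pytest.approx(1.49, abs=1e-6)
    for i in range(4):
        for j in range(i + 1, 4):
            v1, v2 = os_[i] - s, os_[j] - s
            ang = np.degrees(np.arccos(np.dot(v1, v2) / 1.49**2))
            assert ang == pytest.approx(109.4712, abs=1e-3)


# --- real-space refinement --------------------------------------------------

@pytest.mark.parametrize("species", ["water", "sulfate"])
def test_refinement_fixed_point(species):
    probe = ProbeModel(species)
    center = np.array([10.0, 10.0, 10.0])
    g = _probe_grid(probe, center)
    refined, cc = real_space_refine(probe, g, center)
    assert np.linalg.norm(refined.translation) < 0.05
    assert cc > 0.99


def test_refinement_recovers_displacement():
    probe = ProbeModel("water")
    true_center = np.array([10.0, 10.0, 10.6])
    start = np.array([10.0, 10.0, 10.0])
    g = _probe_grid(probe, true_center)
    refined, cc = real_space_refine(probe, g, start, max_shift=1.0)
    assert np.linalg.norm(refined.translation - (true_center - start)) < 0.1
    assert cc > 0.98


def test_refinement_on_noise_has_low_rscc():
    rng = np.random.default_rng(7)
    g = DensityGrid("two_fofc", rng.normal(size=(40, 40, 40)), CELL).standardize()
    _, cc = real_space_refine(ProbeModel("water"), g, np.array([10.0, 10.0, 10.0]))
    assert cc < 0.5   # pure noise: no coherent density to fit


def test_refinement_outside_grid_is_deterministic():
    probe = ProbeModel("sulfate")
    center = np.array([10.0, 10.0, 10.0])
    g = _probe_grid(probe, center)
    r1 = real_space_refine(probe, g, center)
    r2 = real_space_refine(probe, g, center)
    assert np.array_equal(r1[0].translation, r2[0].translation)
    assert r1[1] == r2[1]


# --- peak volume ------------------------------------------------------------

def _flat_grid(n=20, edge=10.0):
    return DensityGrid("two_fofc", np.zeros((n, n, n)),
                       gemmi.UnitCell(edge, edge, edge, 90, 90, 90))


def test_peak_volume_below_contour_is_zero():
    g = _flat_grid()
    assert peak_volume(g, np.array([5.0, 5.0, 5.0]), contour=1.0) == 0.0


def test_peak_volume_counts_voxels():
    g = _flat_grid()
    g.values[9:12, 9:12, 9:12] = 5.0     # 27 voxels above contour
    v = peak_volume(g, np.array([5.0, 5.0, 5.0]), contour=1.0)
    assert v == pytest.approx(27 * g.voxel_volume)


def test_peak_volume_ignores_disconnected_blob():
    g = _flat_grid()
    g.values[9:12, 9:12, 9:12] = 5.0
    g.values[1:3, 1:3, 1:3] = 5.0        # separate component across a gap
    v = peak_volume(g, np.array([5.0, 5.0, 5.0]), contour=1.0)
    assert v == pytest.approx(27 * g.voxel_volume)


# --- contact features -------------------------------------------------------

def _contact_structure(positions, resnames, names=None, elements=None):
    atoms = [Atom(element=(elements or ["C"] * len(positions))[i],
                  name=(names or ["CA"] * len(positions))[i],
                  resname=resnames[i], resid=i + 1, chain="A",
                  pos=np.asarray(p, dtype=float))
             for i, p in enumerate(positions)]
    return StructureModel(atoms=atoms, cell=CELL)


def test_cf1_nearest_macromolecule():
    st = _contact_structure([(10, 10, 13.1)], ["ALA"])
    peak = Peak(id="p", coordinate=np.array([10.0, 10.0, 10.0]),
                resolution=2.0, source="user")
    out = extract_cc(peak, st)
    assert out["CF1"] == pytest.approx(3.1, abs=1e-6)


def test_cf1_updated_by_validated_solvent():
    st = _contact_structure([(10, 10, 13.1)], ["ALA"])
    peak = Peak(id="p", coordinate=np.array([10.0, 10.0, 10.0]),
                resolution=2.0, source="user")
    out = extract_cc(peak, st, validated_solvent=[np.array([10.0, 10.0, 12.7])])
    assert out["CF1"] == pytest.approx(2.7, abs=1e-6)


def test_cf2_single_type_environment():
    st = _contact_structure([(10, 10, 12), (10, 12, 10), (12, 10, 10)],
                            ["ALA"] * 3, names=["CB"] * 3, elements=["C"] * 3)
    peak = Peak(id="p", coordinate=np.array([10.0, 10.0, 10.0]),
                resolution=2.0, source="user")
    weights = {"carbon": -0.1}
    out = extract_cc(peak, st, weights=weights)
    assert out["CF2"] == pytest.approx(3 * -0.1)


def test_isolated_peak_raises():
    atoms = [Atom(element="C", name="CA", resname="ALA", resid=1, chain="A",
                  pos=np.array([1.0, 1.0, 1.0]))]
    st = StructureModel(atoms=atoms, cell=gemmi.UnitCell(80, 80, 80, 90, 90, 90))
    peak = Peak(id="p", coordinate=np.array([40.0, 40.0, 40.0]),
                resolution=2.0, source="user")
    with pytest.raises(ValueError, match="isolated"):
        extract_cc(peak, st)


def test_atom_contact_typing():
    a = Atom(element="N", name="NZ", resname="LYS", resid=1, chain="A",
             pos=np.zeros(3))
    assert atom_contact_type(a) == "guanidinium_amine_N"
    b = Atom(element="O", name="O", resname="GLY", resid=1, chain="A",
             pos=np.zeros(3))
    assert atom_contact_type(b) == "backbone_O"


# --- full ED extraction on paired scenes ------------------------------------

def test_feature_vector_requires_all_21():
    with pytest.raises(ValueError, match="missing feature"):
        FeatureVector(peak_id="p", resolution=2.0, values={"CC1": 0.5})


@pytest.fixture(scope="module")
def paired_ed(water_scene, sulfate_scene):
    out = {}
    for name, scene in (("water", water_scene), ("sulfate", sulfate_scene)):
        peak = scene["peaks"][0]
        out[name] = extract_ed(peak, scene["grids"])
    return out


def test_sulfate_scene_prefers_sulfate_probe(paired_ed):
    # on sulfate density the tetrahedral probe beats the single-O probe
    assert paired_ed["sulfate"]["CC4"] > paired_ed["sulfate"]["CC2"]


def test_sulfate_volume_exceeds_water_volume(paired_ed):
    assert paired_ed["sulfate"]["ED4"] > paired_ed["water"]["ED4"]
    assert paired_ed["sulfate"]["ED3"] > paired_ed["water"]["ED3"]


def test_rotational_spread_nonnegative_and_small_for_sphere(paired_ed):
    for k in ("ED1", "ED2"):
        assert paired_ed["water"][k] >= 0
        assert paired_ed["sulfate"][k] >= 0
    # a single water blob is spherically symmetric: rotating the probe
    # around it cannot change the fit
    assert paired_ed["water"]["ED1"] < 0.02
    assert paired_ed["water"]["ED2"] < 0.02


def test_missing_grid_raises(water_scene):
    grids = dict(water_scene["grids"])
    del grids["pseudoinverse_fofc"]
    with pytest.raises(ValueError, match="pseudoinverse_fofc"):
        extract_ed(water_scene["peaks"][0], grids)


def test_ed_features_affine_invariant_rsccs(water_scene):
    """RSCC features are unchanged when map values are rescaled affinely."""
    peak = water_scene["peaks"][0]
    base = extract_ed(peak, water_scene["grids"])
    grids2 = {}
    for k, g in water_scene["grids"].items():
        g2 = DensityGrid(k, 3.0 * g.values + 1.0, g.cell, g.origin.copy())
        grids2[k] = g2
    out = extract_ed(peak, grids2)
    for f in [f"CC{i}" for i in range(1, 15)]:
        assert out[f] == pytest.approx(base[f], abs=1e-9)
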