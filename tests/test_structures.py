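"""Structure and map I/O, peak picking, symmetry-aware neighbor queries."""

import gemmi
import numpy as np
import pytest

from solventscope.features import rscc
from solventscope.structures import (Atom, DensityGrid, Peak, StructureModel,
                                     associate_solvent_peaks,
                                     find_difference_peaks, make_pseudoinverse,
                                     neighbors, read_density, read_peaks,
                                     read_structure, write_density,
                                     write_peaks, write_structure)

CELL = gemmi.UnitCell(20, 20, 20, 90, 90, 90)


def _toy_structure(positions, resnames=None, spacegroup="P 1", cell=CELL):
    atoms = [Atom(element="O", name="O", resname=(resnames or ["ALA"] * len(positions))[i],
                  resid=i + 1, chain="A", pos=np.asarray(p, dtype=float))
             for i, p in enumerate(positions)]
    return StructureModel(atoms=atoms, cell=cell, spacegroup=spacegroup)


def _gaussian_grid(centers, heights, n=40, edge=20.0, kind="fofc"):
    ax = np.arange(n) * edge / n
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    v = np.zeros((n, n, n))
    for c, h in zip(centers, heights):
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        v += h * np.exp(-d2 / (2 * 0.8**2))
    return DensityGrid(kind, v, gemmi.UnitCell(edge, edge, edge, 90, 90, 90))


# --- structure I/O ----------------------------------------------------------

def test_structure_roundtrip(tmp_path):
    st = _toy_structure([(3, 4, 5), (6, 7, 8), (9, 1, 2), (4, 4, 4), (11, 12, 13)])
    path = tmp_path / "toy.pdb"
    write_structure(st, path)
    back = read_structure(path)
    assert len(back.atoms) == 5
    for a, b in zip(st.atoms, back.atoms):
        assert np.linalg.norm(a.pos - b.pos) < 1e-3


def test_missing_unit_cell_raises(tmp_path):
    path = tmp_path / "nocell.pdb"
    path.write_text(
        "ATOM      1  O   HOH A   1       1.000   2.000   3.000  1.00 20.00           O\n"
        "END\n")
    with pytest.raises(ValueError, match="missing unit cell"):
        read_structure(path)


def test_peak_list_roundtrip(tmp_path):
    peaks = [Peak(id="P1", coordinate=np.array([1.0, 2.0, 3.0]),
                  resolution=2.0, source="difference_map"),
             Peak(id="P2", coordinate=np.array([4.0, 5.0, 6.0]),
                  resolution=2.0, source="user")]
    path = tmp_path / "peaks.tsv"
    write_peaks(peaks, path)
    back = read_peaks(path, resolution=2.0)
    assert [p.id for p in back] == ["P1", "P2"]
    assert np.allclose(back[0].coordinate, [1, 2, 3], atol=1e-3)


# --- density maps -----------------------------------------------------------

def test_map_sigma_standardization_and_roundtrip(tmp_path):
    g = _gaussian_grid([(10, 10, 10)], [5.0]).standardize()
    assert abs(g.values.mean()) < 1e-6
    assert abs(g.values.std() - 1) < 1e-6
    path = tmp_path / "m.ccp4"
    write_density(g, path)
    back = read_density(path, "fofc")
    assert back.kind == "fofc"
    # float32 storage dominates the round-trip error
    assert np.max(np.abs(back.values - g.values)) < 1e-5


def test_zero_variance_map_rejected():
    g = DensityGrid("fofc", np.zeros((8, 8, 8)), CELL)
    with pytest.raises(ValueError, match="zero variance"):
        g.standardize()


def test_pseudoinverse_negation_and_involution():
    g = _gaussian_grid([(10, 10, 10)], [5.0]).standardize()
    pg = make_pseudoinverse(g)
    assert pg.kind == "pseudoinverse_fofc"
    assert np.allclose(pg.values, -g.values)
    with pytest.raises(ValueError):
        make_pseudoinverse(pg)
    # applying the sign inversion twice restores the original values
    assert np.allclose(-make_pseudoinverse(g).values, g.values)


def test_pseudoinverse_rscc_antisymmetry():
    rng = np.random.default_rng(0)
    g = DensityGrid("fofc", rng.normal(size=(10, 10, 10)), CELL).standardize()
    model = rng.normal(size=200)
    obs = g.values.ravel()[:200]
    assert rscc(model, obs) + rscc(model, -obs) == pytest.approx(0.0, abs=1e-12)


# --- peak picking -----------------------------------------------------------

def test_flat_map_has_no_peaks():
    rng = np.random.default_rng(1)
    g = DensityGrid("fofc", rng.normal(0, 1e-3, (20, 20, 20)), CELL).standardize()
    # standardized noise rarely exceeds 5 sigma on 8000 voxels
    assert find_difference_peaks(g, 6.0) == []


def test_single_gaussian_peak_located():
    center = (10.1, 9.7, 10.4)
    g = _gaussian_grid([center], [5.0])
    g.values /= g.values.std()
    g.values -= g.values.mean()
    peaks = find_difference_peaks(g, 3.0)
    assert len(peaks) == 1
    # within half a voxel (0.25 Å at 0.5 Å spacing)
    assert np.linalg.norm(peaks[0].coordinate - np.array(center)) < 0.25


def test_two_separated_gaussians_give_two_peaks():
    g = _gaussian_grid([(7, 10, 10), (13, 10, 10)], [5.0, 5.0])
    g.values = (g.values - g.values.mean()) / g.values.std()
    assert len(find_difference_peaks(g, 3.0)) == 2


def test_peak_picking_translation_equivariance():
    g = _gaussian_grid([(10.1, 9.7, 10.4)], [5.0]).standardize()
    shift_vox = (3, 5, 7)
    g2 = DensityGrid("fofc", np.roll(g.values, shift_vox, axis=(0, 1, 2)), g.cell)
    p1 = find_difference_peaks(g, 3.0)[0]
    p2 = find_difference_peaks(g2, 3.0)[0]
    spacing = 20.0 / 40
    expected = p1.coordinate + np.array(shift_vox) * spacing
    assert np.linalg.norm((p2.coordinate - expected + 10) % 20 - 10) < 1e-6


# --- solvent association ----------------------------------------------------

def test_associate_solvent_within_cutoff():
    st = _toy_structure([(10, 10, 10)], resnames=["HOH"])
    map_peak = Peak(id="P1", coordinate=np.array([10.0, 10.0, 11.5]),
                    resolution=2.0, source="difference_map")
    out = associate_solvent_peaks(st, [map_peak], cutoff=2.0)
    assert len(out) == 1
    assert out[0].source == "solvent_model"
    assert out[0].linked_atom == 0


def test_associate_solvent_beyond_cutoff():
    st = _toy_structure([(10, 10, 10)], resnames=["HOH"])
    map_peak = Peak(id="P1", coordinate=np.array([10.0, 10.0, 12.5]),
                    resolution=2.0, source="difference_map")
    assert associate_solvent_peaks(st, [map_peak], cutoff=2.0) == []


def test_two_waters_nearest_same_peak_both_emitted():
    st = _toy_structure([(10, 10, 11), (10, 10, 9)], resnames=["HOH", "HOH"])
    map_peak = Peak(id="P1", coordinate=np.array([10.0, 10.0, 10.0]),
                    resolution=2.0, source="difference_map")
    out = associate_solvent_peaks(st, [map_peak], cutoff=2.0)
    assert len(out) == 2
    assert {o.linked_atom for o in out} == {0, 1}


# --- neighbors --------------------------------------------------------------

def _brute_force_neighbors(structure, coord, radius):
    """Independent oracle: explicit double loop over operators and 3x3x3 cells."""
    mat = np.array(structure.cell.orth.mat.tolist())
    fmat = np.array(structure.cell.frac.mat.tolist())
    found = []
    for ai, a in enumerate(structure.atoms):
        fa = fmat @ a.pos
        for R, t in structure.ops:
            fi = R @ fa + t
            for di in (-2, -1, 0, 1, 2):
                for dj in (-2, -1, 0, 1, 2):
                    for dk in (-2, -1, 0, 1, 2):
                        pos = mat @ (fi + np.array([di, dj, dk]))
                        d = np.linalg.norm(pos - coord)
                        if d <= radius:
                            found.append((ai, round(pos[0], 3), round(pos[1], 3),
                                          round(pos[2], 3), d))
    uniq = {}
    for ai, x, y, z, d in found:
        uniq[(ai, x, y, z)] = d
    return sorted(uniq.values())


@pytest.mark.parametrize("spacegroup", ["P 1", "P 21 21 21", "C 2"])
def test_neighbors_matches_brute_force(spacegroup):
    rng = np.random.default_rng(3)
    cell = gemmi.UnitCell(14, 17, 11, 90, 90 if spacegroup != "C 2" else 105, 90)
    st = _toy_structure(rng.uniform(0, 11, size=(12, 3)), spacegroup=spacegroup,
                        cell=cell)
    q = np.array([5.0, 6.0, 4.0])
    got = sorted(c.distance for c in neighbors(st, q, 7.0))
    expected = _brute_force_neighbors(st, q, 7.0)
    assert len(got) == len(expected)
    assert np.allclose(got, expected, atol=1e-6)


def test_neighbors_closed_ball_boundary():
    st = _toy_structure([(10, 10, 13)])
    got = neighbors(st, np.array([10.0, 10.0, 10.0]), radius=3.0)
    assert len(got) == 1 and got[0].distance == pytest.approx(3.0)


def test_neighbors_empty_structure():
    st = StructureModel(atoms=[], cell=CELL)
    assert neighbors(st, np.zeros(3), 5.0) == []


def test_neighbors_sorted_and_excludes():
    st = _toy_structure([(10, 10, 12), (10, 10, 14)], resnames=["ALA", "HOH"])
    got = neighbors(st, np.array([10.0, 10.0, 10.0]), 6.0,
                    exclude=lambda a: a.is_solvent)
    assert [c.atom_index for c in got] == [0]


def test_peak_source_validation():
    with pytest.raises(ValueError):
        Peak(id="x", coordinate=np.zeros(3), resolution=2.0, source="nonsense")


def test_out_of_range_resolution_flagged():
    p = Peak(id="x", coordinate=np.zeros(3), resolution=8.0, source="user")
    assert "out_of_range" in p.flags
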