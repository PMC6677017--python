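"""Structures, density grids, peak picking and symmetry-aware neighbor queries.

PDB/mmCIF structures and CCP4/MRC maps are read through gemmi; maps are
rescaled to sigma units (mean 0, sd 1 over the grid) on load.  Difference-map
peaks are 26-connected local maxima above a sigma threshold with a quadratic
sub-voxel interpolation of the maximum position.  Neighbor queries expand all
space-group operators and the 27 surrounding cell translations, so contacts
across crystallographic symmetry are counted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np
from scipy import ndimage

from .config import (
    HETEROGEN_RESNAMES,
    METAL_RESNAMES,
    RESOLUTION_RANGE,
    SOLVENT_RESNAMES,
    SULFATE_RESNAMES,
    WATER_RESNAMES,
)

MAP_KINDS = ("two_fofc", "fofc", "pseudoinverse_two_fofc", "pseudoinverse_fofc")
PSEUDOINVERSE_OF = {"two_fofc": "pseudoinverse_two_fofc", "fofc": "pseudoinverse_fofc"}


# ---------------------------------------------------------------------------
# Structure model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    element: str
    name: str
    resname: str
    resid: int
    chain: str
    pos: np.ndarray          # orthogonal Å
    occ: float = 1.0
    b: float = 20.0

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def is_solvent(self) -> bool:
        return self.resname in SOLVENT_RESNAMES

    def solvent_class(self) -> str | None:
        if self.resname in WATER_RESNAMES:
            return "water"
        if self.resname in SULFATE_RESNAMES:
            return "sulfate"
        if self.resname in METAL_RESNAMES:
            return "metal"
        if self.resname in HETEROGEN_RESNAMES:
            return "heterogen"
        return None


@dataclass
class StructureModel:
    """Atoms + unit cell + space-group operators + nominal resolution."""

    atoms: list
    cell: gemmi.UnitCell
    spacegroup: str = "P 1"
    resolution: float = 2.0

    def __post_init__(self):
        if self.cell.volume <= 0:
            raise ValueError("missing unit cell")
        for a in self.atoms:
            a.pos = np.asarray(a.pos, dtype=float)
            if not np.all(np.isfinite(a.pos)):
                raise ValueError("non-finite atom coordinate")

    @property
    def ops(self) -> list:
        """Symmetry operators as (rot 3x3, trans 3) acting on fractional coords."""
        sg = gemmi.SpaceGroup(self.spacegroup)
        out = []
        for op in sg.operations():
            R = np.array(op.rot, dtype=float) / op.DEN
            t = np.array(op.tran, dtype=float) / op.DEN
            out.append((R, t))
        return out

    def macromolecule_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_solvent]

    def solvent_atoms(self) -> list:
        return [a for a in self.atoms if a.is_solvent]

    def centroid(self) -> np.ndarray:
        macro = self.macromolecule_atoms() or self.atoms
        if not macro:
            return np.zeros(3)
        return np.mean([a.pos for a in macro], axis=0)

    def strip_solvent(self) -> "StructureModel":
        return StructureModel(
            atoms=[a for a in self.atoms if not a.is_solvent],
            cell=self.cell, spacegroup=self.spacegroup, resolution=self.resolution,
        )

    def frac(self, orth: np.ndarray) -> np.ndarray:
        f = self.cell.fractionalize(gemmi.Position(*orth))
        return np.array([f.x, f.y, f.z])

    def orth(self, frac: np.ndarray) -> np.ndarray:
        p = self.cell.orthogonalize(gemmi.Fractional(*frac))
        return np.array([p.x, p.y, p.z])


def read_structure(path: str) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (H atoms dropped)."""
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable structure file {path}: {exc}") from exc
    st.setup_entities()
    if st.cell.a <= 1.0 or st.cell.volume <= 1.5:
        raise ValueError(f"missing unit cell in {path}")
    sg = st.spacegroup_hm or "P 1"
    atoms = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    if at.element.is_hydrogen:
                        continue
                    atoms.append(Atom(
                        element=at.element.name,
                        name=at.name,
                        resname=res.name,
                        resid=res.seqid.num,
                        chain=chain.name,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occ=at.occ,
                        b=at.b_iso,
                    ))
        break  # first model only
    resolution = st.resolution if st.resolution and st.resolution > 0 else 2.0
    return StructureModel(atoms=atoms, cell=st.cell, spacegroup=sg, resolution=resolution)


def write_structure(model: StructureModel, path: str) -> None:
    st = gemmi.Structure()
    st.cell = model.cell
    st.spacegroup_hm = model.spacegroup
    st.resolution = model.resolution
    md = gemmi.Model("1")
    chains = {}
    for a in model.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        ch = chains[a.chain]
        res = None
        if len(ch) > 0 and ch[-1].seqid.num == a.resid and ch[-1].name == a.resname:
            res = ch[-1]
        if res is None:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resid, " ")
            ch.add_residue(res)
            res = ch[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.pos)
        at.occ = a.occ
        at.b_iso = a.b
        res.add_atom(at)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Density grids
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """A full-unit-cell density grid in sigma units.

    ``values[i, j, k]`` lives at fractional coordinate
    ``(i/nx, j/ny, k/nz) + origin``; the grid is periodic under unit-cell
    translations.
    """

    kind: str
    values: np.ndarray
    cell: gemmi.UnitCell
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3D with at least 2 points per axis")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.values.size

    def standardize(self) -> "DensityGrid":
        sd = self.values.std()
        if sd <= 0:
            raise ValueError("zero variance map")
        self.values = (self.values - self.values.mean()) / sd
        return self

    def frac_of_index(self, idx: np.ndarray) -> np.ndarray:
        n = np.array(self.shape, dtype=float)
        return np.asarray(idx, dtype=float) / n + self.origin

    def orth_of_index(self, idx: np.ndarray) -> np.ndarray:
        fr = self.frac_of_index(idx)
        fr = np.atleast_2d(fr)
        out = np.array([
            [*self.cell.orthogonalize(gemmi.Fractional(*f))] for f in fr
        ])
        return out[0] if out.shape[0] == 1 and np.asarray(idx).ndim == 1 else out

    def frac_of_orth(self, orth: np.ndarray) -> np.ndarray:
        f = self.cell.fractionalize(gemmi.Position(*orth))
        return np.array([f.x, f.y, f.z])

    def index_of_orth(self, orth: np.ndarray) -> np.ndarray:
        """Continuous (fractional) grid index of an orthogonal position."""
        n = np.array(self.shape, dtype=float)
        return (self.frac_of_orth(orth) - self.origin) * n

    def interp(self, orth_points: np.ndarray) -> np.ndarray:
        """Periodic trilinear interpolation at orthogonal positions (n, 3)."""
        pts = np.atleast_2d(np.asarray(orth_points, dtype=float))
        n = np.array(self.shape)
        mat = np.array(self.cell.frac.mat.tolist())
        fr = pts @ mat.T - self.origin
        g = fr * n
        i0 = np.floor(g).astype(int)
        w = g - i0
        vals = np.zeros(len(pts))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    idx = (i0 + np.array([dx, dy, dz])) % n
                    weight = (
                        (w[:, 0] if dx else 1 - w[:, 0])
                        * (w[:, 1] if dy else 1 - w[:, 1])
                        * (w[:, 2] if dz else 1 - w[:, 2])
                    )
                    vals += weight * self.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        return vals if np.asarray(orth_points).ndim > 1 else vals[:1]

    def region_indices(self, center_orth: np.ndarray, radius: float) -> np.ndarray:
        """Grid indices (wrapped) of voxels within ``radius`` Å of a point."""
        n = np.array(self.shape)
        abc = np.array([self.cell.a, self.cell.b, self.cell.c])
        c_idx = self.index_of_orth(center_orth)
        half = np.ceil(radius / abc * n * 1.5).astype(int) + 1
        ranges = [np.arange(int(np.floor(c_idx[d])) - half[d],
                            int(np.ceil(c_idx[d])) + half[d] + 1) for d in range(3)]
        I, J, K = np.meshgrid(*ranges, indexing="ij")
        idx = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
        mat = np.array(self.cell.orth.mat.tolist())
        orth = (idx / n + self.origin) @ mat.T
        d = np.linalg.norm(orth - np.asarray(center_orth), axis=1)
        return idx[d <= radius]

    def values_at_indices(self, idx: np.ndarray) -> np.ndarray:
        n = np.array(self.shape)
        w = idx % n
        return self.values[w[:, 0], w[:, 1], w[:, 2]]


def read_density(path: str, kind: str) -> DensityGrid:
    """Read a CCP4/MRC map, expand to the full unit cell, rescale to sigma units."""
    m = gemmi.read_ccp4_map(str(path), setup=True)
    arr = np.array(m.grid, copy=True)
    grid = DensityGrid(kind=kind, values=arr, cell=m.grid.unit_cell)
    return grid.standardize()


def write_density(grid: DensityGrid, path: str) -> None:
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32),
                             grid.cell, gemmi.SpaceGroup("P 1"))
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def make_pseudoinverse(grid: DensityGrid) -> DensityGrid:
    """Sign-inverted counterpart of an observed map (rho+ = -rho).

    Model fit against the pseudoinverse map measures overlap with negative
    and void density rather than with signal.
    """
    if grid.kind not in PSEUDOINVERSE_OF:
        raise ValueError(f"map of kind {grid.kind!r} is already a pseudoinverse")
    return DensityGrid(kind=PSEUDOINVERSE_OF[grid.kind], values=-grid.values,
                       cell=grid.cell, origin=grid.origin.copy())


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

@dataclass
class Peak:
    """A candidate solvent site."""

    id: str
    coordinate: np.ndarray      # orthogonal Å
    resolution: float
    source: str                 # difference_map | solvent_model | user
    linked_atom: int | None = None   # index into StructureModel.atoms
    cluster_id: int | None = None
    flags: set = field(default_factory=set)
    height: float = float("nan")     # map value at the maximum (sigma)

    def __post_init__(self):
        if self.source not in ("difference_map", "solvent_model", "user"):
            raise ValueError(f"invalid peak source {self.source!r}")
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        lo, hi = RESOLUTION_RANGE
        if not (lo <= self.resolution <= hi):
            self.flags.add("out_of_range")


@dataclass
class AtomContact:
    peak_id: str
    atom_index: int
    distance: float
    partner_kind: str           # macromolecule | solvent
    op_index: int = 0


def find_difference_peaks(fofc: DensityGrid, threshold_sigma: float = 3.0,
                          resolution: float = 2.0,
                          structure: StructureModel | None = None) -> list:
    """26-connected local maxima of the difference map above a sigma threshold.

    The reported coordinate refines the voxel maximum with a per-axis
    quadratic fit.  If a structure with >1 symmetry operator is supplied,
    symmetry-equivalent maxima are reduced to the image nearest the
    macromolecular centroid.
    """
    if fofc.kind != "fofc":
        raise ValueError("peak picking expects an fofc difference map")
    v = fofc.values
    footprint = np.ones((3, 3, 3), dtype=bool)
    mx = ndimage.maximum_filter(v, footprint=footprint, mode="wrap")
    mask = (v >= threshold_sigma) & (v >= mx)
    peaks = []
    n = np.array(v.shape)
    for count, (i, j, k) in enumerate(np.argwhere(mask)):
        center = np.array([i, j, k], dtype=float)
        for d, idx in enumerate((i, j, k)):
            lo_i = list((i, j, k))
            hi_i = list((i, j, k))
            lo_i[d] = (idx - 1) % n[d]
            hi_i[d] = (idx + 1) % n[d]
            fm, f0, fp = v[tuple(lo_i)], v[i, j, k], v[tuple(hi_i)]
            denom = fm + fp - 2 * f0
            if denom < 0:
                center[d] += float(np.clip((fm - fp) / (2 * denom), -0.5, 0.5))
        frac = center / n + fofc.origin
        mat = np.array(fofc.cell.orth.mat.tolist())
        coord = mat @ frac
        peaks.append(Peak(id=f"P{count + 1:04d}", coordinate=coord,
                          resolution=resolution, source="difference_map",
                          height=float(v[i, j, k])))
    if structure is not None and len(structure.ops) > 1 and peaks:
        peaks = _dedup_symmetry(peaks, structure)
    for i, p in enumerate(peaks):
        p.id = f"P{i + 1:04d}"
    return peaks


def _dedup_symmetry(peaks: list, structure: StructureModel, tol: float = 0.5) -> list:
    """Collapse symmetry-equivalent peaks; keep the image nearest the centroid."""
    centroid = structure.centroid()
    ops = structure.ops
    mat = np.array(structure.cell.orth.mat.tolist())
    kept: list = []
    for p in peaks:
        fp = structure.frac(p.coordinate)
        merged = False
        for q in kept:
            fq = structure.frac(q.coordinate)
            for R, t in ops:
                d = (R @ fp + t) - fq
                d -= np.round(d)
                if np.linalg.norm(mat @ d) < tol:
                    merged = True
                    break
            if merged:
                # keep whichever image is closer to the macromolecular centroid
                if (np.linalg.norm(p.coordinate - centroid)
                        < np.linalg.norm(q.coordinate - centroid)):
                    q.coordinate = p.coordinate
                    q.height = max(q.height, p.height)
                break
        if not merged:
            kept.append(p)
    return kept


def associate_solvent_peaks(structure: StructureModel, map_peaks: Sequence[Peak],
                            cutoff: float = 2.0) -> list:
    """Turn input-model solvent atoms near a difference-map peak into peaks.

    A solvent atom closer than ``cutoff`` to its nearest map peak (minimum
    image under lattice translations) becomes a ``solvent_model`` Peak linked
    to that atom.
    """
    if not map_peaks:
        return []
    out = []
    mat = np.array(structure.cell.orth.mat.tolist())
    fmat = np.array(structure.cell.frac.mat.tolist())
    peak_xyz = np.array([p.coordinate for p in map_peaks])
    count = 0
    for ia, atom in enumerate(structure.atoms):
        if not atom.is_solvent:
            continue
        df = (peak_xyz - atom.pos) @ fmat.T
        df -= np.round(df)
        d = np.linalg.norm(df @ mat.T, axis=1)
        j = int(np.argmin(d))
        if d[j] < cutoff:
            count += 1
            out.append(Peak(
                id=f"S{count:04d}", coordinate=atom.pos.copy(),
                resolution=map_peaks[j].resolution, source="solvent_model",
                linked_atom=ia, height=map_peaks[j].height,
            ))
    return out


def neighbors(structure: StructureModel, coordinate: np.ndarray, radius: float,
              exclude: Callable[[Atom], bool] | None = None,
              peak_id: str = "") -> list:
    """All atoms (with symmetry images) within ``radius`` Å, sorted by distance.

    Expands every space-group operator over the 27 neighboring cell
    translations; a closed ball (distance <= radius) is used, and coincident
    images of the same atom (special positions) are reported once.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    atoms = [(i, a) for i, a in enumerate(structure.atoms)
             if exclude is None or not exclude(a)]
    if not atoms:
        return []
    coordinate = np.asarray(coordinate, dtype=float)
    mat = np.array(structure.cell.orth.mat.tolist())
    fmat = np.array(structure.cell.frac.mat.tolist())
    fr_atoms = np.array([a.pos for _, a in atoms]) @ fmat.T
    fr_q = fmat @ coordinate
    shifts = np.array([[di, dj, dk] for di in (-1, 0, 1)
                       for dj in (-1, 0, 1) for dk in (-1, 0, 1)])
    contacts = []
    seen = {}
    for iop, (R, t) in enumerate(structure.ops):
        fr_im = fr_atoms @ R.T + t
        base = fr_im - np.round(fr_im - fr_q)  # principal image near the query
        for sh in shifts:
            orth = (base + sh) @ mat.T
            d = np.linalg.norm(orth - coordinate, axis=1)
            for row in np.nonzero(d <= radius)[0]:
                ai = atoms[row][0]
                key = (ai, round(orth[row, 0], 3), round(orth[row, 1], 3),
                       round(orth[row, 2], 3))
                if key in seen:
                    continue
                seen[key] = True
                kind = "solvent" if atoms[row][1].is_solvent else "macromolecule"
                contacts.append(AtomContact(peak_id=peak_id, atom_index=ai,
                                            distance=float(d[row]),
                                            partner_kind=kind, op_index=iop))
    contacts.sort(key=lambda c: c.distance)
    return contacts


# ---------------------------------------------------------------------------
# Peak list I/O (tab-delimited)
# ---------------------------------------------------------------------------

def write_peaks(peaks: Iterable[Peak], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tx\ty\tz\tsource\n")
        for p in peaks:
            fh.write(f"{p.id}\t{p.coordinate[0]:.4f}\t{p.coordinate[1]:.4f}"
                     f"\t{p.coordinate[2]:.4f}\t{p.source}\n")


def read_peaks(path: str, resolution: float = 2.0) -> list:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                continue
            src = parts[cols["source"]] if "source" in cols else "user"
            out.append(Peak(
                id=parts[cols.get("id", 0)],
                coordinate=np.array([float(parts[cols["x"]]),
                                     float(parts[cols["y"]]),
                                     float(parts[cols["z"]])]),
                resolution=resolution,
                source=src if src in ("difference_map", "solvent_model", "user") else "user",
            ))
    return out
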