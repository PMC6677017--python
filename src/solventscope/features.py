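"""Extraction of the 21 per-peak features.

Nineteen features describe the local electron density: CC1-CC14 are
real-space correlation coefficients (RSCC) between observed density and an
idealized probe model (a single water O, or a rigid tetrahedral sulfate)
fitted by real-space refinement, evaluated against the 2Fo-Fc, Fo-Fc and
their sign-inverted ("pseudoinverse") maps in various refined/unrefined
combinations; ED1/ED2 are rotational-sensitivity spreads, ED3/ED4 are
flood-fill peak volumes, and ED5 is the 2Fo-Fc map value at the peak.  The
remaining two are chemical-environment features: CF1, the distance to the
closest model atom, and CF2, a log-odds sum over neighboring atom types
expressing how sulfate-like the contact environment is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .config import ALL_FEATURES, DEFAULT_CONFIG, FeatureConfig
from .structures import Atom, DensityGrid, Peak, StructureModel, neighbors

ELECTRONS = {"O": 8.0, "S": 16.0, "N": 7.0, "C": 6.0, "P": 15.0}

# Ideal tetrahedral sulfate: S at origin, O along the cube diagonals.
_SO4_DIRS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)
SO4_BOND = 1.49  # Å


@dataclass
class ProbeModel:
    """Rigid idealized probe (water O or sulfate) with a pose."""

    species: str                       # "water" | "sulfate"
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def local_atoms(self):
        if self.species == "water":
            return [("O", np.zeros(3))]
        if self.species == "sulfate":
            return [("S", np.zeros(3))] + [("O", SO4_BOND * d) for d in _SO4_DIRS]
        raise ValueError(f"unknown probe species {self.species!r}")

    def atoms_at(self, center: np.ndarray):
        """(elements, positions) of the posed probe around ``center``."""
        els, pos = zip(*self.local_atoms())
        xyz = np.array(pos) @ self.rotation.T + np.asarray(center) + self.translation
        return list(els), xyz


def gaussian_width(resolution: float, b_equivalent: float = 20.0) -> float:
    """Probe-atom Gaussian sigma (Å): fixed-B width + resolution blur in quadrature."""
    sigma_b = np.sqrt(b_equivalent / (8 * np.pi**2))
    return float(np.sqrt(sigma_b**2 + (resolution / 3.0) ** 2))


def model_density(elements, positions, points: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of isotropic atom Gaussians (amplitude = electron count) at ``points``."""
    points = np.atleast_2d(points)
    vals = np.zeros(len(points))
    for el, p in zip(elements, positions):
        z = ELECTRONS.get(el, 6.0)
        d2 = np.sum((points - p) ** 2, axis=1)
        vals += z * np.exp(-d2 / (2 * sigma**2))
    return vals


def rscc(model_vals: np.ndarray, observed_vals: np.ndarray) -> float:
    """Pearson correlation between model and observed density over a region."""
    m = np.asarray(model_vals, dtype=float)
    o = np.asarray(observed_vals, dtype=float)
    if m.size < 2 or m.size != o.size:
        raise ValueError("degenerate region")
    ms, os_ = m.std(), o.std()
    if ms <= 0 or os_ <= 0:
        raise ValueError("degenerate region")
    return float(np.dot(m - m.mean(), o - o.mean()) / (m.size * ms * os_))


def _probe_region(grid: DensityGrid, center: np.ndarray, probe: ProbeModel,
                  radius: float, pad: float = 0.0):
    """Voxel indices within ``radius`` (+pad) of any probe atom at the center pose."""
    _, xyz = probe.atoms_at(center)
    reach = radius + pad + (SO4_BOND if probe.species == "sulfate" else 0.0)
    idx = grid.region_indices(center, reach)
    mat = np.array(grid.cell.orth.mat.tolist())
    n = np.array(grid.shape)
    orth = (idx / n + grid.origin) @ mat.T
    dmin = np.min(np.linalg.norm(orth[:, None, :] - xyz[None, :, :], axis=2), axis=1)
    keep = dmin <= radius + pad
    return idx[keep], orth[keep]


def probe_rscc(probe: ProbeModel, grid: DensityGrid, center: np.ndarray,
               resolution: float, cfg: FeatureConfig = DEFAULT_CONFIG.features) -> float:
    """RSCC of the posed probe against a grid over the probe region."""
    idx, orth = _probe_region(grid, center, probe, cfg.probe_region_radius)
    els, xyz = probe.atoms_at(center)
    sigma = gaussian_width(resolution, cfg.model_b_equivalent)
    return rscc(model_density(els, xyz, orth, sigma), grid.values_at_indices(idx))


def real_space_refine(probe: ProbeModel, grid: DensityGrid, start: np.ndarray,
                      max_shift: float = 1.0, resolution: float = 2.0,
                      cfg: FeatureConfig = DEFAULT_CONFIG.features):
    """Fit the probe pose to local density by bounded direct search.

    Translations are projected onto the ball of radius ``max_shift``; sulfate
    additionally refines a rigid rotation (rotation-vector parameterization).
    The observed region is fixed at the start pose (padded by ``max_shift``)
    so the objective is smooth; the returned RSCC is re-evaluated on the
    tight probe region at the final pose.  Deterministic for fixed inputs.
    """
    start = np.asarray(start, dtype=float)
    n = np.array(grid.shape)
    fr = grid.frac_of_orth(start)
    if not np.all(np.isfinite(fr)):
        raise ValueError("start position outside grid")
    rotate = probe.species == "sulfate"
    idx, orth = _probe_region(grid, start, probe, cfg.probe_region_radius, pad=max_shift)
    obs = grid.values_at_indices(idx)
    if obs.std() <= 0:
        raise ValueError("degenerate region")
    sigma = gaussian_width(resolution, cfg.model_b_equivalent)
    els, _ = zip(*probe.local_atoms())
    local = np.array([p for _, p in probe.local_atoms()])
    obs_c = obs - obs.mean()
    obs_n = np.linalg.norm(obs_c)

    def pose(params):
        t = params[:3]
        tn = np.linalg.norm(t)
        if tn > max_shift:
            t = t * (max_shift / tn)
        R = Rotation.from_rotvec(params[3:6]).as_matrix() if rotate else np.eye(3)
        return R, t

    def objective(params):
        R, t = pose(params)
        xyz = local @ R.T + start + t
        m = model_density(list(els), xyz, orth, sigma)
        mc = m - m.mean()
        mn = np.linalg.norm(mc)
        if mn <= 0:
            return 1.0
        return -float(np.dot(mc, obs_c) / (mn * obs_n))

    ndim = 6 if rotate else 3
    x0 = np.zeros(ndim)
    simplex = np.zeros((ndim + 1, ndim))
    steps = [0.25] * 3 + [0.35] * 3
    for i in range(ndim):
        simplex[i + 1, i] = steps[i]
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxfev": cfg.refine_max_eval, "xatol": 1e-3,
                            "fatol": cfg.refine_tol,
                            "initial_simplex": simplex})
    R, t = pose(res.x)
    refined = replace(probe, rotation=R @ probe.rotation,
                      translation=probe.translation + t)
    cc = probe_rscc(refined, grid, start, resolution, cfg)
    return refined, cc


def peak_volume(grid: DensityGrid, peak_xyz: np.ndarray, contour: float,
                cap_radius: float = 5.0) -> float:
    """Volume (Å³) of the 26-connected above-contour component holding the peak.

    The flood fill is capped at ``cap_radius`` from the peak so that density
    continuous with the macromolecule does not inflate the estimate.
    """
    n = np.array(grid.shape)
    c_idx = grid.index_of_orth(peak_xyz)
    abc = np.array([grid.cell.a, grid.cell.b, grid.cell.c])
    half = np.ceil(cap_radius / abc * n * 1.5).astype(int) + 1
    c0 = np.round(c_idx).astype(int)
    ranges = [np.arange(c0[d] - half[d], c0[d] + half[d] + 1) for d in range(3)]
    sub = grid.values[np.ix_(*[r % n[d] for d, r in enumerate(ranges)])]
    I, J, K = np.meshgrid(*ranges, indexing="ij")
    mat = np.array(grid.cell.orth.mat.tolist())
    orth = (np.stack([I, J, K], axis=-1) / n + grid.origin) @ mat.T
    dist = np.linalg.norm(orth - np.asarray(peak_xyz), axis=-1)
    mask = (sub > contour) & (dist <= cap_radius)
    center = tuple(half)
    if not mask[center]:
        return 0.0
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    return float(np.count_nonzero(labels == labels[center]) * grid.voxel_volume)


# --- deterministic rotation set for CC13/CC14/ED1/ED2 -----------------------

def _rotation_set() -> list:
    """12 fixed generic rotations, none a symmetry of the tetrahedral probe."""
    axes = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0],
                     [1.0, 1.0, 1.0] / np.sqrt(3)])
    angles = np.deg2rad([36.0, 72.0, 144.0])
    return [Rotation.from_rotvec(ang * ax).as_matrix()
            for ax in axes for ang in angles]


ROTATION_SET = _rotation_set()


@dataclass
class FeatureVector:
    """The 21 named feature values for one peak."""

    peak_id: str
    resolution: float
    values: dict

    def __post_init__(self):
        missing = [f for f in ALL_FEATURES if f not in self.values]
        if missing:
            raise ValueError(f"missing feature(s): {', '.join(missing)}")
        bad = [f for f in ALL_FEATURES if not np.isfinite(self.values[f])]
        if bad:
            raise ValueError(f"non-finite feature(s): {', '.join(bad)}")


def extract_ed(peak: Peak, grids: dict, cfg: FeatureConfig = DEFAULT_CONFIG.features) -> dict:
    """Compute CC1-CC14 and ED1-ED5 at a peak from the four map kinds."""
    for kind in ("two_fofc", "fofc", "pseudoinverse_two_fofc", "pseudoinverse_fofc"):
        if kind not in grids:
            raise ValueError(f"missing density map: {kind}")
    fofc, twofofc = grids["fofc"], grids["two_fofc"]
    pfofc, ptwofofc = grids["pseudoinverse_fofc"], grids["pseudoinverse_two_fofc"]
    x = peak.coordinate
    d = peak.resolution
    out = {}

    water = ProbeModel("water")
    sulfate = ProbeModel("sulfate")
    w_fo, out["CC1"] = real_space_refine(water, fofc, x, cfg.max_shift, d, cfg)
    w_2fo, out["CC2"] = real_space_refine(water, twofofc, x, cfg.max_shift, d, cfg)
    s_fo, out["CC3"] = real_space_refine(sulfate, fofc, x, cfg.max_shift, d, cfg)
    s_2fo, out["CC4"] = real_space_refine(sulfate, twofofc, x, cfg.max_shift, d, cfg)

    # fit of the observed-map poses against the sign-inverted maps (unrefined)
    out["CC5"] = probe_rscc(s_fo, pfofc, x, d, cfg)
    out["CC6"] = probe_rscc(s_2fo, ptwofofc, x, d, cfg)
    # re-refined against the pseudoinverse maps ...
    ps_fo, out["CC7"] = real_space_refine(s_fo, pfofc, x, cfg.max_shift, d, cfg)
    ps_2fo, out["CC8"] = real_space_refine(s_2fo, ptwofofc, x, cfg.max_shift, d, cfg)
    # ... and those poses scored back against the true maps
    out["CC9"] = probe_rscc(ps_fo, fofc, x, d, cfg)
    out["CC10"] = probe_rscc(ps_2fo, twofofc, x, d, cfg)
    # water poses against the pseudoinverse maps
    out["CC11"] = probe_rscc(w_fo, pfofc, x, d, cfg)
    out["CC12"] = probe_rscc(w_2fo, ptwofofc, x, d, cfg)

    # rotational sensitivity of the refined sulfate fits
    cc13 = [probe_rscc(replace(s_fo, rotation=R @ s_fo.rotation), fofc, x, d, cfg)
            for R in ROTATION_SET]
    cc14 = [probe_rscc(replace(s_2fo, rotation=R @ s_2fo.rotation), twofofc, x, d, cfg)
            for R in ROTATION_SET]
    out["CC13"] = float(np.mean(cc13))
    out["CC14"] = float(np.mean(cc14))
    out["ED1"] = float(np.std(cc13))
    out["ED2"] = float(np.std(cc14))

    out["ED3"] = peak_volume(fofc, x, cfg.ed3_contour, cfg.volume_cap_radius)
    out["ED4"] = peak_volume(twofofc, x, cfg.ed4_contour, cfg.volume_cap_radius)
    out["ED5"] = float(twofofc.interp(x[None, :])[0])
    return out


# --- chemical-environment features ------------------------------------------

_SIDECHAIN_TYPES = {
    ("ARG", "NE"): "guanidinium_amine_N", ("ARG", "NH1"): "guanidinium_amine_N",
    ("ARG", "NH2"): "guanidinium_amine_N", ("LYS", "NZ"): "guanidinium_amine_N",
    ("HIS", "ND1"): "imidazole_N", ("HIS", "NE2"): "imidazole_N",
    ("ASP", "OD1"): "carboxylate_O", ("ASP", "OD2"): "carboxylate_O",
    ("GLU", "OE1"): "carboxylate_O", ("GLU", "OE2"): "carboxylate_O",
    ("SER", "OG"): "hydroxyl_O", ("THR", "OG1"): "hydroxyl_O",
    ("TYR", "OH"): "hydroxyl_O",
    ("ASN", "OD1"): "amide_NO", ("ASN", "ND2"): "amide_NO",
    ("GLN", "OE1"): "amide_NO", ("GLN", "NE2"): "amide_NO",
}


def atom_contact_type(atom: Atom) -> str:
    """Map an atom to the CF2 vocabulary of contact types."""
    t = _SIDECHAIN_TYPES.get((atom.resname, atom.name))
    if t:
        return t
    if atom.name == "N" and atom.element == "N":
        return "backbone_N"
    if atom.name in ("O", "OXT") and atom.element == "O":
        return "backbone_O"
    if atom.element == "C":
        return "carbon"
    return "other"


def default_cf2_weights() -> dict:
    """Fallback log-odds table used before a table is trained from contacts.

    Signs follow sulfate coordination chemistry: anion binding favors
    positively charged / H-bond-donating nitrogens and disfavors carboxylates
    and backbone carbonyls.
    """
    return {
        "guanidinium_amine_N": 1.2, "imidazole_N": 0.9, "backbone_N": 0.5,
        "backbone_O": -0.4, "carboxylate_O": -0.8, "hydroxyl_O": 0.4,
        "amide_NO": 0.3, "carbon": -0.1, "other": 0.0,
    }


def extract_cc(peak: Peak, structure: StructureModel,
               validated_solvent: list | None = None,
               weights: dict | None = None,
               cfg: FeatureConfig = DEFAULT_CONFIG.features) -> dict:
    """CF1 (closest-atom distance, symmetry-aware) and CF2 (sulfate-likeness)."""
    if not structure.atoms:
        raise ValueError("isolated peak: empty structure")
    weights = weights or default_cf2_weights()
    contacts = neighbors(structure, peak.coordinate, cfg.cf1_max_search,
                         exclude=lambda a: a.is_solvent, peak_id=peak.id)
    dists = [c.distance for c in contacts if c.distance > 1e-6]
    if validated_solvent:
        mat = np.array(structure.cell.orth.mat.tolist())
        fmat = np.array(structure.cell.frac.mat.tolist())
        for pos in validated_solvent:
            df = fmat @ (np.asarray(pos) - peak.coordinate)
            df -= np.round(df)
            dd = float(np.linalg.norm(mat @ df))
            if dd > 1e-6:
                dists.append(dd)
    if not dists:
        raise ValueError("isolated peak")
    cf1 = float(min(dists))
    cf2 = 0.0
    for c in contacts:
        if c.distance <= cfg.cf2_contact_radius:
            cf2 += weights.get(atom_contact_type(structure.atoms[c.atom_index]), 0.0)
    return {"CF1": cf1, "CF2": float(cf2)}


def extract_features(peak: Peak, structure: StructureModel, grids: dict,
                     validated_solvent: list | None = None,
                     weights: dict | None = None,
                     cfg: FeatureConfig = DEFAULT_CONFIG.features) -> FeatureVector:
    """All 21 features for one peak."""
    vals = extract_ed(peak, grids, cfg)
    vals.update(extract_cc(peak, structure, validated_solvent, weights, cfg))
    return FeatureVector(peak_id=peak.id, resolution=peak.resolution, values=vals)
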