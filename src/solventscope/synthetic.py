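"""Synthetic training data and toy density scenes.

Two generators make every stage of the classifier testable without any
deposited data:

* :func:`sample_features` draws labeled 21-feature tables with the
  statistical structure the score pipeline assumes: per-class feature means
  that drift smoothly with resolution, a factor-model correlation structure
  among the 19 ED features, and skewed Johnson-S_U marginals.  Class
  frequencies default to 96.2% water, 1.7% sulfate, 1.6% heterogen and 0.5%
  metal.

* :func:`make_scene` builds a toy crystal: a pseudo-peptide stand-in
  macromolecule plus planted waters and sulfates in a P1 cell, with
  Gaussian-atom 2Fo-Fc and (solvent-omit) Fo-Fc maps, so peak picking,
  feature extraction and triage run end to end.

Class separations are planted so that sulfate-water separation is largest on
the volume features (ED3/ED4) and the tetrahedral-probe correlations
(CC3/CC4/CC13/CC14), near zero on the rotational spreads (ED1/ED2); metals
imitate their real signature (sharp high peak, short contacts: sulfate-like
ED scores but water-like-or-lower CC scores); heterogens sit between water
and sulfate on density features with a water-like contact environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import gemmi
import numpy as np
import pandas as pd

from .config import ALL_FEATURES, CC_FEATURES, CLASSES, ED_FEATURES
from .features import SO4_BOND, _SO4_DIRS, gaussian_width
from .structures import Atom, DensityGrid, StructureModel

DEFAULT_FREQUENCIES = (0.962, 0.017, 0.016, 0.005)

# --- planted feature-table structure ---------------------------------------

# sulfate-minus-water separation, units of the feature sd
_SEPARATION = {
    "CC1": 0.5, "CC2": 0.4, "CC3": 1.6, "CC4": 3.2, "CC5": 0.3, "CC6": 0.3,
    "CC7": 0.2, "CC8": 0.2, "CC9": 0.8, "CC10": 0.8, "CC11": -0.3, "CC12": -0.3,
    "CC13": 1.4, "CC14": 2.2, "ED1": 0.05, "ED2": 0.05, "ED3": 3.6, "ED4": 4.4,
    "ED5": 2.0, "CF1": 2.6, "CF2": 2.2,
}

# class offsets from the water mean, units of the feature sd.  Heterogens sit
# halfway to sulfate on every density feature but keep a near-water contact
# environment; metals show sulfate-like density (sharper and taller: big ED5)
# with shorter-than-water contacts.
_HETEROGEN_FACTOR = {f: 0.5 for f in ALL_FEATURES}
_HETEROGEN_FACTOR["CF1"] = 0.3
_HETEROGEN_FACTOR["CF2"] = 0.8

_METAL_OFFSET = {f: 0.9 * _SEPARATION[f] for f in ALL_FEATURES}
_METAL_OFFSET.update({"ED1": 0.0, "ED2": 0.0, "ED5": 4.0, "CF1": -1.2, "CF2": 0.0})

# raw-unit anchors for the two contact features (Å for CF1, log-odds for CF2)
_CC_BASE = {"CF1": (2.9, 0.35), "CF2": (-0.5, 1.2)}


def _default_trends(rng: np.random.Generator):
    """Per-feature smooth resolution trends (linear+quadratic, in sd units)."""
    amp = rng.uniform(1.0, 2.5, size=len(ED_FEATURES)) * rng.choice([-1, 1], size=len(ED_FEATURES))
    curv = rng.uniform(-0.6, 0.6, size=len(ED_FEATURES))
    return {f: (float(a), float(b)) for f, a, b in zip(ED_FEATURES, amp, curv)}


def _default_loadings(d: np.ndarray) -> np.ndarray:
    """(n, 19, 2) factor loadings: one RSCC factor, one volume factor."""
    n = len(d)
    L = np.zeros((n, len(ED_FEATURES), 2))
    drift = 1.0 + 0.1 * (d - 2.5) / 2.5
    for j, f in enumerate(ED_FEATURES):
        if f.startswith("CC"):
            L[:, j, 0] = 0.6 * drift
        if f in ("ED3", "ED4", "ED5"):
            L[:, j, 1] = 0.6
    L[:, ED_FEATURES.index("CC4"), 1] = 0.2
    return np.clip(L, -0.95, 0.95)


@dataclass
class FeatureGeneratorConfig:
    """Statistical design of the synthetic labeled feature table."""

    frequencies: tuple = DEFAULT_FREQUENCIES
    resolution_range: tuple = (0.6, 5.0)
    resolution_beta: tuple = (2.2, 3.0)     # Beta shape of the resolution density
    separation: dict = field(default_factory=lambda: dict(_SEPARATION))
    heterogen_factor: dict = field(default_factory=lambda: dict(_HETEROGEN_FACTOR))
    metal_offset: dict = field(default_factory=lambda: dict(_METAL_OFFSET))
    trends: dict | None = None              # ED feature -> (linear, quadratic), sd units
    loadings: Callable[[np.ndarray], np.ndarray] | None = None
    jsu_gamma: dict | None = None           # per-feature skew shapes
    jsu_delta: dict | None = None
    sd_trend: float = 0.2                   # relative sd drift across resolution
    sulfate_sd_mult: float = 1.1
    minority_floor: int = 100
    structure_block: int = 400              # rows per pseudo-structure id

    def __post_init__(self):
        rng = np.random.default_rng(20231115)   # fixed: part of the design, not the draw
        if self.trends is None:
            self.trends = _default_trends(rng)
        if self.loadings is None:
            self.loadings = _default_loadings
        if self.jsu_gamma is None:
            g = rng.uniform(-0.8, 0.8, size=len(ALL_FEATURES))
            self.jsu_gamma = {f: float(v) for f, v in zip(ALL_FEATURES, g)}
        if self.jsu_delta is None:
            dl = rng.uniform(1.2, 2.5, size=len(ALL_FEATURES))
            self.jsu_delta = {f: float(v) for f, v in zip(ALL_FEATURES, dl)}
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ValueError("class frequencies must sum to 1")


def _jsu_standardized(z: np.ndarray, gamma: float, delta: float) -> np.ndarray:
    """Map standard normals through a Johnson-S_U shape, re-standardized.

    If Z ~ N(0,1) then sinh((Z - gamma)/delta) is S_U distributed; dividing
    out its analytic mean/sd leaves a zero-mean unit-sd skewed variable.
    """
    y = np.sinh((z - gamma) / delta)
    w = np.exp(delta**-2.0)
    m0 = -np.sqrt(w) * np.sinh(gamma / delta)
    v0 = 0.5 * (w - 1) * (w * np.cosh(2 * gamma / delta) + 1)
    return (y - m0) / np.sqrt(v0)


def _class_offset(config: FeatureGeneratorConfig, feature: str, label: str) -> float:
    s = config.separation[feature]
    return {"water": 0.0, "sulfate": s,
            "heterogen": config.heterogen_factor[feature] * s,
            "metal": config.metal_offset[feature]}[label]


def feature_sd(config: FeatureGeneratorConfig, feature: str, d):
    """Planted within-class sd.  ED features drift with resolution; the
    contact features CF1/CF2 are resolution-independent by construction."""
    d = np.asarray(d, dtype=float)
    if feature in CC_FEATURES:
        return _CC_BASE[feature][1] * np.ones_like(d)
    u = (d - 2.8) / 2.2
    return 1.0 + config.sd_trend * np.tanh(u)


def class_mean(config: FeatureGeneratorConfig, feature: str, label: str, d):
    """Planted mean of ``feature`` for class ``label`` at resolution ``d``.

    Class offsets are expressed in units of the local (resolution-dependent)
    within-class sd, so class separability does not drift with resolution;
    the resolution trend itself lives in the water baseline.
    """
    d = np.asarray(d, dtype=float)
    off = _class_offset(config, feature, label)
    sd = feature_sd(config, feature, d)
    if feature in CC_FEATURES:
        return _CC_BASE[feature][0] + off * sd
    u = (d - 2.8) / 2.2
    a, b = config.trends[feature]
    return a * u + b * u**2 + off * sd


def pooled_mean(config: FeatureGeneratorConfig, feature: str, d):
    """Frequency-weighted mean over classes (the standardization target)."""
    return sum(f * class_mean(config, feature, c, d)
               for f, c in zip(config.frequencies, CLASSES))


def _class_counts(n: int, config: FeatureGeneratorConfig, rng) -> np.ndarray:
    counts = rng.multinomial(n, config.frequencies)
    floor = min(config.minority_floor, max(n // 20, 1))
    for i in range(1, len(counts)):
        if counts[i] < floor:
            counts[i] = floor
    counts[0] = n - counts[1:].sum()
    if counts[0] <= 0:
        raise ValueError("n too small for the minority-class floor")
    return counts


def sample_features(n: int, seed: int, config: FeatureGeneratorConfig | None = None) -> pd.DataFrame:
    """Draw a labeled synthetic feature table (deterministic per seed)."""
    config = config or FeatureGeneratorConfig()
    rng = np.random.default_rng(seed)
    counts = _class_counts(n, config, rng)
    labels = np.repeat(CLASSES, counts)
    lo, hi = config.resolution_range
    a, b = config.resolution_beta
    d = lo + (hi - lo) * rng.beta(a, b, size=n)

    L = config.loadings(d)                         # (n, 19, k)
    resid = np.sqrt(np.clip(1.0 - np.sum(L**2, axis=2), 0.05, None))
    F = rng.standard_normal((n, L.shape[2]))
    E = rng.standard_normal((n, len(ED_FEATURES)))
    Z = resid * E + np.einsum("njk,nk->nj", L, F)

    sd_mult = np.where(labels == "sulfate", config.sulfate_sd_mult, 1.0)
    data = {}
    for j, f in enumerate(ED_FEATURES):
        y = _jsu_standardized(Z[:, j], config.jsu_gamma[f], config.jsu_delta[f])
        mu = np.empty(n)
        for c in CLASSES:
            m = labels == c
            mu[m] = class_mean(config, f, c, d[m])
        data[f] = mu + feature_sd(config, f, d) * sd_mult * y
    Zc = rng.standard_normal((n, len(CC_FEATURES)))
    for j, f in enumerate(CC_FEATURES):
        y = _jsu_standardized(Zc[:, j], config.jsu_gamma[f], config.jsu_delta[f])
        mu = np.empty(n)
        for c in CLASSES:
            m = labels == c
            mu[m] = class_mean(config, f, c, d[m])
        data[f] = mu + feature_sd(config, f, d) * sd_mult * y

    df = pd.DataFrame(data)
    df.insert(0, "resolution", d)
    df["label"] = labels
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df.insert(0, "peak_id", [f"R{i:07d}" for i in range(n)])
    df.insert(1, "structure_id", np.arange(n) // config.structure_block)
    return df


def reference_dataset(seed: int, n: int = 200_000,
                      config: FeatureGeneratorConfig | None = None) -> pd.DataFrame:
    """The default generator output used by the acceptance suite."""
    return sample_features(n, seed=seed, config=config)


def write_features(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_features(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- toy density scenes ------------------------------------------------------

@dataclass
class SceneConfig:
    """A toy P1 crystal with planted solvent."""

    n_waters: int = 10
    n_sulfates: int = 1
    n_residues: int = 8
    cell_edge: float = 30.0
    resolution: float = 2.0
    grid_spacing: float = 0.5
    noise_sd: float = 0.01     # fraction of a water-O peak amplitude
    min_solvent_distance: float = 2.4
    max_solvent_distance: float = 12.0   # solvent stays in shells near the chain
    seed: int = 0
    water_positions: list | None = None     # explicit placement overrides
    sulfate_positions: list | None = None


def _pseudo_chain(cfg: SceneConfig) -> list:
    """A crude peptide stand-in: backbone N/CA/C/O every 3.8 Å along a curve."""
    atoms = []
    c = cfg.cell_edge / 2.0
    for i in range(cfg.n_residues):
        t = i * 3.8
        base = np.array([c - 7.0 + t * 0.55, c + 4.0 * np.sin(t / 6.0), c + 3.5])
        for name, el, off in (("N", "N", (0.0, 0.0, 0.0)),
                              ("CA", "C", (1.2, 0.8, 0.0)),
                              ("C", "C", (2.4, 0.0, 0.4)),
                              ("O", "O", (2.6, -1.2, 0.6))):
            atoms.append(Atom(element=el, name=name, resname="ALA", resid=i + 1,
                              chain="A", pos=base + np.array(off)))
    return atoms


def _place_solvent(cfg: SceneConfig, macro_xyz: np.ndarray, rng) -> tuple:
    """Rejection-sample water O and sulfate S positions inside the cell."""
    placed: list = []

    def ok(p):
        if len(macro_xyz):
            dmin = np.min(np.linalg.norm(macro_xyz - p, axis=1))
            if dmin < cfg.min_solvent_distance or dmin > cfg.max_solvent_distance:
                return False
        return all(np.linalg.norm(p - q) >= 3.0 for q in placed)

    def take(explicit, n_total):
        sites = []
        for p in explicit or []:
            p = np.asarray(p, dtype=float)
            if not ok(p):
                raise ValueError(f"planted solvent at {p} overlaps existing atoms")
            placed.append(p)
            sites.append(p)
        margin = 4.0
        tries = 0
        while len(sites) < n_total:
            p = rng.uniform(margin, cfg.cell_edge - margin, size=3)
            if ok(p):
                placed.append(p)
                sites.append(p)
            tries += 1
            if tries > 20000:
                raise ValueError("could not place solvent without overlap")
        return sites

    waters = take(cfg.water_positions, cfg.n_waters)
    sulfates = take(cfg.sulfate_positions, cfg.n_sulfates)
    return waters, sulfates


def make_scene(cfg: SceneConfig | None = None):
    """Build (structure, two_fofc, fofc, truth) for a toy crystal.

    The 2Fo-Fc map is the Gaussian-atom synthesis of macromolecule plus
    solvent; the Fo-Fc map contains the solvent only, emulating a
    solvent-omit difference map.  Both carry white noise and are rescaled to
    sigma units.  The returned structure includes the planted solvent (the
    "deposited" model); truth is a table of site coordinates and classes.
    """
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    macro = _pseudo_chain(cfg)
    macro_xyz = np.array([a.pos for a in macro])
    waters, sulfates = _place_solvent(cfg, macro_xyz, rng)

    atoms = list(macro)
    truth_rows = []
    for i, w in enumerate(waters):
        atoms.append(Atom(element="O", name="O", resname="HOH", resid=100 + i,
                          chain="S", pos=np.asarray(w)))
        truth_rows.append({"x": w[0], "y": w[1], "z": w[2], "label": "water"})
    for i, s in enumerate(sulfates):
        R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        atoms.append(Atom(element="S", name="S", resname="SO4", resid=200 + i,
                          chain="S", pos=np.asarray(s)))
        for k, dvec in enumerate(_SO4_DIRS @ R.T):
            atoms.append(Atom(element="O", name=f"O{k + 1}", resname="SO4",
                              resid=200 + i, chain="S",
                              pos=np.asarray(s) + SO4_BOND * dvec))
        truth_rows.append({"x": s[0], "y": s[1], "z": s[2], "label": "sulfate"})

    cell = gemmi.UnitCell(cfg.cell_edge, cfg.cell_edge, cfg.cell_edge, 90, 90, 90)
    structure = StructureModel(atoms=atoms, cell=cell, spacegroup="P 1",
                               resolution=cfg.resolution)

    ngrid = int(np.ceil(cfg.cell_edge / cfg.grid_spacing))
    ax = np.arange(ngrid) * cfg.cell_edge / ngrid
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    sigma = gaussian_width(cfg.resolution)

    def synth(atom_list):
        v = np.zeros(pts.shape[:3])
        from .features import ELECTRONS
        for a in atom_list:
            z = ELECTRONS.get(a.element, 6.0)
            dvec = pts - a.pos
            dvec -= np.round(dvec / cfg.cell_edge) * cfg.cell_edge
            v += z * np.exp(-np.sum(dvec**2, axis=-1) / (2 * sigma**2))
        return v

    solvent_atoms = atoms[len(macro):]
    amp_water = 8.0   # water-O peak amplitude before noise
    v_all = synth(atoms)
    v_solv = synth(solvent_atoms)
    # band-limited noise: white noise smoothed to ~the map's feature size,
    # then rescaled so noise_sd is the post-smoothing amplitude.  White noise
    # would scatter spurious local maxima that real (Fourier-truncated)
    # difference maps do not show.
    from scipy.ndimage import gaussian_filter

    def noise_field():
        w = gaussian_filter(rng.standard_normal(v_all.shape), sigma=1.2, mode="wrap")
        return w / w.std() * cfg.noise_sd * amp_water

    two_fofc = DensityGrid("two_fofc", v_all + noise_field(), cell)
    fofc = DensityGrid("fofc", v_solv + noise_field(), cell)
    truth = pd.DataFrame(truth_rows)
    return structure, two_fofc.standardize(), fofc.standardize(), truth


def scene_feature_table(n_scenes: int = 12, seed: int = 0,
                        resolutions=(1.6, 2.0, 2.5, 3.0),
                        waters_per: int = 12, sulfates_per: int = 6) -> pd.DataFrame:
    """Extract labeled features from a batch of toy scenes.

    Gives a small physically grounded training table (as opposed to the
    statistical table of :func:`sample_features`) whose feature values carry
    the units and dynamic range of real map extraction.  The water:sulfate
    ratio is deliberately enriched so both classes support distribution
    fits at this scale.
    """
    from .features import extract_features
    from .structures import find_difference_peaks, make_pseudoinverse

    rows = []
    for i in range(n_scenes):
        res = resolutions[i % len(resolutions)]
        cfg = SceneConfig(n_waters=waters_per, n_sulfates=sulfates_per,
                          cell_edge=34.0, resolution=res, seed=seed * 1000 + i)
        structure, two_fofc, fofc, truth = make_scene(cfg)
        grids = {"two_fofc": two_fofc, "fofc": fofc,
                 "pseudoinverse_two_fofc": make_pseudoinverse(two_fofc),
                 "pseudoinverse_fofc": make_pseudoinverse(fofc)}
        stripped = structure.strip_solvent()
        peaks = find_difference_peaks(fofc, 3.0, resolution=res)
        txyz = truth[["x", "y", "z"]].to_numpy()
        tlab = truth["label"].to_numpy()
        for p in peaks:
            d = np.linalg.norm(txyz - p.coordinate, axis=1)
            if d.min() > 1.0:
                continue
            fv = extract_features(p, stripped, grids)
            rows.append({"peak_id": f"s{i}_{p.id}", "structure_id": i,
                         "resolution": res, **fv.values,
                         "label": tlab[int(np.argmin(d))]})
    return pd.DataFrame(rows)


_SCENE_MODEL_CACHE: dict = {}


def scene_reference_model(seed: int = 0):
    """A classifier trained on scene-extracted features (cached per seed)."""
    from .training import train

    if seed not in _SCENE_MODEL_CACHE:
        _SCENE_MODEL_CACHE[seed] = train(scene_feature_table(seed=seed), seed=seed)
    return _SCENE_MODEL_CACHE[seed]
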