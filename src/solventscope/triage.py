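"""Iterative triage: from scored peaks to an output solvent model.

One round of triage (a) flags likely model errors — peaks whose density
looks too big for water (sulfate-like ED score) while the chemistry says
water (low CC score) and whose fitted water would clash with the
macromolecule; (b) groups nearby peaks (symmetry-aware) into clusters and
decides, per member, whether it belongs to the cluster representative's
multi-atom model, to a neighboring cluster, to a water model, or is a split
peak; (c) updates CF1 distances against newly validated solvent and rescores
the affected peaks; and (d) rebuilds the per-structure adaptive prior.
Rounds repeat until the accumulated assignments stop changing (at most 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .classifier import ClassificationResult, adaptive_prior, predict
from .config import CLASSES, DEFAULT_CONFIG, Config
from .features import SO4_BOND, _SO4_DIRS, extract_features, default_cf2_weights
from .scorespace import ScoreTriple
from .structures import (Atom, DensityGrid, Peak, StructureModel,
                         associate_solvent_peaks, find_difference_peaks,
                         make_pseudoinverse, neighbors)

SULFATE_BOND_RANGE = 1.8   # Å: member within S-O bonding distance of a representative


@dataclass
class PeakCluster:
    members: list                       # peak ids
    representative: str | None = None
    dispositions: dict = field(default_factory=dict)   # peak id -> disposition


@dataclass
class SolventAssignment:
    peak_id: str
    cls: str
    coordinates: np.ndarray             # (n_atoms, 3)
    elements: list
    resname: str
    provenance: str                     # fitted | carried_over
    validated: bool = False
    b_factor: float = 20.0


def sym_min_distance(structure: StructureModel, p: np.ndarray, q: np.ndarray) -> float:
    """Minimum distance between two points over symmetry images and translations."""
    mat = np.array(structure.cell.orth.mat.tolist())
    fmat = np.array(structure.cell.frac.mat.tolist())
    fp = fmat @ np.asarray(p)
    fq = fmat @ np.asarray(q)
    best = np.inf
    for R, t in structure.ops:
        d = (R @ fq + t) - fp
        d -= np.round(d)
        best = min(best, float(np.linalg.norm(mat @ d)))
    return best


def flag_model_errors(results: dict, clash_counts: dict,
                      cfg=DEFAULT_CONFIG.triage) -> set:
    """Peaks with sulfate-like ED, water-like CC and several short contacts.

    The clash requirement distinguishes true modelling errors from metals,
    which show the same score pattern without steric trouble.
    """
    flagged = set()
    for pid, res in results.items():
        s = res.scores
        if (s.ed > cfg.model_error_t_ed and s.cc < cfg.model_error_t_cc
                and clash_counts.get(pid, 0) >= cfg.model_error_n_clash):
            flagged.add(pid)
    return flagged


def mark_suspicious_cf1(peaks: list, features: dict, results: dict,
                        cfg=DEFAULT_CONFIG.triage) -> None:
    """Set the suspicious_cf1 flag where the contact distance looks inflated."""
    for p in peaks:
        res = results.get(p.id)
        if res is None:
            continue
        s = res.scores
        cf1 = features[p.id]["CF1"]
        trigger = (s.ed < 0 and s.cc > 0 and cf1 > cfg.suspicious_cf1_threshold) or \
            ((1 - s.p_notwater) > cfg.suspicious_p_water
             and res.predicted_class != "water")
        if trigger:
            p.flags.add("suspicious_cf1")


def update_cf1(peaks: list, features: dict, assignments: list,
               structure: StructureModel) -> int:
    """Shrink CF1 of suspicious peaks toward newly validated solvent.

    Only validated assignments count, and CF1 only ever decreases.  Returns
    the number of peaks whose CF1 changed.
    """
    validated = [a for a in assignments if a.validated]
    if not validated:
        return 0
    changed = 0
    for p in peaks:
        if "suspicious_cf1" not in p.flags:
            continue
        dists = [sym_min_distance(structure, p.coordinate, a.coordinates[0])
                 for a in validated if a.peak_id != p.id]
        dists = [d for d in dists if d > 1e-6]
        if not dists:
            continue
        nearest = min(dists)
        if nearest < features[p.id]["CF1"]:
            features[p.id]["CF1"] = nearest
            changed += 1
    return changed


def _edge_weight(d: float, s_i: ScoreTriple, s_j: ScoreTriple, sigma: float) -> float:
    sim = np.exp(-((s_i.ed - s_j.ed) ** 2 + (s_i.cc - s_j.cc) ** 2) / 8.0)
    return float(np.exp(-d**2 / (2 * sigma**2)) * sim)


def cluster_peaks(peaks: list, structure: StructureModel, results: dict,
                  cfg=DEFAULT_CONFIG.triage) -> list:
    """Connected components of the symmetry-aware peak adjacency graph.

    Peaks closer than the edge cutoff are linked with a weight combining
    distance and score similarity; within each component, the member with
    the strongest sulfate/heterogen likelihood (if any is so predicted)
    becomes the representative.  Membership is independent of input order.
    """
    ordered = sorted(peaks, key=lambda p: p.id)
    G = nx.Graph()
    for p in ordered:
        G.add_node(p.id)
    for i, p in enumerate(ordered):
        for q in ordered[i + 1:]:
            d = sym_min_distance(structure, p.coordinate, q.coordinate)
            if d < cfg.cluster_edge_cutoff:
                w = _edge_weight(d, results[p.id].scores, results[q.id].scores,
                                 cfg.cluster_sigma)
                G.add_edge(p.id, q.id, weight=w, distance=d)
    clusters = []
    for comp in sorted(nx.connected_components(G), key=lambda c: sorted(c)[0]):
        members = sorted(comp)
        rep = None
        best = -np.inf
        for pid in members:
            res = results[pid]
            if res.predicted_class in ("sulfate", "heterogen"):
                L = max(L_s[res.predicted_class] for L_s in res.likelihoods.values())
                if L > best:
                    best, rep = L, pid
        clusters.append(PeakCluster(members=members, representative=rep))
    for cl, cid in zip(clusters, range(len(clusters))):
        for p in ordered:
            if p.id in cl.members:
                p.cluster_id = cid
    return clusters


def resolve_cluster(cluster: PeakCluster, clusters: list, peaks_by_id: dict,
                    results: dict, structure: StructureModel,
                    cfg=DEFAULT_CONFIG.triage) -> dict:
    """Assign each member one of the four dispositions."""
    disp = {}
    rep = cluster.representative
    reps_elsewhere = [(c.representative, peaks_by_id[c.representative])
                      for c in clusters
                      if c is not cluster and c.representative is not None]
    water_taken: list = []
    for pid in cluster.members:
        p = peaks_by_id[pid]
        if pid == rep:
            disp[pid] = "representative"
            continue
        if rep is not None:
            d_rep = sym_min_distance(structure, p.coordinate,
                                     peaks_by_id[rep].coordinate)
            if d_rep <= SULFATE_BOND_RANGE:
                disp[pid] = "part_of_representative_model"
                continue
            w_own = _edge_weight(d_rep, results[pid].scores,
                                 results[rep].scores, cfg.cluster_sigma)
        else:
            w_own = 0.0
        other = 0.0
        for rid, rpeak in reps_elsewhere:
            d = sym_min_distance(structure, p.coordinate, rpeak.coordinate)
            w = _edge_weight(d, results[pid].scores, results[rid].scores,
                             cfg.cluster_sigma)
            other = max(other, w)
        if other > w_own and other > 1e-3:
            disp[pid] = "other_cluster"
            continue
        # candidate water model; merge split peaks
        split = False
        for q in water_taken:
            if sym_min_distance(structure, p.coordinate, q) < cfg.split_peak_distance:
                disp[pid] = "split_peak"
                p.flags.add("split_peak")
                split = True
                break
        if not split:
            disp[pid] = "water"
            water_taken.append(p.coordinate)
    cluster.dispositions = disp
    return disp


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _clash_count(structure: StructureModel, coord: np.ndarray,
                 cfg=DEFAULT_CONFIG.triage) -> int:
    contacts = neighbors(structure, coord, cfg.clash_distance,
                         exclude=lambda a: a.is_solvent)
    return sum(1 for c in contacts if c.distance > 1e-6)


def _b_from_height(height: float, cfg=DEFAULT_CONFIG.triage) -> float:
    if not np.isfinite(height) or height <= 0:
        return 30.0
    return float(max(cfg.b_factor_floor, 80.0 / height))


def _make_assignment(peak: Peak, res: ClassificationResult, features: dict,
                     structure: StructureModel, cfg) -> SolventAssignment | None:
    cls = res.predicted_class
    ed5 = features.get("ED5", 2.0)
    b = _b_from_height(ed5, cfg)
    linked = structure.atoms[peak.linked_atom] if peak.linked_atom is not None else None
    carried = (linked is not None and linked.solvent_class() == cls
               and np.linalg.norm(linked.pos - peak.coordinate) < 2.0)
    if cls == "water":
        return SolventAssignment(
            peak_id=peak.id, cls="water", coordinates=peak.coordinate[None, :],
            elements=["O"], resname="HOH",
            provenance="carried_over" if carried else "fitted",
            validated=res.quality in ("strong", "moderate"), b_factor=b)
    if cls == "sulfate":
        xyz = np.vstack([peak.coordinate,
                         peak.coordinate + SO4_BOND * _SO4_DIRS])
        return SolventAssignment(
            peak_id=peak.id, cls="sulfate", coordinates=xyz,
            elements=["S", "O", "O", "O", "O"], resname="SO4",
            provenance="carried_over" if carried else "fitted",
            validated=res.quality in ("strong", "moderate"), b_factor=b)
    # heterogen / metal: no de novo building; carry over an input model only
    if carried:
        same = [a for a in structure.atoms
                if a.resname == linked.resname and a.resid == linked.resid
                and a.chain == linked.chain]
        return SolventAssignment(
            peak_id=peak.id, cls=cls,
            coordinates=np.array([a.pos for a in same]),
            elements=[a.element for a in same], resname=linked.resname,
            provenance="carried_over",
            validated=res.quality in ("strong", "moderate"), b_factor=b)
    return None


def emit_solvent(assignments: list, structure: StructureModel,
                 cfg=DEFAULT_CONFIG.triage) -> StructureModel:
    """Build the output solvent-only model; clashing atoms are dropped."""
    macro = structure.strip_solvent()
    atoms = []
    resid = 1
    for a in assignments:
        keep = True
        for xyz in a.coordinates:
            contacts = neighbors(macro, xyz, cfg.clash_distance) if macro.atoms else []
            if any(c.distance < cfg.clash_distance - 1e-9 for c in contacts):
                keep = False
                break
        if not keep:
            continue
        names = (["O"] if a.resname == "HOH"
                 else ["S", "O1", "O2", "O3", "O4"] if a.resname == "SO4"
                 else [f"{el}{i + 1}" for i, el in enumerate(a.elements)])
        for el, name, xyz in zip(a.elements, names, a.coordinates):
            atoms.append(Atom(element=el, name=name, resname=a.resname,
                              resid=resid, chain="W", pos=np.asarray(xyz, dtype=float),
                              occ=1.0, b=a.b_factor))
        resid += 1
    return StructureModel(atoms=atoms, cell=structure.cell,
                          spacegroup=structure.spacegroup,
                          resolution=structure.resolution)


def run_pipeline(structure: StructureModel, two_fofc: DensityGrid,
                 fofc: DensityGrid, trained, config: Config | None = None,
                 peaks: list | None = None, verbose: bool = False):
    """Full classification of a structure's solvent (the outer loop).

    Returns ``(report, assignments, solvent_model)``: a per-peak report
    table, the final solvent assignments, and a solvent-only structure.
    Deterministic for fixed inputs; iterates to a fixed point (max 10
    rounds).
    """
    cfg = config or DEFAULT_CONFIG
    if two_fofc is None or fofc is None:
        raise ValueError("both 2Fo-Fc and Fo-Fc maps are required")
    stripped = structure.strip_solvent()
    grids = {
        "two_fofc": two_fofc, "fofc": fofc,
        "pseudoinverse_two_fofc": make_pseudoinverse(two_fofc),
        "pseudoinverse_fofc": make_pseudoinverse(fofc),
    }
    if peaks is None:
        map_peaks = find_difference_peaks(
            fofc, cfg.triage.peak_threshold_sigma, structure.resolution,
            structure=stripped)
        solvent_peaks = associate_solvent_peaks(
            structure, map_peaks, cfg.triage.solvent_associate_cutoff)
        claimed = set()
        for sp in solvent_peaks:
            d = [np.linalg.norm(mp.coordinate - sp.coordinate) for mp in map_peaks]
            if d and min(d) < cfg.triage.solvent_associate_cutoff:
                claimed.add(map_peaks[int(np.argmin(d))].id)
        peaks = [p for p in map_peaks if p.id not in claimed] + solvent_peaks
    if not peaks:
        return pd.DataFrame(), [], emit_solvent([], structure, cfg.triage)

    weights = trained.cf2_weights or default_cf2_weights()
    features = {}
    for p in peaks:
        fv = extract_features(p, stripped if p.source != "solvent_model" else stripped,
                              grids, weights=weights, cfg=cfg.features)
        features[p.id] = dict(fv.values)
    clash_counts = {p.id: _clash_count(stripped, p.coordinate, cfg.triage)
                    for p in peaks}

    def score_all(ids=None):
        ids = ids if ids is not None else [p.id for p in peaks]
        rows = pd.DataFrame([{"resolution": peaks_by_id[i].resolution,
                              **features[i]} for i in ids])
        sc = trained.score_frame(rows)
        for i, (_, r) in zip(ids, sc.iterrows()):
            triples[i] = ScoreTriple(ed=float(r["ed"]), cc=float(r["cc"]),
                                     c2=float(r["c2"]),
                                     p_notwater=float(r["p_notwater"]))

    peaks_by_id = {p.id: p for p in peaks}
    triples: dict = {}
    score_all()

    validated_ids: set = set()
    prev_sig = None
    assignments: list = []
    results: dict = {}
    for iteration in range(cfg.triage.max_iterations):
        prior_vec, _ = adaptive_prior(list(triples.values()), trained.histograms,
                                      trained.priors.training, cfg.training)
        trained.priors.adaptive = prior_vec
        results = {p.id: predict(triples[p.id], trained.histograms,
                                 trained.priors, peak_id=p.id) for p in peaks}
        errors = flag_model_errors(results, clash_counts, cfg.triage)
        for pid in errors:
            peaks_by_id[pid].flags.add("model_error")
            results[pid].disposition = "model_error"
        live = [p for p in peaks if p.id not in errors]
        clusters = cluster_peaks(live, structure, results, cfg.triage)
        assignments = []
        for cl in clusters:
            disp = resolve_cluster(cl, clusters, peaks_by_id, results,
                                   structure, cfg.triage)
            for pid, dd in disp.items():
                results[pid].disposition = dd
                if dd not in ("representative", "water"):
                    continue
                res = results[pid]
                if dd == "water" and res.predicted_class in ("sulfate", "heterogen"):
                    # non-representative member examined as a water model
                    res = ClassificationResult(
                        peak_id=pid, likelihoods=res.likelihoods,
                        predicted_class="water", quality="weak", scores=res.scores)
                a = _make_assignment(peaks_by_id[pid], res, features[pid],
                                     structure, cfg.triage)
                if a is not None:
                    assignments.append(a)
        # validated set only ever grows (monotone loop -> guaranteed fixed point)
        for a in assignments:
            if a.validated:
                validated_ids.add(a.peak_id)
            elif a.peak_id in validated_ids:
                a.validated = True
        mark_suspicious_cf1(peaks, features, results, cfg.triage)
        n_changed = update_cf1(peaks, features, assignments, structure)
        if n_changed:
            score_all([p.id for p in peaks if "suspicious_cf1" in p.flags])
        sig = tuple(sorted((a.peak_id, a.cls) for a in assignments))
        if verbose:
            counts = {c: sum(1 for a in assignments if a.cls == c) for c in CLASSES}
            print(f"iteration {iteration + 1}: {counts}, cf1 updates {n_changed}")
        if sig == prev_sig and n_changed == 0:
            break
        prev_sig = sig

    report_rows = []
    for p in peaks:
        res = results[p.id]
        s = triples[p.id]
        row = {"peak_id": p.id, "x": p.coordinate[0], "y": p.coordinate[1],
               "z": p.coordinate[2], "source": p.source,
               "ed": s.ed, "cc": s.cc, "c2": s.c2, "p_notwater": s.p_notwater,
               "predicted_class": res.predicted_class, "quality": res.quality,
               "disposition": res.disposition,
               "flags": ",".join(sorted(p.flags))}
        for scheme, L in res.likelihoods.items():
            for c in CLASSES:
                row[f"L_{scheme}_{c}"] = L[c]
        report_rows.append(row)
    report = pd.DataFrame(report_rows)
    solvent_model = emit_solvent(assignments, structure, cfg.triage)
    return report, assignments, solvent_model
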