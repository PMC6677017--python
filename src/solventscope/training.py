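"""Classifier training: estimating every spline, constant and histogram.

Training is staged: each transformation's parameters are estimated from the
training table, the table is pushed through that transformation, and the
transformed data feed the next stage.  Resolution-dependent parameters are
estimated per moving resolution window and smoothed into six-parameter
natural cubic splines (RPMS); resolution-independent ones (the CC-feature
path) are global constants (RIMPs).  The parameter census of a trained model
is fixed by construction: 591 ED-path parameters of which 361 belong to the
decorrelation matrix, plus 20 RIMPs and 2 RPMSs on the CC path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import ClassHistograms, PriorSet
from .config import (ALL_FEATURES, CC_FEATURES, CF2_VOCABULARY, CLASSES,
                     DEFAULT_CONFIG, ED_FEATURES, TrainingConfig)
from .scorespace import (DecorrelationModel, JsuParams, ScorePipelineParams,
                         WaterScoreStats, decorrelate, fit_rpms,
                         raw_score_cc, raw_score_ed, rescale_score, scale_midpoint_ed,
                         score_table, standardize_cc, standardize_ed)

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Moving resolution windows
# ---------------------------------------------------------------------------

@dataclass
class ResolutionWindow:
    start: int                # row range [start, end) in the resolution-sorted table
    end: int
    mean_resolution: float


def moving_windows(resolutions: np.ndarray, window_size: int,
                   step: float = 0.5, min_window: int = 200) -> list:
    """Overlapping windows over the resolution-sorted rows, last one anchored."""
    n = len(resolutions)
    if window_size < min_window:
        raise ValueError(f"window_size must be >= {min_window}")
    if n < min_window:
        raise ValueError(f"need at least {min_window} rows, got {n}")
    window_size = min(window_size, n)
    order_ok = np.all(np.diff(resolutions) >= 0)
    if not order_ok:
        raise ValueError("resolutions must be sorted ascending")
    step_rows = max(int(round(step * window_size)), 1)
    starts = list(range(0, n - window_size + 1, step_rows))
    if starts[-1] != n - window_size:
        starts.append(n - window_size)
    return [ResolutionWindow(s, s + window_size,
                             float(np.mean(resolutions[s:s + window_size])))
            for s in starts]


# ---------------------------------------------------------------------------
# Window PCA with continuity alignment
# ---------------------------------------------------------------------------

def window_pca(Z: np.ndarray, prev_vectors: np.ndarray | None = None):
    """Eigen decomposition of a window's covariance, aligned to the previous one.

    Eigenvalues come back descending.  To keep the spline fits of the modal
    matrix smooth, each eigenvector is greedily matched (max |dot|) to the
    previous window's and sign-flipped when anti-parallel; the first window
    fixes each sign by making the largest-magnitude entry positive.
    """
    Z = np.asarray(Z, dtype=float)
    cov = np.cov(Z, rowvar=False)
    p = cov.shape[0]
    if np.linalg.matrix_rank(cov) < p:
        cov = cov + 1e-6 * np.eye(p)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if prev_vectors is None:
        for j in range(p):
            k = np.argmax(np.abs(vecs[:, j]))
            if vecs[k, j] < 0:
                vecs[:, j] = -vecs[:, j]
        return vals, vecs
    dots = prev_vectors.T @ vecs                      # (prev_j, cur_k)
    used = np.zeros(p, dtype=bool)
    new_vecs = np.empty_like(vecs)
    new_vals = np.empty_like(vals)
    for j in range(p):
        masked = np.where(used, -np.inf, np.abs(dots[j]))
        k = int(np.argmax(masked))
        used[k] = True
        sgn = 1.0 if dots[j, k] >= 0 else -1.0
        new_vecs[:, j] = sgn * vecs[:, k]
        new_vals[j] = vals[k]
    return new_vals, new_vecs


# ---------------------------------------------------------------------------
# Johnson S_U maximum-likelihood fit
# ---------------------------------------------------------------------------

def _jsu_nll_grad(params: np.ndarray, x: np.ndarray):
    gamma, logd, xi, logl = params
    delta, lam = np.exp(logd), np.exp(logl)
    z = (x - xi) / lam
    sq = np.sqrt(1.0 + z * z)
    u = np.arcsinh(z)
    t = gamma + delta * u
    n = x.size
    nll = -(np.log(delta) - np.log(lam) - 0.5 * np.log(2 * np.pi)) * n \
        + 0.5 * np.sum(np.log1p(z * z)) + 0.5 * np.sum(t * t)
    r = z / (1.0 + z * z)
    w = r + t * delta / sq
    g_gamma = np.sum(t)
    g_logd = -n + delta * np.sum(t * u)
    g_xi = -np.sum(w) / lam
    g_logl = n - np.sum(w * z)
    return nll / n, np.array([g_gamma, g_logd, g_xi, g_logl]) / n


def _jsu_moment_init(x: np.ndarray, gamma0: float, delta0: float) -> np.ndarray:
    m, s = float(np.mean(x)), float(np.std(x))
    w = np.exp(delta0**-2.0)
    v0 = 0.5 * (w - 1) * (w * np.cosh(2 * gamma0 / delta0) + 1)
    lam0 = s / np.sqrt(v0)
    xi0 = m + lam0 * np.sqrt(w) * np.sinh(gamma0 / delta0)
    return np.array([gamma0, np.log(delta0), xi0, np.log(lam0)])


def fit_jsu(values: np.ndarray, max_sample: int | None = None) -> JsuParams:
    """Fit Johnson-S_U parameters by moment-matched start + L-BFGS-B polish.

    Deterministic: when the sample exceeds ``max_sample`` an evenly strided
    subset is used.  The returned fit never has a worse likelihood than its
    moment-matched start.
    """
    from scipy.optimize import minimize

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50 or np.std(x) <= 0:
        raise ValueError("degenerate sample for Johnson-SU fit")
    if max_sample is not None and x.size > max_sample:
        x = x[np.linspace(0, x.size - 1, max_sample).astype(int)]
    skew = float(np.mean(((x - x.mean()) / x.std()) ** 3))
    starts = [(0.0, 1.8), (-np.sign(skew) * 0.7 if skew else 0.7, 1.2), (0.0, 3.0)]
    best = None
    for g0, d0 in starts:
        p0 = _jsu_moment_init(x, g0, d0)
        nll0, _ = _jsu_nll_grad(p0, x)
        res = minimize(_jsu_nll_grad, p0, args=(x,), jac=True, method="L-BFGS-B",
                       bounds=[(-6, 6), (np.log(0.05), np.log(50)),
                               (None, None), (np.log(1e-6), None)],
                       options={"maxiter": 100})
        cand = (min(res.fun, nll0), res.x if res.fun <= nll0 else p0)
        if best is None or cand[0] < best[0]:
            best = cand
    g, logd, xi, logl = best[1]
    return JsuParams(gamma=float(g), delta=float(np.exp(logd)),
                     xi=float(xi), lam=float(np.exp(logl)))


# ---------------------------------------------------------------------------
# CF2 contact-frequency weights
# ---------------------------------------------------------------------------

def estimate_cf2_weights(counts_sulfate: dict, counts_water: dict) -> dict:
    """Add-one-smoothed log-odds of contact-type frequency near SO4 vs HOH."""
    T = len(CF2_VOCABULARY)
    n_so4 = sum(counts_sulfate.get(t, 0) for t in CF2_VOCABULARY)
    n_hoh = sum(counts_water.get(t, 0) for t in CF2_VOCABULARY)
    return {
        t: float(np.log((counts_sulfate.get(t, 0) + 1.0) / (counts_water.get(t, 0) + 1.0)
                        * (n_hoh + T) / (n_so4 + T)))
        for t in CF2_VOCABULARY
    }


# ---------------------------------------------------------------------------
# The trained classifier
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """Full parameter registry: score pipeline, histograms, priors, calibration."""

    pipeline: ScorePipelineParams
    histograms: ClassHistograms
    priors: PriorSet
    water_stats: WaterScoreStats
    cf2_weights: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def census(self) -> dict:
        return self.pipeline.census()

    # -- scoring ------------------------------------------------------------

    def score_frame(self, df: pd.DataFrame) -> pd.DataFrame:
        """ED/CC/C2 scores and not-water probability for a feature table."""
        X_ed = df[ED_FEATURES].to_numpy(dtype=float)
        X_cc = df[CC_FEATURES].to_numpy(dtype=float)
        res = df["resolution"].to_numpy(dtype=float)
        ed, cc, c2v, p = score_table(X_ed, X_cc, res, self.pipeline, self.water_stats)
        return pd.DataFrame({"ed": ed, "cc": cc, "c2": c2v, "p_notwater": p},
                            index=df.index)

    def predict_table(self, ed: np.ndarray, cc: np.ndarray,
                      prior: np.ndarray | None = None) -> np.ndarray:
        """Vectorized argmax-class prediction for score arrays under one prior."""
        from .classifier import HIST_FLOOR

        prior = np.full(4, 0.25) if prior is None else np.asarray(prior, dtype=float)
        edges = self.histograms.edges
        i = np.clip(np.searchsorted(edges, ed, side="right") - 1, 0, len(edges) - 2)
        j = np.clip(np.searchsorted(edges, cc, side="right") - 1, 0, len(edges) - 2)
        masses = np.stack([
            np.maximum(self.histograms.ed_hist[c][i] * self.histograms.cc_hist[c][j],
                       HIST_FLOOR) * prior[k]
            for k, c in enumerate(CLASSES)
        ])
        return np.asarray(CLASSES, dtype=object)[np.argmax(masses, axis=0)]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "pipeline": self.pipeline.to_dict(),
            "histograms": self.histograms.to_dict(),
            "priors": self.priors.to_dict(),
            "water_stats": self.water_stats.to_dict(),
            "cf2_weights": dict(self.cf2_weights),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedClassifier":
        return cls(
            pipeline=ScorePipelineParams.from_dict(d["pipeline"]),
            histograms=ClassHistograms.from_dict(d["histograms"]),
            priors=PriorSet.from_dict(d["priors"]),
            water_stats=WaterScoreStats.from_dict(d["water_stats"]),
            cf2_weights=d.get("cf2_weights", {}),
            metadata=d.get("metadata", {}),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "TrainedClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Staged training
# ---------------------------------------------------------------------------

def _window_class_stats(values: np.ndarray, labels: np.ndarray, windows,
                        min_class: int = 5):
    """Per-window sulfate/water midpoint and pooled sd of a value column."""
    pts_res, pts_c, pts_s = [], [], []
    for w in windows:
        lab = labels[w.start:w.end]
        v = values[w.start:w.end]
        vs, vw = v[lab == "sulfate"], v[lab == "water"]
        if len(vs) < min_class or len(vw) < min_class:
            continue
        c = 0.5 * (vs.mean() + vw.mean())
        s = np.sqrt(0.5 * (vs.var() + vw.var()))
        if s <= 0:
            continue
        pts_res.append(w.mean_resolution)
        pts_c.append(c)
        pts_s.append(s)
    if not pts_res:
        raise ValueError("no window had enough sulfate and water rows")
    return fit_rpms(pts_res, pts_c), fit_rpms(pts_res, pts_s)


def train(df: pd.DataFrame, config: TrainingConfig | None = None,
          seed: int = 0) -> TrainedClassifier:
    """Estimate every parameter of the classifier from a labeled feature table.

    The table needs ``resolution``, the 21 feature columns and ``label``
    (sulfate and water must both be present).  Deterministic for fixed data.
    """
    cfg = config or DEFAULT_CONFIG.training
    missing = [c for c in ["resolution", "label", *ALL_FEATURES] if c not in df.columns]
    if missing:
        raise ValueError(f"training table lacks column(s): {', '.join(missing)}")
    for need in ("sulfate", "water"):
        if need not in set(df["label"]):
            raise ValueError(f"training requires class {need!r}")
    df = df.sort_values("resolution", kind="mergesort").reset_index(drop=True)
    res = df["resolution"].to_numpy(dtype=float)
    labels = df["label"].to_numpy()
    n = len(df)
    window_size = min(cfg.window_size, max(n // 10, cfg.min_window))
    windows = moving_windows(res, window_size, cfg.window_step, cfg.min_window)
    wres = [w.mean_resolution for w in windows]

    # (1) standardization splines from per-window feature moments
    X = df[ED_FEATURES].to_numpy(dtype=float)
    ed_standardize = []
    for j in range(len(ED_FEATURES)):
        mus = [X[w.start:w.end, j].mean() for w in windows]
        sds = [X[w.start:w.end, j].std() for w in windows]
        ed_standardize.append((fit_rpms(wres, mus), fit_rpms(wres, sds)))
    partial = ScorePipelineParams(
        ed_standardize=ed_standardize, decorrelation=None, ed_scale=None,
        ed_jsu=None, ed_rescale=None, cc_standardize=None, cc_jsu=None,
        cc_rescale=None)
    Z = standardize_ed(X, res, partial)

    # (2) per-window PCA -> 361 modal-matrix splines.  Each window's
    # eigenbasis is aligned to the global PCA by orthogonal Procrustes:
    # near-equal eigenvalues leave the eigenbasis free to rotate inside a
    # degenerate subspace from window to window, and without the alignment
    # the splines would chase that arbitrary rotation instead of the real
    # covariance drift.
    _, ref = window_pca(Z)
    mats = []
    for w in windows:
        _, vecs = window_pca(Z[w.start:w.end], ref)
        U, _, Wt = np.linalg.svd(vecs.T @ ref)
        mats.append(vecs @ (U @ Wt))
    mats = np.array(mats)                               # (nw, 19, 19)
    p = len(ED_FEATURES)
    splines = [[fit_rpms(wres, mats[:, i, j]) for j in range(p)] for i in range(p)]
    decorr = DecorrelationModel(splines=splines)
    Y = decorrelate(Z, res, decorr)

    # (3) midpoint scaling of the decorrelated components
    ed_scale = [(_window_class_stats(Y[:, j], labels, windows)) for j in range(p)]
    partial.decorrelation = decorr
    partial.ed_scale = ed_scale
    S = scale_midpoint_ed(Y, res, partial)

    # (4) Johnson-SU fits -> 8 splines per component.  The shape parameters
    # (gamma, delta) are pooled over all windows of a class — per-window
    # minority-class samples are far too small for stable tail estimates and
    # the scaled components are shape-stationary by construction — while the
    # location/scale (xi, lambda) track the windowed moments analytically.
    ed_jsu = []
    for j in range(p):
        per_class = {}
        for cls_name in ("sulfate", "water"):
            cls_mask = labels == cls_name
            shape = fit_jsu(S[cls_mask, j], max_sample=4 * cfg.jsu_subsample)
            g, dlt = shape.gamma, shape.delta
            w_ = np.exp(dlt**-2.0)
            m0 = -np.sqrt(w_) * np.sinh(g / dlt)
            v0 = 0.5 * (w_ - 1) * (w_ * np.cosh(2 * g / dlt) + 1)
            pr, pxi, plam = [], [], []
            for w in windows:
                v = S[w.start:w.end, j][labels[w.start:w.end] == cls_name]
                if len(v) < 20 or v.std() <= 0:
                    continue
                lam_w = float(v.std() / np.sqrt(v0))
                xi_w = float(v.mean() - lam_w * m0)
                pr.append(w.mean_resolution)
                pxi.append(xi_w)
                plam.append(lam_w)
            if not pr:
                raise ValueError(f"no window had enough {cls_name} rows for SU fits")
            per_class[cls_name] = [fit_rpms(pr, [g] * len(pr)),
                                   fit_rpms(pr, [dlt] * len(pr)),
                                   fit_rpms(pr, pxi), fit_rpms(pr, plam)]
        ed_jsu.append(per_class)
    partial.ed_jsu = ed_jsu

    # (5) raw ED scores -> rescale splines
    raw_ed = raw_score_ed(S, res, partial)
    partial.ed_rescale = _window_class_stats(raw_ed, labels, windows)

    # (6) CC path: global RIMPs + rescale splines
    Xc = df[CC_FEATURES].to_numpy(dtype=float)
    cc_standardize = [(float(Xc[:, j].mean()), float(Xc[:, j].std()))
                      for j in range(len(CC_FEATURES))]
    partial.cc_standardize = cc_standardize
    Zc = standardize_cc(Xc, partial)
    cc_jsu = []
    for j in range(len(CC_FEATURES)):
        cc_jsu.append({
            cls_name: fit_jsu(Zc[labels == cls_name, j], max_sample=4 * cfg.jsu_subsample)
            for cls_name in ("sulfate", "water")
        })
    partial.cc_jsu = cc_jsu
    raw_cc = raw_score_cc(Zc, partial)
    partial.cc_rescale = _window_class_stats(raw_cc, labels, windows)

    census = partial.census()
    if census["ed_total"] != 591 or census["ed_decorrelation"] != 361 \
            or census["cc_rimps"] != 20 or census["cc_rpms"] != 2:
        raise RuntimeError(f"parameter census mismatch: {census}")

    # (7) final scores -> per-class histograms
    ed_final = rescale_score(raw_ed, res, partial.ed_rescale)
    cc_final = rescale_score(raw_cc, res, partial.cc_rescale)
    lo, hi = cfg.hist_range
    edges = np.linspace(lo, hi, cfg.hist_bins + 1)
    ed_hist, cc_hist = {}, {}
    for cls_name in CLASSES:
        m = labels == cls_name
        if not np.any(m):
            # class absent from training: zero mass everywhere (the lookup
            # floor keeps likelihoods finite), so it never outbids a class
            # that was actually observed
            ed_hist[cls_name] = np.zeros(cfg.hist_bins)
            cc_hist[cls_name] = np.zeros(cfg.hist_bins)
            continue
        he, _ = np.histogram(np.clip(ed_final[m], lo, hi - 1e-9), bins=edges)
        hc, _ = np.histogram(np.clip(cc_final[m], lo, hi - 1e-9), bins=edges)
        ed_hist[cls_name] = he / he.sum()
        cc_hist[cls_name] = hc / hc.sum()
    hists = ClassHistograms(edges=edges, ed_hist=ed_hist, cc_hist=cc_hist)

    # (8) training prior: Dirichlet-smoothed class frequencies
    counts = np.array([(labels == c).sum() for c in CLASSES], dtype=float)
    training_prior = (counts + cfg.dirichlet_alpha) / (counts + cfg.dirichlet_alpha).sum()
    priors = PriorSet(training=training_prior)

    # (9) C2 calibration from the water score population
    mw = labels == "water"
    water_stats = WaterScoreStats(
        mu_ed=float(ed_final[mw].mean()), sd_ed=float(ed_final[mw].std()),
        mu_cc=float(cc_final[mw].mean()), sd_cc=float(cc_final[mw].std()))

    meta = {"n_rows": int(n), "resolution_min": float(res.min()),
            "resolution_max": float(res.max()), "seed": int(seed),
            "n_windows": len(windows), "window_size": int(window_size)}
    return TrainedClassifier(pipeline=partial, histograms=hists, priors=priors,
                             water_stats=water_stats, metadata=meta)
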