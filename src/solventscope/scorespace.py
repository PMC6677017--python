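"""Mapping 21-feature vectors to resolution-independent ED and CC scores.

The 19 electron-density (ED) features are strongly resolution-dependent and
mutually correlated, so their path to a score runs through five stages:

    standardize -> decorrelate -> scale -> naive-Bayes log-odds -> rescale

Every resolution-dependent parameter of those stages is represented by a
resolution-to-parameter mapping spline (RPMS): a six-parameter natural cubic
regression spline evaluated at the peak's resolution.  The two contact (CC)
features, CF1 and CF2, are resolution-independent; their parameters are plain
scalars (RIMPs) except the final rescale, which remains spline-valued.

Scores are signed so that positive means sulfate-like, negative water-like.
The C2 score is a pseudo-chi-squared distance of the (ED, CC) pair from the
water population, converted to a not-water probability through the chi2(2 df)
CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .config import ALL_FEATURES, CC_FEATURES, ED_FEATURES

PDF_FLOOR = 1e-12  # pdf floor before taking logs: bounds outlier influence
LOG_PDF_FLOOR = float(np.log(PDF_FLOOR))


# ---------------------------------------------------------------------------
# RPMS: six-parameter natural cubic regression spline of resolution
# ---------------------------------------------------------------------------

def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (K basis functions for K knots).

    Truncated-power construction: 1, x, and K-2 combinations of cubic terms
    that are linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    K = len(knots)
    cols = [np.ones_like(x), x]

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    dKm1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dKm1)
    return np.column_stack(cols)


@dataclass
class Rpms:
    """Resolution-to-parameter mapping spline, clamped outside its fit range."""

    knots: np.ndarray          # 6 knot resolutions (Å), ascending
    coef: np.ndarray           # 6 basis coefficients
    lo: float                  # valid range: evaluation clamps to [lo, hi]
    hi: float
    residual_sd: float = 0.0

    def __call__(self, resolution):
        r = np.clip(np.asarray(resolution, dtype=float), self.lo, self.hi)
        scalar = r.ndim == 0
        vals = _natural_spline_basis(np.atleast_1d(r), self.knots) @ self.coef
        return float(vals[0]) if scalar else vals

    @classmethod
    def constant(cls, value: float, lo: float = 0.6, hi: float = 5.0) -> "Rpms":
        knots = np.linspace(lo, hi, 6)
        coef = np.zeros(6)
        coef[0] = value
        return cls(knots=knots, coef=coef, lo=lo, hi=hi)

    def to_dict(self) -> dict:
        return {
            "knots": self.knots.tolist(),
            "coef": self.coef.tolist(),
            "lo": self.lo,
            "hi": self.hi,
            "residual_sd": self.residual_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rpms":
        return cls(
            knots=np.asarray(d["knots"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            lo=float(d["lo"]),
            hi=float(d["hi"]),
            residual_sd=float(d.get("residual_sd", 0.0)),
        )


def fit_rpms(resolutions: Sequence[float], estimates: Sequence[float]) -> Rpms:
    """Least-squares natural cubic regression spline with 6 basis functions.

    Knots sit at the {0, 0.2, ..., 1.0} quantiles of the point resolutions,
    which keeps the fit well-conditioned under uneven resolution coverage.
    With exactly 6 distinct points the fit interpolates; with fewer than 6
    points (or degenerate spread) a constant spline is returned.
    """
    r = np.asarray(resolutions, dtype=float)
    y = np.asarray(estimates, dtype=float)
    if r.size != y.size or r.size == 0:
        raise ValueError("resolutions and estimates must be equal-length and non-empty")
    lo, hi = float(r.min()), float(r.max())
    knots = np.quantile(r, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    if r.size < 6 or len(np.unique(knots)) < 6:
        return Rpms.constant(float(y.mean()), lo=lo if lo < hi else lo - 0.5, hi=hi if hi > lo else hi + 0.5)
    X = _natural_spline_basis(r, knots)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rsd = float(np.sqrt(np.mean(resid**2)))
    return Rpms(knots=knots, coef=coef, lo=lo, hi=hi, residual_sd=rsd)


# ---------------------------------------------------------------------------
# Johnson S_U distribution
# ---------------------------------------------------------------------------

@dataclass
class JsuParams:
    """Johnson S_U parameters: shapes gamma/delta, location xi, scale lam."""

    gamma: float
    delta: float
    xi: float
    lam: float

    def __post_init__(self):
        if self.delta <= 0 or self.lam <= 0:
            raise ValueError("delta and lam must be positive")

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "delta": self.delta, "xi": self.xi, "lam": self.lam}

    @classmethod
    def from_dict(cls, d: dict) -> "JsuParams":
        return cls(float(d["gamma"]), float(d["delta"]), float(d["xi"]), float(d["lam"]))

    def mean(self) -> float:
        w = np.exp(self.delta**-2)
        return self.xi - self.lam * np.sqrt(w) * np.sinh(self.gamma / self.delta)

    def var(self) -> float:
        w = np.exp(self.delta**-2)
        return 0.5 * self.lam**2 * (w - 1) * (w * np.cosh(2 * self.gamma / self.delta) + 1)


def jsu_logpdf(x, gamma, delta, xi, lam):
    """Vectorized log-density; parameters may be scalars or arrays."""
    z = (np.asarray(x, dtype=float) - xi) / lam
    t = gamma + delta * np.arcsinh(z)
    return (
        np.log(delta)
        - np.log(lam)
        - 0.5 * np.log(2 * np.pi)
        - 0.5 * np.log1p(z**2)
        - 0.5 * t**2
    )


def jsu_pdf(x, p: JsuParams):
    """Density of Johnson's S_U at ``x``."""
    return np.exp(jsu_logpdf(x, p.gamma, p.delta, p.xi, p.lam))


# ---------------------------------------------------------------------------
# Trained parameter containers
# ---------------------------------------------------------------------------

@dataclass
class DecorrelationModel:
    """19x19 modal matrix, each entry an RPMS of resolution.

    Columns are eigenvectors of the standardized-ED-feature covariance,
    ordered by descending eigenvalue and sign/order aligned across the
    training windows so the splines fit a smooth function.
    """

    splines: list  # 19 rows x 19 cols of Rpms

    def matrix(self, resolution: float) -> np.ndarray:
        n = len(self.splines)
        M = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                M[i, j] = self.splines[i][j](resolution)
        return M

    def matrices(self, resolutions: np.ndarray) -> np.ndarray:
        """(n_res, 19, 19) stack of modal matrices."""
        n = len(self.splines)
        out = np.empty((len(resolutions), n, n))
        for i in range(n):
            for j in range(n):
                out[:, i, j] = self.splines[i][j](resolutions)
        return out

    def n_parameters(self) -> int:
        return len(self.splines) ** 2

    def to_dict(self) -> dict:
        return {"splines": [[s.to_dict() for s in row] for row in self.splines]}

    @classmethod
    def from_dict(cls, d: dict) -> "DecorrelationModel":
        return cls(splines=[[Rpms.from_dict(s) for s in row] for row in d["splines"]])


@dataclass
class ScorePipelineParams:
    """Full parameter registry of the feature-to-score mapping."""

    # ED path (indexed in ED_FEATURES order, then component order post-PCA)
    ed_standardize: list       # 19 x (Rpms mean, Rpms sd)
    decorrelation: DecorrelationModel
    ed_scale: list             # 19 x (Rpms center, Rpms sd), per component
    ed_jsu: list               # 19 x {"sulfate": [4 Rpms], "water": [4 Rpms]}
    ed_rescale: tuple          # (Rpms center, Rpms sd)
    # CC path (CF1, CF2)
    cc_standardize: list       # 2 x (mean RIMP, sd RIMP)
    cc_jsu: list               # 2 x {"sulfate": JsuParams, "water": JsuParams}
    cc_rescale: tuple          # (Rpms center, Rpms sd)

    def census(self) -> dict:
        """Parameter counts; the ED path must total 591 with 361 decorrelation."""
        ed_std = sum(len(pair) for pair in self.ed_standardize)
        ed_scl = sum(len(pair) for pair in self.ed_scale)
        ed_jsu = sum(len(d["sulfate"]) + len(d["water"]) for d in self.ed_jsu)
        decorr = self.decorrelation.n_parameters()
        ed_total = ed_std + decorr + ed_scl + ed_jsu + 2
        cc_rimps = sum(len(pair) for pair in self.cc_standardize) + 4 * 2 * len(self.cc_jsu)
        return {
            "ed_total": ed_total,
            "ed_decorrelation": decorr,
            "cc_rimps": cc_rimps,
            "cc_rpms": 2,
        }

    def to_dict(self) -> dict:
        return {
            "ed_standardize": [[p.to_dict() for p in pair] for pair in self.ed_standardize],
            "decorrelation": self.decorrelation.to_dict(),
            "ed_scale": [[p.to_dict() for p in pair] for pair in self.ed_scale],
            "ed_jsu": [
                {c: [p.to_dict() for p in d[c]] for c in ("sulfate", "water")}
                for d in self.ed_jsu
            ],
            "ed_rescale": [p.to_dict() for p in self.ed_rescale],
            "cc_standardize": [list(pair) for pair in self.cc_standardize],
            "cc_jsu": [
                {c: d[c].to_dict() for c in ("sulfate", "water")} for d in self.cc_jsu
            ],
            "cc_rescale": [p.to_dict() for p in self.cc_rescale],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScorePipelineParams":
        return cls(
            ed_standardize=[[Rpms.from_dict(p) for p in pair] for pair in d["ed_standardize"]],
            decorrelation=DecorrelationModel.from_dict(d["decorrelation"]),
            ed_scale=[[Rpms.from_dict(p) for p in pair] for pair in d["ed_scale"]],
            ed_jsu=[
                {c: [Rpms.from_dict(p) for p in e[c]] for c in ("sulfate", "water")}
                for e in d["ed_jsu"]
            ],
            ed_rescale=tuple(Rpms.from_dict(p) for p in d["ed_rescale"]),
            cc_standardize=[tuple(pair) for pair in d["cc_standardize"]],
            cc_jsu=[
                {c: JsuParams.from_dict(e[c]) for c in ("sulfate", "water")}
                for e in d["cc_jsu"]
            ],
            cc_rescale=tuple(Rpms.from_dict(p) for p in d["cc_rescale"]),
        )


@dataclass
class ScoreTriple:
    """ED/CC composite scores plus the water-distance pseudo-chi-squared."""

    ed: float
    cc: float
    c2: float
    p_notwater: float


# ---------------------------------------------------------------------------
# Pipeline stages (vectorized over rows)
# ---------------------------------------------------------------------------

def standardize_ed(X: np.ndarray, resolutions: np.ndarray, params: ScorePipelineParams) -> np.ndarray:
    """(x - mu(d)) / sigma(d) per ED feature; X is (n, 19)."""
    Z = np.empty_like(X, dtype=float)
    for j, (mu_s, sd_s) in enumerate(params.ed_standardize):
        sd = sd_s(resolutions)
        if np.any(sd <= 0):
            raise ValueError(f"degenerate scale for ED feature {ED_FEATURES[j]}")
        Z[:, j] = (X[:, j] - mu_s(resolutions)) / sd
    return Z


def decorrelate(Z: np.ndarray, resolutions: np.ndarray, model: DecorrelationModel,
                chunk: int = 8192) -> np.ndarray:
    """y = M(d)^T z row-wise, with the modal matrix evaluated per resolution."""
    Z = np.asarray(Z, dtype=float)
    out = np.empty_like(Z)
    for s in range(0, len(Z), chunk):
        e = min(s + chunk, len(Z))
        M = model.matrices(np.asarray(resolutions[s:e], dtype=float))
        out[s:e] = np.einsum("rij,ri->rj", M, Z[s:e])
    return out


def scale_midpoint_ed(Y: np.ndarray, resolutions: np.ndarray, params: ScorePipelineParams) -> np.ndarray:
    """(y - c(d)) / s(d): c is the sulfate/water class-mean midpoint, s pooled sd."""
    S = np.empty_like(Y, dtype=float)
    for j, (c_s, s_s) in enumerate(params.ed_scale):
        s = s_s(resolutions)
        if np.any(s <= 0):
            raise ValueError(f"degenerate scale for ED component {j}")
        S[:, j] = (Y[:, j] - c_s(resolutions)) / s
    return S


def _jsu_logpdf_from_splines(x: np.ndarray, resolutions: np.ndarray, splines) -> np.ndarray:
    g, d, xi, lam = (sp(resolutions) for sp in splines)
    d = np.maximum(d, 1e-6)
    lam = np.maximum(lam, 1e-9)
    return jsu_logpdf(x, g, d, xi, lam)


def raw_score_ed(S: np.ndarray, resolutions: np.ndarray, params: ScorePipelineParams) -> np.ndarray:
    """Naive-Bayes log-odds: sum over components of ln pdf_SO4 - ln pdf_HOH."""
    total = np.zeros(len(S))
    for j, entry in enumerate(params.ed_jsu):
        lp_s = _jsu_logpdf_from_splines(S[:, j], resolutions, entry["sulfate"])
        lp_w = _jsu_logpdf_from_splines(S[:, j], resolutions, entry["water"])
        total += np.maximum(lp_s, LOG_PDF_FLOOR) - np.maximum(lp_w, LOG_PDF_FLOOR)
    return total


def raw_score(values: np.ndarray, sulfate_pdfs: Sequence[JsuParams],
              water_pdfs: Sequence[JsuParams]) -> float:
    """Scalar naive-Bayes log-odds for one decorrelated+scaled vector."""
    total = 0.0
    for x, ps, pw in zip(values, sulfate_pdfs, water_pdfs):
        total += np.log(max(jsu_pdf(x, ps), PDF_FLOOR)) - np.log(max(jsu_pdf(x, pw), PDF_FLOOR))
    return float(total)


def rescale_score(raw, resolutions, rescale_pair) -> np.ndarray:
    c_s, s_s = rescale_pair
    s = s_s(resolutions)
    if np.any(np.asarray(s) <= 0):
        raise ValueError("degenerate rescale sd")
    return (raw - c_s(resolutions)) / s


def standardize_cc(X: np.ndarray, params: ScorePipelineParams) -> np.ndarray:
    Z = np.empty_like(X, dtype=float)
    for j, (mu, sd) in enumerate(params.cc_standardize):
        if sd <= 0:
            raise ValueError(f"degenerate scale for {CC_FEATURES[j]}")
        Z[:, j] = (X[:, j] - mu) / sd
    return Z


def raw_score_cc(Z: np.ndarray, params: ScorePipelineParams) -> np.ndarray:
    total = np.zeros(len(Z))
    for j, entry in enumerate(params.cc_jsu):
        ps, pw = entry["sulfate"], entry["water"]
        lp_s = jsu_logpdf(Z[:, j], ps.gamma, ps.delta, ps.xi, ps.lam)
        lp_w = jsu_logpdf(Z[:, j], pw.gamma, pw.delta, pw.xi, pw.lam)
        total += np.maximum(lp_s, LOG_PDF_FLOOR) - np.maximum(lp_w, LOG_PDF_FLOOR)
    return total


@dataclass
class WaterScoreStats:
    """Water-class moments of the final scores, for the C2 statistic."""

    mu_ed: float
    sd_ed: float
    mu_cc: float
    sd_cc: float

    def to_dict(self) -> dict:
        return {"mu_ed": self.mu_ed, "sd_ed": self.sd_ed, "mu_cc": self.mu_cc, "sd_cc": self.sd_cc}

    @classmethod
    def from_dict(cls, d: dict) -> "WaterScoreStats":
        return cls(float(d["mu_ed"]), float(d["sd_ed"]), float(d["mu_cc"]), float(d["sd_cc"]))


def c2_score(ed, cc, water_stats: WaterScoreStats):
    """Pseudo-chi-squared distance from the water score population.

    Returns (c2, p_notwater) where p_notwater is the chi2(2 df) CDF at c2:
    a peak sitting at the water means has c2 = 0 and is certainly waterlike.
    """
    c2v = ((np.asarray(ed) - water_stats.mu_ed) / water_stats.sd_ed) ** 2 + (
        (np.asarray(cc) - water_stats.mu_cc) / water_stats.sd_cc
    ) ** 2
    return c2v, chi2.cdf(c2v, df=2)


def score_table(X_ed: np.ndarray, X_cc: np.ndarray, resolutions: np.ndarray,
                params: ScorePipelineParams, water_stats: WaterScoreStats | None = None):
    """Vectorized feature-to-score mapping.

    Parameters
    ----------
    X_ed : (n, 19) raw ED feature values in ED_FEATURES order.
    X_cc : (n, 2) raw CF1/CF2 values.
    resolutions : (n,) peak resolutions in Å.

    Returns ``(ed, cc)`` arrays, or ``(ed, cc, c2, p_notwater)`` when
    ``water_stats`` is given.
    """
    resolutions = np.asarray(resolutions, dtype=float)
    Z = standardize_ed(np.asarray(X_ed, dtype=float), resolutions, params)
    Y = decorrelate(Z, resolutions, params.decorrelation)
    S = scale_midpoint_ed(Y, resolutions, params)
    ed = rescale_score(raw_score_ed(S, resolutions, params), resolutions, params.ed_rescale)
    Zc = standardize_cc(np.asarray(X_cc, dtype=float), params)
    cc = rescale_score(raw_score_cc(Zc, params), resolutions, params.cc_rescale)
    if water_stats is None:
        return ed, cc
    c2v, p = c2_score(ed, cc, water_stats)
    return ed, cc, c2v, p


def compute_scores(features: dict, resolution: float, params: ScorePipelineParams,
                   water_stats: WaterScoreStats) -> ScoreTriple:
    """Score a single peak from its keyed 21-feature mapping."""
    missing = [f for f in ALL_FEATURES if f not in features]
    if missing:
        raise ValueError(f"missing feature(s): {', '.join(missing)}")
    X_ed = np.array([[features[f] for f in ED_FEATURES]], dtype=float)
    X_cc = np.array([[features[f] for f in CC_FEATURES]], dtype=float)
    ed, cc, c2v, p = score_table(X_ed, X_cc, np.array([resolution]), params, water_stats)
    return ScoreTriple(ed=float(ed[0]), cc=float(cc[0]), c2=float(c2v[0]), p_notwater=float(p[0]))
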