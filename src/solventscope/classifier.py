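"""Class prediction in the 2D ED/CC score plane.

Each solvent class contributes a normalized 1D histogram of its ED scores
and one of its CC scores (shared bin edges); the joint 2D distribution is
their outer product, justified by the decorrelation built into the score
pipeline.  For a peak with scores (ed, cc) the evidence for class c is

    L_c = ln[ pi_c J_c(ed, cc) / sum_{c' != c} pi_{c'} J_{c'}(ed, cc) ]

so L_c = 0 means class c is exactly as likely as all other classes
combined.  Three prior schemes are used — flat, the training-set class
frequencies, and an adaptive per-structure prior built from the
classifier's own high-confidence tallies — and the final call is a
consensus across them with a quality grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CLASSES, DEFAULT_CONFIG, TrainingConfig
from .scorespace import ScoreTriple

HIST_FLOOR = 1e-9


@dataclass
class ClassHistograms:
    """Per-class normalized ED and CC score histograms on shared edges."""

    edges: np.ndarray                 # (nbins+1,) shared bin edges
    ed_hist: dict                     # class -> (nbins,) normalized
    cc_hist: dict                     # class -> (nbins,) normalized

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        for h in (self.ed_hist, self.cc_hist):
            for c, v in h.items():
                v = np.asarray(v, dtype=float)
                # all-zero marks a class absent from training
                if v.sum() > 0 and abs(v.sum() - 1.0) > 1e-6:
                    raise ValueError(f"histogram for {c!r} is not normalized")
                h[c] = v

    def bin_index(self, value: float) -> int:
        i = int(np.searchsorted(self.edges, value, side="right")) - 1
        return int(np.clip(i, 0, len(self.edges) - 2))

    def joint(self, cls: str) -> np.ndarray:
        return build_joint(self.ed_hist[cls], self.cc_hist[cls])

    def to_dict(self) -> dict:
        return {
            "edges": self.edges.tolist(),
            "ed_hist": {c: v.tolist() for c, v in self.ed_hist.items()},
            "cc_hist": {c: v.tolist() for c, v in self.cc_hist.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassHistograms":
        return cls(edges=np.asarray(d["edges"]),
                   ed_hist={c: np.asarray(v) for c, v in d["ed_hist"].items()},
                   cc_hist={c: np.asarray(v) for c, v in d["cc_hist"].items()})


def build_joint(ed_hist: np.ndarray, cc_hist: np.ndarray) -> np.ndarray:
    """Outer-product joint distribution of two normalized 1D histograms."""
    ed_hist = np.asarray(ed_hist, dtype=float)
    cc_hist = np.asarray(cc_hist, dtype=float)
    for h in (ed_hist, cc_hist):
        if abs(h.sum() - 1.0) > 1e-6 or np.any(h < 0):
            raise ValueError("histograms must be normalized and non-negative")
    return np.outer(ed_hist, cc_hist)


@dataclass
class PriorSet:
    """The three prior schemes over the four solvent classes."""

    flat: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    training: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    adaptive: np.ndarray | None = None

    def __post_init__(self):
        for name in ("flat", "training"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(v.sum() - 1.0) > 1e-6 or np.any(v <= 0):
                raise ValueError(f"{name} prior must be positive and sum to 1")
            setattr(self, name, v)

    def schemes(self) -> dict:
        out = {"flat": self.flat, "training": self.training}
        out["adaptive"] = self.adaptive if self.adaptive is not None else self.training
        return out

    def to_dict(self) -> dict:
        return {"flat": self.flat.tolist(), "training": self.training.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSet":
        return cls(flat=np.asarray(d["flat"]), training=np.asarray(d["training"]))


@dataclass
class ClassificationResult:
    peak_id: str
    likelihoods: dict                  # scheme -> {class: L}
    predicted_class: str
    quality: str                       # strong | moderate | weak
    disposition: str = "classified"
    scores: ScoreTriple | None = None


def class_likelihoods(scores, hists: ClassHistograms, prior) -> dict:
    """Log-ratio L_c for each class at the (ed, cc) bin of the scores."""
    ed = scores.ed if isinstance(scores, ScoreTriple) else scores[0]
    cc = scores.cc if isinstance(scores, ScoreTriple) else scores[1]
    prior = np.asarray(prior, dtype=float)
    i, j = hists.bin_index(ed), hists.bin_index(cc)
    masses = np.array([
        max(hists.ed_hist[c][i] * hists.cc_hist[c][j], HIST_FLOOR) * prior[k]
        for k, c in enumerate(CLASSES)
    ])
    total = masses.sum()
    return {c: float(np.log(masses[k] / (total - masses[k])))
            for k, c in enumerate(CLASSES)}


def _argmax_class(L: dict) -> str:
    return max(CLASSES, key=lambda c: L[c])


def predict(scores: ScoreTriple, hists: ClassHistograms, priors: PriorSet,
            peak_id: str = "") -> ClassificationResult:
    """Consensus prediction across the three prior schemes.

    The final class is the majority of the per-scheme argmaxes (ties broken
    by the adaptive scheme).  Quality is strong when the schemes are
    unanimous and the evidence is decisive (max L >= 0.5), weak when the
    evidence is negative or the not-water probability contradicts the call,
    and moderate otherwise.
    """
    likelihoods = {name: class_likelihoods(scores, hists, pri)
                   for name, pri in priors.schemes().items()}
    votes = [_argmax_class(L) for L in likelihoods.values()]
    counts = {c: votes.count(c) for c in set(votes)}
    best = max(counts.values())
    leaders = [c for c, n in counts.items() if n == best]
    if len(leaders) == 1:
        cls = leaders[0]
    else:
        cls = _argmax_class(likelihoods["adaptive"])
    max_l = max(L[cls] for L in likelihoods.values())
    unanimous = len(set(votes)) == 1
    contradiction = False
    if scores.p_notwater is not None:
        if cls == "water" and scores.p_notwater > 0.95:
            contradiction = True
        if cls != "water" and scores.p_notwater < 0.05:
            contradiction = True
    if max_l < 0 or contradiction:
        quality = "weak"
    elif unanimous and max_l >= 0.5:
        quality = "strong"
    else:
        quality = "moderate"
    return ClassificationResult(peak_id=peak_id, likelihoods=likelihoods,
                                predicted_class=cls, quality=quality,
                                scores=scores)


def adaptive_prior(score_triples, hists: ClassHistograms, training_prior,
                   cfg: TrainingConfig = DEFAULT_CONFIG.training):
    """Iterated per-structure prior from high-confidence tallies.

    Starting flat, peaks are classified, classes with decisive evidence
    (max L >= threshold) are tallied, and the tally — smoothed by
    training-prior pseudo-counts — becomes the next prior, until the
    prediction multiset stops changing (<= 10 rounds).  Structures with too
    few peaks keep the training prior.
    """
    training_prior = np.asarray(training_prior, dtype=float)
    if len(score_triples) < cfg.adaptive_min_peaks:
        preds = [_argmax_class(class_likelihoods(s, hists, training_prior))
                 for s in score_triples]
        return training_prior.copy(), preds
    prior = np.full(4, 0.25)
    prev_preds = None
    for _ in range(10):
        Ls = [class_likelihoods(s, hists, prior) for s in score_triples]
        preds = [_argmax_class(L) for L in Ls]
        tally = np.zeros(4)
        for L, p in zip(Ls, preds):
            if L[p] >= cfg.adaptive_tally_threshold:
                tally[CLASSES.index(p)] += 1
        prior = tally + cfg.adaptive_pseudocount_weight * training_prior
        prior = prior / prior.sum()
        if prev_preds is not None and sorted(preds) == sorted(prev_preds):
            break
        prev_preds = preds
    return prior, preds
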