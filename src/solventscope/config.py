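"""Central configuration: feature names, solvent dictionaries and triage thresholds.

Every numeric threshold used by triage and clustering lives here so that a
single config object can be inspected, serialized, or overridden from the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: The 19 electron-density feature names, in canonical order.
ED_FEATURES = [f"CC{i}" for i in range(1, 15)] + [f"ED{i}" for i in range(1, 6)]
#: The two chemical-environment ("contact") feature names.
CC_FEATURES = ["CF1", "CF2"]
#: All 21 features in canonical order.
ALL_FEATURES = ED_FEATURES + CC_FEATURES

#: Solvent classes in canonical order.
CLASSES = ["water", "sulfate", "heterogen", "metal"]

# Residue-name dictionaries identifying solvent in input models.  The sulfate
# class deliberately merges sulfate and phosphate (chemically near-identical
# tetrahedral anions at typical map resolutions).
WATER_RESNAMES = {"HOH", "DOD"}
SULFATE_RESNAMES = {"SO4", "PO4"}
METAL_RESNAMES = {"MG", "CA", "ZN", "MN"}
HETEROGEN_RESNAMES = {"GOL", "EDO", "PEG", "PG4", "ACT", "CL", "BR", "NO3", "FMT"}
SOLVENT_RESNAMES = WATER_RESNAMES | SULFATE_RESNAMES | METAL_RESNAMES | HETEROGEN_RESNAMES

#: Atom-type vocabulary for the CF2 (sulfate-likeness) contact statistic.
CF2_VOCABULARY = [
    "guanidinium_amine_N",   # Arg NE/NH1/NH2, Lys NZ
    "imidazole_N",           # His ND1/NE2
    "backbone_N",
    "backbone_O",
    "carboxylate_O",         # Asp OD1/OD2, Glu OE1/OE2
    "hydroxyl_O",            # Ser OG, Thr OG1, Tyr OH
    "amide_NO",              # Asn OD1/ND2, Gln OE1/NE2
    "carbon",
    "other",
]

#: Trained resolution range (Å): peaks outside are flagged out-of-range.
RESOLUTION_RANGE = (0.6, 5.0)


@dataclass
class FeatureConfig:
    """Parameters of feature extraction."""

    probe_region_radius: float = 2.0    # Å around probe atoms used for RSCC
    model_b_equivalent: float = 20.0    # Å² isotropic B for the Gaussian probe atoms
    max_shift: float = 1.0              # Å bound on real-space-refinement translation
    refine_tol: float = 1e-5            # RSCC convergence tolerance
    refine_max_eval: int = 200
    ed3_contour: float = 3.0            # σ, Fo-Fc flood-fill contour
    ed4_contour: float = 1.0            # σ, 2Fo-Fc flood-fill contour
    volume_cap_radius: float = 5.0      # Å cap on flood fills
    cf2_contact_radius: float = 4.0     # Å
    cf1_max_search: float = 15.0        # Å; beyond this a peak is "isolated"


@dataclass
class TriageConfig:
    """Thresholds of the iterative triage loop (calibration constants)."""

    model_error_t_ed: float = 1.0
    model_error_t_cc: float = 0.0
    model_error_n_clash: int = 2
    clash_distance: float = 2.2         # Å
    cluster_edge_cutoff: float = 2.4    # Å
    cluster_sigma: float = 1.0          # Å, gaussian width of distance weight
    split_peak_distance: float = 0.9    # Å
    suspicious_cf1_threshold: float = 3.2  # Å
    suspicious_p_water: float = 0.9
    peak_threshold_sigma: float = 3.0   # σ, difference-map peak pick
    solvent_associate_cutoff: float = 2.0  # Å
    max_iterations: int = 10
    b_factor_floor: float = 10.0        # emitted-atom B = max(floor, 80/ED5)


@dataclass
class TrainingConfig:
    """Parameters of classifier training."""

    window_size: int = 20000            # rows per moving window (or n/10 if smaller)
    window_step: float = 0.5            # fraction of window_size
    min_window: int = 200
    jsu_subsample: int = 3000           # cap on values per Johnson-SU fit
    hist_bins: int = 40
    hist_range: tuple = (-6.0, 6.0)
    adaptive_min_peaks: int = 20
    adaptive_tally_threshold: float = 0.5
    adaptive_pseudocount_weight: float = 5.0
    dirichlet_alpha: float = 1.0


@dataclass
class Config:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = Config()
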