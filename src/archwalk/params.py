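"""Model parameters: foot geometry, ligaments, contact, reflex gains, cost weights.

All geometric quantities are stored in SI units internally (metres, kilograms,
radians); the configuration surface mirrors the published parameter tables in
their original units (cm, mm^2, MPa, degrees) and is converted exactly once on
load.  Parameters of the surrounding neuromusculoskeletal model (segments,
muscles, reflex architecture constants) that are not specific to the foot are
grouped in :data:`COMPANION`, one auditable block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import math

import yaml

CM = 1e-2
MM2 = 1e-6
MPA = 1e6
DEG = math.pi / 180.0

#: the six foot-model variants, from a flat rigid segment to the
#: windlass-coupled three-segment foot
FOOT_KINDS = ("1s-lA", "1s-hA", "2s-TJ", "2s-MTJ", "3s-nW", "3s-W")


def has_toe(kind: str) -> bool:
    """True for variants with a toe segment and toe joint."""
    return kind in ("2s-TJ", "3s-nW", "3s-W")


def has_mobile_arch(kind: str) -> bool:
    """True for variants with a midtarsal joint (mobile arch)."""
    return kind in ("2s-MTJ", "3s-nW", "3s-W")


def is_coupled(kind: str) -> bool:
    """True when toe and arch motion are coupled through the plantar fascia."""
    return kind == "3s-W"


def check_kind(kind: str) -> str:
    if kind not in FOOT_KINDS:
        raise ValueError(
            f"unknown foot model kind {kind!r}; expected one of {FOOT_KINDS}"
        )
    return kind


@dataclass
class LigamentParams:
    """Constitutive parameters of one plantar ligament (PF or PL).

    area_mm2 : cross-sectional area A (mm^2)
    k_mpa    : collagen stiffness k (MPa)
    d_s      : damping parameter d (s); multiplies the strain-ratio rate
    l0_cm    : resting length l0 (cm)
    alpha    : dimensionless constitutive exponent
    """

    area_mm2: float
    k_mpa: float
    d_s: float
    l0_cm: float
    alpha: float

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0 or self.k_mpa <= 0 or self.l0_cm <= 0 or self.alpha <= 0:
            raise ValueError("ligament parameters A, k, l0, alpha must be positive")
        if self.d_s < 0:
            raise ValueError("ligament damping d must be non-negative")

    # SI accessors
    @property
    def area(self) -> float:
        return self.area_mm2 * MM2

    @property
    def k(self) -> float:
        return self.k_mpa * MPA

    @property
    def l0(self) -> float:
        return self.l0_cm * CM

    @property
    def d(self) -> float:
        return self.d_s


def default_pf() -> LigamentParams:
    return LigamentParams(area_mm2=50.0, k_mpa=340.0, d_s=3.0, l0_cm=15.0, alpha=9.0)


def default_pl() -> LigamentParams:
    return LigamentParams(area_mm2=120.0, k_mpa=340.0, d_s=30.0, l0_cm=15.0, alpha=9.0)


@dataclass
class ContactParams:
    """Hunt-Crossley vertical contact and continuous friction parameters."""

    k_y: float = 78.3e3  # N/m
    v_max: float = 0.03  # m/s, maximum relaxation speed
    mu_d: float = 0.80
    mu_s: float = 0.90
    v_t: float = 0.01  # m/s, friction transition velocity

    def __post_init__(self) -> None:
        if self.mu_s < self.mu_d:
            raise ValueError("static friction coefficient must be >= dynamic")
        if min(self.k_y, self.v_max, self.v_t) <= 0:
            raise ValueError("k_y, v_max and v_t must be positive")


@dataclass
class FootGeometry:
    """Planar foot geometry in the hindfoot (ankle) frame A, centimetres.

    Vectors follow the published table: ``r_AM`` locates the midtarsal joint
    (origin of frame M), ``r_MT`` the toe joint (origin of frame T, expressed
    in M).  Contact-element centers are variant dependent: the flat low-arch
    foot has its sole at ankle height while all other variants carry the sole
    8 cm below the ankle.
    """

    r_AM: tuple[float, float] = (7.0, -1.4)
    r_MT: tuple[float, float] = (6.0, -4.6)
    r_A_CoM: tuple[float, float] = (5.0, -5.0)
    r_A_H: tuple[float, float] = (-2.0, -6.0)  # PL/PF heel attachment, frame A
    r_M_B: tuple[float, float] = (-2.0, -6.0)  # PL/PF ball attachment, frame M
    r_A_CH: tuple[float, float] = (-4.0, -3.0)
    r_A_CB: tuple[float, float] = (13.0, -2.27)
    r_A_CT: tuple[float, float] = (18.5, -8.0)
    R_H: float = 5.0
    R_B: float = 5.73
    R_T: float = 0.0
    R_PF: float = 1.0  # metatarsal-head wrap radius

    @property
    def l_arch_cm(self) -> float:
        dx = self.r_A_CB[0] - self.r_A_CH[0]
        dy = self.r_A_CB[1] - self.r_A_CH[1]
        return math.hypot(dx, dy)


def default_geometry(kind: str) -> FootGeometry:
    """Table geometry for one variant (low-arch foot has the sole at y=0)."""
    check_kind(kind)
    if kind == "1s-lA":
        return FootGeometry(
            r_A_CoM=(5.0, 3.0),
            r_A_CH=(-4.0, 5.0),
            r_A_CB=(13.0, 5.73),
            r_A_CT=(18.5, 0.0),
        )
    return FootGeometry()


@dataclass
class FootInertia:
    """Foot mass and inertia, identical for every variant.

    The forefoot and toe segments are (near-)massless so that all variants
    share the same inertial properties; ``light_mass_fraction`` sets their
    mass and inertia as a fraction of the hindfoot values.
    """

    m_foot: float = 1.160  # kg
    I_foot: float = 0.005  # kg m^2
    light_mass_fraction: float = 3e-2


@dataclass
class SimConfig:
    """Simulation settings.

    duration  : simulated time (s)
    rel_tol   : relative tolerance of the stiff (BDF) integrator
    max_step  : maximum internal step size (s)
    control_dt: reflex-controller sampling / delay-buffer interval (s)
    record_dt : trajectory recording interval (s)
    seed      : seed for the (small) random perturbation of the initial pose
    """

    duration: float = 15.0
    rel_tol: float = 1e-4
    max_step: float = 0.1
    control_dt: float = 1e-3
    record_dt: float = 1e-3
    seed: int = 0
    perturbation: float = 0.0
    fall_height_frac: float = 0.5
    fall_pitch_deg: float = 60.0


@dataclass
class CostWeights:
    """Multi-objective gait cost weights (defaults from the published table)."""

    w1: float = 5.35e2  # metabolic energy (W)
    w2: float = 1e3  # summed squared muscle activation (-)
    w3: float = 3.0  # |GRF rate| (N/s)
    w4: float = 1e4  # |HAT acceleration| (m/s^2)
    w5: float = 15.0  # |knee stop moment| (Nm)
    w6: float = 20.0  # |ankle stop moment| (Nm)
    w7: float = 1e5  # early-fall penalty (-)


#: reflex gain names in the published column order
GAIN_NAMES = (
    "k_phi",
    "G_HAMHFL",
    "G_GAS",
    "G_TA",
    "G_VAS",
    "G_SOLTA",
    "G_SOL",
    "G_HFL",
    "G_HAM",
    "G_GLU",
)

#: optimized gain columns per foot model (force-feedback gains for GAS, VAS,
#: SOLTA, SOL, HAM, GLU are normalized to the muscle's F_max)
GAIN_TABLE: dict[str, dict[str, float]] = {
    "1s-lA": dict(k_phi=2.02, G_HAMHFL=2.00, G_GAS=1.10, G_TA=1.23, G_VAS=1.24,
                  G_SOLTA=4.00e3, G_SOL=1.20, G_HFL=0.41, G_HAM=0.65, G_GLU=0.40),
    "1s-hA": dict(k_phi=2.94, G_HAMHFL=3.00, G_GAS=1.10, G_TA=1.10, G_VAS=1.15,
                  G_SOLTA=4.27, G_SOL=1.20, G_HFL=0.38, G_HAM=0.65, G_GLU=0.49),
    "2s-TJ": dict(k_phi=2.00, G_HAMHFL=4.00, G_GAS=1.09, G_TA=2.10, G_VAS=1.15,
                  G_SOLTA=1.22, G_SOL=1.20, G_HFL=0.35, G_HAM=0.65, G_GLU=0.46),
    "2s-MTJ": dict(k_phi=2.00, G_HAMHFL=3.50, G_GAS=1.10, G_TA=2.60, G_VAS=1.15,
                   G_SOLTA=0.73, G_SOL=1.20, G_HFL=0.29, G_HAM=0.65, G_GLU=0.40),
    "3s-nW": dict(k_phi=2.00, G_HAMHFL=3.51, G_GAS=1.10, G_TA=1.07, G_VAS=1.15,
                  G_SOLTA=0.30, G_SOL=1.20, G_HFL=0.35, G_HAM=0.65, G_GLU=0.40),
    "3s-W": dict(k_phi=2.00, G_HAMHFL=3.47, G_GAS=1.10, G_TA=1.10, G_VAS=1.15,
                 G_SOLTA=4.25e3, G_SOL=1.20, G_HFL=0.85, G_HAM=0.65, G_GLU=0.40),
}


@dataclass
class ReflexGains:
    """The ten optimized reflex-controller gains for one foot model."""

    k_phi: float = 2.0
    G_HAMHFL: float = 4.0
    G_GAS: float = 1.10
    G_TA: float = 1.10
    G_VAS: float = 1.15
    G_SOLTA: float = 0.30
    G_SOL: float = 1.20
    G_HFL: float = 0.35
    G_HAM: float = 0.65
    G_GLU: float = 0.40

    @classmethod
    def table(cls, kind: str) -> "ReflexGains":
        """Published optimized gain column for one variant."""
        return cls(**GAIN_TABLE[check_kind(kind)])

    def as_array(self):
        import numpy as np

        return np.array([getattr(self, n) for n in GAIN_NAMES])

    @classmethod
    def from_array(cls, arr) -> "ReflexGains":
        return cls(**{n: float(v) for n, v in zip(GAIN_NAMES, arr)})


# --------------------------------------------------------------------------
# companion-model defaults (segment, muscle and control-architecture
# parameters of the planar reflex-walking model the foot variants plug into)
# --------------------------------------------------------------------------

MUSCLES = ("SOL", "TA", "GAS", "VAS", "HAM", "GLU", "HFL")

COMPANION: dict = {
    "gravity": 9.81,
    "segments": {
        # mass kg, length m, CoM offset from proximal joint (m, along -y),
        # inertia about CoM (kg m^2)
        "HAT": {"m": 53.5, "l": 0.80, "d": -0.35, "I": 3.0},  # CoM above hip
        "thigh": {"m": 8.5, "l": 0.50, "d": 0.20, "I": 0.15},
        "shank": {"m": 3.5, "l": 0.50, "d": 0.20, "I": 0.05},
    },
    "muscles": {
        # F_max N, v_max l_opt/s, l_opt m, l_slack m
        "SOL": {"F_max": 4000.0, "v_max": 6.0, "l_opt": 0.04, "l_slack": 0.26},
        "TA": {"F_max": 800.0, "v_max": 12.0, "l_opt": 0.06, "l_slack": 0.24},
        "GAS": {"F_max": 1500.0, "v_max": 12.0, "l_opt": 0.05, "l_slack": 0.40},
        "VAS": {"F_max": 6000.0, "v_max": 12.0, "l_opt": 0.08, "l_slack": 0.23},
        "HAM": {"F_max": 3000.0, "v_max": 12.0, "l_opt": 0.10, "l_slack": 0.31},
        "GLU": {"F_max": 1500.0, "v_max": 12.0, "l_opt": 0.11, "l_slack": 0.13},
        "HFL": {"F_max": 2000.0, "v_max": 12.0, "l_opt": 0.11, "l_slack": 0.10},
    },
    "hill": {"w": 0.56, "c": math.log(0.05), "N": 1.5, "K": 5.0,
             "eps_ref": 0.04, "tau_act": 0.01},
    # attachment routing: joint, moment arm r0 (m), pennation-like scaling rho,
    # reference angles (deg); 'var' selects the angle-dependent arm
    # r(phi) = r0 cos(phi - phi_max); sign s: +1 if the MTU lengthens with
    # increasing joint angle phi
    "attachments": {
        "SOL": [{"joint": "ankle", "r0": 0.05, "phi_max": 110.0, "phi_ref": 80.0,
                 "rho": 0.5, "s": 1, "var": True}],
        "TA": [{"joint": "ankle", "r0": 0.04, "phi_max": 80.0, "phi_ref": 110.0,
                "rho": 0.7, "s": -1, "var": True}],
        "GAS": [{"joint": "ankle", "r0": 0.05, "phi_max": 110.0, "phi_ref": 80.0,
                 "rho": 0.7, "s": 1, "var": True},
                {"joint": "knee", "r0": 0.05, "phi_max": 140.0, "phi_ref": 165.0,
                 "rho": 0.7, "s": 1, "var": True}],
        "VAS": [{"joint": "knee", "r0": 0.06, "phi_max": 165.0, "phi_ref": 170.0,
                 "rho": 0.6, "s": -1, "var": True}],
        "HAM": [{"joint": "knee", "r0": 0.05, "phi_max": 180.0, "phi_ref": 180.0,
                 "rho": 0.7, "s": 1, "var": True},
                {"joint": "hip", "r0": 0.08, "phi_max": 0.0, "phi_ref": 155.0,
                 "rho": 0.7, "s": -1, "var": False}],
        "GLU": [{"joint": "hip", "r0": 0.10, "phi_max": 0.0, "phi_ref": 150.0,
                 "rho": 0.5, "s": -1, "var": False}],
        "HFL": [{"joint": "hip", "r0": 0.10, "phi_max": 0.0, "phi_ref": 180.0,
                 "rho": 0.5, "s": 1, "var": False}],
    },
    "control": {
        # resting stimuli
        "S0": {"SOL": 0.01, "TA": 0.01, "GAS": 0.01, "VAS": 0.09,
               "HAM": 0.05, "GLU": 0.05, "HFL": 0.05},
        # feedback delays (s): long (ankle), medium (knee), short (hip)
        "delay": {"SOL": 0.020, "TA": 0.020, "GAS": 0.020, "VAS": 0.010,
                  "HAM": 0.010, "GLU": 0.005, "HFL": 0.005},
        # length-feedback offsets, in l_opt
        "l_off": {"TA": 0.71, "HFL": 0.50, "HAM": 1.066},
        # trunk balance PD (per rad, per rad/s) and reference forward lean
        "theta_ref_deg": 5.75,
        "k_p": 6.43,
        "k_d": 0.30,
        # swing-onset lean feedforward on HFL; the swing target samples
        # lean + k_tdot * lean_rate at toe-off (velocity-informed placement)
        "k_lean": 4.64,
        "k_tdot": 0.05,
        # double-support inhibition of the trailing leg's VAS and
        # swing-preparation hip drive
        "k_ds": 3.92,
        "k_sp": 1.29,
        # leg loaded / unloaded thresholds (N)
        "contact_on": 20.0,
        "contact_off": 10.0,
        # knee-overextension protection reference (deg, biomech knee angle)
        "phi_knee_off_deg": 170.0,
    },
    "joint_stops": {
        # soft limits on the biomechanical angles (deg); stiffness Nm/rad,
        # damping Nm s/rad, engaged quadratically-smoothed beyond the limit
        "knee_max_deg": 175.0,
        "ankle_min_deg": 70.0,
        "ankle_max_deg": 130.0,
        "hip_max_deg": 230.0,
        "hip_min_deg": 100.0,
        "k_stop": 114.6,  # = 2 Nm/deg
        "d_stop": 11.46,  # = 0.2 Nm s/deg
    },
    "residual_joint": {
        # MTJ/TJ return spring-dampers (Nm/deg, Nm s/deg)
        "k_deg": 0.01,
        "d_deg": 0.001,
    },
    "metabolic": {
        # Margaria efficiencies for positive/negative fiber work, activation
        # maintenance heat coefficient (W per F_max*l_opt) and basal rate (W)
        "eta_pos": 0.25,
        "eta_neg": 1.20,
        "c_act": 0.01,
        "basal": 80.0,
    },
}


def total_body_mass(inertia: FootInertia | None = None) -> float:
    """Total model mass (kg): HAT + 2 x (thigh + shank + foot)."""
    inertia = inertia or FootInertia()
    seg = COMPANION["segments"]
    return seg["HAT"]["m"] + 2.0 * (seg["thigh"]["m"] + seg["shank"]["m"]
                                    + inertia.m_foot)


# --------------------------------------------------------------------------
# config file IO
# --------------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def variant_config(kind: str) -> dict:
    """Full structured configuration document for one foot-model variant."""
    check_kind(kind)
    geo = default_geometry(kind)
    doc = {
        "kind": kind,
        "geometry_cm": asdict(geo),
        "contact": asdict(ContactParams()),
        "ligaments": {"PF": asdict(default_pf()), "PL": asdict(default_pl())},
        "inertia": asdict(FootInertia()),
        "gains": GAIN_TABLE[kind],
    }
    return doc


def load_variant_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_bundled_configs(directory: str | Path | None = None) -> list[Path]:
    """Write the six canonical variant configs (mirrors the parameter table)."""
    directory = Path(directory or _DATA_DIR)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for kind in FOOT_KINDS:
        p = directory / f"foot_{kind.replace('-', '_')}.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(variant_config(kind), fh, sort_keys=False)
        paths.append(p)
    return paths


def geometry_from_config(doc: dict) -> FootGeometry:
    g = dict(doc["geometry_cm"])
    for k, v in list(g.items()):
        if isinstance(v, list):
            g[k] = tuple(v)
    return FootGeometry(**g)
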