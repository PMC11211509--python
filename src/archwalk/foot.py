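"""The six planar foot-model variants.

Nomenclature is ``#segments - feature``: 1s-lA (flat rigid, low arch),
1s-hA (rigid high arch), 2s-TJ (rigid arch + toe joint), 2s-MTJ (mobile
arch, no toe), 3s-nW (mobile arch + toe, decoupled), 3s-W (mobile arch +
toe coupled through the plantar fascia - the windlass model).

Frames: A is the hindfoot frame with its origin at the ankle, M the
forefoot/midfoot frame at the midtarsal joint (MTJ), T the toe frame at the
toe joint (TJ).  All internal lengths are SI (m); joint angles at the public
interface are degrees with the published conventions: ``phi_MTJ`` is a
clockwise rotation A->M (positive = arch plantarflexion/shortening) and
``phi_TJ`` a counter-clockwise rotation M->T (positive = toe dorsiflexion).

The plantar-fascia path length is variant specific:

  2s-MTJ : chord between the heel and ball attachments
  2s-TJ  : l0 + phi_TJ * R_PF (wrap around the metatarsal head)
  3s-nW  : the pair (chord ; l0 + phi_TJ * R_PF), evaluated independently
  3s-W   : chord + phi_TJ * R_PF (single coupled path)

Strain is referenced to the neutral pose: lam = 1 + (l - l_neutral)/l0 with
the tabulated resting length l0 as denominator, so that strain is exactly
zero in the neutral pose for every variant and the strain produced by a
given elongation is identical across variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import (
    CM,
    DEG,
    FOOT_KINDS,
    ContactParams,
    FootGeometry,
    FootInertia,
    LigamentParams,
    check_kind,
    default_geometry,
    default_pf,
    default_pl,
    has_mobile_arch,
    has_toe,
    is_coupled,
)

#: residual MTJ/TJ return spring-damper (converted from 0.01 Nm/deg, 0.001 Nm s/deg)
RESIDUAL_K = 0.01 / DEG  # Nm/rad
RESIDUAL_D = 0.001 / DEG  # Nm s/rad


@dataclass
class FootJointState:
    """Internal foot joint angles (deg) and rates (deg/s)."""

    phi_MTJ: float = 0.0
    phi_TJ: float = 0.0
    phi_MTJ_dot: float = 0.0
    phi_TJ_dot: float = 0.0


def _rot(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


@dataclass
class ContactElementDef:
    """A circular contact element attached to one foot segment."""

    name: str  # 'C_H', 'C_B', 'C_T'
    segment: str  # 'A', 'M' or 'T'
    center: np.ndarray  # position in the parent segment frame (m)
    radius: float  # m


@dataclass
class FootModel:
    """Assembled foot-model variant: segments, joints, ligaments, contacts."""

    kind: str
    geometry: FootGeometry
    inertia: FootInertia
    segments: tuple[str, ...]
    joints: tuple[str, ...]
    ligaments: tuple[str, ...]
    contacts: list[ContactElementDef]
    pf: LigamentParams = field(default_factory=default_pf)
    pl: LigamentParams = field(default_factory=default_pl)

    # anchor of M in A and of T in its parent (m)
    r_AM: np.ndarray = field(default=None)
    r_toe_anchor: np.ndarray = field(default=None)
    toe_parent: str = "M"

    # ligament attachments (m): heel attachment in A, ball attachment in the
    # frame named by ball_frame ('M' for mobile arches, 'A' otherwise)
    att_H: np.ndarray = field(default=None)
    att_B: np.ndarray = field(default=None)
    ball_frame: str = "M"

    R_PF: float = 0.01
    chord_neutral: float = 0.0

    @property
    def has_toe(self) -> bool:
        return has_toe(self.kind)

    @property
    def has_mobile_arch(self) -> bool:
        return has_mobile_arch(self.kind)

    @property
    def is_coupled(self) -> bool:
        return is_coupled(self.kind)

    # -- geometry ---------------------------------------------------------

    def ball_attachment_in_A(self, q_mtj_rad: float) -> np.ndarray:
        """World (A-frame) position of the PL/PF ball attachment."""
        if self.ball_frame == "A":
            return self.att_B
        return self.r_AM + _rot(q_mtj_rad) @ self.att_B

    def chord_length(self, q_mtj_rad: float) -> float:
        """Heel-to-ball attachment chord length (m)."""
        return float(np.linalg.norm(self.ball_attachment_in_A(q_mtj_rad) - self.att_H))


def build_foot(
    kind: str,
    geometry: FootGeometry | None = None,
    inertia: FootInertia | None = None,
    pf: LigamentParams | None = None,
    pl: LigamentParams | None = None,
) -> FootModel:
    """Assemble one of the six foot-model variants.

    Raises ``ValueError`` for an unknown kind or when the geometry violates
    the l_arch = 17 cm invariant by more than 1 mm.
    """
    check_kind(kind)
    geometry = geometry or default_geometry(kind)
    inertia = inertia or FootInertia()
    pf = pf or default_pf()
    pl = pl or default_pl()

    if abs(geometry.l_arch_cm - 17.0) > 0.1 + 1e-12:
        # the published geometry gives 17.016 cm; 1 mm is the hard bound
        raise ValueError(
            f"heel-ball contact spacing {geometry.l_arch_cm:.3f} cm violates "
            "the 17 cm arch-length invariant by more than 1 mm"
        )

    toe = has_toe(kind)
    arch = has_mobile_arch(kind)

    segments = ["A"]
    joints: list[str] = []
    if arch:
        segments.append("M")
        joints.append("MTJ")
    if toe:
        segments.append("T")
        joints.append("TJ")

    ligs: list[str] = []
    if arch:
        ligs.append("PL")
    if arch or toe:
        ligs.append("PF")

    g = geometry
    r_AM = np.array(g.r_AM) * CM
    r_MT = np.array(g.r_MT) * CM
    r_A_TJ = r_AM + r_MT

    contacts = [
        ContactElementDef("C_H", "A", np.array(g.r_A_CH) * CM, g.R_H * CM)
    ]
    if toe:
        # ball element rides on the toe segment so forefoot-toe relative
        # motion does not rotate it
        contacts.append(
            ContactElementDef("C_B", "T", np.array(g.r_A_CB) * CM - r_A_TJ, g.R_B * CM)
        )
        contacts.append(
            ContactElementDef("C_T", "T", np.array(g.r_A_CT) * CM - r_A_TJ, g.R_T * CM)
        )
    elif arch:
        contacts.append(
            ContactElementDef("C_B", "M", np.array(g.r_A_CB) * CM - r_AM, g.R_B * CM)
        )
    else:
        contacts.append(ContactElementDef("C_B", "A", np.array(g.r_A_CB) * CM, g.R_B * CM))

    model = FootModel(
        kind=kind,
        geometry=geometry,
        inertia=inertia,
        segments=tuple(segments),
        joints=tuple(joints),
        ligaments=tuple(ligs),
        contacts=contacts,
        pf=pf,
        pl=pl,
        r_AM=r_AM,
        r_toe_anchor=(r_MT if arch else r_A_TJ) if toe else None,
        toe_parent="M" if arch else "A",
        att_H=np.array(g.r_A_H) * CM,
        att_B=np.array(g.r_M_B) * CM if arch else r_AM + np.array(g.r_M_B) * CM,
        ball_frame="M" if arch else "A",
        R_PF=g.R_PF * CM,
    )
    model.chord_neutral = model.chord_length(0.0)
    return model


# --------------------------------------------------------------------------
# path lengths and generalized forces
# --------------------------------------------------------------------------


def ligament_path_lengths(model: FootModel, state: FootJointState) -> dict[str, float]:
    """Ligament path lengths (m) for the given joint state.

    Returns a dict with key ``l_PL`` (mobile arches) and, depending on the
    variant, ``l_PF`` or the decoupled pair ``l_PF_1``/``l_PF_2``.
    """
    if not model.has_toe and state.phi_TJ:
        raise ValueError(f"{model.kind} has no toe joint; phi_TJ must be zero")
    if not model.has_mobile_arch and state.phi_MTJ:
        raise ValueError(f"{model.kind} has a rigid arch; phi_MTJ must be zero")

    q_mtj = -state.phi_MTJ * DEG  # clockwise convention -> CCW rotation
    phi_tj = state.phi_TJ * DEG
    out: dict[str, float] = {}
    l0_pf = model.pf.l0

    if model.has_mobile_arch:
        chord = model.chord_length(q_mtj)
        out["l_PL"] = chord
    else:
        chord = model.chord_neutral

    kind = model.kind
    if kind == "2s-MTJ":
        out["l_PF"] = chord
    elif kind == "2s-TJ":
        out["l_PF"] = l0_pf + phi_tj * model.R_PF
    elif kind == "3s-nW":
        out["l_PF_1"] = chord
        out["l_PF_2"] = l0_pf + phi_tj * model.R_PF
    elif kind == "3s-W":
        out["l_PF"] = chord + phi_tj * model.R_PF
    # rigid variants: no PF
    for v in out.values():
        if v < 0:
            raise ValueError("negative ligament path length: internal geometry error")
    return out


@dataclass
class LigamentForces:
    """Generalized foot-internal forces from the ligament tensions.

    ``M_TJ`` (Nm) opposes toe dorsiflexion (it is the negative generalized
    torque on the CCW toe coordinate).  The chord tension acts as an
    equal-and-opposite force pair along the heel-ball attachment chord:
    ``f_on_A`` at the heel attachment and ``f_on_M = -f_on_A`` at the ball
    attachment (A-frame components).
    """

    M_TJ: float = 0.0
    f_on_A: np.ndarray = field(default_factory=lambda: np.zeros(2))
    f_on_M: np.ndarray = field(default_factory=lambda: np.zeros(2))
    chord_tension: float = 0.0


def ligament_generalized_forces(
    model: FootModel,
    F_PL: float = 0.0,
    F_PF_chord: float = 0.0,
    F_PF_toe: float = 0.0,
    state: FootJointState | None = None,
) -> LigamentForces:
    """Map ligament tensions (N, >= 0) to joint moment and attachment forces.

    ``F_PF_chord`` acts along the arch chord (from l_PF or l_PF_1);
    ``F_PF_toe`` makes the toe-joint moment M_TJ = F * R_PF (from l_PF or
    l_PF_2).  For the coupled model one PF tension drives both.
    """
    for f in (F_PL, F_PF_chord, F_PF_toe):
        if f < 0:
            raise ValueError("ligament tensions must be >= 0")
    state = state or FootJointState()
    q_mtj = -state.phi_MTJ * DEG
    out = LigamentForces()
    out.M_TJ = F_PF_toe * model.R_PF

    chord_force = F_PL + F_PF_chord
    if chord_force > 0.0 and model.has_mobile_arch:
        b = model.ball_attachment_in_A(q_mtj)
        u = b - model.att_H
        n = np.linalg.norm(u)
        if n <= 0:
            raise ValueError("degenerate ligament chord")
        u = u / n
        # tension pulls the heel attachment towards the ball and vice versa
        out.f_on_A = chord_force * u
        out.f_on_M = -chord_force * u
        out.chord_tension = chord_force
    return out


def residual_joint_torque(phi_deg: float, phi_dot_deg: float) -> float:
    """Linear MTJ/TJ return spring-damper torque (Nm), restoring to neutral.

    tau = -k*phi - d*phi_dot with k = 0.01 Nm/deg and d = 0.001 Nm s/deg.
    """
    return -0.01 * phi_deg - 0.001 * phi_dot_deg
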