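"""Assembly of the full planar walking model for one foot variant.

Packs the 7-to-11-body kinematic tree (trunk, two legs, variant-dependent
foot segments), the 14 Hill-type muscles and all contact/ligament parameters
into the flat array tuple consumed by the numba core, and provides the
initial standing state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _core
from .foot import FootModel, build_foot
from .params import (
    COMPANION,
    DEG,
    ContactParams,
    FootInertia,
    MUSCLES,
    SimConfig,
    total_body_mass,
)

#: per-leg observation channels, in block order (prefixed L_/R_)
LEG_CHANNELS = (
    "grf_v", "grf_h",
    "Fv_H", "Fv_B", "Fv_T",
    "Fh_H", "Fh_B", "Fh_T",
    "px_H", "px_B", "px_T",
    "pow_H", "pow_B", "pow_T",
    "pf_pow", "pl_pow", "pf_lam", "pl_lam", "pf_Fc", "pf_Ft", "pl_F",
    "tau_ank", "phi_ank", "phid_ank",
    "Tstop_knee", "Tstop_ank",
    "q_mtj", "q_tj", "qd_mtj", "qd_tj",
    "phi_hip", "phi_knee",
)

GLOBAL_CHANNELS = (
    "pitch", "pitch_rate", "hat_vx", "hat_vy", "hat_ax", "hat_ay",
    "met_rate", "act2", "hat_x", "hat_y",
)

CHANNELS = GLOBAL_CHANNELS + tuple("L_" + c for c in LEG_CHANNELS) + tuple(
    "R_" + c for c in LEG_CHANNELS
)

_JOINT_CODE = {"hip": 0, "knee": 1, "ankle": 2}


@dataclass
class CompiledModel:
    """A walking model compiled to the flat arrays used by the numba core."""

    foot: FootModel
    P: tuple
    nb: int
    n: int
    nm: int
    leg_bodies: np.ndarray
    total_mass: float
    standing_hat_height: float
    muscle_names: tuple[str, ...] = field(default_factory=tuple)
    S0: np.ndarray = None
    delays: np.ndarray = None
    F_max: np.ndarray = None
    l_opt: np.ndarray = None

    @property
    def kind(self) -> str:
        return self.foot.kind

    @property
    def nstate(self) -> int:
        return 2 * self.n + 2 * self.nm

    def muscle_index(self, leg: int, name: str) -> int:
        return leg * 7 + MUSCLES.index(name)


def build_compiled(
    kind_or_model: str | FootModel,
    contact: ContactParams | None = None,
    companion: dict | None = None,
) -> CompiledModel:
    """Build the full-body model around one foot variant."""
    foot = (kind_or_model if isinstance(kind_or_model, FootModel)
            else build_foot(kind_or_model))
    comp = companion or COMPANION
    contact = contact or ContactParams()
    seg = comp["segments"]
    inertia = foot.inertia
    g = foot.geometry

    arch = foot.has_mobile_arch
    toe = foot.has_toe
    extra = (1 if arch else 0) + (1 if toe else 0)
    per_leg = 3 + extra
    nb = 1 + 2 * per_leg
    n = nb + 2

    parent = np.zeros(nb, np.int64)
    anchor = np.zeros((nb, 2))
    com = np.zeros((nb, 2))
    mass = np.zeros(nb)
    iner = np.zeros(nb)

    com[0] = (0.0, abs(seg["HAT"]["d"]))  # HAT CoM above the hip
    mass[0] = seg["HAT"]["m"]
    iner[0] = seg["HAT"]["I"]

    frac = inertia.light_mass_fraction
    leg_bodies = -np.ones((2, 5), np.int64)
    for leg in range(2):
        b0 = 1 + leg * per_leg
        thigh, shank, ft = b0, b0 + 1, b0 + 2
        parent[thigh] = 0
        anchor[thigh] = (0.0, 0.0)
        com[thigh] = (0.0, -seg["thigh"]["d"])
        mass[thigh] = seg["thigh"]["m"]
        iner[thigh] = seg["thigh"]["I"]
        parent[shank] = thigh
        anchor[shank] = (0.0, -seg["thigh"]["l"])
        com[shank] = (0.0, -seg["shank"]["d"])
        mass[shank] = seg["shank"]["m"]
        iner[shank] = seg["shank"]["I"]
        parent[ft] = shank
        anchor[ft] = (0.0, -seg["shank"]["l"])
        com[ft] = np.array(g.r_A_CoM) * 1e-2
        mass[ft] = inertia.m_foot
        iner[ft] = inertia.I_foot
        leg_bodies[leg, 0:3] = (thigh, shank, ft)
        nxt = ft + 1
        if arch:
            parent[nxt] = ft
            anchor[nxt] = foot.r_AM
            com[nxt] = (0.03, -0.03)
            mass[nxt] = frac * inertia.m_foot
            iner[nxt] = frac * inertia.I_foot
            leg_bodies[leg, 3] = nxt
            nxt += 1
        if toe:
            parent[nxt] = leg_bodies[leg, 3] if arch else ft
            anchor[nxt] = foot.r_toe_anchor
            com[nxt] = (0.02, -0.01)
            mass[nxt] = frac * inertia.m_foot
            iner[nxt] = frac * inertia.I_foot
            leg_bodies[leg, 4] = nxt

    # contact elements, per leg in (heel, ball, toe) order
    seg_map = {}
    ce_body, ce_loc, ce_R, ce_leg = [], [], [], []
    for leg in range(2):
        seg_map = {"A": leg_bodies[leg, 2], "M": leg_bodies[leg, 3],
                   "T": leg_bodies[leg, 4]}
        for ce in foot.contacts:
            ce_body.append(seg_map[ce.segment])
            ce_loc.append(ce.center)
            ce_R.append(ce.radius)
            ce_leg.append(leg)
    ce_body = np.array(ce_body, np.int64)
    ce_loc = np.array(ce_loc, float)
    ce_R = np.array(ce_R, float)
    ce_leg = np.array(ce_leg, np.int64)

    cpar = np.array([contact.k_y, contact.v_max, contact.mu_d, contact.mu_s,
                     contact.v_t])

    foot_flags = np.array(
        [1 if toe else 0, 1 if arch else 0, 1 if foot.is_coupled else 0],
        np.int64,
    )
    lig_geo = np.array([
        foot.att_H[0], foot.att_H[1], foot.att_B[0], foot.att_B[1],
        foot.r_AM[0], foot.r_AM[1], foot.chord_neutral, foot.R_PF,
        1.0 if foot.ball_frame == "M" else 0.0,
    ])
    lig_par = np.array([
        [foot.pf.area, foot.pf.k, foot.pf.d, foot.pf.l0, foot.pf.alpha],
        [foot.pl.area, foot.pl.k, foot.pl.d, foot.pl.l0, foot.pl.alpha],
    ])

    # muscles
    nm = 14
    mus = comp["muscles"]
    att = comp["attachments"]
    ctrl = comp["control"]
    mus_par = np.zeros((nm, 4))
    att_n = np.zeros(nm, np.int64)
    att_qidx = np.zeros((nm, 2), np.int64)
    att_jt = np.zeros((nm, 2), np.int64)
    att_r0 = np.zeros((nm, 2))
    att_phimax = np.zeros((nm, 2))
    att_phiref = np.zeros((nm, 2))
    att_rho = np.zeros((nm, 2))
    att_sgn = np.zeros((nm, 2))
    att_var = np.zeros((nm, 2), np.int64)
    S0 = np.zeros(nm)
    delays = np.zeros(nm)
    joint_q = lambda leg, jn: {"hip": leg_bodies[leg, 0],
                               "knee": leg_bodies[leg, 1],
                               "ankle": leg_bodies[leg, 2]}[jn] + 2
    for leg in range(2):
        for mi, name in enumerate(MUSCLES):
            m = leg * 7 + mi
            p = mus[name]
            mus_par[m] = (p["F_max"], p["v_max"], p["l_opt"], p["l_slack"])
            paths = att[name]
            att_n[m] = len(paths)
            for pi, pa in enumerate(paths):
                att_qidx[m, pi] = joint_q(leg, pa["joint"])
                att_jt[m, pi] = _JOINT_CODE[pa["joint"]]
                att_r0[m, pi] = pa["r0"]
                att_phimax[m, pi] = pa["phi_max"] * DEG
                att_phiref[m, pi] = pa["phi_ref"] * DEG
                att_rho[m, pi] = pa["rho"]
                att_sgn[m, pi] = float(pa["s"])
                att_var[m, pi] = 1 if pa["var"] else 0
            S0[m] = ctrl["S0"][name]
            delays[m] = ctrl["delay"][name]

    h = comp["hill"]
    met = comp["metabolic"]
    hill = np.array([h["w"], h["c"], h["N"], h["K"], h["eps_ref"],
                     h["tau_act"], met["eta_pos"], met["eta_neg"],
                     met["c_act"]])
    st = comp["joint_stops"]
    stops = np.array([st["knee_max_deg"] * DEG, st["ankle_min_deg"] * DEG,
                      st["ankle_max_deg"] * DEG, st["hip_max_deg"] * DEG,
                      st["hip_min_deg"] * DEG, st["k_stop"], st["d_stop"]])
    rj = comp["residual_joint"]
    resid = np.array([rj["k_deg"] / DEG, rj["d_deg"] / DEG])

    P = (parent, anchor, com, mass, iner, float(comp["gravity"]),
         ce_body, ce_loc, ce_R, ce_leg, cpar,
         leg_bodies, foot_flags, lig_geo, lig_par,
         mus_par, att_n, att_qidx, att_jt, att_r0, att_phimax, att_phiref,
         att_rho, att_sgn, att_var, hill, stops, resid,
         float(met["basal"]))

    # standing HAT CoM height: hip above the ground sole
    hip_h = seg["thigh"]["l"] + seg["shank"]["l"] + _sole_below_ankle(foot)
    cm = CompiledModel(
        foot=foot, P=P, nb=nb, n=n, nm=nm, leg_bodies=leg_bodies,
        total_mass=float(mass.sum()),
        standing_hat_height=hip_h + abs(seg["HAT"]["d"]),
        muscle_names=tuple(f"{'LR'[leg]}_{m}" for leg in range(2)
                           for m in MUSCLES),
        S0=S0, delays=delays,
        F_max=mus_par[:, 0].copy(), l_opt=mus_par[:, 2].copy(),
    )
    return cm


def _sole_below_ankle(foot: FootModel) -> float:
    """Height of the ankle above the sole plane at neutral pose (m)."""
    g = foot.geometry
    return -(g.r_A_CH[1] - g.R_H) * 1e-2


# --------------------------------------------------------------------------
# initial state
# --------------------------------------------------------------------------

#: standing-start pose per variant; biomechanical angles in degrees
#: (hip/knee/ankle of the leading and trailing leg), forward trunk lean,
#: initial forward speed and initial sole penetration
DEFAULT_POSE: dict[str, dict] = {
    "1s-lA": dict(lean=4.696031917413065, vx=1.1874737625813123, pen=0.0047511823022700446,
        lead=dict(hip=170.68583256425825, knee=172.69087281256907, ankle=96.84559441428495,
                  hip_rate=0.0, knee_rate=0.0),
        trail=dict(hip=145.3575702976562, knee=107.03904149586849, ankle=97.99885946359701,
                   hip_rate=2.3989556212521657, knee_rate=2.7116231672079967)),
    "1s-hA": dict(lean=4.0, vx=1.161, pen=0.007,
        lead=dict(hip=173.4, knee=176.6, ankle=93.0,
                  hip_rate=0.0, knee_rate=0.0),
        trail=dict(hip=148.0, knee=135.0, ankle=90.0,
                   hip_rate=2.25, knee_rate=3.39)),
    "2s-TJ": dict(lean=3.447891521594722, vx=1.2812792263021977, pen=0.005921151506553171,
        lead=dict(hip=169.37115045157154, knee=175.86786381606404, ankle=89.38149149013573,
                  hip_rate=0.0, knee_rate=0.0),
        trail=dict(hip=147.31154362044862, knee=131.6034109657767, ankle=88.33047150245305,
                   hip_rate=1.8744331749773342, knee_rate=3.137327031498007)),
    "2s-MTJ": dict(lean=6.333100968361672, vx=1.3115623566386383, pen=0.005086107869621878,
        lead=dict(hip=171.12525239208392, knee=172.3988439746184, ankle=93.9059028668854,
                  hip_rate=0.0, knee_rate=0.0),
        trail=dict(hip=146.70918713033006, knee=112.9936844868809, ankle=92.25166263199554,
                   hip_rate=3.0, knee_rate=2.20962565307792)),
    "3s-nW": dict(lean=7.248320569168106, vx=1.3076632976036748, pen=0.004,
        lead=dict(hip=170.43275573705986, knee=175.50037104847087, ankle=93.68323182966945,
                  hip_rate=0.0, knee_rate=0.0),
        trail=dict(hip=151.37084394996634, knee=114.20131083877708, ankle=87.65599715465372,
                   hip_rate=3.0, knee_rate=2.8029909761737692)),
    "3s-W": dict(lean=7.643117102460438, vx=1.123896161840127, pen=0.004,
        lead=dict(hip=171.40659953353696, knee=174.61308730672053, ankle=94.76489393112679,
                  hip_rate=0.0, knee_rate=0.0),
        trail=dict(hip=153.79366587114362, knee=113.61134714652019, ankle=88.40784700076527,
                   hip_rate=3.0, knee_rate=2.7291690992841797)),
}


def initial_state(cm: CompiledModel, pose: dict | None = None,
                  config: SimConfig | None = None) -> np.ndarray:
    """Initial full state: standing posture with a forward push.

    The leading (stance) leg is the right leg so the analyzed left leg has
    settled strides behind it by the end of the run.  A small seeded
    perturbation can be applied through ``config.perturbation``.
    """
    config = config or SimConfig()
    pose = pose or DEFAULT_POSE[cm.kind]
    n = cm.n
    q = np.zeros(n)
    qd = np.zeros(n)
    q[2] = -pose["lean"] * DEG

    for leg, key in ((1, "lead"), (0, "trail")):
        ang = pose[key]
        thigh, shank, ft = cm.leg_bodies[leg, 0:3]
        q[thigh + 2] = math.pi - ang["hip"] * DEG
        q[shank + 2] = ang["knee"] * DEG - math.pi
        q[ft + 2] = ang["ankle"] * DEG - math.pi / 2
        qd[thigh + 2] = ang.get("hip_rate", 0.0)
        qd[shank + 2] = ang.get("knee_rate", 0.0)

    if config.perturbation:
        rng = np.random.default_rng(config.seed)
        q[2:] += config.perturbation * DEG * rng.standard_normal(n - 2)

    # drop the trunk so the deepest contact point penetrates by `pen`
    q[1] = 1.2
    parent, anchor = cm.P[0], cm.P[1]
    th, om, o, vo = _core._fk(q, qd, parent, anchor)
    low = np.inf
    ce_body, ce_loc, ce_R = cm.P[6], cm.P[7], cm.P[8]
    for e in range(len(ce_body)):
        b = ce_body[e]
        c, s = math.cos(th[b]), math.sin(th[b])
        cy = o[b, 1] + s * ce_loc[e, 0] + c * ce_loc[e, 1]
        low = min(low, cy - ce_R[e])
    q[1] += -low - pose["pen"]

    qd[0] = pose["vx"]

    # muscle states: resting activation, CE length at zero tendon strain
    act = cm.S0.copy()
    mus_par = cm.P[15]
    lmtu = mtu_lengths(cm, q)
    lce = np.empty(cm.nm)
    for m in range(cm.nm):
        l_opt, l_slack = mus_par[m, 2], mus_par[m, 3]
        lce[m] = min(max(lmtu[m] - l_slack, 0.5 * l_opt), 1.4 * l_opt)
    return np.concatenate([q, qd, act, lce])


def mtu_lengths(cm: CompiledModel, q: np.ndarray) -> np.ndarray:
    """Muscle-tendon unit lengths at pose q (m)."""
    mus_par = cm.P[15]
    att_n, att_qidx, att_jt = cm.P[16], cm.P[17], cm.P[18]
    att_r0, att_phimax, att_phiref = cm.P[19], cm.P[20], cm.P[21]
    att_rho, att_sgn, att_var = cm.P[22], cm.P[23], cm.P[24]
    out = np.zeros(cm.nm)
    for m in range(cm.nm):
        l = mus_par[m, 2] + mus_par[m, 3]
        for p in range(att_n[m]):
            qi = att_qidx[m, p]
            jt = att_jt[m, p]
            if jt == 0:
                phi = math.pi - q[qi]
            elif jt == 1:
                phi = math.pi + q[qi]
            else:
                phi = math.pi / 2 + q[qi]
            if att_var[m, p]:
                l += att_sgn[m, p] * att_rho[m, p] * att_r0[m, p] * (
                    math.sin(phi - att_phimax[m, p])
                    - math.sin(att_phiref[m, p] - att_phimax[m, p]))
            else:
                l += att_sgn[m, p] * att_rho[m, p] * att_r0[m, p] * (
                    phi - att_phiref[m, p])
        out[m] = l
    return out
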