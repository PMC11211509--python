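"""Virtual quasi-static compression test bench for the isolated foot.

Emulates an in-vivo arch-compression protocol: the foot stands on the
ground with heel and ball supported, a vertical load ramp is applied at the
ankle, and the static equilibrium (vertical penetration, foot pitch, MTJ
and TJ angles) is solved at each load level.  Horizontal pinning of the
contact points by static friction is modelled with stiff horizontal springs
anchored at the unloaded contact positions.

Used to calibrate the plantar-ligament cross-sectional area A_PL against
arch-compression/MTJ-angle targets; this module is an independent
pure-numpy path through the foot mechanics (the walking simulator uses the
compiled core), which makes it a useful cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .foot import FootModel, build_foot, RESIDUAL_K, RESIDUAL_D  # noqa: F401
from .ligament import ligament_force
from .params import ContactParams, LigamentParams, default_pl, has_mobile_arch


@dataclass
class TestBenchResult:
    """Static response of one foot model under a vertical ankle load ramp."""

    load: np.ndarray  # N
    compression: np.ndarray  # ankle drop (mm)
    mtj_angle: np.ndarray  # arch-flattening MTJ angle (deg)
    tj_angle: np.ndarray  # toe-joint angle (deg), zero for toeless feet
    converged: np.ndarray  # per-level solver success
    residual: np.ndarray  # final residual norm per level


class _StaticFoot:
    """Generalized-force evaluator for the isolated foot."""

    def __init__(self, foot: FootModel, contact: ContactParams):
        self.foot = foot
        self.kp = contact.k_y
        self.has_arch = foot.has_mobile_arch
        self.has_toe = foot.has_toe
        self.nq = 2 + (1 if self.has_arch else 0) + (1 if self.has_toe else 0)
        # anchor x of each contact point at the neutral pose
        self.x0 = [self._contact_world(np.zeros(self.nq), i)[0][0]
                   for i in range(len(foot.contacts))]

    # u = [y, th, (q_mtj), (q_tj)] ; x is pinned at 0
    def _frames(self, u):
        foot = self.foot
        y, th = u[0], u[1]
        qm = u[2] if self.has_arch else 0.0
        qt = u[-1] if self.has_toe else 0.0
        A = (np.array([0.0, y]), th)
        frames = {"A": A}
        if self.has_arch:
            oM = A[0] + _rot(th) @ foot.r_AM
            frames["M"] = (oM, th + qm)
        if self.has_toe:
            parent = frames["M" if foot.toe_parent == "M" else "A"]
            oT = parent[0] + _rot(parent[1]) @ foot.r_toe_anchor
            frames["T"] = (oT, parent[1] + qt)
        return frames

    def _contact_world(self, u, i):
        ce = self.foot.contacts[i]
        o, th = self._frames(u)[ce.segment]
        c = o + _rot(th) @ ce.center
        return (c[0], c[1] - ce.radius), ce

    def _point_jac(self, u, fn, h=1e-7):
        """d(point)/du by central differences; fn(u) -> (x, y)."""
        J = np.zeros((2, self.nq))
        for j in range(self.nq):
            up = u.copy(); up[j] += h
            um = u.copy(); um[j] -= h
            pp = np.array(fn(up))
            pm = np.array(fn(um))
            J[:, j] = (pp - pm) / (2 * h)
        return J

    def residual(self, u, load):
        """Generalized static force residual [Q_y, Q_th, (Q_mtj), (Q_tj)]."""
        foot = self.foot
        Q = np.zeros(self.nq)
        Q[0] -= load  # vertical ankle load
        Q[0] -= foot.inertia.m_foot * 9.81

        # contacts: vertical penalty + horizontal pinning spring
        for i in range(len(foot.contacts)):
            (px, py), _ = self._contact_world(u, i)
            f = np.zeros(2)
            if py < 0.0:
                f[1] = -self.kp * py
                f[0] = -self.kp * (px - self.x0[i])
            if f.any():
                J = self._point_jac(u, lambda uu: self._contact_world(uu, i)[0])
                Q += J.T @ f

        # ligaments
        qm = u[2] if self.has_arch else 0.0
        qt = u[-1] if self.has_toe else 0.0
        dl_ch = foot.chord_length(qm) - foot.chord_neutral if self.has_arch else 0.0
        arc = qt * foot.R_PF
        l0 = foot.pf.l0
        if foot.is_coupled:
            F = ligament_force(1.0 + (dl_ch + arc) / l0, 0.0, foot.pf)
            Fc, Ft = F, F
        elif self.has_toe and self.has_arch:
            Fc = ligament_force(1.0 + dl_ch / l0, 0.0, foot.pf)
            Ft = ligament_force(1.0 + arc / l0, 0.0, foot.pf)
        elif self.has_toe:
            Fc, Ft = 0.0, ligament_force(1.0 + arc / l0, 0.0, foot.pf)
        else:
            Fc, Ft = ligament_force(1.0 + dl_ch / l0, 0.0, foot.pf), 0.0
        if self.has_arch:
            Fc += ligament_force(1.0 + dl_ch / foot.pl.l0, 0.0, foot.pl)
            # chord force enters through d(chord)/du
            Jc = np.zeros(self.nq)
            h = 1e-7
            for j in range(self.nq):
                up = u.copy(); up[j] += h
                um = u.copy(); um[j] -= h
                qp = up[2] if self.has_arch else 0.0
                qm_ = um[2] if self.has_arch else 0.0
                Jc[j] = (foot.chord_length(qp) - foot.chord_length(qm_)) / (2 * h)
            Q += -Fc * Jc
        if self.has_toe:
            i_tj = self.nq - 1
            Q[i_tj] += -Ft * foot.R_PF
        # residual return springs
        if self.has_arch:
            Q[2] += -RESIDUAL_K * qm
        if self.has_toe:
            Q[self.nq - 1] += -RESIDUAL_K * qt
        return Q


def _rot(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


def compression_test(
    foot: FootModel | str,
    load_max: float = 800.0,
    steps: int = 12,
    contact: ContactParams | None = None,
) -> TestBenchResult:
    """Quasi-static vertical compression of one foot model.

    The load ramps from 0 to ``load_max`` (N, roughly body weight) in
    ``steps`` levels; each level is solved for static equilibrium starting
    from the previous solution (load continuation).
    """
    if isinstance(foot, str):
        foot = build_foot(foot)
    sf = _StaticFoot(foot, contact or ContactParams())
    loads = np.linspace(0.0, load_max, steps + 1)
    u = np.zeros(sf.nq)
    u[0] = -1e-4  # start just touching so the contact stiffness is active
    comp = np.zeros_like(loads)
    mtj = np.zeros_like(loads)
    tj = np.zeros_like(loads)
    ok = np.zeros_like(loads, dtype=bool)
    resn = np.zeros_like(loads)
    y_ref = None
    for i, F in enumerate(loads):
        sol = optimize.least_squares(sf.residual, u, args=(F,),
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
        u = sol.x
        r = sf.residual(u, F)
        ok[i] = np.linalg.norm(r) < 1e-3 * max(F, 10.0)
        resn[i] = float(np.linalg.norm(r))
        if y_ref is None:
            y_ref = u[0]
        comp[i] = (y_ref - u[0]) * 1e3
        mtj[i] = math.degrees(u[2]) if sf.has_arch else 0.0
        tj[i] = math.degrees(u[-1]) if sf.has_toe else 0.0
    if not ok.all():
        worst = float(resn.max())
        if worst > 1.0:
            raise RuntimeError(
                f"static equilibrium not found (max residual {worst:.3g} N)")
    return TestBenchResult(load=loads, compression=comp, mtj_angle=mtj,
                           tj_angle=tj, converged=ok, residual=resn)


def calibrate_A_PL(
    target_load: np.ndarray,
    target_compression_mm: np.ndarray,
    kind: str = "2s-MTJ",
    target_mtj_deg: np.ndarray | None = None,
    bounds: tuple[float, float] = (20.0, 400.0),
) -> float:
    """Least-squares fit of the plantar-ligament cross-section A_PL (mm^2).

    The forward test bench is run over the target load levels and A_PL is
    adjusted so the predicted arch compression (and optionally MTJ angle)
    match the supplied targets.
    """
    target_load = np.asarray(target_load, dtype=float)
    target_compression_mm = np.asarray(target_compression_mm, dtype=float)
    if target_load.size == 0:
        raise ValueError("empty calibration target")
    if not has_mobile_arch(kind):
        raise ValueError("A_PL calibration requires a mobile-arch variant")
    if bounds[0] >= bounds[1] or bounds[0] <= 0:
        raise ValueError("infeasible A_PL bounds")
    lmax = float(target_load.max())
    steps = len(target_load) - 1 if len(target_load) > 1 else 1

    def forward(a_pl):
        a_pl = float(np.atleast_1d(a_pl)[0])
        pl = default_pl()
        pl = LigamentParams(area_mm2=a_pl, k_mpa=pl.k_mpa, d_s=pl.d_s,
                            l0_cm=pl.l0_cm, alpha=pl.alpha)
        foot = build_foot(kind, pl=pl)
        res = compression_test(foot, load_max=lmax, steps=steps)
        comp = np.interp(target_load, res.load, res.compression)
        if target_mtj_deg is not None:
            ang = np.interp(target_load, res.load, res.mtj_angle)
            return np.concatenate([comp - target_compression_mm,
                                   ang - np.asarray(target_mtj_deg)])
        return comp - target_compression_mm

    fit = optimize.least_squares(forward, x0=[120.0], bounds=([bounds[0]],
                                                              [bounds[1]]),
                                 xtol=1e-10, ftol=1e-12)
    return float(fit.x[0])
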