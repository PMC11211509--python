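"""Numba-compiled planar multibody dynamics core.

The skeleton is a kinematic tree of rigid bodies: a floating trunk (3 DOF)
with two legs (thigh, shank, hindfoot and, depending on the foot variant,
forefoot and/or toe) attached by revolute joints.  Generalized coordinates
are ``q = [x_t, y_t, th_t, q_joint(body 1), ..., q_joint(body nb-1)]`` with
the joint coordinate of body ``i`` at index ``i + 2``; all joint coordinates
are zero in the neutral standing pose.

Dynamics are assembled Jacobian-wise:  ``M(q) qdd = Q_ext + Q_g - c(q, qd)``
with the mass matrix from the bodies' CoM Jacobians and the bias vector from
an acceleration recursion at ``qdd = 0``.  External forces (ground contact,
ligaments, muscles, joint stops) enter through point Jacobians.

Everything here operates on the packed parameter tuple built by
:mod:`archwalk.model`; the public API lives in the surrounding modules.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# indices into the packed parameter tuple P (see model.build_compiled)
# P = (parent, anchor, com, mass, inertia, grav,
#      ce_body, ce_loc, ce_R, ce_leg, cpar,
#      leg_bodies, foot_flags, lig_geo, lig_par,
#      mus_par, att_n, att_qidx, att_jt, att_r0, att_phimax, att_phiref,
#      att_rho, att_sgn, att_var, hill, stops, resid, met)


@njit(cache=True, error_model='numpy')
def _fk(q, qd, parent, anchor):
    nb = parent.shape[0]
    th = np.empty(nb)
    om = np.empty(nb)
    o = np.empty((nb, 2))
    vo = np.empty((nb, 2))
    th[0] = q[2]
    om[0] = qd[2]
    o[0, 0] = q[0]
    o[0, 1] = q[1]
    vo[0, 0] = qd[0]
    vo[0, 1] = qd[1]
    for i in range(1, nb):
        p = parent[i]
        cp = math.cos(th[p])
        sp = math.sin(th[p])
        rx = cp * anchor[i, 0] - sp * anchor[i, 1]
        ry = sp * anchor[i, 0] + cp * anchor[i, 1]
        o[i, 0] = o[p, 0] + rx
        o[i, 1] = o[p, 1] + ry
        vo[i, 0] = vo[p, 0] - om[p] * ry
        vo[i, 1] = vo[p, 1] + om[p] * rx
        th[i] = th[p] + q[i + 2]
        om[i] = om[p] + qd[i + 2]
    return th, om, o, vo


@njit(cache=True, error_model='numpy')
def _apply_point_force(Q, b, px, py, fx, fy, parent, o):
    """Generalized force of a force (fx, fy) at world point (px, py) on body b."""
    Q[0] += fx
    Q[1] += fy
    Q[2] += (px - o[0, 0]) * fy - (py - o[0, 1]) * fx
    i = b
    while i > 0:
        Q[i + 2] += (px - o[i, 0]) * fy - (py - o[i, 1]) * fx
        i = parent[i]


@njit(cache=True, error_model='numpy')
def _apply_torque(Q, b, tau, parent):
    Q[2] += tau
    i = b
    while i > 0:
        Q[i + 2] += tau
        i = parent[i]


@njit(cache=True, error_model='numpy')
def _mass_bias(q, qd, parent, anchor, com, mass, inertia, grav):
    """Mass matrix and combined gravity/Coriolis generalized force.

    Returns (M, rhs0) such that M qdd = Q_ext + rhs0.
    """
    nb = parent.shape[0]
    n = nb + 2
    th, om, o, vo = _fk(q, qd, parent, anchor)

    # acceleration recursion at qdd = 0
    ao = np.zeros((nb, 2))
    al = np.zeros(nb)
    for i in range(1, nb):
        p = parent[i]
        cp = math.cos(th[p])
        sp = math.sin(th[p])
        rx = cp * anchor[i, 0] - sp * anchor[i, 1]
        ry = sp * anchor[i, 0] + cp * anchor[i, 1]
        ao[i, 0] = ao[p, 0] - al[p] * ry - om[p] * om[p] * rx
        ao[i, 1] = ao[p, 1] + al[p] * rx - om[p] * om[p] * ry
        al[i] = al[p]

    M = np.zeros((n, n))
    rhs0 = np.zeros(n)
    Jv = np.empty((2, n))
    anc = np.empty(nb, np.bool_)
    for b in range(nb):
        cb = math.cos(th[b])
        sb = math.sin(th[b])
        cx = cb * com[b, 0] - sb * com[b, 1]
        cy = sb * com[b, 0] + cb * com[b, 1]
        pcx = o[b, 0] + cx
        pcy = o[b, 1] + cy
        # CoM acceleration at qdd = 0
        acx = ao[b, 0] - al[b] * cy - om[b] * om[b] * cx
        acy = ao[b, 1] + al[b] * cx - om[b] * om[b] * cy

        # ancestor flags
        for i in range(nb):
            anc[i] = False
        anc[0] = True
        i = b
        while i > 0:
            anc[i] = True
            i = parent[i]

        for j in range(n):
            Jv[0, j] = 0.0
            Jv[1, j] = 0.0
        Jv[0, 0] = 1.0
        Jv[1, 1] = 1.0
        Jv[0, 2] = -(pcy - o[0, 1])
        Jv[1, 2] = pcx - o[0, 0]
        for bi in range(1, nb):
            if anc[bi]:
                Jv[0, bi + 2] = -(pcy - o[bi, 1])
                Jv[1, bi + 2] = pcx - o[bi, 0]

        m = mass[b]
        Ib = inertia[b]
        gx = 0.0
        gy = -grav
        for j in range(n):
            a0 = Jv[0, j]
            a1 = Jv[1, j]
            if a0 == 0.0 and a1 == 0.0:
                jw = 1.0 if (j == 2 or (j >= 3 and anc[j - 2])) else 0.0
                if jw == 0.0:
                    continue
            rhs0[j] += m * (a0 * (gx - acx) + a1 * (gy - acy))
            for k in range(j, n):
                M[j, k] += m * (a0 * Jv[0, k] + a1 * Jv[1, k])
        # rotational part
        for j in range(2, n):
            if j == 2 or anc[j - 2]:
                rhs0[j] += -Ib * al[b]
                for k in range(j, n):
                    if k == 2 or anc[k - 2]:
                        M[j, k] += Ib
    for j in range(n):
        for k in range(j + 1, n):
            M[k, j] = M[j, k]
    return M, rhs0, th, om, o, vo


@njit(cache=True, error_model='numpy')
def _contact_forces(th, om, o, vo, parent, ce_body, ce_loc, ce_R, cpar, Q, rec):
    """Hunt-Crossley + continuous-friction forces for all contact elements.

    rec rows per element: [F_v, F_h_applied, p_x, power, p_y]
    """
    k_y = cpar[0]
    v_max = cpar[1]
    mu_d = cpar[2]
    mu_s = cpar[3]
    v_t = cpar[4]
    nc = ce_body.shape[0]
    for e in range(nc):
        b = ce_body[e]
        cb = math.cos(th[b])
        sb = math.sin(th[b])
        lx = ce_loc[e, 0]
        ly = ce_loc[e, 1]
        rx = cb * lx - sb * ly
        ry = sb * lx + cb * ly
        cx = o[b, 0] + rx
        cy = o[b, 1] + ry
        R = ce_R[e]
        px = cx
        py = cy - R
        rec[e, 2] = px
        rec[e, 4] = py
        dy = py
        if dy > 0.0:
            rec[e, 0] = 0.0
            rec[e, 1] = 0.0
            rec[e, 3] = 0.0
            continue
        vcx = vo[b, 0] - om[b] * ry
        vcy = vo[b, 1] + om[b] * rx
        vy = vcy
        vbar_y = vy / v_max
        if vbar_y >= 1.0:
            Fv = 0.0
        else:
            Fv = -k_y * dy * (1.0 - vbar_y)
        # material slip velocity at the point of action (rolling contact)
        vslip = vcx + om[b] * R
        vbx = vslip / v_t
        mu = mu_d * math.tanh(4.0 * vbx) + (mu_s - mu_d) * vbx / (
            (0.25 * vbx * vbx + 0.75) * (0.25 * vbx * vbx + 0.75)
        )
        Fh = -Fv * mu  # reaction opposing sliding
        rec[e, 0] = Fv
        rec[e, 1] = Fh
        rec[e, 3] = Fh * vslip + Fv * vy
        _apply_point_force(Q, b, px, py, Fh, Fv, parent, o)


@njit(cache=True, error_model='numpy')
def _lig_force(lam, lam_dot, A, k, d, alpha):
    if lam < 1.0:
        return 0.0
    damp = 1.0 + d * lam_dot
    if damp <= 0.0:
        return 0.0
    e = alpha * (lam * lam - 1.0)
    if e > 50.0:  # overflow guard for diverged implicit-solver iterates
        e = 50.0
    return A * lam * lam * (k / (2.0 * alpha)) * (math.exp(e) - 1.0) * damp


@njit(cache=True, error_model='numpy')
def _ligaments(q, qd, th, o, parent, leg_bodies, foot_flags, lig_geo, lig_par,
               resid, Q, rec):
    """Ligament chord forces, toe-joint moments and MTJ/TJ residual springs.

    foot_flags: [has_toe, has_arch, coupled]
    lig_geo: [attHx, attHy, attBx, attBy, rAMx, rAMy, chord0, R_PF, ball_on_M]
    lig_par rows: PF = [A, k, d, l0, alpha], PL = same
    rec per leg: [pf_pow, pl_pow, pf_lam, pl_lam, pf_Fc, pf_Ft, pl_F]
    """
    has_toe = foot_flags[0] == 1
    has_arch = foot_flags[1] == 1
    coupled = foot_flags[2] == 1
    R_PF = lig_geo[7]
    chord0 = lig_geo[6]
    k_res = resid[0]
    d_res = resid[1]

    for leg in range(2):
        foot = leg_bodies[leg, 2]
        fore = leg_bodies[leg, 3]
        toe = leg_bodies[leg, 4]
        q_mtj = q[fore + 2] if fore >= 0 else 0.0
        qd_mtj = qd[fore + 2] if fore >= 0 else 0.0
        q_tj = q[toe + 2] if toe >= 0 else 0.0
        qd_tj = qd[toe + 2] if toe >= 0 else 0.0

        # residual return spring-dampers
        if fore >= 0:
            _apply_torque(Q, fore, -k_res * q_mtj - d_res * qd_mtj, parent)
            _apply_torque(Q, foot, k_res * q_mtj + d_res * qd_mtj, parent)
        if toe >= 0:
            tp = fore if fore >= 0 else foot
            _apply_torque(Q, toe, -k_res * q_tj - d_res * qd_tj, parent)
            _apply_torque(Q, tp, k_res * q_tj + d_res * qd_tj, parent)

        base = leg * 7
        for i in range(7):
            rec[base + i] = 0.0
        rec[base + 2] = 1.0
        rec[base + 3] = 1.0
        if not (has_toe or has_arch):
            continue

        # chord between heel attachment (hindfoot) and ball attachment
        dl_ch = 0.0
        ldot_ch = 0.0
        ux = 0.0
        uy = 0.0
        hx = hy = bx = by = 0.0
        darm = 0.0
        if has_arch and fore >= 0:
            ca = math.cos(th[foot])
            sa = math.sin(th[foot])
            hx = o[foot, 0] + ca * lig_geo[0] - sa * lig_geo[1]
            hy = o[foot, 1] + sa * lig_geo[0] + ca * lig_geo[1]
            cm = math.cos(th[fore])
            sm = math.sin(th[fore])
            bx = o[fore, 0] + cm * lig_geo[2] - sm * lig_geo[3]
            by = o[fore, 1] + sm * lig_geo[2] + cm * lig_geo[3]
            dx = bx - hx
            dy = by - hy
            ch = math.sqrt(dx * dx + dy * dy)
            ux = dx / ch
            uy = dy / ch
            dl_ch = ch - chord0
            # d(chord)/d(q_mtj) = u . (z x (b - mtj)): lever of the chord
            # about the MTJ; relative joint rate only
            mjx = o[fore, 0]
            mjy = o[fore, 1]
            ldot_ch = qd_mtj * ((-(by - mjy)) * ux + (bx - mjx) * uy)

        arc = q_tj * R_PF
        arc_dot = qd_tj * R_PF

        # PF
        A_pf = lig_par[0, 0]
        k_pf = lig_par[0, 1]
        d_pf = lig_par[0, 2]
        l0_pf = lig_par[0, 3]
        al_pf = lig_par[0, 4]
        F_pf_chord = 0.0
        F_pf_toe = 0.0
        if coupled:
            lam = 1.0 + (dl_ch + arc) / l0_pf
            lam_dot = (ldot_ch + arc_dot) / l0_pf
            F = _lig_force(lam, lam_dot, A_pf, k_pf, d_pf, al_pf)
            F_pf_chord = F
            F_pf_toe = F
            rec[base + 2] = lam
        elif has_toe and has_arch:  # 3s-nW: decoupled evaluation
            lam1 = 1.0 + dl_ch / l0_pf
            lam1_dot = ldot_ch / l0_pf
            F_pf_chord = _lig_force(lam1, lam1_dot, A_pf, k_pf, d_pf, al_pf)
            lam2 = 1.0 + arc / l0_pf
            lam2_dot = arc_dot / l0_pf
            F_pf_toe = _lig_force(lam2, lam2_dot, A_pf, k_pf, d_pf, al_pf)
            rec[base + 2] = lam1 if lam1 > lam2 else lam2
        elif has_toe:  # 2s-TJ
            lam = 1.0 + arc / l0_pf
            lam_dot = arc_dot / l0_pf
            F_pf_toe = _lig_force(lam, lam_dot, A_pf, k_pf, d_pf, al_pf)
            rec[base + 2] = lam
        else:  # 2s-MTJ
            lam = 1.0 + dl_ch / l0_pf
            lam_dot = ldot_ch / l0_pf
            F_pf_chord = _lig_force(lam, lam_dot, A_pf, k_pf, d_pf, al_pf)
            rec[base + 2] = lam

        # PL (mobile arches only)
        F_pl = 0.0
        if has_arch:
            A_pl = lig_par[1, 0]
            k_pl = lig_par[1, 1]
            d_pl = lig_par[1, 2]
            l0_pl = lig_par[1, 3]
            al_pl = lig_par[1, 4]
            lam_pl = 1.0 + dl_ch / l0_pl
            lam_pl_dot = ldot_ch / l0_pl
            F_pl = _lig_force(lam_pl, lam_pl_dot, A_pl, k_pl, d_pl, al_pl)
            rec[base + 3] = lam_pl

        # apply chord tension pair
        Fc = F_pf_chord + F_pl
        if Fc > 0.0 and has_arch and fore >= 0:
            _apply_point_force(Q, foot, hx, hy, Fc * ux, Fc * uy, parent, o)
            _apply_point_force(Q, fore, bx, by, -Fc * ux, -Fc * uy, parent, o)
        # toe-joint moment opposing dorsiflexion (reaction on the parent)
        if F_pf_toe > 0.0 and toe >= 0:
            tp = fore if fore >= 0 else foot
            _apply_torque(Q, toe, -F_pf_toe * R_PF, parent)
            _apply_torque(Q, tp, F_pf_toe * R_PF, parent)

        rec[base + 0] = -(F_pf_chord * ldot_ch + F_pf_toe * arc_dot)
        rec[base + 1] = -F_pl * ldot_ch
        rec[base + 4] = F_pf_chord
        rec[base + 5] = F_pf_toe
        rec[base + 6] = F_pl


@njit(cache=True, error_model='numpy')
def _stop_torque(phi, phid, lo, hi, k, d):
    """Soft joint-limit torque on the biomechanical angle phi.

    Spring beyond the limit plus damping that acts only while moving deeper
    into the violation -- damping an exiting joint would rate-limit its
    return to the admissible range.
    """
    if phi > hi:
        t = -k * (phi - hi)
        if phid > 0.0:
            t -= d * phid
        return t
    if phi < lo:
        t = -k * (phi - lo)
        if phid < 0.0:
            t -= d * phid
        return t
    return 0.0


@njit(cache=True, error_model='numpy')
def _joint_stops(q, qd, parent, leg_bodies, stops, Q, rec):
    """Knee/ankle/hip soft limits; rec per leg: [|T_kne|, |T_ank|]."""
    knee_max = stops[0]
    ank_lo = stops[1]
    ank_hi = stops[2]
    hip_hi = stops[3]
    hip_lo = stops[4]
    k = stops[5]
    d = stops[6]
    HALF_PI = 1.5707963267948966
    PI = 3.141592653589793
    for leg in range(2):
        thigh = leg_bodies[leg, 0]
        shank = leg_bodies[leg, 1]
        foot = leg_bodies[leg, 2]
        # hip: phi = pi - q, dphi/dq = -1
        phi_h = PI - q[thigh + 2]
        t = _stop_torque(phi_h, -qd[thigh + 2], hip_lo, hip_hi, k, d)
        if t != 0.0:
            _apply_torque(Q, thigh, -t, parent)
            _apply_torque(Q, 0, t, parent)
        # knee: phi = pi + q
        phi_k = PI + q[shank + 2]
        t = _stop_torque(phi_k, qd[shank + 2], 0.0, knee_max, k, d)
        rec[leg * 2 + 0] = abs(t)
        if t != 0.0:
            _apply_torque(Q, shank, t, parent)
            _apply_torque(Q, thigh, -t, parent)
        # ankle: phi = pi/2 + q
        phi_a = HALF_PI + q[foot + 2]
        t = _stop_torque(phi_a, qd[foot + 2], ank_lo, ank_hi, k, d)
        rec[leg * 2 + 1] = abs(t)
        if t != 0.0:
            _apply_torque(Q, foot, t, parent)
            _apply_torque(Q, shank, -t, parent)
        # internal foot joints: bony-support range stops (the ligaments are
        # tension-only, so without these the arch could fold freely)
        fore = leg_bodies[leg, 3]
        toe = leg_bodies[leg, 4]
        if fore >= 0:
            qm = q[fore + 2]
            t = _stop_torque(qm, qd[fore + 2], -0.2094, 0.2618, k, d)
            if t != 0.0:
                _apply_torque(Q, fore, t, parent)
                _apply_torque(Q, foot, -t, parent)
        if toe >= 0:
            qt = q[toe + 2]
            t = _stop_torque(qt, qd[toe + 2], -0.0873, 1.3090, k, d)
            if t != 0.0:
                tp = fore if fore >= 0 else foot
                _apply_torque(Q, toe, t, parent)
                _apply_torque(Q, tp, -t, parent)


@njit(cache=True, error_model='numpy')
def _inv_fv(f, v_max, N, K):
    """Inverse of the Hill force-velocity relation, normalized units (l_opt/s)."""
    if f < 0.0:
        f = 0.0
    if f < 1.0:
        return v_max * (f - 1.0) / (1.0 + K * f)
    fmax = N - 1e-3
    if f > fmax:
        f = fmax
    return v_max * (f - 1.0) / (7.56 * K * (N - f) + (N - 1.0))


@njit(cache=True, error_model='numpy')
def _muscles(q, qd, parent, leg_bodies, mus_par, att_n, att_qidx, att_jt,
             att_r0, att_phimax, att_phiref, att_rho, att_sgn, att_var, hill,
             act, lce, stim, Q, lce_dot, rec_F, rec_tau_ank, rec_met):
    """Hill-type muscle forces, joint torques and CE dynamics.

    rec_F: tendon force per muscle (N); rec_tau_ank: net muscle ankle torque
    per leg; rec_met: [metabolic rate (W), sum of squared activations].
    """
    w = hill[0]
    c = hill[1]
    N = hill[2]
    K = hill[3]
    eps_ref = hill[4]
    eta_pos = hill[6]
    eta_neg = hill[7]
    c_act = hill[8]
    HALF_PI = 1.5707963267948966
    PI = 3.141592653589793
    nm = mus_par.shape[0]
    met = 0.0
    act2 = 0.0
    rec_tau_ank[0] = 0.0
    rec_tau_ank[1] = 0.0
    for m in range(nm):
        F_max = mus_par[m, 0]
        v_max = mus_par[m, 1]
        l_opt = mus_par[m, 2]
        l_slack = mus_par[m, 3]
        # MTU length from the spanned joint angles
        l_mtu = l_opt + l_slack
        for p in range(att_n[m]):
            qi = att_qidx[m, p]
            jt = att_jt[m, p]
            if jt == 0:
                phi = PI - q[qi]
            elif jt == 1:
                phi = PI + q[qi]
            else:
                phi = HALF_PI + q[qi]
            if att_var[m, p] == 1:
                l_mtu += att_sgn[m, p] * att_rho[m, p] * att_r0[m, p] * (
                    math.sin(phi - att_phimax[m, p])
                    - math.sin(att_phiref[m, p] - att_phimax[m, p])
                )
            else:
                l_mtu += att_sgn[m, p] * att_rho[m, p] * att_r0[m, p] * (
                    phi - att_phiref[m, p]
                )
        lc = lce[m]
        a = act[m]
        if a < 0.01:
            a = 0.01
        eps = (l_mtu - lc - l_slack) / l_slack
        F_se = F_max * (eps / eps_ref) * (eps / eps_ref) if eps > 0.0 else 0.0
        x = (lc - l_opt) / (l_opt * w)
        f_l = math.exp(c * abs(x) * abs(x) * abs(x))
        F_pe = F_max * x * x if lc > l_opt else 0.0
        lmin = l_opt * (1.0 - w)
        xb = (lmin - lc) / (0.5 * l_opt * w)
        F_be = F_max * xb * xb if lc < lmin else 0.0
        if eps <= 0.0:
            # slack tendon: the fiber simply tracks the path length; this
            # avoids the numerically violent v_max rush into the buffer
            # elasticity that the Hill inversion would produce at near-zero
            # activation
            lce_dot[m] = (l_mtu - l_slack - lc) / 0.02
            rec_F[m] = 0.0
        else:
            denom = a * F_max * f_l + F_pe
            f_v = (F_se + F_be) / denom if denom > 1e-9 else 2.0
            u = _inv_fv(f_v, v_max, N, K)
            lce_dot[m] = u * l_opt
            rec_F[m] = F_se

        # torques on the spanned joints
        if F_se > 0.0:
            for p in range(att_n[m]):
                qi = att_qidx[m, p]
                jt = att_jt[m, p]
                if jt == 0:
                    phi = PI - q[qi]
                    dphidq = -1.0
                elif jt == 1:
                    phi = PI + q[qi]
                    dphidq = 1.0
                else:
                    phi = HALF_PI + q[qi]
                    dphidq = 1.0
                if att_var[m, p] == 1:
                    arm = att_r0[m, p] * math.cos(phi - att_phimax[m, p])
                    if arm < 0.0:
                        arm = 0.0
                else:
                    arm = att_r0[m, p]
                dldq = att_sgn[m, p] * att_rho[m, p] * arm * dphidq
                tau = -F_se * dldq
                body = qi - 2
                _apply_torque(Q, body, tau, parent)
                _apply_torque(Q, parent[body], -tau, parent)
                if jt == 2:
                    leg = 0 if qi - 2 == leg_bodies[0, 2] else 1
                    rec_tau_ank[leg] += tau

        # metabolic rate: Margaria efficiencies on fiber work + maintenance
        P_ce = F_se - F_pe + F_be  # contractile-element force
        if P_ce < 0.0:
            P_ce = 0.0
        p_mech = -P_ce * lce_dot[m]  # >0 when shortening
        if p_mech > 0.0:
            met += p_mech / eta_pos
        else:
            met += -p_mech / eta_neg
        met += c_act * a * a * F_max * l_opt
        act2 += act[m] * act[m]
    rec_met[0] = met
    rec_met[1] = act2


@njit(cache=True, error_model='numpy')
def _eval(q, qd, act, lce, stim, P, Q, recs):
    """Assemble all generalized forces; returns (M, rhs0, kinematics)."""
    (parent, anchor, com, mass, inertia, grav, ce_body, ce_loc, ce_R, ce_leg,
     cpar, leg_bodies, foot_flags, lig_geo, lig_par, mus_par, att_n, att_qidx,
     att_jt, att_r0, att_phimax, att_phiref, att_rho, att_sgn, att_var, hill,
     stops, resid, met_basal) = P
    M, rhs0, th, om, o, vo = _mass_bias(q, qd, parent, anchor, com, mass,
                                        inertia, grav)
    ce_rec, lig_rec, stop_rec, mus_F, tau_ank, met_rec, lce_dot = recs
    _contact_forces(th, om, o, vo, parent, ce_body, ce_loc, ce_R, cpar, Q,
                    ce_rec)
    _ligaments(q, qd, th, o, parent, leg_bodies, foot_flags, lig_geo, lig_par,
               resid, Q, lig_rec)
    _joint_stops(q, qd, parent, leg_bodies, stops, Q, stop_rec)
    _muscles(q, qd, parent, leg_bodies, mus_par, att_n, att_qidx, att_jt,
             att_r0, att_phimax, att_phiref, att_rho, att_sgn, att_var, hill,
             act, lce, stim, Q, lce_dot, mus_F, tau_ank, met_rec)
    met_rec[0] += met_basal
    return M, rhs0, th, om, o, vo


@njit(cache=True, error_model='numpy')
def rhs(t, y, stim, P):
    """Time derivative of the full state [q, qd, activations, l_CE]."""
    parent = P[0]
    nb = parent.shape[0]
    n = nb + 2
    nm = P[15].shape[0]
    nc = P[6].shape[0]
    tau_act = P[25][5]
    q = y[:n]
    qd = y[n:2 * n]
    act = y[2 * n:2 * n + nm]
    lce = y[2 * n + nm:2 * n + 2 * nm]

    Q = np.zeros(n)
    recs = (np.zeros((nc, 5)), np.zeros(14), np.zeros(4), np.zeros(nm),
            np.zeros(2), np.zeros(2), np.zeros(nm))
    M, rhs0, th, om, o, vo = _eval(q, qd, act, lce, stim, P, Q, recs)
    b = Q + rhs0
    ok = True
    for i in range(n):
        if not np.isfinite(b[i]):
            ok = False
    if ok:
        qdd = np.linalg.solve(M, b)
    else:
        qdd = np.full(n, np.nan)

    ydot = np.empty(y.shape[0])
    ydot[:n] = qd
    ydot[n:2 * n] = qdd
    for m in range(nm):
        s = stim[m]
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
        ydot[2 * n + m] = (s - act[m]) / tau_act
        ydot[2 * n + nm + m] = recs[6][m]
    return ydot


@njit(cache=True, error_model='numpy')
def rhs_ramp(t, y, stim0, stim1, t0, dtc, P):
    """RHS with the stimulus ramping linearly over one control interval.

    Keeps the vector field continuous across controller updates, which the
    implicit (BDF) integrator rewards with much larger steps.
    """
    w = (t - t0) / dtc
    if w < 0.0:
        w = 0.0
    elif w > 1.0:
        w = 1.0
    stim = stim0 + w * (stim1 - stim0)
    return rhs(t, y, stim, P)


@njit(cache=True, error_model='numpy')
def observe(y, stim, P, hat_com, out):
    """Fill the observation channel vector for one recorded sample.

    Layout (see model.CHANNELS): global block then one block per leg.
    """
    parent = P[0]
    leg_bodies = P[11]
    com = P[2]
    nb = parent.shape[0]
    n = nb + 2
    nm = P[15].shape[0]
    nc = P[6].shape[0]
    ce_leg = P[9]
    q = y[:n]
    qd = y[n:2 * n]
    act = y[2 * n:2 * n + nm]
    lce = y[2 * n + nm:2 * n + 2 * nm]

    Q = np.zeros(n)
    ce_rec = np.zeros((nc, 5))
    lig_rec = np.zeros(14)
    stop_rec = np.zeros(4)
    mus_F = np.zeros(nm)
    tau_ank = np.zeros(2)
    met_rec = np.zeros(2)
    lce_dot = np.zeros(nm)
    recs = (ce_rec, lig_rec, stop_rec, mus_F, tau_ank, met_rec, lce_dot)
    M, rhs0, th, om, o, vo = _eval(q, qd, act, lce, stim, P, Q, recs)
    qdd = np.linalg.solve(M, Q + rhs0)

    # trunk CoM kinematics (the HAT segment is body 0)
    c0 = math.cos(th[0])
    s0 = math.sin(th[0])
    cx = c0 * com[0, 0] - s0 * com[0, 1]
    cy = s0 * com[0, 0] + c0 * com[0, 1]
    hat_com[0] = o[0, 0] + cx
    hat_com[1] = o[0, 1] + cy
    vx = vo[0, 0] - om[0] * cy
    vy = vo[0, 1] + om[0] * cx
    # a = (recursion at qdd=0 is zero for the root) + Jv qdd
    ax = qdd[0] - qdd[2] * cy - om[0] * om[0] * cx
    ay = qdd[1] + qdd[2] * cx - om[0] * om[0] * cy

    out[0] = th[0]
    out[1] = om[0]
    out[2] = vx
    out[3] = vy
    out[4] = ax
    out[5] = ay
    out[6] = met_rec[0]
    out[7] = met_rec[1]
    out[8] = hat_com[0]
    out[9] = hat_com[1]

    PI = 3.141592653589793
    HALF_PI = 1.5707963267948966
    for leg in range(2):
        b = 10 + leg * 32
        gv = 0.0
        gh = 0.0
        # up to 3 elements per leg in order of definition
        ei = 0
        for e in range(nc):
            if ce_leg[e] != leg:
                continue
            out[b + 2 + ei] = ce_rec[e, 0]
            out[b + 5 + ei] = ce_rec[e, 1]
            out[b + 8 + ei] = ce_rec[e, 2]
            out[b + 11 + ei] = ce_rec[e, 3]
            gv += ce_rec[e, 0]
            gh += ce_rec[e, 1]
            ei += 1
        for k in range(ei, 3):
            out[b + 2 + k] = 0.0
            out[b + 5 + k] = 0.0
            out[b + 8 + k] = np.nan
            out[b + 11 + k] = 0.0
        out[b + 0] = gv
        out[b + 1] = gh
        for k in range(7):
            out[b + 14 + k] = lig_rec[leg * 7 + k]
        foot = leg_bodies[leg, 2]
        out[b + 21] = tau_ank[leg] + (
            _stop_torque(HALF_PI + q[foot + 2], qd[foot + 2], P[26][1],
                         P[26][2], P[26][5], P[26][6]))
        out[b + 22] = HALF_PI + q[foot + 2]
        out[b + 23] = qd[foot + 2]
        out[b + 24] = stop_rec[leg * 2 + 0]
        out[b + 25] = stop_rec[leg * 2 + 1]
        fore = leg_bodies[leg, 3]
        toe = leg_bodies[leg, 4]
        out[b + 26] = q[fore + 2] if fore >= 0 else 0.0
        out[b + 27] = q[toe + 2] if toe >= 0 else 0.0
        out[b + 28] = qd[fore + 2] if fore >= 0 else 0.0
        out[b + 29] = qd[toe + 2] if toe >= 0 else 0.0
        thigh = leg_bodies[leg, 0]
        shank = leg_bodies[leg, 1]
        out[b + 30] = PI - q[thigh + 2]
        out[b + 31] = PI + q[shank + 2]


@njit(cache=True, error_model='numpy')
def muscle_signals(y, P, out_F, out_l):
    """Normalized tendon forces and CE lengths for the reflex pathways."""
    parent = P[0]
    nb = parent.shape[0]
    n = nb + 2
    mus_par = P[15]
    nm = mus_par.shape[0]
    act = y[2 * n:2 * n + nm]
    lce = y[2 * n + nm:2 * n + 2 * nm]
    q = y[:n]
    att_n = P[16]
    att_qidx = P[17]
    att_jt = P[18]
    att_r0 = P[19]
    att_phimax = P[20]
    att_phiref = P[21]
    att_rho = P[22]
    att_sgn = P[23]
    att_var = P[24]
    hill = P[25]
    eps_ref = hill[4]
    HALF_PI = 1.5707963267948966
    PI = 3.141592653589793
    for m in range(nm):
        F_max = mus_par[m, 0]
        l_opt = mus_par[m, 2]
        l_slack = mus_par[m, 3]
        l_mtu = l_opt + l_slack
        for p in range(att_n[m]):
            qi = att_qidx[m, p]
            jt = att_jt[m, p]
            if jt == 0:
                phi = PI - q[qi]
            elif jt == 1:
                phi = PI + q[qi]
            else:
                phi = HALF_PI + q[qi]
            if att_var[m, p] == 1:
                l_mtu += att_sgn[m, p] * att_rho[m, p] * att_r0[m, p] * (
                    math.sin(phi - att_phimax[m, p])
                    - math.sin(att_phiref[m, p] - att_phimax[m, p])
                )
            else:
                l_mtu += att_sgn[m, p] * att_rho[m, p] * att_r0[m, p] * (
                    phi - att_phiref[m, p]
                )
        eps = (l_mtu - lce[m] - l_slack) / l_slack
        out_F[m] = (eps / eps_ref) ** 2 if eps > 0.0 else 0.0
        out_l[m] = lce[m] / l_opt


# --------------------------------------------------------------------------
# stiff one-step integrator (TR-BDF2)
# --------------------------------------------------------------------------

_TRBDF2_GAMMA = 2.0 - math.sqrt(2.0)


@njit(cache=True, error_model='numpy')
def _fd_jacobian(t, y, stim0, stim1, tc0, dtc, P, J):
    ny = y.shape[0]
    f0 = rhs_ramp(t, y, stim0, stim1, tc0, dtc, P)
    yp = y.copy()
    for j in range(ny):
        h = 1e-6 * (abs(y[j]) + 1e-4)
        yj = y[j]
        yp[j] = yj + h
        fj = rhs_ramp(t, yp, stim0, stim1, tc0, dtc, P)
        yp[j] = yj
        for i in range(ny):
            v = (fj[i] - f0[i]) / h
            if not np.isfinite(v):
                v = 0.0
            J[i, j] = v
    return f0


@njit(cache=True, error_model='numpy')
def _newton_stage(t_new, y_guess, rhs_const, a_h, stim0, stim1, tc0, dtc, P,
                  A):
    """Solve y - a_h * f(t_new, y) = rhs_const by Newton iteration.

    Returns (y, converged).  A = I - a_h * J is the (possibly stale)
    iteration matrix.
    """
    y = y_guess.copy()
    ny = y.shape[0]
    for it in range(8):
        f = rhs_ramp(t_new, y, stim0, stim1, tc0, dtc, P)
        r = np.empty(ny)
        nrm = 0.0
        bad = False
        for i in range(ny):
            r[i] = y[i] - a_h * f[i] - rhs_const[i]
            if not np.isfinite(r[i]):
                bad = True
        if bad:
            return y_guess.copy(), False
        delta = np.linalg.solve(A, r)
        # damped update: keeps oscillatory stiction iterations bounded
        lam = 1.0 if it < 4 else 0.5
        for i in range(ny):
            y[i] -= lam * delta[i]
            s = abs(delta[i]) / (abs(y[i]) + 1e-6)
            if s > nrm:
                nrm = s
        if not np.isfinite(nrm):
            return y, False
        if nrm < 1e-9:
            return y, True
    return y, nrm < 1e-7


@njit(cache=True, error_model='numpy')
def trbdf2_step(t, y, h, stim0, stim1, tc0, dtc, P, J, A, jac_fresh):
    """One TR-BDF2 step; returns (y_new, ok).  A = I - (gamma/2) h J."""
    g = _TRBDF2_GAMMA
    a_h = 0.5 * g * h
    f0 = rhs_ramp(t, y, stim0, stim1, tc0, dtc, P)
    ny = y.shape[0]
    rc = np.empty(ny)
    guess = np.empty(ny)
    for i in range(ny):
        rc[i] = y[i] + a_h * f0[i]
        guess[i] = y[i] + g * h * f0[i]  # explicit predictor
    yA, ok1 = _newton_stage(t + g * h, guess, rc, a_h, stim0, stim1, tc0,
                            dtc, P, A)
    if not ok1:
        return y, False
    w1 = 1.0 / (g * (2.0 - g))
    w0 = -(1.0 - g) * (1.0 - g) / (g * (2.0 - g))
    for i in range(ny):
        rc[i] = w1 * yA[i] + w0 * y[i]
        guess[i] = y[i] + (yA[i] - y[i]) / g  # linear extrapolation to t+h
    yB, ok2 = _newton_stage(t + h, guess, rc, a_h, stim0, stim1, tc0, dtc, P,
                            A)
    if not ok2:
        return y, False
    return yB, True


@njit(cache=True, error_model='numpy')
def integrate_chunk(y, t0, t1, h_base, stim0, stim1, P, J, A, jac_age):
    """Advance the state from t0 to t1 with TR-BDF2.

    Steps at ``h_base`` nominally; on Newton failure the Jacobian is
    refreshed and, if that is not enough, the step is halved locally (down
    to h_base/4096), growing back after a run of successes.  The iteration
    matrix A (with its Jacobian J) persists across calls through the
    caller-owned arrays; jac_age = [steps since refresh, step A was built
    for].  Returns 1.0 on success, 0.0 on a hard failure (y is left at the
    last accepted state).
    """
    g = _TRBDF2_GAMMA
    t = t0
    ny = y.shape[0]
    h_min = h_base / 4096.0
    h_cur = jac_age[2] if jac_age[2] > 0.0 else h_base
    if h_cur > h_base:
        h_cur = h_base
    streak = 0
    while t < t1 - 1e-12:
        h = min(h_cur, t1 - t)
        if jac_age[1] != h or jac_age[0] > 100:
            _fd_jacobian(t, y, stim0, stim1, t0, t1 - t0, P, J)
            a_h = 0.5 * g * h
            for i in range(ny):
                for k in range(ny):
                    A[i, k] = -a_h * J[i, k]
                A[i, i] += 1.0
            jac_age[0] = 0
            jac_age[1] = h
        ynew, ok = trbdf2_step(t, y, h, stim0, stim1, t0, t1 - t0, P, J, A,
                               jac_age[0] == 0)
        if not ok and jac_age[0] > 0:
            # stale Jacobian: rebuild at the current state and retry
            _fd_jacobian(t, y, stim0, stim1, t0, t1 - t0, P, J)
            a_h = 0.5 * g * h
            for i in range(ny):
                for k in range(ny):
                    A[i, k] = -a_h * J[i, k]
                A[i, i] += 1.0
            jac_age[0] = 0
            jac_age[1] = h
            ynew, ok = trbdf2_step(t, y, h, stim0, stim1, t0, t1 - t0, P, J,
                                   A, True)
        if not ok:
            if h_cur <= h_min:
                jac_age[1] = 0.0
                jac_age[2] = h_base
                return 0.0
            h_cur = 0.5 * h_cur
            jac_age[1] = 0.0  # force matrix rebuild at the new step
            streak = 0
            continue
        for i in range(ny):
            y[i] = ynew[i]
        t += h
        jac_age[0] += 1
        streak += 1
        if h_cur < h_base and streak >= 8:
            h_cur = min(2.0 * h_cur, h_base)
            jac_age[1] = 0.0
            streak = 0
    jac_age[2] = h_cur
    return 1.0
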