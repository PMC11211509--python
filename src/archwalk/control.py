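"""Reflex controller: muscle stimuli from delayed force/length feedback.

The controller is local and phase-dependent (stance vs swing per leg).
During stance the ankle plantarflexors run on positive force feedback, the
tibialis on length feedback with plantarflexor inhibition, the vasti on
force feedback with knee-overextension protection, and the hip muscles
balance the trunk with a PD law on forward lean blended by the leg's load
share.  During swing the hip flexor runs on length feedback (inhibited by
hamstring stretch) to protract the leg, while hamstring and gluteus force
feedback brake it.  All feedback signals are delayed (5/10/20 ms for
hip/knee/ankle pathways) through a fixed-step history buffer.

Stimuli are clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core
from .model import CompiledModel
from .params import COMPANION, DEG, MUSCLES, ReflexGains

_SOL, _TA, _GAS, _VAS, _HAM, _GLU, _HFL = (MUSCLES.index(m) for m in MUSCLES)


def reflex_stimulus(gain: float, feedback: float, S0: float) -> float:
    """Single reflex pathway: S = clip(S0 + G * delayed signal, 0, 1)."""
    return min(max(S0 + gain * feedback, 0.0), 1.0)


@dataclass
class LegState:
    in_contact: bool = False
    contact_start: float = -1.0
    lean_at_toeoff: float = 0.0


class ReflexController:
    """Phase-based reflex control for the 14-muscle planar walker."""

    def __init__(self, cm: CompiledModel, gains: ReflexGains,
                 control_dt: float, companion: dict | None = None):
        self.cm = cm
        self.g = gains
        self.dt = control_dt
        ctrl = (companion or COMPANION)["control"]
        self.S0 = cm.S0
        self.theta_ref = ctrl["theta_ref_deg"] * DEG
        self.k_p = ctrl["k_p"]
        self.k_d = ctrl["k_d"]
        self.k_lean = ctrl["k_lean"]
        self.k_ds = ctrl["k_ds"]
        self.k_sp = ctrl.get("k_sp", 0.25)
        self.k_tdot = ctrl.get("k_tdot", 0.25)
        self.on_N = ctrl["contact_on"]
        self.off_N = ctrl["contact_off"]
        self.phi_k_off = ctrl["phi_knee_off_deg"] * DEG
        self.l_off = {k: v for k, v in ctrl["l_off"].items()}
        self.delay_steps = np.maximum(
            1, np.rint(cm.delays / control_dt).astype(int))
        nbuf = int(self.delay_steps.max()) + 2
        self.bufF = np.zeros((nbuf, cm.nm))
        self.bufL = np.zeros((nbuf, cm.nm))
        self.head = -1
        self.count = 0
        self.legs = (LegState(), LegState())
        self._sigF = np.zeros(cm.nm)
        self._sigL = np.zeros(cm.nm)

    # -- history ----------------------------------------------------------

    def push_signals(self, y: np.ndarray) -> None:
        _core.muscle_signals(y, self.cm.P, self._sigF, self._sigL)
        self.head = (self.head + 1) % self.bufF.shape[0]
        self.bufF[self.head] = self._sigF
        self.bufL[self.head] = self._sigL
        self.count += 1

    def _delayed(self, buf: np.ndarray, m: int) -> float:
        d = int(self.delay_steps[m])
        if self.count <= d:
            d = max(self.count - 1, 0)
        idx = (self.head - d) % buf.shape[0]
        return buf[idx, m]

    # -- control law ------------------------------------------------------

    def stimuli(self, t: float, y: np.ndarray, grf: np.ndarray,
                lean: float, lean_rate: float) -> np.ndarray:
        """Muscle stimuli in [0, 1] for the current control step.

        grf: total vertical GRF per leg (N); lean: forward trunk lean (rad).
        """
        cm = self.cm
        g = self.g
        S = np.empty(cm.nm)
        tot = grf[0] + grf[1]

        # ankle world x per leg identifies the trailing leg in double support
        ankle_x = [0.0, 0.0]
        for leg in (0, 1):
            thigh, shank = cm.leg_bodies[leg, 0], cm.leg_bodies[leg, 1]
            a_thigh = y[2] + y[thigh + 2]
            a_shank = a_thigh + y[shank + 2]
            # segment axes point along -y at zero joint angles
            ankle_x[leg] = (y[0] + 0.5 * math.sin(a_thigh)
                            + 0.5 * math.sin(a_shank))

        # contact state with hysteresis + phase transitions
        for leg in (0, 1):
            ls = self.legs[leg]
            if ls.in_contact:
                if grf[leg] < self.off_N:
                    ls.in_contact = False
                    # velocity-informed placement: the swing target reflects
                    # both the lean and its rate at swing onset
                    ls.lean_at_toeoff = lean + self.k_tdot * lean_rate
            else:
                if grf[leg] > self.on_N:
                    ls.in_contact = True
                    ls.contact_start = t
        double = self.legs[0].in_contact and self.legs[1].in_contact

        pd = self.k_p * (lean - self.theta_ref) + self.k_d * lean_rate

        n = cm.n
        q = y[:n]
        qd = y[n:2 * n]
        for leg in (0, 1):
            ls = self.legs[leg]
            other = self.legs[1 - leg]
            base = leg * 7
            xi = grf[leg] / tot if tot > 1e-9 else 0.5
            xi_c = 1.0 - xi
            shank = cm.leg_bodies[leg, 1]
            phi_k = math.pi + q[shank + 2]
            phid_k = qd[shank + 2]

            Fd = lambda mi: self._delayed(self.bufF, base + mi)
            Ld = lambda mi: self._delayed(self.bufL, base + mi)

            S0 = self.S0
            sol = S0[base + _SOL]
            ta = S0[base + _TA] + g.G_TA * max(Ld(_TA) - self.l_off["TA"], 0.0)
            gas = S0[base + _GAS]
            vas = S0[base + _VAS]
            ham = S0[base + _HAM]
            glu = S0[base + _GLU]
            hfl = S0[base + _HFL]

            if ls.in_contact:
                sol += g.G_SOL * Fd(_SOL)
                ta -= g.G_SOLTA * Fd(_SOL)
                gas += g.G_GAS * Fd(_GAS)
                vas += g.G_VAS * Fd(_VAS)
                if phi_k > self.phi_k_off and phid_k > 0.0:
                    vas -= g.k_phi * (phi_k - self.phi_k_off)
                trailing = double and ankle_x[leg] < ankle_x[1 - leg]
                if trailing:
                    # swing preparation: unload the knee and drive the hip
                    # forward in proportion to the contralateral load
                    vas -= self.k_ds * xi_c
                    hfl += self.k_sp * xi_c
                    glu -= self.k_sp * xi_c
                    ham -= self.k_sp * xi_c
                glu += xi * max(pd, 0.0)
                hfl += xi * max(-pd, 0.0)
                ham += xi * max(pd, 0.0)
                ham += g.G_HAM * Fd(_HAM)
            else:
                hfl += g.G_HFL * max(Ld(_HFL) - self.l_off["HFL"], 0.0)
                hfl -= g.G_HAMHFL * max(Ld(_HAM) - self.l_off["HAM"], 0.0)
                hfl += self.k_lean * (ls.lean_at_toeoff - self.theta_ref)
                ham += g.G_HAM * Fd(_HAM)
                glu += g.G_GLU * Fd(_GLU)

            for mi, v in ((_SOL, sol), (_TA, ta), (_GAS, gas), (_VAS, vas),
                          (_HAM, ham), (_GLU, glu), (_HFL, hfl)):
                S[base + mi] = min(max(v, 0.0), 1.0)
        return S
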