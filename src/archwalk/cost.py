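"""Multi-objective gait cost and the metabolic energy model.

The cost integrates, from the third step to the end of the simulation and
normalized by the distance walked over that window,

    J = (1/x_walk) * Int [ w1 E_met + w2 ACT^2 + w3 |GRF_rate|
                           + w4 |a_HAT| + w5 |T_kne| + w6 |T_ank| ] dt
        + w7 (t_sim_max - t_sim_des)^2

E_met is the whole-body metabolic rate from a Margaria-efficiency muscle
model (positive fiber work / 0.25, |negative fiber work| / 1.20, plus an
activation-squared maintenance heat and a basal rate); ACT^2 sums squared
activations over all muscles; GRF_rate is the time derivative of the
unfiltered total GRF magnitude of each leg, rectified; a_HAT is the trunk
CoM acceleration magnitude; T_kne/T_ank are the knee/ankle soft-limit stop
moments.  For a stable walk that reaches the desired simulation time the
penalty term is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import contact_intervals, filter_grf
from .params import CostWeights
from .simulate import Trajectory

TERMS = ("E_met", "ACT2", "GRF_rate", "a_HAT", "T_kne", "T_ank")


@dataclass
class CostBreakdown:
    """Cost value with per-term integrals and relative contributions."""

    total: float
    penalty: float
    terms: dict = field(default_factory=dict)  # weighted, distance-normalized
    rel: dict = field(default_factory=dict)  # percent of (total - penalty)
    x_walk: float = 0.0
    t_third_step: float = 0.0
    flag: str = ""


def metabolic_energy_rate(traj: Trajectory) -> np.ndarray:
    """Whole-body metabolic rate time series (W), always non-negative."""
    return traj.channels.met_rate.to_numpy()


def third_step_time(traj: Trajectory) -> tuple[float, int]:
    """Time of the third touch-down event (either leg).

    Returns (time, number of touch-downs found).
    """
    ch = traj.channels
    fs = traj.fs
    onsets = []
    for side in ("L", "R"):
        f = filter_grf(ch[side + "_grf_v"].to_numpy(), fs)
        iv = contact_intervals(f, on=20.0, off=10.0)
        for i_on, _ in iv:
            if traj.t[i_on] > 0.05:  # skip contacts present at the start
                onsets.append(i_on)
    onsets.sort()
    if len(onsets) < 3:
        return traj.t[-1], len(onsets)
    return float(traj.t[onsets[2]]), len(onsets)


def cost_function(traj: Trajectory, weights: CostWeights | None = None,
                  t_sim_des: float | None = None) -> CostBreakdown:
    """Evaluate the multi-objective gait cost on a finished trajectory."""
    w = weights or CostWeights()
    t_des = t_sim_des if t_sim_des is not None else traj.config.duration
    ch = traj.channels
    t = traj.t
    dt = t[1] - t[0]

    t3, nsteps = third_step_time(traj)
    flag = "" if nsteps >= 3 else "fewer than 3 steps"
    i3 = int(np.searchsorted(t, t3))
    sl = slice(min(i3, len(t) - 2), len(t))

    x_walk = float(ch.hat_x.iloc[-1] - ch.hat_x.iloc[sl.start])
    x_walk = max(x_walk, 1e-3)

    grf_rate = np.zeros(len(t))
    for side in ("L", "R"):
        mag = np.hypot(ch[side + "_grf_v"].to_numpy(),
                       ch[side + "_grf_h"].to_numpy())
        grf_rate += np.abs(np.gradient(mag, dt))
    a_hat = np.hypot(ch.hat_ax.to_numpy(), ch.hat_ay.to_numpy())
    t_kne = ch.L_Tstop_knee.to_numpy() + ch.R_Tstop_knee.to_numpy()
    t_ank = ch.L_Tstop_ank.to_numpy() + ch.R_Tstop_ank.to_numpy()

    integrands = {
        "E_met": w.w1 * ch.met_rate.to_numpy(),
        "ACT2": w.w2 * ch.act2.to_numpy(),
        "GRF_rate": w.w3 * grf_rate,
        "a_HAT": w.w4 * a_hat,
        "T_kne": w.w5 * t_kne,
        "T_ank": w.w6 * t_ank,
    }
    terms = {k: float(np.trapezoid(v[sl], dx=dt) / x_walk)
             for k, v in integrands.items()}
    penalty = w.w7 * (traj.t_sim_max - t_des) ** 2
    run = sum(terms.values())
    total = run + penalty
    rel = {k: (100.0 * v / run if run > 0 else np.nan)
           for k, v in terms.items()}
    return CostBreakdown(total=float(total), penalty=float(penalty),
                         terms=terms, rel=rel, x_walk=x_walk,
                         t_third_step=t3, flag=flag)
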