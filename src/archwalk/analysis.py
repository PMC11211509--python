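"""Gait analysis: filtering, cycle segmentation, powers, work, global measures.

Conventions: a gait cycle runs from heel strike to the next heel strike of
the same leg, detected on the filtered vertical GRF with a 1 N onset /
0.5 N release hysteresis.  All headline results are evaluated on the last
full cycle of the left leg.  Work integrals use the unfiltered force and
point-of-action velocity channels; filtering (zero-phase 2nd-order
Butterworth, 50 Hz) is only for plotting and event detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import Trajectory

ON_N = 1.0
OFF_N = 0.5


def filter_grf(series, fs: float, cutoff: float = 50.0, order: int = 2):
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    Raises for ``fs <= 2 * cutoff`` (cutoff infeasible).
    """
    x = np.asarray(series, dtype=float)
    if fs <= 2.0 * cutoff:
        raise ValueError(
            f"sampling rate {fs} Hz cannot support a {cutoff} Hz cutoff")
    b, a = sps.butter(order, cutoff / (fs / 2.0))
    return sps.filtfilt(b, a, x)


def contact_intervals(f, on: float = ON_N, off: float = OFF_N):
    """Hysteresis threshold detection: list of (i_on, i_off) index pairs.

    ``i_off`` is exclusive; an interval still open at the end of the series
    is closed at ``len(f)``.
    """
    f = np.asarray(f, dtype=float)
    out = []
    inside = f[0] > on
    start = 0 if inside else -1
    for i in range(1, len(f)):
        if not inside and f[i] > on:
            inside = True
            start = i
        elif inside and f[i] < off:
            inside = False
            out.append((start, i))
    if inside:
        out.append((start, len(f)))
    return out


@dataclass
class GaitCycle:
    """One heel-strike-to-heel-strike window of one leg (index slice)."""

    i0: int
    i1: int
    i_toe_off: int | None = None
    i_heel_off: int | None = None
    i_opp_td: int | None = None

    @property
    def sl(self) -> slice:
        return slice(self.i0, self.i1 + 1)


def segment_gait_cycles(t, grf_leg, grf_heel=None, grf_opp=None,
                        fs: float | None = None,
                        min_stance: float = 0.1) -> list[GaitCycle]:
    """Stride windows and intra-stride events from vertical GRFs.

    grf_leg: total vertical GRF of the analyzed leg; grf_heel: its heel
    contact element (for heel-off); grf_opp: contralateral leg total (for
    opposite touch-down).  GRFs are low-pass filtered before thresholding.
    Contacts shorter than ``min_stance`` (s) are treated as swing-phase
    ground grazing, not steps.  Raises if no full cycle is present.
    """
    t = np.asarray(t)
    if fs is None:
        fs = 1.0 / (t[1] - t[0])
    f = filter_grf(grf_leg, fs)
    iv = contact_intervals(f)
    iv = [p for p in iv if t[min(p[1], len(t) - 1)] - t[p[0]] >= min_stance]
    if len(iv) < 2:
        raise ValueError("fewer than one full gait cycle in the trajectory")
    fh = filter_grf(grf_heel, fs) if grf_heel is not None else None
    fo = filter_grf(grf_opp, fs) if grf_opp is not None else None
    cycles = []
    for (a0, a1), (b0, _) in zip(iv[:-1], iv[1:]):
        c = GaitCycle(i0=a0, i1=b0, i_toe_off=a1)
        if fh is not None:
            heel_iv = [p for p in contact_intervals(fh) if p[0] >= a0 - 5
                       and p[0] < a1]
            if heel_iv:
                c.i_heel_off = heel_iv[0][1]
        if fo is not None:
            opp_on = [p[0] for p in contact_intervals(fo)
                      if a0 < p[0] <= b0]
            if opp_on:
                c.i_opp_td = opp_on[0]
        cycles.append(c)
    return cycles


def last_left_cycle(traj: Trajectory) -> GaitCycle:
    """The last full gait cycle of the left leg."""
    ch = traj.channels
    cycles = segment_gait_cycles(traj.t, ch.L_grf_v.to_numpy(),
                                 ch.L_Fv_H.to_numpy(),
                                 ch.R_grf_v.to_numpy())
    return cycles[-1]


def power_amplification(P_ank) -> float:
    """Peak positive push-off power over peak negative stance power.

    Undefined (raises) when the series has no negative phase.
    """
    P = np.asarray(P_ank, dtype=float)
    pos = P[P > 0]
    neg = P[P < 0]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("power amplification undefined: single-signed power")
    return float(abs(pos.max()) / abs(neg.min()))


def ankle_power(traj: Trajectory, side: str = "L") -> np.ndarray:
    """Ankle joint power (W): net joint moment times angular velocity."""
    leg = traj.leg(side)
    return (leg.tau_ank * leg.phid_ank).to_numpy()


def xcorr_to_reference(sim, ref) -> float:
    """Maximum normalized cross-correlation between two series in [-1, 1].

    Both series must live on the same (stride-normalized) grid; they are
    mean-removed and compared over all circular lags.
    """
    x = np.asarray(sim, dtype=float)
    y = np.asarray(ref, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share one stride-normalized grid")
    x = x - x.mean()
    y = y - y.mean()
    sx, sy = np.linalg.norm(x), np.linalg.norm(y)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("cross-correlation undefined for zero-variance input")
    n = len(x)
    c = np.fft.irfft(np.fft.rfft(x, n) * np.conj(np.fft.rfft(y, n)), n)
    return float(c.max() / (sx * sy))


def resample_cycle(t, x, i0, i1, npts: int = 101):
    """Resample one cycle onto a normalized-time grid [0, 100]% stride."""
    tt = t[i0:i1 + 1]
    xx = x[i0:i1 + 1]
    s = (tt - tt[0]) / (tt[-1] - tt[0])
    return np.interp(np.linspace(0, 1, npts), s, xx)


@dataclass
class GaitMetrics:
    """Global gait measures of one steady stride."""

    t_s: float  # stride time (s)
    l_s: float  # stride length (m)
    v_HAT: float  # mean upper-body velocity (m/s)
    DF: float  # duty factor
    CoT: float  # cost of transport (J / (kg m))
    P_amp: float  # ankle power amplification
    work: dict = field(default_factory=dict)  # per-element work (J/kg)

    def as_series(self) -> pd.Series:
        d = {"t_s": self.t_s, "l_s": self.l_s, "v_HAT": self.v_HAT,
             "DF": self.DF, "CoT": self.CoT, "P_amp": self.P_amp}
        d.update({f"W_{k}": v for k, v in self.work.items()})
        return pd.Series(d)


def work_breakdown(traj: Trajectory, cycle: GaitCycle | None = None,
                   side: str = "L") -> dict[str, float]:
    """Per-contact-element and per-ligament work over one stride (J/kg).

    Contact work integrates force times point-of-action velocity
    (unfiltered); ligament work is the net work done by PF and PL on the
    skeleton (elastic return minus storage minus damping loss), so a
    negative value is net dissipation.
    """
    cycle = cycle or last_left_cycle(traj)
    leg = traj.leg(side)
    sl = cycle.sl
    dt = traj.t[1] - traj.t[0]
    m = traj.total_mass
    out = {}
    for name, col in (("heel", "pow_H"), ("ball", "pow_B"), ("toe", "pow_T")):
        out[name] = float(np.trapezoid(leg[col].to_numpy()[sl], dx=dt) / m)
    out["PF"] = float(np.trapezoid(leg.pf_pow.to_numpy()[sl], dx=dt) / m)
    out["PL"] = float(np.trapezoid(leg.pl_pow.to_numpy()[sl], dx=dt) / m)
    out["ligaments"] = out["PF"] + out["PL"]
    out["contacts"] = out["heel"] + out["ball"] + out["toe"]
    out["total"] = out["contacts"] + out["ligaments"]
    return out


def global_measures(traj: Trajectory, cycle: GaitCycle | None = None) -> GaitMetrics:
    """Stride time/length, HAT velocity, duty factor, CoT and P_amp for the
    last full left-leg cycle (or an explicit cycle)."""
    cycle = cycle or last_left_cycle(traj)
    ch = traj.channels
    t = traj.t
    i0, i1 = cycle.i0, cycle.i1
    t_s = t[i1] - t[i0]
    x = ch.hat_x.to_numpy()
    l_s = x[i1] - x[i0]
    v = l_s / t_s
    t_stance = (t[cycle.i_toe_off] - t[i0]) if cycle.i_toe_off else np.nan
    DF = t_stance / t_s
    dt = t[1] - t[0]
    E = np.trapezoid(ch.met_rate.to_numpy()[cycle.sl], dx=dt)
    CoT = E / (traj.total_mass * l_s)
    P = ankle_power(traj)[cycle.sl]
    try:
        P_amp = power_amplification(P)
    except ValueError:
        P_amp = np.nan
    return GaitMetrics(t_s=float(t_s), l_s=float(l_s), v_HAT=float(v),
                       DF=float(DF), CoT=float(CoT), P_amp=float(P_amp),
                       work=work_breakdown(traj, cycle))


def cop_progression(traj: Trajectory, cycle: GaitCycle | None = None,
                    side: str = "L") -> np.ndarray:
    """CoP x within the foot, relative to the heel point at touch-down.

    NaN where the leg carries no load.
    """
    cycle = cycle or last_left_cycle(traj)
    leg = traj.leg(side)
    sl = cycle.sl
    F = leg[["Fv_H", "Fv_B", "Fv_T"]].to_numpy()[sl]
    X = leg[["px_H", "px_B", "px_T"]].to_numpy()[sl]
    X = np.where(np.isnan(X), 0.0, X)
    tot = F.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = (F * X).sum(axis=1) / tot
    heel0 = leg.px_H.to_numpy()[cycle.i0]
    return np.where(tot > OFF_N, cop - heel0, np.nan)


def max_toe_flexion_deg(traj: Trajectory, cycle: GaitCycle | None = None,
                        side: str = "L") -> float:
    """Maximum toe dorsiflexion angle over the cycle (deg)."""
    cycle = cycle or last_left_cycle(traj)
    leg = traj.leg(side)
    return float(np.degrees(leg.q_tj.to_numpy()[cycle.sl].max()))


def mtj_excursion_deg(traj: Trajectory, cycle: GaitCycle | None = None,
                      side: str = "L", stance_only: bool = True) -> float:
    """Peak midtarsal-joint angular excursion from neutral (deg)."""
    cycle = cycle or last_left_cycle(traj)
    leg = traj.leg(side)
    sl = (slice(cycle.i0, cycle.i_toe_off + 1)
          if stance_only and cycle.i_toe_off else cycle.sl)
    return float(np.degrees(np.abs(leg.q_mtj.to_numpy()[sl]).max()))


def vgrf_peaks(traj: Trajectory, cycle: GaitCycle | None = None,
               side: str = "L", filtered: bool = True):
    """(initial loading peak, later maxima) of the stance vertical GRF (N).

    Returns the unfiltered initial loading peak and the list of local
    maxima of the (optionally filtered) stance vGRF for M-shape checks.
    """
    cycle = cycle or last_left_cycle(traj)
    leg = traj.leg(side)
    f_raw = leg.grf_v.to_numpy()
    i0 = cycle.i0
    i1 = cycle.i_toe_off or cycle.i1
    stance = f_raw[i0:i1 + 1]
    # initial loading peak: first local max of the raw signal
    first_peak = None
    for i in range(1, len(stance) - 1):
        if stance[i] >= stance[i - 1] and stance[i] > stance[i + 1]:
            first_peak = float(stance[i])
            break
    fs = 1.0 / (traj.t[1] - traj.t[0])
    f = filter_grf(f_raw, fs)[i0:i1 + 1] if filtered else stance
    pk, _ = sps.find_peaks(f, height=0.3 * f.max(), prominence=0.02 * f.max())
    return first_peak, f[pk]


def load_reference_kinematics(path=None) -> pd.DataFrame:
    """Stride-normalized reference joint kinematics (deg).

    Defaults to the bundled *synthetic* reference curves (a smooth stand-in
    with the gross features of averaged human sagittal kinematics); a real
    dataset in the same two-column-per-joint CSV layout can be supplied
    instead.
    """
    from pathlib import Path

    p = Path(path) if path else (Path(__file__).parent / "data"
                                 / "reference_gait_synthetic.csv")
    return pd.read_csv(p)


def kinematic_correlations(traj: Trajectory, reference=None,
                           cycle: GaitCycle | None = None) -> dict[str, float]:
    """Maximum normalized cross-correlation of hip/knee/ankle angles of the
    last left cycle against stride-normalized reference curves."""
    ref = reference if reference is not None else load_reference_kinematics()
    cycle = cycle or last_left_cycle(traj)
    leg = traj.leg("L")
    npts = len(ref)
    out = {}
    for joint, col, conv in (("hip", "phi_hip", lambda x: 180.0 - np.degrees(x)),
                             ("knee", "phi_knee", lambda x: 180.0 - np.degrees(x)),
                             ("ankle", "phi_ank", lambda x: np.degrees(x) - 90.0)):
        sim = conv(leg[col].to_numpy())
        simr = resample_cycle(traj.t, sim, cycle.i0, cycle.i1, npts)
        out[joint] = xcorr_to_reference(simr, ref[joint + "_deg"].to_numpy())
    return out
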