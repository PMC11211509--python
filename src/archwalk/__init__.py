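"""archwalk: predictive reflex-controlled neuromuscular walking simulation
with interchangeable planar foot models (rigid to windlass-coupled)."""

__version__ = "0.1.0"

from .params import (  # noqa: F401
    FOOT_KINDS,
    ContactParams,
    CostWeights,
    FootGeometry,
    FootInertia,
    LigamentParams,
    ReflexGains,
    SimConfig,
    has_mobile_arch,
    has_toe,
    is_coupled,
    total_body_mass,
)
from .foot import (  # noqa: F401
    FootJointState,
    FootModel,
    build_foot,
    ligament_generalized_forces,
    ligament_path_lengths,
    residual_joint_torque,
)
from .ligament import ligament_force  # noqa: F401
from .contact import (  # noqa: F401
    center_of_pressure,
    contact_point,
    horizontal_force,
    vertical_force,
)


def __getattr__(name):
    # heavyweight modules (numba compilation) are imported lazily
    if name in ("simulate", "Trajectory"):
        from . import simulate as _sim

        return getattr(_sim, name)
    if name in ("global_measures", "work_breakdown", "power_amplification",
                "xcorr_to_reference", "last_left_cycle"):
        from . import analysis as _an

        return getattr(_an, name)
    if name in ("cost_function", "metabolic_energy_rate"):
        from . import cost as _cost

        return getattr(_cost, name)
    if name in ("optimize_gains", "GASettings"):
        from . import optimize as _opt

        return getattr(_opt, name)
    if name in ("compression_test", "calibrate_A_PL"):
        from . import testbench as _tb

        return getattr(_tb, name)
    raise AttributeError(name)
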