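"""Planar multibody engine: Lagrangian oracle and energy conservation."""

import math

import numpy as np
import pytest

from archwalk import _core


def _random_chain(rng, nb=3):
    """A floating-base chain of nb bodies with random geometry."""
    parent = np.arange(-1, nb - 1, dtype=np.int64)
    parent[0] = 0  # root convention: parent[0] unused
    anchor = rng.uniform(-0.4, 0.4, (nb, 2))
    anchor[0] = 0.0
    com = rng.uniform(-0.3, 0.3, (nb, 2))
    mass = rng.uniform(0.5, 5.0, nb)
    inertia = rng.uniform(0.01, 0.5, nb)
    return parent, anchor, com, mass, inertia


def engine_qdd(q, qd, parent, anchor, com, mass, inertia, g=9.81):
    M, rhs0, *_ = _core._mass_bias(q, qd, parent, anchor, com, mass, inertia, g)
    return np.linalg.solve(M, rhs0)


def test_against_sympy_lagrangian_oracle(rng):
    """qdd of a 3-body floating chain matches a symbolic Lagrangian model."""
    import sympy as sp
    from sympy.physics.mechanics import dynamicsymbols, LagrangesMethod

    parent, anchor, com, mass, inertia = _random_chain(rng, 3)

    t = sp.symbols("t")
    qs = dynamicsymbols("x y th0 q1 q2")
    qds = [sp.diff(s, t) for s in qs]
    x, y, th0, q1, q2 = qs

    def rot(a):
        return sp.Matrix([[sp.cos(a), -sp.sin(a)], [sp.sin(a), sp.cos(a)]])

    g = sp.Float(9.81)
    o = [sp.Matrix([x, y])]
    th = [th0, th0 + q1, th0 + q1 + q2]
    for i in (1, 2):
        o.append(o[i - 1] + rot(th[i - 1]) * sp.Matrix(anchor[i]))
    L = 0
    for i in range(3):
        c = o[i] + rot(th[i]) * sp.Matrix(com[i])
        v = c.diff(t)
        w = sp.diff(th[i], t)
        L += (sp.Rational(1, 2) * mass[i] * (v.T * v)[0]
              + sp.Rational(1, 2) * inertia[i] * w**2
              - mass[i] * g * c[1])
    lm = LagrangesMethod(sp.simplify(L), qs)
    lm.form_lagranges_equations()
    Mm = lm.mass_matrix
    F = lm.forcing
    fM = sp.lambdify(qs + qds, Mm, "numpy")
    fF = sp.lambdify(qs + qds, F, "numpy")

    for _ in range(3):
        q = rng.uniform(-1.0, 1.0, 5)
        qd = rng.uniform(-2.0, 2.0, 5)
        args = list(q) + list(qd)
        ref = np.linalg.solve(np.array(fM(*args), float),
                              np.array(fF(*args), float).ravel())
        got = engine_qdd(q, qd, parent, anchor, com, mass, inertia)
        assert np.allclose(got, ref, rtol=1e-9, atol=1e-9)


def _energy(q, qd, parent, anchor, com, mass, inertia, g=9.81):
    th, om, o, vo = _core._fk(q, qd, parent, anchor)
    E = 0.0
    for b in range(len(mass)):
        c, s = math.cos(th[b]), math.sin(th[b])
        cx = c * com[b, 0] - s * com[b, 1]
        cy = s * com[b, 0] + c * com[b, 1]
        vx = vo[b, 0] - om[b] * cy
        vy = vo[b, 1] + om[b] * cx
        E += 0.5 * mass[b] * (vx * vx + vy * vy) + 0.5 * inertia[b] * om[b] ** 2
        E += mass[b] * g * (o[b, 1] + cy)
    return E


def test_passive_energy_conservation(rng):
    """A passive chain in free fall conserves total mechanical energy."""
    parent, anchor, com, mass, inertia = _random_chain(rng, 4)
    n = 4 + 2
    q = rng.uniform(-0.5, 0.5, n)
    qd = rng.uniform(-1.0, 1.0, n)
    E0 = _energy(q, qd, parent, anchor, com, mass, inertia)
    dt = 2e-5
    for _ in range(4000):  # RK4, 80 ms of free flight
        k1q, k1v = qd, engine_qdd(q, qd, parent, anchor, com, mass, inertia)
        k2q = qd + 0.5 * dt * k1v
        k2v = engine_qdd(q + 0.5 * dt * k1q, k2q, parent, anchor, com, mass, inertia)
        k3q = qd + 0.5 * dt * k2v
        k3v = engine_qdd(q + 0.5 * dt * k2q, k3q, parent, anchor, com, mass, inertia)
        k4q = qd + dt * k3v
        k4v = engine_qdd(q + dt * k3q, k4q, parent, anchor, com, mass, inertia)
        q = q + dt / 6 * (k1q + 2 * k2q + 2 * k3q + k4q)
        qd = qd + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
    E1 = _energy(q, qd, parent, anchor, com, mass, inertia)
    assert abs(E1 - E0) < 1e-6 * max(abs(E0), 1.0)


def test_point_force_jacobian_consistency(rng):
    """Generalized force of a point force matches the virtual-work gradient."""
    parent, anchor, com, mass, inertia = _random_chain(rng, 3)
    n = 5
    q = rng.uniform(-0.5, 0.5, n)
    loc = np.array([0.2, -0.1])
    F = np.array([3.0, -7.0])

    def point(qv):
        th, om, o, vo = _core._fk(qv, np.zeros(n), parent, anchor)
        b = 2
        c, s = math.cos(th[b]), math.sin(th[b])
        return np.array([o[b, 0] + c * loc[0] - s * loc[1],
                         o[b, 1] + s * loc[0] + c * loc[1]])

    th, om, o, vo = _core._fk(q, np.zeros(n), parent, anchor)
    Q = np.zeros(n)
    p = point(q)
    _core._apply_point_force(Q, 2, p[0], p[1], F[0], F[1], parent, o)
    h = 1e-7
    for j in range(n):
        qp = q.copy(); qp[j] += h
        qm = q.copy(); qm[j] -= h
        dW = (point(qp) - point(qm)) / (2 * h) @ F
        assert Q[j] == pytest.approx(dW, rel=1e-6, abs=1e-8)
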