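"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately use different algorithms from the package
(latitude-band surface quadrature instead of Fibonacci points; explicit
permutation enumeration; rotation grid search) so that agreement is
evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from fibrilstab import (
    Atom,
    FibrilModel,
    FragmentId,
    GateState,
    HelicalParameters,
    LayerSpec,
    TraceStep,
    attr_like_layer_spec,
    make_fibril,
    make_layer,
)


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def closed_layer() -> FibrilModel:
    return make_layer(attr_like_layer_spec(GateState.CLOSED))


@pytest.fixture(scope="session")
def closed_fibril() -> FibrilModel:
    return make_fibril(
        attr_like_layer_spec(GateState.CLOSED), HelicalParameters(-1.26, 4.81), 3
    )


@pytest.fixture(scope="session")
def open_fibril() -> FibrilModel:
    return make_fibril(
        attr_like_layer_spec(GateState.OPEN), HelicalParameters(-1.26, 4.81), 3
    )


def small_layer_spec(n_res: int = 20, gate_state: GateState = GateState.CLOSED) -> LayerSpec:
    """Compact two-fragment layer for fast SASA/stacking tests."""
    from fibrilstab.synthetic import _meander_trace

    trace = (
        _meander_trace(10, strand_len=5)
        + [TraceStep(turn=-90.0, step=10.0)]
        + _meander_trace(n_res - 10, strand_len=5)[1:]
    )
    assert len(trace) == n_res
    return LayerSpec(
        trace=trace,
        sequence="V" * n_res,
        split=10,
        gate=(11, 11),  # no gate: plain two-fragment layer
        gate_state=gate_state,
        n_start=11,
        c_start=60,
    )


@pytest.fixture(scope="session")
def small_fibril() -> FibrilModel:
    return make_fibril(small_layer_spec(), HelicalParameters(-1.3, 4.8), 5)


def toy_atoms(coords, radius=1.9) -> list[Atom]:
    """Bare carbon atoms at given coordinates (one fake residue each)."""
    return [
        Atom(
            element="C",
            name="CA",
            residue_number=i + 1,
            residue_name="ALA",
            fragment_id=FragmentId.N_TERM,
            layer_index=0,
            position=tuple(map(float, c)),
            radius=radius,
        )
        for i, c in enumerate(coords)
    ]


# ---------------------------------------------------------------- oracles
def sasa_grid_oracle(coords, radii, probe=1.4, arc=0.1) -> np.ndarray:
    """Per-atom SASA by latitude-band quadrature at ``arc`` Angstrom surface
    resolution — an independent integration scheme for small clusters."""
    coords = np.asarray(coords, float).reshape(-1, 3)
    radii = np.asarray(radii, float)
    n = len(coords)
    exp_r = radii + probe
    out = np.zeros(n)
    for i in range(n):
        R = exp_r[i]
        n_theta = max(4, int(math.ceil(math.pi * R / arc)))
        d_theta = math.pi / n_theta
        area = 0.0
        for it in range(n_theta):
            theta = (it + 0.5) * d_theta
            ring_r = R * math.sin(theta)
            circ = 2.0 * math.pi * ring_r
            n_phi = max(1, int(math.ceil(circ / arc)))
            d_phi = 2.0 * math.pi / n_phi
            phis = (np.arange(n_phi) + 0.5) * d_phi
            pts = coords[i] + np.column_stack(
                [
                    ring_r * np.cos(phis),
                    ring_r * np.sin(phis),
                    np.full(n_phi, R * math.cos(theta)),
                ]
            )
            exposed = np.ones(n_phi, dtype=bool)
            for j in range(n):
                if j == i:
                    continue
                d2 = ((pts - coords[j]) ** 2).sum(axis=1)
                exposed &= d2 > exp_r[j] ** 2
            # each point represents a patch R^2 sin(theta) dtheta dphi
            area += exposed.sum() * (R**2) * math.sin(theta) * d_theta * d_phi
        out[i] = area
    return out


def mann_whitney_exact_oracle(a, b) -> tuple[float, float]:
    """(U, two-sided p) by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    m = len(a)

    def u_of(group_a_idx):
        ga = [pooled[i] for i in group_a_idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(group_a_idx)]
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in ga for y in gb
        )

    u_obs = sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b)
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), m)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs + 1e-12) / total
    p_ge = sum(1 for u in us if u >= u_obs - 1e-12) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def rotation_grid_min_rmsd(a, b, n_steps=24) -> float:
    """Minimum rmsd over a coarse grid of Euler-angle rotations (after
    centroid removal) — an upper-bounding oracle for the Kabsch optimum."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    angles = np.linspace(0.0, 2.0 * math.pi, n_steps, endpoint=False)
    betas = np.linspace(0.0, math.pi, n_steps // 2 + 1)
    best = np.inf
    for alpha in angles:
        ca, sa = math.cos(alpha), math.sin(alpha)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for beta in betas:
            cb, sb = math.cos(beta), math.sin(beta)
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for gamma in angles:
                cg, sg = math.cos(gamma), math.sin(gamma)
                rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                rot = rz1 @ ry @ rz2
                rmsd = math.sqrt(((b0 - a0 @ rot.T) ** 2).sum() / len(a0))
                if rmsd < best:
                    best = rmsd
    return best
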