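"""Helical symmetry of cross-beta fibrils.

Consecutive layers of an amyloid fibril are related by a screw operator:
a rotation (*twist*, degrees per subunit, negative = left-handed) about the
fibril axis followed by a translation (*rise*, Angstrom per subunit) along
it.  The *crossover distance* — the axial length over which the fibril's
projection rotates by 180 degrees, the quantity read directly off
micrographs — follows as ``(180/|twist|) * rise``.

The axis convention is the z-axis through the centroid of the reference
layer's C-alpha atoms, the standard orientation of deposited fibril models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model import Atom, FibrilModel, ModelError

#: Below this |twist| (degrees) a stack is treated as untwisted.
UNTWISTED_TOL = 0.01


class UntwistedError(ModelError):
    """Crossover distance is undefined: the fibril lacks a twist."""


class CorrespondenceError(ModelError):
    """Layers cannot be matched atom-by-atom."""


@dataclass(frozen=True)
class HelicalParameters:
    """Screw operator relating consecutive fibril layers.

    twist : degrees per subunit, signed (negative = left-handed)
    rise : Angstrom per subunit
    twist_sd, rise_sd : dispersion over consecutive layer pairs when the
        parameters were estimated from a model (0 for exact parameters).
    """

    twist: float
    rise: float
    twist_sd: float = 0.0
    rise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")

    @property
    def is_twisted(self) -> bool:
        return abs(self.twist) >= UNTWISTED_TOL

    @property
    def crossover(self) -> float:
        return crossover_distance(self.twist, self.rise)


def crossover_distance(twist: float, rise: float) -> float:
    """Crossover distance (Angstrom) from twist (deg/subunit) and rise (A).

    ``c = (180 / |twist|) * rise``.  Report to the nearest Angstrom when
    comparing with values read from micrographs.

    Raises
    ------
    UntwistedError
        For an (effectively) untwisted fibril, where the projection never
        completes a half turn and the crossover is infinite.
    """
    if rise <= 0:
        raise ValueError("rise must be positive")
    if abs(twist) < UNTWISTED_TOL:
        raise UntwistedError(
            f"twist {twist} deg/subunit is below {UNTWISTED_TOL}: "
            "straight (untwisted) fibrils have no finite crossover"
        )
    return (180.0 / abs(twist)) * rise


def _axis_origin(layer: FibrilModel) -> np.ndarray:
    """Helical-axis origin: centroid of the layer's C-alpha atoms (x, y only)."""
    ca = np.array(
        [a.position for a in layer.atoms if a.name == "CA"], dtype=float
    )
    if ca.size == 0:  # fall back to all atoms for CA-free fixtures
        ca = layer.coords()
    c = ca.mean(axis=0)
    return np.array([c[0], c[1], 0.0])


def expand_symmetry(
    layer: FibrilModel, params: HelicalParameters, n_layers: int
) -> FibrilModel:
    """Stack ``n_layers`` copies of a single layer under the screw operator.

    Layer ``k`` is the input rotated by ``k * twist`` about the z-axis
    through the layer's C-alpha centroid and translated by ``k * rise``
    along z.  Layer 0 is the input itself.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if not layer.atoms:
        raise ModelError("cannot expand an empty layer")
    if layer.layers != 1:
        raise ModelError("expand_symmetry expects a single-layer model")

    origin = _axis_origin(layer)
    base = layer.coords() - origin
    atoms: list[Atom] = []
    for k in range(n_layers):
        ang = math.radians(k * params.twist)
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        moved = base @ rot.T + origin
        moved[:, 2] += k * params.rise
        for a, pos in zip(layer.atoms, moved):
            atoms.append(replace(a, layer_index=k, position=tuple(pos)))
    out = FibrilModel(atoms, fold=layer.fold, helical=params)
    return out


def _screw_from_transform(rot: np.ndarray, trans: np.ndarray) -> tuple[float, float]:
    """Signed twist (deg) about the rotation's own axis and rise along it.

    The axis is oriented to +z so that the sign convention matches the
    left-handed-negative convention of fibril depositions.
    """
    # rotation angle from the trace; axis from the antisymmetric part
    cos_t = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    angle = math.acos(cos_t)
    if angle < 1e-9:
        return 0.0, float(trans[2])
    axis = np.array(
        [rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]]
    )
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        # angle ~ pi; take the dominant eigenvector of (R + I)
        w, v = np.linalg.eigh(rot + np.eye(3))
        axis = v[:, np.argmax(w)]
    else:
        axis = axis / norm
    if axis[2] < 0:  # orient axis along +z
        axis = -axis
        angle = -angle
    else:
        # sin(angle) carried the sign already via the antisymmetric part
        pass
    rise = float(trans @ axis)
    return math.degrees(angle), rise


def estimate_helical_parameters(model: FibrilModel) -> HelicalParameters:
    """Recover twist and rise from a stacked model (>= 2 layers).

    Each consecutive layer pair is superposed by least squares (Kabsch);
    the rotation angle about the best-fit axis (oriented to +z) and the
    translation along it give per-pair twist and rise.  The mean over all
    pairs is returned with the standard deviation as dispersion.

    Raises
    ------
    CorrespondenceError
        If consecutive layers do not carry matching atom sets.
    """
    from .compare import kabsch_superpose  # local import: compare depends on model only

    n = model.layers
    if n < 2:
        raise ModelError("need at least 2 layers to estimate helical parameters")
    twists, rises = [], []
    prev = model.layer(0)
    for k in range(1, n):
        cur = model.layer(k)
        if prev.n_atoms != cur.n_atoms or [
            (a.name, a.residue_number) for a in prev.atoms
        ] != [(a.name, a.residue_number) for a in cur.atoms]:
            raise CorrespondenceError(f"layers {k-1} and {k} have mismatched atom sets")
        a = prev.coords()
        b = cur.coords()
        rot, trans, _ = kabsch_superpose(a, b)  # b ~ rot @ a + trans
        twist, rise = _screw_from_transform(rot, trans)
        twists.append(twist)
        rises.append(rise)
        prev = cur
    twist = float(np.mean(twists))
    rise = float(np.mean(rises))
    if abs(twist) < UNTWISTED_TOL:
        twist = 0.0
    return HelicalParameters(
        twist=twist,
        rise=rise,
        twist_sd=float(np.std(twists)),
        rise_sd=float(np.std(rises)),
    )
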