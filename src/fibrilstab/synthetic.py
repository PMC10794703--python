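"""Synthetic fibril models and particle tables.

Real inputs to the analysis are deposited fibril coordinates and
refinement particle tables; neither is needed to exercise the pipeline.
This module generates (a) idealized cross-beta layers — a self-avoiding
2D C-alpha trace at z = 0, decorated with an ideal-geometry backbone and
C-beta atoms, two fragments per layer, with a configurable channel-gate
conformation — stacked under a helical operator, and (b) STAR particle
tables whose segments lie on smooth per-filament curves with known
(ground-truth) polymorph composition per filament.

Synthetic layers are backbone-level (N, CA, C, O, CB) by design: they test
geometry and scoring code paths, not side-chain packing.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .helical import HelicalParameters, expand_symmetry
from .model import Atom, FibrilModel, FragmentId, ModelError

CA_CA_STEP = 3.8  # trans peptide C-alpha spacing, Angstrom
MIN_NONADJACENT_DIST = 3.5

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_RADII = {"C": 1.9, "N": 1.7, "O": 1.4}


class GateState(enum.Enum):
    CLOSED = "CLOSED"
    OPEN = "OPEN"
    ABSENT = "ABSENT"
    BROKEN = "BROKEN"


class GeometryError(ModelError):
    """The requested trace self-intersects."""


@dataclass(frozen=True)
class TraceStep:
    """One turtle instruction of the 2D C-alpha trace: turn, then step."""

    turn: float = 0.0  # degrees, applied before stepping
    step: float = CA_CA_STEP  # Angstrom


@dataclass
class LayerSpec:
    """Recipe for one idealized fibril layer.

    ``trace[i]`` places residue i; ``split`` is the first index of the
    C-terminal fragment; ``gate`` is the index slice (within the trace)
    holding the channel gate, rewritten according to ``gate_state``;
    residue numbers are ``n_start + i`` before the split and
    ``c_start + (i - split)`` after it.
    """

    trace: list[TraceStep]
    sequence: str
    split: int
    gate: tuple[int, int]  # half-open [start, stop) trace-index interval
    gate_state: GateState = GateState.CLOSED
    n_start: int = 11
    c_start: int = 57
    #: in-plane unit direction the rebuilt gate heads into (None = away
    #: from the centroid of the non-gate residues)
    gate_direction: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.trace) != len(self.sequence):
            raise ValueError("trace length must equal sequence length")
        if not (0 < self.split < len(self.trace)):
            raise ValueError("split must fall inside the trace")


def _turtle(trace: list[TraceStep]) -> np.ndarray:
    """2D C-alpha path from turtle instructions, starting at the origin
    heading +x; ``trace[0]``'s step is ignored (it places the start)."""
    pos = np.zeros(2)
    heading = 0.0
    pts = [pos.copy()]
    for ins in trace[1:]:
        heading += math.radians(ins.turn)
        pos = pos + ins.step * np.array([math.cos(heading), math.sin(heading)])
        pts.append(pos.copy())
    return np.array(pts)


def _check_self_avoiding(ca: np.ndarray, split: int) -> None:
    n = ca.shape[0]
    if n < 3:
        return
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    ii, jj = np.triu_indices(n, k=2)
    # the split is a chain break, not a bonded pair, but the fragments may
    # legitimately pack close; enforce the same clearance everywhere
    bad = d[ii, jj] < MIN_NONADJACENT_DIST
    if bad.any():
        i, j = ii[bad][0], jj[bad][0]
        raise GeometryError(
            f"trace self-intersects: residues {i} and {j} at {d[i, j]:.2f} A"
        )


def _rot2(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _gate_positions(
    base: np.ndarray,
    g0: int,
    g1: int,
    state: GateState,
    direction: tuple[float, float] | None = None,
) -> np.ndarray:
    """Replacement 2D positions for the gate residues.

    The first gate residue stays anchored at its base position; the rest
    are rebuilt heading into ``direction`` (default: away from the
    centroid of the non-gate residues): straight for the OPEN state,
    turning 72 degrees per step for the pentagon-like CLOSED closure.
    """
    anchor = base[g0]
    if direction is None:
        non_gate = np.concatenate([base[:g0], base[g1:]])
        out = anchor - non_gate.mean(axis=0)
    else:
        out = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(out)
    out = out / norm if norm > 1e-9 else np.array([1.0, 0.0])
    heading = math.atan2(out[1], out[0])
    pts = [anchor]
    pos = anchor.copy()
    for _ in range(g1 - g0 - 1):
        if state is GateState.CLOSED:
            heading += math.radians(72.0)
        pos = pos + CA_CA_STEP * np.array([math.cos(heading), math.sin(heading)])
        pts.append(pos.copy())
    return np.array(pts)


def make_layer(spec: LayerSpec) -> FibrilModel:
    """Build one idealized fibril layer from a :class:`LayerSpec`.

    C-alpha atoms follow the 2D trace at z = 0; N, C, O are placed by
    ideal in-plane geometry and C-beta atoms alternate above/below the
    layer plane (the cross-beta side-chain alternation).  The gate
    sub-trace is rewritten per the gate state — CLOSED: pentagon-like
    closure; OPEN: extended; ABSENT: residues removed; BROKEN: start
    truncated — leaving every non-gate residue at identical coordinates
    across states.  Raises :class:`GeometryError` on a self-intersecting
    trace.
    """
    numbers = [
        spec.n_start + i if i < spec.split else spec.c_start + (i - spec.split)
        for i in range(len(spec.trace))
    ]
    seq = list(spec.sequence)
    ca2d = _turtle(spec.trace)
    g0, g1 = spec.gate
    keep = np.ones(len(spec.trace), dtype=bool)
    if g1 > g0:
        if spec.gate_state in (GateState.CLOSED, GateState.OPEN):
            ca2d = ca2d.copy()
            ca2d[g0:g1] = _gate_positions(
                ca2d, g0, g1, spec.gate_state, spec.gate_direction
            )
        elif spec.gate_state is GateState.ABSENT:
            keep[g0:g1] = False
        elif spec.gate_state is GateState.BROKEN:
            keep[g0 : g0 + (g1 - g0) // 2] = False
    ca2d = ca2d[keep]
    numbers = [n for n, k in zip(numbers, keep) if k]
    seq = [s for s, k in zip(seq, keep) if k]
    split = int(keep[: spec.split].sum())
    _check_self_avoiding(ca2d, split)

    n = ca2d.shape[0]
    atoms: list[Atom] = []
    for i in range(n):
        frag = FragmentId.N_TERM if i < split else FragmentId.C_TERM
        resnum = numbers[i]
        resname = ONE_TO_THREE.get(seq[i].upper(), "ALA")
        p = ca2d[i]
        # local chain directions (2D unit vectors)
        d_next = ca2d[i + 1] - p if i + 1 < n else p - ca2d[i - 1]
        d_prev = p - ca2d[i - 1] if i > 0 else ca2d[i + 1] - p
        d_next = d_next / np.linalg.norm(d_next)
        d_prev = d_prev / np.linalg.norm(d_prev)

        def at(name: str, element: str, xy: np.ndarray, z: float) -> Atom:
            return Atom(
                element=element,
                name=name,
                residue_number=resnum,
                residue_name=resname,
                fragment_id=frag,
                layer_index=0,
                position=(float(xy[0]), float(xy[1]), z),
                radius=_RADII[element],
            )

        n_xy = p - 1.45 * _rot2(d_prev, 25.0)
        c_xy = p + 1.52 * _rot2(d_next, -25.0)
        o_xy = c_xy + 1.23 * _rot2(d_next, -115.0)
        atoms.append(at("N", "N", n_xy, 0.0))
        atoms.append(at("CA", "C", p, 0.0))
        atoms.append(at("C", "C", c_xy, 0.0))
        atoms.append(at("O", "O", o_xy, 0.35))
        if seq[i].upper() != "G":
            atoms.append(at("CB", "C", p + 0.55 * _rot2(d_next, 90.0),
                            1.45 * (1.0 if i % 2 == 0 else -1.0)))
    model = FibrilModel(atoms)
    model.metadata["gate_state"] = spec.gate_state.value
    return model


def make_fibril(
    spec: LayerSpec,
    params: HelicalParameters,
    n_layers: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FibrilModel:
    """Idealized fibril: one layer expanded under the screw operator, with
    optional i.i.d. Gaussian coordinate noise added after expansion.

    Deterministic for a fixed seed.
    """
    layer = make_layer(spec)
    fib = expand_symmetry(layer, params, n_layers)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(fib.n_atoms, 3))
        fib = fib.with_atoms(
            replace(a, position=tuple(np.asarray(a.position) + dx))
            for a, dx in zip(fib.atoms, noise)
        )
        fib.helical = params
    fib.metadata.update({"noise_sd": noise_sd, "seed": seed,
                         "gate_state": spec.gate_state.value})
    return fib


def _meander_trace(
    n_res: int, strand_len: int = 8, first_turn: float = 1.0
) -> list[TraceStep]:
    """Serpentine (beta-meander) trace: straight strands joined by U-turns
    of two 90-degree corners, strand spacing = one C-alpha step."""
    steps: list[TraceStep] = [TraceStep()]
    direction = first_turn
    pos_in_strand = 1
    for _ in range(1, n_res):
        if pos_in_strand < strand_len:
            steps.append(TraceStep(turn=0.0))
            pos_in_strand += 1
        else:
            steps.append(TraceStep(turn=90.0 * direction))
            steps.append(TraceStep(turn=90.0 * direction))
            direction *= -1.0
            pos_in_strand = 2
    return steps[:n_res]


def attr_like_layer_spec(gate_state: GateState = GateState.CLOSED) -> LayerSpec:
    """Default layer recipe loosely shaped like the ATTR protofilament:
    an N-fragment (residues 11-35) and a C-fragment (residues 57-124)
    folded as beta-meanders, with the gate at the start of the C-fragment.
    """
    n_len, c_len = 25, 68  # residues 11..35 and 57..124
    n_trace = _meander_trace(n_len, strand_len=9)
    # C fragment: drop below the N block, run the gate down a free column,
    # then meander rightwards in rows below the gate pocket
    c_trace = [TraceStep(turn=-90.0, step=22.0)]  # residue 57, chain break
    c_trace += [TraceStep() for _ in range(5)]  # gate residues 58-62
    tail = _meander_trace(c_len - 6, strand_len=8, first_turn=-1.0)
    c_trace += [TraceStep(turn=90.0)] + tail[1:]  # residue 63 onwards
    trace = n_trace + c_trace
    # mature-TTR subsequences: residues 11-35 and 57-124
    n_seq = "LMVKVLDAVRGSPAINVAVHVFRKA"
    c_seq = "GELHGLTTEEEFVEGIYKVEIDTKSYWKALGISPFHEHAEVVFTANDSGPRRYTIAALLSPYSYSTTA"
    return LayerSpec(
        trace=trace,
        sequence=(n_seq[:n_len] + c_seq[:c_len]),
        split=n_len,
        gate=(n_len + 1, n_len + 6),  # the five gate residues 58-62
        gate_state=gate_state,
        n_start=11,
        c_start=57,
        gate_direction=(-1.0, 0.0),  # into the free pocket left of the gate column
    )


@dataclass
class ClassMixture:
    """Per-filament polymorph composition model."""

    p_pure_a: float = 0.4
    p_pure_b: float = 0.3
    p_mixed: float = 0.3
    switch_prob: float = 0.2  # per-segment class-switch probability in mixed filaments

    def __post_init__(self) -> None:
        tot = self.p_pure_a + self.p_pure_b + self.p_mixed
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError("mixture probabilities must sum to 1")


@dataclass
class SyntheticStarSpec:
    """Recipe for a synthetic refinement particle table."""

    n_micrographs: int = 15
    filaments_per_micrograph: int = 10
    segments_per_filament: int = 20
    class_mixture: ClassMixture = field(default_factory=ClassMixture)
    unassigned_fraction: float = 0.0  # segments dropped from the refined subset
    seed: int = 0
    micrograph_size: int = 4096  # pixels, square
    spacing_px: float = 50.0  # inter-segment spacing along the filament

    def __post_init__(self) -> None:
        if not 0.0 <= self.unassigned_fraction <= 1.0:
            raise ValueError("unassigned_fraction must be in [0, 1]")


def make_star_fixture(spec: SyntheticStarSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic particle table plus ground-truth filament composition.

    Segments of each filament lie on a smooth, slightly curved path within
    the micrograph bounds.  Each filament is pure class 1, pure class 2, or
    mixed (classes alternating under a per-segment switch probability).  A
    fraction ``unassigned_fraction`` of segments is omitted from the
    returned particle table, emulating segments discarded during
    refinement; the ground truth records every filament's true composition
    and the retained-segment coverage.

    Returns ``(particles, truth)``: particles with columns ``micrograph,
    x, y, tube, class_label``; truth with one row per filament.
    """
    rng = np.random.default_rng(spec.seed)
    mix = spec.class_mixture
    rows = []
    truth_rows = []
    size = float(spec.micrograph_size)
    margin = 0.05 * size
    for m in range(spec.n_micrographs):
        mic = f"synthetic_{m + 1:04d}.mrc"
        for tube in range(1, spec.filaments_per_micrograph + 1):
            length = spec.segments_per_filament * spec.spacing_px
            lo = margin + length / 2.0
            hi = size - margin - length / 2.0
            center = rng.uniform(lo, hi, 2)
            theta = rng.uniform(0, 2 * np.pi)
            curv = rng.normal(0.0, 2e-5)
            t = (np.arange(spec.segments_per_filament)
                 - (spec.segments_per_filament - 1) / 2.0) * spec.spacing_px
            d = np.array([np.cos(theta), np.sin(theta)])
            nvec = np.array([-np.sin(theta), np.cos(theta)])
            xy = center[None, :] + t[:, None] * d[None, :] + (curv * t**2)[:, None] * nvec[None, :]
            xy = np.clip(xy, 0.0, size)

            kind = rng.choice(3, p=[mix.p_pure_a, mix.p_pure_b, mix.p_mixed])
            if kind == 0:
                labels = np.ones(spec.segments_per_filament, dtype=int)
            elif kind == 1:
                labels = np.full(spec.segments_per_filament, 2, dtype=int)
            else:
                labels = np.empty(spec.segments_per_filament, dtype=int)
                labels[0] = rng.choice([1, 2])
                for i in range(1, spec.segments_per_filament):
                    flip = rng.random() < mix.switch_prob
                    labels[i] = (3 - labels[i - 1]) if flip else labels[i - 1]
                if len(set(labels)) == 1:  # a mixed draw may come out pure
                    kind = labels[0] - 1
            keep = rng.random(spec.segments_per_filament) >= spec.unassigned_fraction
            for i in range(spec.segments_per_filament):
                if keep[i]:
                    rows.append(
                        (mic, float(xy[i, 0]), float(xy[i, 1]), tube, int(labels[i]))
                    )
            counts = {c: int((labels == c).sum()) for c in sorted(set(labels))}
            truth_rows.append(
                {
                    "micrograph": mic,
                    "tube": tube,
                    "n_segments": spec.segments_per_filament,
                    "n_retained": int(keep.sum()),
                    "coverage": float(keep.mean()),
                    "true_mixed": bool(len(counts) > 1),
                    "true_composition": ";".join(f"{c}:{n}" for c, n in counts.items()),
                }
            )
    particles = pd.DataFrame(
        rows, columns=["micrograph", "x", "y", "tube", "class_label"]
    )
    truth = pd.DataFrame(truth_rows)
    return particles, truth
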