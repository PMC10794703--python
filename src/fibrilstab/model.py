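"""Domain types for amyloid fibril models.

A fibril model is an ordered collection of atoms grouped into *layers*
(rungs of the cross-beta stack) and, within each layer, into two peptide
*fragments*: the N-terminal and C-terminal proteolytic fragments of
transthyretin that occupy one rung at a 1:1 ratio.  Residue numbers follow
the mature-transthyretin convention (1-127) throughout; files are never
renumbered.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


class FragmentId(enum.Enum):
    """Which proteolytic fragment of the layer an atom belongs to."""

    N_TERM = "N_TERM"
    C_TERM = "C_TERM"


class FoldName(enum.Enum):
    CLOSED_GATE = "CLOSED_GATE"
    OPEN_GATE = "OPEN_GATE"
    ABSENT_GATE = "ABSENT_GATE"
    BROKEN_GATE = "BROKEN_GATE"
    CUSTOM = "CUSTOM"


class ModelError(Exception):
    """Base class for fibril-model errors."""


class MappingError(ModelError):
    """A chain in the input file is not covered by the chain mapping."""


class SelectionError(ModelError):
    """A coordinate selection matched nothing it was required to match."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a fibril model.

    ``radius`` is the (united-atom) van der Waals radius in Angstrom;
    hydrogens are never stored, their volume is absorbed by the radii.
    """

    element: str
    name: str
    residue_number: int
    residue_name: str
    fragment_id: FragmentId
    layer_index: int
    position: tuple[float, float, float]
    radius: float = 1.8

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self.name}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite coordinate for atom {self.name}")


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive residue-number interval in mature-TTR numbering."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"empty residue range {self.start}..{self.stop}")

    def __contains__(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.stop

    def __len__(self) -> int:
        return self.stop - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.stop + 1)

    def overlaps(self, other: "ResidueRange") -> bool:
        return self.start <= other.stop and other.start <= self.stop


@dataclass(frozen=True)
class FoldDefinition:
    """A named fibril polymorph: residue spans of the two fragments and,
    where one exists, of the channel gate."""

    name: FoldName
    n_range: ResidueRange
    c_range: ResidueRange
    gate_range: ResidueRange | None = None

    def __post_init__(self) -> None:
        if self.n_range.overlaps(self.c_range):
            raise ValueError("N- and C-fragment ranges overlap")
        if self.n_range.stop >= self.c_range.start:
            raise ValueError("N-fragment must precede the C-fragment")


# The four polymorphs resolved from ATTRv-I84S cardiac fibrils, by the
# conformation of the short segment (the "gate") that closes the polar
# channel.  Residue spans are the modelled spans of each deposition.
CLOSED_GATE = FoldDefinition(
    FoldName.CLOSED_GATE, ResidueRange(11, 35), ResidueRange(57, 124), ResidueRange(58, 62)
)
OPEN_GATE = FoldDefinition(
    FoldName.OPEN_GATE, ResidueRange(11, 35), ResidueRange(60, 124), ResidueRange(60, 66)
)
ABSENT_GATE = FoldDefinition(
    FoldName.ABSENT_GATE, ResidueRange(12, 35), ResidueRange(68, 124), None
)
BROKEN_GATE = FoldDefinition(
    FoldName.BROKEN_GATE, ResidueRange(12, 35), ResidueRange(64, 122), ResidueRange(64, 66)
)

FOLDS: dict[FoldName, FoldDefinition] = {
    f.name: f for f in (CLOSED_GATE, OPEN_GATE, ABSENT_GATE, BROKEN_GATE)
}

#: Residues ordered in every polymorph: Leu12-Lys35 plus Gly67-Val122.
COMMON_CORE: tuple[ResidueRange, ResidueRange] = (ResidueRange(12, 35), ResidueRange(67, 122))


@dataclass
class FibrilModel:
    """Ordered atoms of a fibril, grouped into layers and fragments."""

    atoms: list[Atom]
    fold: FoldDefinition | None = None
    helical: "object | None" = None  # HelicalParameters; untyped to avoid a cycle
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def layers(self) -> int:
        if not self.atoms:
            return 0
        return max(a.layer_index for a in self.atoms) + 1

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def layer(self, layer_index: int) -> "FibrilModel":
        """Sub-model of one layer (layer_index re-based to 0)."""
        sel = [a for a in self.atoms if a.layer_index == layer_index]
        if not sel:
            raise SelectionError(f"layer {layer_index} not present")
        sel = [replace(a, layer_index=0) for a in sel]
        return FibrilModel(sel, fold=self.fold, helical=self.helical)

    def layer_indices(self, layer_index: int) -> np.ndarray:
        """Positional indices (into ``atoms``) of one layer."""
        idx = np.array(
            [i for i, a in enumerate(self.atoms) if a.layer_index == layer_index], dtype=int
        )
        if idx.size == 0:
            raise SelectionError(f"layer {layer_index} not present")
        return idx

    def residues_present(self, layer_index: int = 0) -> set[int]:
        return {a.residue_number for a in self.atoms if a.layer_index == layer_index}

    def validate(self) -> None:
        """Check the structural invariants of a well-formed fibril model."""
        if not self.atoms:
            raise ModelError("empty model")
        layer_set = {a.layer_index for a in self.atoms}
        if layer_set != set(range(self.layers)):
            raise ModelError(f"layer indices not contiguous from 0: {sorted(layer_set)}")
        for k in layer_set:
            for frag in FragmentId:
                nums = [
                    a.residue_number
                    for a in self.atoms
                    if a.layer_index == k and a.fragment_id == frag and a.name == "CA"
                ]
                if any(b <= a for a, b in zip(nums, nums[1:])):
                    raise ModelError(
                        f"residue numbers not strictly increasing in layer {k} {frag.value}"
                    )

    def with_atoms(self, atoms: Iterable[Atom]) -> "FibrilModel":
        return FibrilModel(list(atoms), fold=self.fold, helical=self.helical,
                           metadata=dict(self.metadata))


def select_calpha(
    model: FibrilModel,
    residues: Sequence[ResidueRange] | ResidueRange,
    layer: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """C-alpha coordinates for a residue interval set on one layer.

    Returns ``(coords, omitted)`` where ``coords`` holds one row per
    requested residue present in the model, in residue order over both
    fragments, and ``omitted`` lists requested residue numbers with no
    C-alpha in that layer.

    Raises
    ------
    SelectionError
        If the layer is absent or the layer carries no C-alpha atoms at all.
    """
    if isinstance(residues, ResidueRange):
        residues = [residues]
    if layer >= model.layers or layer < 0:
        raise SelectionError(f"layer {layer} not present (model has {model.layers})")
    ca = {
        a.residue_number: a.position
        for a in model.atoms
        if a.layer_index == layer and a.name == "CA"
    }
    if not ca:
        raise SelectionError(f"no C-alpha atoms in layer {layer}")
    wanted: list[int] = []
    for rng in residues:
        wanted.extend(rng.residues())
    coords = [ca[r] for r in wanted if r in ca]
    omitted = [r for r in wanted if r not in ca]
    return np.array(coords, dtype=float).reshape(-1, 3), omitted
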