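"""Superposition-based comparison of fibril polymorphs.

All four ATTR polymorphs share an ordered common core (Leu12-Lys35 plus
Gly67-Val122); comparing folds means superposing C-alpha traces over a
chosen fit set with a single least-squares (Kabsch) fit, then reading both
the overall r.m.s.d. over the fitted atoms and the per-residue deviations
of *all* shared residues under that one fit — so a displaced channel gate
can show deviations far above the overall value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model import (
    COMMON_CORE,
    FibrilModel,
    ModelError,
    ResidueRange,
    select_calpha,
)


class ConditioningError(ModelError):
    """Superposition input is degenerate (collinear or fewer than 3 points)."""


class CorrespondenceError(ModelError):
    """Coordinate sets cannot be put in one-to-one correspondence."""


class InsufficientOverlapError(ModelError):
    """Fewer than 3 residues shared between the two models."""


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns ``(rotation, translation, rmsd)`` with
    ``coords_b ~ rotation @ coords_a + translation`` and the rotation a
    proper rotation (det = +1; reflections are never returned).

    Raises
    ------
    CorrespondenceError
        If the two sets differ in length.
    ConditioningError
        If fewer than 3 points are given or the points are collinear.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape[0] != b.shape[0]:
        raise CorrespondenceError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 3:
        raise ConditioningError("need at least 3 points for a rigid superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ConditioningError("points are (nearly) collinear; rotation ill-determined")
    # scipy's align_vectors(b0, a0) finds proper R minimising sum |b0 - R a0|^2
    rot_obj, _ = Rotation.align_vectors(b0, a0)
    rot = rot_obj.as_matrix()
    trans = cb - rot @ ca
    resid = b0 - a0 @ rot.T
    rmsd = float(np.sqrt((resid**2).sum() / a.shape[0]))
    return rot, trans, rmsd


@dataclass(frozen=True)
class ResidueCorrespondence:
    """Residue-number pairing between two models over one layer."""

    pairs: tuple[tuple[int, int], ...]
    core_flags: tuple[bool, ...]
    missing_a: tuple[int, ...] = ()
    missing_b: tuple[int, ...] = ()

    @property
    def residues(self) -> list[int]:
        return [p[0] for p in self.pairs]


def common_core(
    model_a: FibrilModel,
    model_b: FibrilModel,
    core: Sequence[ResidueRange] = COMMON_CORE,
) -> ResidueCorrespondence:
    """Pair residues of the shared core by identical residue number.

    Residues of the core missing from either model are excluded and listed.
    Raises :class:`InsufficientOverlapError` when fewer than 3 residues of
    the core are present in both models.
    """
    pres_a = {
        a.residue_number for a in model_a.atoms if a.layer_index == 0 and a.name == "CA"
    }
    pres_b = {
        a.residue_number for a in model_b.atoms if a.layer_index == 0 and a.name == "CA"
    }
    wanted: list[int] = []
    for rng in core:
        wanted.extend(rng.residues())
    pairs = [(r, r) for r in wanted if r in pres_a and r in pres_b]
    if len(pairs) < 3:
        raise InsufficientOverlapError(
            f"only {len(pairs)} core residues shared; need >= 3"
        )
    missing_a = tuple(r for r in wanted if r not in pres_a)
    missing_b = tuple(r for r in wanted if r not in pres_b)
    return ResidueCorrespondence(
        pairs=tuple(pairs),
        core_flags=tuple(True for _ in pairs),
        missing_a=missing_a,
        missing_b=missing_b,
    )


@dataclass
class DeviationProfile:
    """Per-residue C-alpha deviations and overall r.m.s.d. after one fit."""

    per_residue: pd.Series  # index: residue number; values: distance (A)
    rmsd: float
    fit_set: str
    layers_used: int
    n_fit_atoms: int
    metadata: dict = field(default_factory=dict)


def _shared_residues(model_a: FibrilModel, model_b: FibrilModel) -> list[int]:
    pres_a = {
        a.residue_number for a in model_a.atoms if a.layer_index == 0 and a.name == "CA"
    }
    pres_b = {
        a.residue_number for a in model_b.atoms if a.layer_index == 0 and a.name == "CA"
    }
    return sorted(pres_a & pres_b)


def fold_rmsd(
    model_a: FibrilModel,
    model_b: FibrilModel,
    layers: int = 3,
    fit_set: str = "ALL_SHARED",
    core: Sequence[ResidueRange] = COMMON_CORE,
) -> DeviationProfile:
    """Overall r.m.s.d. and per-residue deviations between two folds.

    One Kabsch fit is computed on the C-alpha atoms of the fit set
    (``ALL_SHARED`` residues or the ``COMMON_CORE``) across ``layers``
    consecutive layers; per-residue distances are then reported for *all*
    shared residues under that single fit, RMS-averaged over layers.
    """
    if fit_set not in ("ALL_SHARED", "COMMON_CORE"):
        raise ValueError(f"unknown fit set {fit_set!r}")
    layers = min(layers, model_a.layers, model_b.layers)
    if layers < 1:
        raise ModelError("no layers available for comparison")

    shared = _shared_residues(model_a, model_b)
    if len(shared) < 3:
        raise InsufficientOverlapError(f"only {len(shared)} shared residues")
    if fit_set == "COMMON_CORE":
        corr = common_core(model_a, model_b, core)
        fit_res = corr.residues
    else:
        fit_res = shared

    def stack_coords(model: FibrilModel, res: list[int]) -> np.ndarray:
        rows = []
        for k in range(layers):
            ca = {
                a.residue_number: a.position
                for a in model.atoms
                if a.layer_index == k and a.name == "CA"
            }
            rows.extend(ca[r] for r in res if r in ca)
        return np.array(rows, dtype=float).reshape(-1, 3)

    fit_a = stack_coords(model_a, fit_res)
    fit_b = stack_coords(model_b, fit_res)
    if fit_a.shape[0] != fit_b.shape[0]:
        raise CorrespondenceError("fit-set residues unevenly present across layers")
    rot, trans, rmsd = kabsch_superpose(fit_a, fit_b)

    # per-residue distances for all shared residues under the single fit
    sq_sums = {r: 0.0 for r in shared}
    counts = {r: 0 for r in shared}
    for k in range(layers):
        ca_a = {
            a.residue_number: a.position
            for a in model_a.atoms
            if a.layer_index == k and a.name == "CA"
        }
        ca_b = {
            a.residue_number: a.position
            for a in model_b.atoms
            if a.layer_index == k and a.name == "CA"
        }
        for r in shared:
            if r in ca_a and r in ca_b:
                moved = rot @ np.asarray(ca_a[r]) + trans
                sq_sums[r] += float(((moved - np.asarray(ca_b[r])) ** 2).sum())
                counts[r] += 1
    per_res = pd.Series(
        {r: np.sqrt(sq_sums[r] / counts[r]) for r in shared if counts[r] > 0},
        name="ca_distance_A",
    )
    return DeviationProfile(
        per_residue=per_res,
        rmsd=rmsd,
        fit_set=fit_set,
        layers_used=layers,
        n_fit_atoms=fit_a.shape[0],
        metadata={"fit_residues": list(fit_res)},
    )


def deviation_matrix(
    models: dict[str, FibrilModel],
    layers: int = 3,
    fit_set: str = "ALL_SHARED",
) -> tuple[pd.DataFrame, dict[tuple[str, str], DeviationProfile]]:
    """Pairwise r.m.s.d. table and per-residue profiles for >= 2 models.

    The table is symmetric with a zero diagonal; profiles are keyed by the
    ordered name pair and carry the per-residue deviations for heatmaps.
    """
    names = list(models)
    if len(names) < 2:
        raise ModelError("need at least 2 models")
    table = pd.DataFrame(0.0, index=names, columns=names)
    profiles: dict[tuple[str, str], DeviationProfile] = {}
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            prof = fold_rmsd(models[na], models[nb], layers=layers, fit_set=fit_set)
            table.loc[na, nb] = prof.rmsd
            table.loc[nb, na] = prof.rmsd
            profiles[(na, nb)] = prof
    return table, profiles
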