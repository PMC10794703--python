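"""Solvation-based fibril stabilization energy.

The stabilization energy of a fibril chain is estimated from solvent
burial: for every atom, the solvent-accessible surface area (SASA) it
loses on incorporation into the fibril stack is multiplied by an atomic
solvation parameter (ASP, cal/(mol*A^2)) for its chemical class, and the
products are summed per residue and per chain:

    e_i = sigma_i * (A_i(in stack) - A_i(reference))        [kcal/mol]

so that burying apolar carbon (sigma > 0) yields a negative, stabilizing
energy.  The reference state is by default the isolated chain in the same
conformation (ISOLATED_CHAIN), so the energy measures inter-chain burial
only; a residue-local FULLY_EXTENDED reference approximating an unfolded
chain is available as an option.  SASA uses the Shrake-Rupley rolling-probe
quadrature over deterministic Fibonacci sphere points.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .model import Atom, FibrilModel, ModelError

CAL_TO_KCAL = 1e-3

#: Side-chain atoms carrying a formal charge at physiological pH.
_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}


class ASPConfigError(ModelError):
    """An atom resolves to no atomic solvation parameter."""


class DegenerateInputError(ModelError):
    """Two identical atoms occupy the same position."""


@dataclass(frozen=True)
class ASPTable:
    """Atomic solvation parameters by atom class, cal/(mol*A^2)."""

    classes: dict[str, float]
    provenance: str = "unspecified"

    def classify(self, atom: Atom) -> str:
        """Atom class from element plus charge state of the side chain.

        C-terminal carboxylate oxygens (OXT) count as charged; backbone and
        neutral side-chain N/O share one class; His is treated neutral.
        """
        el = atom.element.upper()
        key = (atom.residue_name.upper(), atom.name.upper())
        if el == "C":
            return "C_APOLAR"
        if el == "O":
            if key in _CHARGED_O or atom.name.upper() == "OXT":
                return "O_CHARGED"
            return "N_O_NEUTRAL"
        if el == "N":
            if key in _CHARGED_N:
                return "N_CHARGED"
            return "N_O_NEUTRAL"
        if el in ("S", "SE"):
            return "S"
        return "C_APOLAR"  # rare elements scored as apolar surface

    def sigma(self, atom: Atom) -> float:
        cls = self.classify(atom)
        if cls not in self.classes:
            raise ASPConfigError(
                f"no solvation parameter for class {cls!r} "
                f"(atom {atom.name} of {atom.residue_name} {atom.residue_number})"
            )
        return self.classes[cls]


def load_asp_table(path: str | Path | None = None) -> ASPTable:
    """Load an ASP table from YAML (shipped Eisenberg-McLachlan set by default)."""
    if path is None:
        ref = importlib.resources.files("fibrilstab.data") / "asp_eisenberg_mclachlan.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    return ASPTable(
        classes={str(k): float(v) for k, v in cfg["classes"].items()},
        provenance=str(cfg.get("provenance", "unspecified")),
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Each atom's solvent-expanded sphere (radius ``r_i + probe``) is sampled
    at ``n_points`` quadrature points; its area is the exposed-point
    fraction times ``4*pi*(r_i+probe)^2``.

    Raises
    ------
    DegenerateInputError
        If two atoms coincide (distance < 1e-6 A).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    if radii.shape[0] != n:
        raise ValueError("coords and radii length mismatch")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    if n == 0:
        return np.zeros(0)

    tree = cKDTree(coords)
    dup = tree.query_pairs(1e-6)
    if dup:
        i, j = next(iter(dup))
        raise DegenerateInputError(f"atoms {i} and {j} coincide")

    sphere = _fibonacci_sphere(n_points)
    exp_r = radii + probe
    max_reach = 2.0 * exp_r.max()
    areas = np.empty(n)
    neighbor_lists = tree.query_ball_tree(tree, max_reach)
    for i in range(n):
        pts = coords[i] + exp_r[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > exp_r[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * exp_r[i] ** 2
    return areas


def _residue_local_reference(
    layer: FibrilModel, probe: float, n_points: int
) -> np.ndarray:
    """Reference SASA approximating a fully extended chain.

    Each atom is scored in the context of its own residue plus the backbone
    (N, CA, C, O) of the peptide-bonded neighbour residues of the same
    fragment — the burial an atom cannot escape even in an extended chain.
    """
    atoms = layer.atoms
    coords = layer.coords()
    radii = layer.radii()
    out = np.empty(len(atoms))
    by_res: dict[tuple, list[int]] = {}
    for idx, a in enumerate(atoms):
        by_res.setdefault((a.fragment_id, a.residue_number), []).append(idx)
    backbone = {"N", "CA", "C", "O"}
    for (frag, resnum), idxs in by_res.items():
        ctx = list(idxs)
        for nb in (resnum - 1, resnum + 1):
            for j in by_res.get((frag, nb), []):
                if atoms[j].name in backbone:
                    ctx.append(j)
        ctx = np.array(sorted(set(ctx)), dtype=int)
        local = shrake_rupley(coords[ctx], radii[ctx], probe, n_points)
        pos = {j: k for k, j in enumerate(ctx)}
        for j in idxs:
            out[j] = local[pos[j]]
    return out


def buried_area(
    model: FibrilModel,
    target_layer: int | None = None,
    reference: str = "ISOLATED_CHAIN",
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, list[str]]:
    """Per-atom buried area dA of one layer inside the full assembly.

    ``dA_i = A_i(reference) - A_i(in assembly)``.  The default reference is
    the target layer alone in the same conformation; FULLY_EXTENDED uses a
    residue-local context approximating an unfolded chain.  Returns the
    per-atom dA (ordered as the target layer's atoms) plus a list of
    warnings — notably when the target layer sits at a stack boundary,
    where burial is not converged.
    """
    if reference not in ("ISOLATED_CHAIN", "FULLY_EXTENDED"):
        raise ValueError(f"unknown reference {reference!r}")
    n_layers = model.layers
    if target_layer is None:
        target_layer = n_layers // 2
    warnings: list[str] = []
    if n_layers >= 3 and target_layer in (0, n_layers - 1):
        warnings.append(
            f"target layer {target_layer} is at the stack boundary; "
            "burial is underestimated relative to a central layer"
        )
    idx = model.layer_indices(target_layer)
    full = shrake_rupley(model.coords(), model.radii(), probe, n_points)
    layer = model.layer(target_layer)
    if reference == "ISOLATED_CHAIN":
        ref = shrake_rupley(layer.coords(), layer.radii(), probe, n_points)
    else:
        ref = _residue_local_reference(layer, probe, n_points)
    return ref - full[idx], warnings


@dataclass
class EnergyProfile:
    """Per-atom, per-residue and per-chain solvation stabilization energies.

    Additivity holds exactly: ``chain_energy == per_residue.sum()
    == per_atom['energy_kcal_mol'].sum()``.
    """

    per_atom: pd.DataFrame  # atom name, residue, dA (A^2), energy (kcal/mol)
    per_residue: pd.Series  # index residue number -> energy (kcal/mol)
    chain_energy: float
    context: dict = field(default_factory=dict)


def stabilization_energy(
    model: FibrilModel,
    asp: ASPTable | None = None,
    stack_layers: int = 5,
    reference: str = "ISOLATED_CHAIN",
    probe: float = 1.4,
    n_points: int = 960,
) -> EnergyProfile:
    """Solvation stabilization energy of one fibril chain (layer).

    A single-layer model with helical parameters is first expanded to an
    odd stack (``2*floor(stack_layers/2)+1`` layers) so the scored chain is
    central; a pre-stacked model is scored at its central layer.  Energies
    follow the sign convention stabilizing = negative kcal/mol.
    """
    from .helical import expand_symmetry

    if asp is None:
        asp = load_asp_table()
    n_stack = 2 * (stack_layers // 2) + 1
    if model.layers == 1:
        if model.helical is None:
            raise ModelError(
                "single-layer model without helical parameters: "
                "cannot build the stack context"
            )
        stack = expand_symmetry(model, model.helical, n_stack)
    else:
        stack = model
        n_stack = model.layers
    central = stack.layers // 2
    dA, warnings = buried_area(stack, central, reference, probe, n_points)
    layer = stack.layer(central)
    sigmas = np.array([asp.sigma(a) for a in layer.atoms])
    energies = -sigmas * dA * CAL_TO_KCAL
    per_atom = pd.DataFrame(
        {
            "atom": [a.name for a in layer.atoms],
            "residue_number": [a.residue_number for a in layer.atoms],
            "residue_name": [a.residue_name for a in layer.atoms],
            "fragment": [a.fragment_id.value for a in layer.atoms],
            "buried_area_A2": dA,
            "sigma_cal_mol_A2": sigmas,
            "energy_kcal_mol": energies,
        }
    )
    per_residue = per_atom.groupby("residue_number")["energy_kcal_mol"].sum()
    return EnergyProfile(
        per_atom=per_atom,
        per_residue=per_residue,
        chain_energy=float(energies.sum()),
        context={
            "stack_layers": n_stack,
            "scored_layer": central,
            "reference": reference,
            "probe_A": probe,
            "n_points": n_points,
            "asp_provenance": asp.provenance,
            "warnings": warnings,
        },
    )


DEFAULT_PALETTE = {
    # bin k covers (edge[k-1], edge[k]]; one more color than edges.
    "edges_kcal_mol": [-2.5, -1.5, -0.5, 0.5, 1.5],
    "colors": ["#67001f", "#b2182b", "#d6604d", "#f7f7f7", "#92c5de", "#2166ac"],
}


def residue_energy_colormap(
    profile: EnergyProfile, palette: dict | None = None
) -> pd.DataFrame:
    """Deterministic per-residue colour bins for structure colouring.

    Strongly stabilizing residues (most negative energies) land in the
    first (red) bins, destabilizing ones in the last (blue) bins.  Returns
    a table ``residue_number, energy_kcal_mol, bin, color`` usable to paint
    a structure (e.g. via B-factors or a PyMOL script).
    """
    pal = palette or DEFAULT_PALETTE
    edges = np.asarray(pal["edges_kcal_mol"], dtype=float)
    colors = list(pal["colors"])
    if len(colors) != len(edges) + 1:
        raise ValueError("palette needs len(edges) + 1 colors")
    e = profile.per_residue
    bins = np.searchsorted(edges, e.values, side="left")
    return pd.DataFrame(
        {
            "residue_number": e.index,
            "energy_kcal_mol": e.values,
            "bin": bins,
            "color": [colors[b] for b in bins],
        }
    )
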