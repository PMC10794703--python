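"""Reading and writing fibril coordinate files (PDB / mmCIF) via gemmi.

Deposited fibril entries store every stacked chain under its own chain id,
with conventions that vary between depositions.  A *chain mapping* assigns
each chain id to a ``(layer_index, fragment)`` slot.  By default the
mapping is inferred: a chain whose residues start in the C-terminal span of
mature transthyretin is the C-fragment, and layers are ranked by the mean
axial (z) coordinate within each fragment.  An explicit mapping (plain
key-value YAML, ``chain_id: [layer, N_TERM|C_TERM]``) overrides inference.

Hydrogens are dropped on read; for alternate locations only the highest
occupancy conformer is kept.  Author residue numbers are taken verbatim.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import gemmi
import yaml

from .model import Atom, FibrilModel, FragmentId, MappingError, ModelError

#: First residue number at or above which an inferred chain is called the
#: C-terminal fragment (the C-fragment of every ATTR polymorph starts at
#: residue 57 or later; the N-fragment ends at residue 35).
C_FRAGMENT_START = 45

PDB_MAX_ATOMS = 99_999


def load_vdw_radii(path: str | Path | None = None) -> dict[str, float]:
    """United-atom van der Waals radii by element, from a YAML config.

    The shipped default is a Chothia-style united-atom set (hydrogens
    absorbed into heavy-atom radii); pass a path to substitute another.
    """
    if path is None:
        ref = importlib.resources.files("fibrilstab.data") / "vdw_radii_united.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    return {str(k).upper(): float(v) for k, v in cfg["radii"].items()}


def load_chain_mapping(path: str | Path) -> dict[str, tuple[int, FragmentId]]:
    """Explicit chain mapping: ``chain_id -> (layer_index, fragment)``."""
    cfg = yaml.safe_load(Path(path).read_text())
    out: dict[str, tuple[int, FragmentId]] = {}
    for chain, (layer, frag) in cfg["chains"].items():
        out[str(chain)] = (int(layer), FragmentId[str(frag)])
    return out


def _infer_chain_mapping(st: gemmi.Structure) -> dict[str, tuple[int, FragmentId]]:
    chains = st[0]
    info: list[tuple[str, FragmentId, float]] = []
    for chain in chains:
        nums = [r.seqid.num for r in chain]
        zs = [a.pos.z for r in chain for a in r]
        if not nums:
            continue
        frag = FragmentId.C_TERM if min(nums) >= C_FRAGMENT_START else FragmentId.N_TERM
        info.append((chain.name, frag, sum(zs) / len(zs)))
    mapping: dict[str, tuple[int, FragmentId]] = {}
    for frag in FragmentId:
        ranked = sorted((i for i in info if i[1] is frag), key=lambda i: i[2])
        for layer, (name, _, _) in enumerate(ranked):
            mapping[name] = (layer, frag)
    return mapping


def read_structure(
    path: str | Path,
    format: str = "auto",
    chain_mapping: dict[str, tuple[int, FragmentId]] | str | Path | None = None,
    vdw_radii: dict[str, float] | None = None,
) -> FibrilModel:
    """Read a PDB or mmCIF file into a :class:`FibrilModel`.

    Parameters
    ----------
    format : "PDB", "mmCIF" or "auto" (by extension/content).
    chain_mapping : explicit mapping dict, path to a mapping YAML, or None
        to infer layers and fragments from residue spans and axial order.
    vdw_radii : element -> radius (A); shipped united-atom set by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ModelError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ModelError(f"{path.name} contains no atoms")

    st.remove_alternative_conformations()
    st.remove_hydrogens()

    if chain_mapping is None:
        mapping = _infer_chain_mapping(st)
    elif isinstance(chain_mapping, (str, Path)):
        mapping = load_chain_mapping(chain_mapping)
    else:
        mapping = chain_mapping

    radii = vdw_radii if vdw_radii is not None else load_vdw_radii()
    default_radius = radii.get("DEFAULT", 1.8)

    atoms: list[Atom] = []
    for chain in st[0]:
        if chain.name not in mapping:
            raise MappingError(
                f"chain {chain.name!r} of {path.name} is not covered by the chain mapping"
            )
        layer, frag = mapping[chain.name]
        for res in chain:
            for at in res:
                el = at.element.name.upper()
                atoms.append(
                    Atom(
                        element=el,
                        name=at.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        fragment_id=frag,
                        layer_index=layer,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        radius=radii.get(el, default_radius),
                    )
                )
    # normalise layer indices to a contiguous 0-based range
    present = sorted({a.layer_index for a in atoms})
    remap = {old: new for new, old in enumerate(present)}
    from dataclasses import replace

    atoms = [replace(a, layer_index=remap[a.layer_index]) for a in atoms]
    atoms.sort(
        key=lambda a: (a.layer_index, a.fragment_id is FragmentId.C_TERM, a.residue_number)
    )
    return FibrilModel(atoms, metadata={"source": str(path)})


_CHAIN_NAMES = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + [
    chr(a) + chr(b)
    for a in range(ord("A"), ord("Z") + 1)
    for b in range(ord("A"), ord("Z") + 1)
]


def write_structure(model: FibrilModel, path: str | Path, format: str = "PDB") -> None:
    """Write a :class:`FibrilModel` to PDB or mmCIF.

    One chain per ``(layer, fragment)`` slot, named A, B, C, ... in layer
    order (N-fragment first within each layer).  Residue numbers are written
    verbatim.  PDB output refuses models above 99,999 atoms; use mmCIF.
    """
    if not model.atoms:
        raise ModelError("refusing to write an empty model")
    fmt = format.lower()
    if fmt == "pdb" and model.n_atoms > PDB_MAX_ATOMS:
        raise ModelError(
            f"{model.n_atoms} atoms exceed the PDB limit of {PDB_MAX_ATOMS}; write mmCIF instead"
        )

    st = gemmi.Structure()
    st.name = "fibril"
    gmodel = gemmi.Model("1")
    slots = sorted(
        {(a.layer_index, a.fragment_id) for a in model.atoms},
        key=lambda s: (s[0], s[1] is FragmentId.C_TERM),
    )
    for slot_i, (layer, frag) in enumerate(slots):
        chain = gemmi.Chain(_CHAIN_NAMES[slot_i])
        current_res: gemmi.Residue | None = None
        for a in model.atoms:
            if a.layer_index != layer or a.fragment_id != frag:
                continue
            if current_res is None or current_res.seqid.num != a.residue_number:
                current_res = gemmi.Residue()
                current_res.name = a.residue_name
                current_res.seqid = gemmi.SeqId(a.residue_number, " ")
                chain.add_residue(current_res)
                current_res = chain[-1]
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*a.position)
            ga.occ = 1.0
            current_res.add_atom(ga)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    path = Path(path)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
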