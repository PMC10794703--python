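"""Filament tracing: map refined-particle class assignments back to fibrils.

Helical refinement keeps only well-defined segments, so a filament's class
labels cover it incompletely; tracing groups the surviving segments back
into filaments (by helical tube id, or by proximity chaining when tube
bookkeeping is absent) and asks whether a single fibril carries more than
one polymorph.  Because coverage is partial, the observed mixed-filament
fraction is a *lower bound* on the true one — filaments whose labelled
segments all agree may still contain the other polymorph in their
unlabelled stretches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

COVERAGE_CAVEAT = (
    "Coverage of the filaments is incomplete: only segments surviving "
    "refinement carry class labels, so filaments not classified as mixed "
    "cannot be concluded pure — the mixed fraction is a lower bound."
)

#: STAR column -> canonical column of the particle table
_STAR_COLUMNS = {
    "rlnMicrographName": "micrograph",
    "rlnCoordinateX": "x",
    "rlnCoordinateY": "y",
    "rlnHelicalTubeID": "tube",
    "rlnClassNumber": "class_label",
}
_CANON_TO_STAR = {v: k for k, v in _STAR_COLUMNS.items()}


class StarFormatError(ValueError):
    """The STAR file has no particles loop or is malformed."""


class StarSchemaError(ValueError):
    """The particles loop lacks required columns."""


def read_star(path: str | Path) -> pd.DataFrame:
    """Read a particle table from a (possibly multi-block) STAR file.

    The block containing coordinate columns is selected (e.g. the
    particles block of a refinement star file, skipping the optics block).
    Canonical columns ``micrograph, x, y, tube, class_label`` are
    extracted; ``tube`` and ``class_label`` are absent-tolerant (NaN);
    unknown columns are preserved under their STAR tags.
    """
    path = Path(path)
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StarFormatError(f"cannot parse {path.name}: {exc}") from exc

    block = None
    for b in doc:
        if b.find_loop("_rlnCoordinateX") or b.find_loop("_rlnCoordinateY"):
            block = b
            break
    if block is None:
        raise StarFormatError(f"{path.name}: no particles loop found")
    missing = [
        c for c in ("rlnCoordinateX", "rlnCoordinateY")
        if not block.find_loop("_" + c)
    ]
    if missing:
        raise StarSchemaError(f"{path.name}: particles loop lacks columns {missing}")

    tags = _loop_tags(block)
    columns: dict[str, list[str]] = {}
    for tag in tags:
        columns[tag] = list(block.find_loop(tag))
    n = len(columns["_rlnCoordinateX"])
    data: dict[str, list] = {}
    for tag, vals in columns.items():
        name = _STAR_COLUMNS.get(tag.lstrip("_"), tag)
        data[name] = vals
    df = pd.DataFrame(data)
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    if "micrograph" not in df:
        raise StarSchemaError(f"{path.name}: particles loop lacks rlnMicrographName")
    if "tube" in df:
        df["tube"] = pd.to_numeric(df["tube"], errors="coerce").astype("Int64")
    if "class_label" in df:
        df["class_label"] = pd.to_numeric(df["class_label"], errors="coerce").astype("Int64")
    if (df["x"] < 0).any() or (df["y"] < 0).any():
        raise StarSchemaError(f"{path.name}: negative particle coordinates")
    assert len(df) == n
    return df


def _loop_tags(block: gemmi.cif.Block) -> list[str]:
    tags = []
    for item in block:
        if item.loop is not None:
            tags.extend(item.loop.tags)
    return tags


def write_star(particles: pd.DataFrame, path: str | Path) -> None:
    """Write a particle table as a single-block STAR file (deterministic:
    fixed float formatting, stable column and row order)."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    cols = list(particles.columns)
    tags = [_CANON_TO_STAR.get(c, c if c.startswith("_") else f"rln{c}") for c in cols]
    tags = [t.lstrip("_") for t in tags]
    loop = block.init_loop("_", tags)
    for _, row in particles.iterrows():
        vals = []
        for c in cols:
            v = row[c]
            if pd.isna(v):
                vals.append("-999")
            elif isinstance(v, float):
                vals.append(f"{v:.6f}")
            else:
                vals.append(str(v))
        loop.add_row(vals)
    doc.write_file(str(path))


@dataclass
class TracedFilament:
    """Segments of one fibril with their polymorph-class composition."""

    micrograph: str
    filament_id: int
    segments: pd.DataFrame  # arc-length ordered
    class_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_labeled(self) -> int:
        return sum(self.class_counts.values())

    @property
    def coverage(self) -> float:
        """Fraction of this filament's segments carrying a class label."""
        return self.n_labeled / self.n_segments if self.n_segments else 0.0

    @property
    def status(self) -> str:
        if self.n_labeled == 0:
            return "unassigned"
        if len(self.class_counts) > 1:
            return "mixed"
        return f"pure_{next(iter(self.class_counts))}"


def _order_along_path(seg: pd.DataFrame) -> pd.DataFrame:
    """Arc-length order: projection onto the principal axis of the points."""
    xy = seg[["x", "y"]].to_numpy(dtype=float)
    center = xy.mean(axis=0)
    u, s, vt = np.linalg.svd(xy - center, full_matrices=False)
    t = (xy - center) @ vt[0]
    return seg.iloc[np.argsort(t, kind="stable")].reset_index(drop=True)


def _class_counts(seg: pd.DataFrame) -> dict[int, int]:
    if "class_label" not in seg:
        return {}
    labeled = seg["class_label"].dropna()
    return {int(k): int(v) for k, v in labeled.value_counts().sort_index().items()}


def group_filaments(
    records: pd.DataFrame,
    linking: str = "TUBE_ID",
    threshold: float | None = None,
) -> list[TracedFilament]:
    """Group particle records into filaments.

    ``TUBE_ID`` groups by (micrograph, helical tube id); ``PROXIMITY``
    single-links segments of the same micrograph lying within
    ``threshold`` pixels of each other and orders each chain along its
    principal axis.  Every input record lands in exactly one filament.
    """
    out: list[TracedFilament] = []
    if linking == "TUBE_ID":
        if "tube" not in records or records["tube"].isna().all():
            raise ValueError("TUBE_ID linking requires a helical tube id column")
        fid = 0
        for (mic, tube), seg in records.groupby(["micrograph", "tube"], sort=True,
                                                dropna=False):
            fid += 1
            seg = _order_along_path(seg)
            out.append(TracedFilament(str(mic), fid, seg, _class_counts(seg)))
    elif linking == "PROXIMITY":
        if threshold is None:
            raise ValueError("PROXIMITY linking requires a distance threshold (pixels)")
        fid = 0
        for mic, seg in records.groupby("micrograph", sort=True):
            xy = seg[["x", "y"]].to_numpy(dtype=float)
            tree = cKDTree(xy)
            pairs = tree.query_pairs(threshold, output_type="ndarray")
            n = len(seg)
            adj = csr_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
            )
            n_comp, labels = connected_components(adj, directed=False)
            for comp in range(n_comp):
                fid += 1
                sub = _order_along_path(seg.iloc[np.flatnonzero(labels == comp)])
                out.append(TracedFilament(str(mic), fid, sub, _class_counts(sub)))
    else:
        raise ValueError(f"unknown linking mode {linking!r}")
    return out


@dataclass
class CooccurrenceSummary:
    """Polymorph co-existence across traced filaments."""

    per_filament: pd.DataFrame
    n_filaments: int
    n_mixed: int
    n_unassigned: int
    pure_counts: dict[int, int]
    mixed_fraction: float  # among filaments with >= 1 labelled segment
    caveat: str = COVERAGE_CAVEAT


def cooccurrence_summary(filaments: list[TracedFilament]) -> CooccurrenceSummary:
    """Classify each filament as pure, mixed or unassigned and summarise.

    A filament is *mixed* iff labelled segments of at least two distinct
    classes occur on it (no minimum run length).  The mixed fraction is
    taken over filaments carrying at least one label and, under partial
    coverage, is a lower bound on the true co-occurrence rate.
    """
    if not any(f.n_labeled for f in filaments):
        raise ValueError("no class labels present on any segment")
    rows = []
    pure_counts: dict[int, int] = {}
    n_mixed = n_unassigned = 0
    for f in filaments:
        status = f.status
        if status == "mixed":
            n_mixed += 1
        elif status == "unassigned":
            n_unassigned += 1
        else:
            cls = int(status.split("_")[1])
            pure_counts[cls] = pure_counts.get(cls, 0) + 1
        rows.append(
            {
                "micrograph": f.micrograph,
                "filament_id": f.filament_id,
                "n_segments": f.n_segments,
                "n_labeled": f.n_labeled,
                "coverage": f.coverage,
                "status": status,
            }
        )
    per_filament = pd.DataFrame(rows)
    n_with_labels = len(filaments) - n_unassigned
    return CooccurrenceSummary(
        per_filament=per_filament,
        n_filaments=len(filaments),
        n_mixed=n_mixed,
        n_unassigned=n_unassigned,
        pure_counts=pure_counts,
        mixed_fraction=n_mixed / n_with_labels if n_with_labels else 0.0,
    )


def export_trace_plot(
    filaments: list[TracedFilament],
    micrograph: str,
    micrograph_size: tuple[float, float] = (4096.0, 4096.0),
    out_png: str | Path | None = None,
) -> pd.DataFrame:
    """Plot-ready per-class coordinate series for one micrograph.

    Returns a table ``class_label, filament_id, x, y`` in the micrograph
    pixel frame; when ``out_png`` is given, an XY scatter matching the
    micrograph dimensions is also written (one colour per class).
    """
    mine = [f for f in filaments if f.micrograph == micrograph]
    if not mine:
        known = sorted({f.micrograph for f in filaments})
        raise KeyError(f"micrograph {micrograph!r} not among {known[:5]}...")
    rows = []
    for f in mine:
        for _, r in f.segments.iterrows():
            label = r.get("class_label")
            rows.append(
                {
                    "class_label": None if pd.isna(label) else int(label),
                    "filament_id": f.filament_id,
                    "x": float(r["x"]),
                    "y": float(r["y"]),
                }
            )
    table = pd.DataFrame(rows, columns=["class_label", "filament_id", "x", "y"])
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for cls, sub in table.groupby("class_label", dropna=False):
            name = "unassigned" if pd.isna(cls) else f"class {int(cls)}"
            ax.scatter(sub["x"], sub["y"], s=8, label=name)
        ax.set_xlim(0, micrograph_size[0])
        ax.set_ylim(0, micrograph_size[1])
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        ax.set_title(micrograph)
        ax.legend(fontsize=7)
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return table
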