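"""End-to-end orchestration: geometry -> energy -> comparison -> tracing.

A run is described by a :class:`RunConfig` (YAML-loadable), validated
before any stage executes, and produces a machine-readable JSON report
plus TSV tables in the output directory.  Every decision toggle (energy
reference state, fit set, layer counts, seeds) is serialized into the
report so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import synthetic
from .compare import deviation_matrix
from .helical import HelicalParameters, estimate_helical_parameters
from .model import FibrilModel
from .solvation import load_asp_table, residue_energy_colormap, stabilization_energy
from .stats import atlas_comparison
from .structure_io import read_structure
from .synthetic import (
    ClassMixture,
    GateState,
    SyntheticStarSpec,
    attr_like_layer_spec,
    make_fibril,
)
from .tracing import cooccurrence_summary, group_filaments, read_star

log = logging.getLogger("fibrilstab")


class ConfigError(ValueError):
    """The run configuration is invalid; nothing was computed."""


@dataclass
class ModelSource:
    """One input model: a coordinate file or a synthetic recipe."""

    name: str
    path: str | None = None
    gate_state: str | None = None  # synthetic: CLOSED/OPEN/ABSENT/BROKEN
    twist: float = -1.26
    rise: float = 4.81
    n_layers: int = 5
    noise_sd: float = 0.0


@dataclass
class StarSource:
    path: str | None = None
    synthetic: dict = field(default_factory=dict)
    linking: str = "TUBE_ID"
    threshold: float | None = None


@dataclass
class RunConfig:
    models: list[ModelSource]
    star: StarSource = field(default_factory=StarSource)
    asp_table: str | None = None
    stack_layers: int = 5
    energy_reference: str = "ISOLATED_CHAIN"
    sasa_points: int = 480
    compare_layers: int = 3
    compare_fit_set: str = "ALL_SHARED"
    seed: int = 0
    output_dir: str = "fibrilstab_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        models = [ModelSource(**m) for m in raw.pop("models", [])]
        star = StarSource(**raw.pop("star", {}))
        return cls(models=models, star=star, **raw)

    def validate(self) -> None:
        if not self.models:
            raise ConfigError("no input models configured")
        for m in self.models:
            if m.path is None and m.gate_state is None:
                raise ConfigError(f"model {m.name!r}: neither path nor synthetic recipe")
            if m.path is not None and not Path(m.path).exists():
                raise ConfigError(f"model {m.name!r}: file not found: {m.path}")
            if m.gate_state is not None and m.gate_state not in GateState.__members__:
                raise ConfigError(f"model {m.name!r}: unknown gate state {m.gate_state}")
        if self.asp_table is not None and not Path(self.asp_table).exists():
            raise ConfigError(f"ASP table not found: {self.asp_table}")
        if self.star.path is not None and not Path(self.star.path).exists():
            raise ConfigError(f"STAR file not found: {self.star.path}")
        if self.compare_fit_set not in ("ALL_SHARED", "COMMON_CORE"):
            raise ConfigError(f"unknown fit set {self.compare_fit_set}")
        if self.energy_reference not in ("ISOLATED_CHAIN", "FULLY_EXTENDED"):
            raise ConfigError(f"unknown energy reference {self.energy_reference}")


def _load_model(src: ModelSource, seed: int) -> FibrilModel:
    if src.path is not None:
        return read_structure(src.path)
    spec = attr_like_layer_spec(GateState[src.gate_state])
    return make_fibril(
        spec,
        HelicalParameters(src.twist, src.rise),
        n_layers=src.n_layers,
        noise_sd=src.noise_sd,
        seed=seed,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the report; returns the report dict.

    Stage failures raise with the stage name attached; the config is fully
    validated before any compute starts.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    asp = load_asp_table(config.asp_table)
    report: dict = {
        "config": {
            **asdict(config),
            "asp_provenance": asp.provenance,
        },
        "stages": {},
    }

    def stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    # --- geometry ------------------------------------------------------
    t0 = stage("geometry")
    models: dict[str, FibrilModel] = {}
    geometry = {}
    for src in config.models:
        try:
            model = _load_model(src, config.seed)
        except Exception as exc:
            raise RuntimeError(f"stage geometry: model {src.name!r}: {exc}") from exc
        models[src.name] = model
        entry: dict = {"n_atoms": model.n_atoms, "layers": model.layers}
        if model.layers >= 2:
            params = estimate_helical_parameters(model)
            entry.update(
                twist_deg=params.twist,
                rise_A=params.rise,
                twist_sd=params.twist_sd,
                rise_sd=params.rise_sd,
            )
            if params.is_twisted:
                entry["crossover_A"] = round(params.crossover)
            else:
                entry["crossover_A"] = None
                entry["untwisted"] = True
        geometry[src.name] = entry
    report["stages"]["geometry"] = geometry
    log.info("geometry done in %.1fs", time.perf_counter() - t0)

    # --- stabilization energy -----------------------------------------
    t0 = stage("energy")
    energy = {}
    for name, model in models.items():
        try:
            profile = stabilization_energy(
                model,
                asp,
                stack_layers=config.stack_layers,
                reference=config.energy_reference,
                n_points=config.sasa_points,
            )
        except Exception as exc:
            raise RuntimeError(f"stage energy: model {name!r}: {exc}") from exc
        profile.per_residue.to_csv(outdir / f"energy_residue_{name}.tsv", sep="\t")
        residue_energy_colormap(profile).to_csv(
            outdir / f"energy_colors_{name}.tsv", sep="\t", index=False
        )
        energy[name] = {
            "chain_energy_kcal_mol": profile.chain_energy,
            "context": profile.context,
        }
    report["stages"]["energy"] = energy
    # cohort comparison against the shipped stability snapshot
    cmp = atlas_comparison()
    report["stages"]["energy"]["atlas_comparison"] = {
        "n_attr": cmp.n_a,
        "n_other": cmp.n_b,
        "U": cmp.u_statistic,
        "p_two_sided": cmp.p_value,
        "method": cmp.method,
    }
    log.info("energy done in %.1fs", time.perf_counter() - t0)

    # --- polymorph comparison -----------------------------------------
    t0 = stage("compare")
    comparison = {}
    if len(models) >= 2:
        try:
            table, profiles = deviation_matrix(
                models, layers=config.compare_layers, fit_set=config.compare_fit_set
            )
        except Exception as exc:
            raise RuntimeError(f"stage compare: {exc}") from exc
        table.to_csv(outdir / "rmsd_matrix.tsv", sep="\t")
        prof_rows = []
        for (na, nb), prof in profiles.items():
            for res, d in prof.per_residue.items():
                prof_rows.append({"pair": f"{na}|{nb}", "residue": res, "distance_A": d})
        pd.DataFrame(prof_rows).to_csv(
            outdir / "rmsd_profiles.tsv", sep="\t", index=False
        )
        comparison = {
            "rmsd_matrix": {a: dict(row) for a, row in table.round(4).iterrows()},
            "fit_set": config.compare_fit_set,
            "layers": config.compare_layers,
        }
    report["stages"]["comparison"] = comparison
    log.info("compare done in %.1fs", time.perf_counter() - t0)

    # --- filament tracing ---------------------------------------------
    t0 = stage("tracing")
    if config.star.path is not None:
        particles = read_star(config.star.path)
    else:
        star_kwargs = dict(config.star.synthetic)
        if "class_mixture" in star_kwargs:
            star_kwargs["class_mixture"] = ClassMixture(**star_kwargs["class_mixture"])
        star_kwargs.setdefault("seed", config.seed)
        particles, _truth = synthetic.make_star_fixture(SyntheticStarSpec(**star_kwargs))
    try:
        filaments = group_filaments(
            particles, linking=config.star.linking, threshold=config.star.threshold
        )
        summary = cooccurrence_summary(filaments)
    except Exception as exc:
        raise RuntimeError(f"stage tracing: {exc}") from exc
    summary.per_filament.to_csv(outdir / "filaments.tsv", sep="\t", index=False)
    report["stages"]["tracing"] = {
        "n_filaments": summary.n_filaments,
        "n_mixed": summary.n_mixed,
        "n_unassigned": summary.n_unassigned,
        "pure_counts": {str(k): v for k, v in summary.pure_counts.items()},
        "mixed_fraction": summary.mixed_fraction,
        "caveat": summary.caveat,
    }
    log.info("tracing done in %.1fs", time.perf_counter() - t0)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
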