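"""End-to-end orchestration: forge fixtures, run analyses, write reports.

A run is fully described by a :class:`RunConfig` (YAML-serializable)
plus its seeds, and is reproducible byte-for-byte in its numeric
outputs.  Stages: load or forge the ensemble, conformation-code
populations, sidechain topology groups, interaction profile, morphology,
and optional reference comparison; a provenance record (config hash,
seed, versions) accompanies every report bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .build import (FilamentSpec, GridPlacement, MixtureSpec,
                    make_mixture_trajectory)
from .geometry import Box
from .interactions import InteractionCriteria, interaction_profile
from .io import read_structure, read_trajectory, write_structure, write_trajectory
from .model import Ensemble, StructureFrame, Trajectory
from .morphology import (ReferenceConformer, min_rmsd_to_reference,
                         morphology_report)
from .sidechain import group_populations, theta_table
from .states import ConformationCode, RegionMap, population_table

log = logging.getLogger("trifil")


class ConfigError(ValueError):
    """Raised for invalid or incomplete run configurations."""


@dataclass
class ForgeSpec:
    """Synthetic-fixture recipe embedded in a run config."""

    sequence: str = "FFF"
    mixture: dict[str, float] = field(
        default_factory=lambda: {"b-b-b": 0.7, "aR-aR-b": 0.3})
    n_frames: int = 200
    n_runs: int = 3
    n_peptides: int = 30
    box: tuple[float, float, float] = (6.0, 6.0, 6.0)
    noise_sigma: float = 0.01
    assembly_rise: float | None = None   # angstrom; None = dispersed monomers


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    forge: ForgeSpec | None = None
    inputs: list[dict] = field(default_factory=list)  # {topology, trajectory}
    references: list[dict] = field(default_factory=list)  # {label, path, code}
    regions_yaml: str | None = None
    criteria: dict = field(default_factory=dict)
    syn_cut: float = 60.0
    anti_cut: float = 115.0
    seed: int = 0
    outdir: str = "trifil_out"
    rmsd_stride: int = 10

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "RunConfig":
        if os.path.exists(source):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        forge = data.pop("forge", None)
        cfg = cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__
                     and k != "forge"})
        if forge:
            if isinstance(forge.get("box"), list):
                forge["box"] = tuple(forge["box"])
            cfg.forge = ForgeSpec(**forge)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.forge is None and not self.inputs:
            raise ConfigError("config has neither forge spec nor input files")
        if self.forge is not None and self.inputs:
            raise ConfigError("config must use either forge or inputs, not both")

    def region_map(self) -> RegionMap:
        if self.regions_yaml:
            return RegionMap.from_yaml(self.regions_yaml)
        return RegionMap.default()

    def interaction_criteria(self) -> InteractionCriteria:
        return InteractionCriteria(**self.criteria)


def _load_ensemble(config: RunConfig) -> Ensemble:
    if config.forge is not None:
        return _forge_ensemble(config)
    runs = []
    for i, entry in enumerate(config.inputs):
        top = entry["topology"]
        traj_path = entry.get("trajectory")
        if traj_path:
            runs.append(read_trajectory(top, traj_path, run_id=f"run{i}"))
        else:
            frame = read_structure(top)
            runs.append(Trajectory(frames=[frame], run_id=f"run{i}"))
    return Ensemble(runs=runs)


def _forge_ensemble(config: RunConfig) -> Ensemble:
    fs = config.forge
    regions = config.region_map()
    components = [(ConformationCode.parse(code), w)
                  for code, w in sorted(fs.mixture.items())]
    mixture = MixtureSpec(components=components, n_frames=fs.n_frames,
                          n_runs=fs.n_runs, seed=config.seed)
    assembly = (FilamentSpec(n_copies=fs.n_peptides, rise=fs.assembly_rise,
                             orient=False)
                if fs.assembly_rise is not None else None)
    placement = GridPlacement(box=Box(*fs.box), n_peptides=fs.n_peptides)
    return make_mixture_trajectory(fs.sequence, mixture, assembly=assembly,
                                   regions=regions, placement=placement,
                                   noise_sigma=fs.noise_sigma)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def forge(config: RunConfig) -> dict:
    """Write the synthetic fixture dataset to disk with a manifest.

    Emits one GRO topology and one multi-model PDB trajectory per run,
    plus ``manifest.json`` listing every file with its SHA-256 checksum.
    """
    config.validate()
    if config.forge is None:
        raise ConfigError("forge requires a forge spec")
    os.makedirs(config.outdir, exist_ok=True)
    ensemble = _forge_ensemble(config)
    files = []
    for run in ensemble.runs:
        top_path = os.path.join(config.outdir, f"{run.run_id}_topology.gro")
        traj_path = os.path.join(config.outdir, f"{run.run_id}_traj.pdb")
        write_structure(run.frames[0], top_path)
        write_trajectory(run, traj_path)
        files.extend([top_path, traj_path])
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": {os.path.basename(p): _sha256(p) for p in files},
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _validate_reports(outdir: str) -> None:
    """Spot-check normalization invariants of the written tables."""
    import pandas as pd
    pop = pd.read_csv(os.path.join(outdir, "populations.csv"))
    if abs(pop["mean_fraction"].sum() - 1.0) > 1e-6:
        raise RuntimeError("population fractions do not sum to 1")
    grp = pd.read_csv(os.path.join(outdir, "groups.csv"))
    if abs(grp["mean_fraction"].sum() - 1.0) > 1e-6:
        raise RuntimeError("group fractions do not sum to 1")


def run_analysis(config: RunConfig, stages: tuple[str, ...] = (
        "classify", "topology", "interactions", "morphology", "report")) -> dict:
    """Run the full analysis pipeline and write the report bundle.

    Returns a dict of output paths.  Any stage failure aborts with the
    stage name and the offending entity in the exception message.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    regions = config.region_map()
    criteria = config.interaction_criteria()
    outputs: dict[str, str] = {}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("load")
        ensemble = _load_ensemble(config)
    except Exception as err:
        raise RuntimeError(f"stage load failed: {err}") from err

    if "classify" in stages:
        try:
            stage("classify")
            table = population_table(ensemble, regions)
            path = os.path.join(config.outdir, "populations.csv")
            table.to_csv(path)
            outputs["populations"] = path
        except Exception as err:
            raise RuntimeError(f"stage classify failed: {err}") from err

    if "topology" in stages:
        try:
            stage("topology")
            groups = group_populations(ensemble, regions,
                                       config.syn_cut, config.anti_cut)
            path = os.path.join(config.outdir, "groups.csv")
            groups.reset_index().to_csv(path, index=False)
            outputs["groups"] = path
            thetas = theta_table(ensemble, config.syn_cut, config.anti_cut)
            tpath = os.path.join(config.outdir, "theta.csv")
            thetas.to_csv(tpath)
            outputs["theta"] = tpath
        except Exception as err:
            raise RuntimeError(f"stage topology failed: {err}") from err

    if "interactions" in stages:
        try:
            stage("interactions")
            profile = interaction_profile(ensemble, criteria)
            path = os.path.join(config.outdir, "interactions.json")
            profile.to_json(path)
            outputs["interactions"] = path
        except Exception as err:
            raise RuntimeError(f"stage interactions failed: {err}") from err

    if "morphology" in stages:
        try:
            stage("morphology")
            report = {run.run_id: [morphology_report(f, criteria)
                                   for f in run.frames]
                      for run in ensemble.runs}
            path = os.path.join(config.outdir, "morphology.json")
            with open(path, "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            outputs["morphology"] = path
        except Exception as err:
            raise RuntimeError(f"stage morphology failed: {err}") from err

    if config.references:
        try:
            stage("references")
            sampled = [f for run in ensemble.runs
                       for f in run.frames[::max(1, config.rmsd_stride)]
                       ]
            conformers = []
            for frame in sampled:
                for pid in frame.peptides():
                    conformers.append(_extract_peptide(frame, int(pid)))
            rows = []
            for entry in config.references:
                ref = ReferenceConformer(label=entry["label"],
                                         frame=read_structure(entry["path"]),
                                         code=entry.get("code"))
                _, rmsd, code = min_rmsd_to_reference(conformers, ref,
                                                      regions=regions)
                rows.append({"reference": ref.label, "stated_code": ref.code,
                             "best_code": code, "rmsd_angstrom": rmsd})
            import pandas as pd
            path = os.path.join(config.outdir, "reference_comparison.csv")
            pd.DataFrame(rows).to_csv(path, index=False)
            outputs["references"] = path
        except Exception as err:
            raise RuntimeError(f"stage references failed: {err}") from err

    if "report" in stages:
        stage("report")
        if "populations" in outputs and "groups" in outputs:
            _validate_reports(config.outdir)
        provenance = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "trifil_version": __version__,
            "numpy_version": np.__version__,
            "outputs": sorted(os.path.basename(p) for p in outputs.values()),
        }
        ppath = os.path.join(config.outdir, "provenance.json")
        with open(ppath, "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        outputs["provenance"] = ppath
    return outputs


def _extract_peptide(frame: StructureFrame, pid: int) -> StructureFrame:
    m = frame.mask(peptide_id=pid)
    sub = StructureFrame(frame.atom_names[m], frame.residue_indices[m],
                         frame.residue_names[m], np.zeros(m.sum(), dtype=int),
                         frame.coords[m], box=None)
    return sub
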