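"""Sidechain rotation angles and the five-way arrangement taxonomy.

The rotation angle theta of two adjacent residues is the torsion of
their CA->CB vectors about the CA-CA axis, i.e. the dihedral
CB_i - CA_i - CA_{i+1} - CB_{i+1}.  A tripeptide has two such angles
(theta1, theta2).  Two adjacent sidechains are *anti* (opposite sides
of the backbone) when |theta| > 115 degrees and *syn* (same side) when
|theta| < 60 degrees; any |theta| in the closed 60-115 band is neither.

Combining the two angles yields five topology groups: all-anti,
all-syn, N-syn (the N-terminal sidechain points with the middle one),
C-syn, and "other" for any angle in the excluded band.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geometry import dihedral
from .model import Ensemble, StructureFrame, TopologyError
from .states import ConformationCode, RegionMap, enumerate_codes

SYN_CUT = 60.0
ANTI_CUT = 115.0


class ThetaPair(NamedTuple):
    theta1: float
    theta2: float


class TopologyGroup(Enum):
    ALL_ANTI = "all_anti"
    ALL_SYN = "all_syn"
    N_SYN = "n_syn"
    C_SYN = "c_syn"
    OTHER = "other"


def rotation_angle(frame: StructureFrame, peptide_id: int, i: int) -> float:
    """Signed rotation angle theta_i (degrees) between residues i and i+1."""
    if i not in (1, 2):
        raise ValueError("theta index must be 1 or 2")
    for r in (i, i + 1):
        if not frame.has_atom(peptide_id, r, "CB"):
            raise TopologyError(
                f"peptide {peptide_id} residue {r} misses CB; "
                f"cannot compute theta{i}")
    return dihedral(frame.position(peptide_id, i, "CB"),
                    frame.position(peptide_id, i, "CA"),
                    frame.position(peptide_id, i + 1, "CA"),
                    frame.position(peptide_id, i + 1, "CB"))


def theta_pair(frame: StructureFrame, peptide_id: int) -> ThetaPair:
    return ThetaPair(rotation_angle(frame, peptide_id, 1),
                     rotation_angle(frame, peptide_id, 2))


def topology_group(thetas: ThetaPair, syn_cut: float = SYN_CUT,
                   anti_cut: float = ANTI_CUT) -> TopologyGroup:
    """Five-way sidechain-arrangement classification from (theta1, theta2).

    The cuts are strict inequalities, so angles exactly at 60 or 115
    degrees fall in the excluded band (OTHER).
    """
    a, b = abs(thetas.theta1), abs(thetas.theta2)

    def is_anti(x):
        return x > anti_cut

    def is_syn(x):
        return x < syn_cut

    if is_anti(a) and is_anti(b):
        return TopologyGroup.ALL_ANTI
    if is_syn(a) and is_syn(b):
        return TopologyGroup.ALL_SYN
    if is_syn(a) and is_anti(b):
        return TopologyGroup.N_SYN
    if is_anti(a) and is_syn(b):
        return TopologyGroup.C_SYN
    return TopologyGroup.OTHER


def reference_theta_map(regions: RegionMap, sequence: str = "FFF",
                        syn_cut: float = SYN_CUT,
                        anti_cut: float = ANTI_CUT) -> pd.DataFrame:
    """(theta1, theta2) and group for every enumerable conformation code.

    Each code is realized as an ideal noise-free fixture at the basin
    centres, giving a computed analogue of the full 48-state scatter of
    sidechain orientations.  Deterministic for a given region map.
    """
    from .build import build_from_code

    rows = []
    for code in enumerate_codes(regions):
        frame = build_from_code(sequence, code, regions)
        t = theta_pair(frame, 0)
        rows.append({"code": str(code), "theta1": t.theta1, "theta2": t.theta2,
                     "group": topology_group(t, syn_cut, anti_cut).value})
    return pd.DataFrame(rows).set_index("code")


def group_populations(ensemble: Ensemble, regions: RegionMap | None = None,
                      syn_cut: float = SYN_CUT,
                      anti_cut: float = ANTI_CUT) -> pd.DataFrame:
    """Topology-group fractions over peptide x frame observations.

    Fractions are computed per run (the five groups sum to one) and
    summarized as mean and sample standard deviation across runs.
    """
    groups = [g.value for g in TopologyGroup]
    per_run = {}
    for run in ensemble.runs:
        counts = dict.fromkeys(groups, 0)
        total = 0
        for frame in run.frames:
            for pid in frame.peptides():
                g = topology_group(theta_pair(frame, pid), syn_cut, anti_cut)
                counts[g.value] += 1
                total += 1
        if total == 0:
            raise ValueError(f"run {run.run_id} contains no peptide observations")
        per_run[run.run_id] = {g: counts[g] / total for g in groups}
    df = pd.DataFrame(per_run, index=groups)
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1) if df.shape[1] > 1 else \
        pd.Series(0.0, index=df.index)
    out = pd.DataFrame({"mean_fraction": mean, "sd_fraction": sd.fillna(0.0)})
    out.index.name = "group"
    return out


@dataclass
class ThetaTable:
    """Per-observation theta values, one row per peptide x frame."""

    table: pd.DataFrame

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def theta_table(ensemble: Ensemble, syn_cut: float = SYN_CUT,
                anti_cut: float = ANTI_CUT) -> ThetaTable:
    rows = []
    for run_id, frame in ensemble.iter_frames():
        for pid in frame.peptides():
            t = theta_pair(frame, pid)
            rows.append({"run": run_id, "frame": frame.frame_index,
                         "peptide": int(pid), "theta1": t.theta1,
                         "theta2": t.theta2,
                         "group": topology_group(t, syn_cut, anti_cut).value})
    return ThetaTable(pd.DataFrame(rows))
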