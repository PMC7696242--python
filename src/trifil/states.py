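"""Backbone rotamer-state classification and conformation codes.

Each amino-acid residue is assigned one of four Ramachandran basins —
right-handed helical (aR), left-handed helical (aL), extended beta (b)
and left-handed polyproline II (p) — from its (phi, psi) pair, and a
tripeptide conformation is the ordered triple of the three per-residue
states, rendered as a three-letter code such as ``b-b-b``.

With four states per residue there are 4^3 = 64 raw codes.  The default
scheme additionally merges the geometrically close beta and PPII basins
at the C-terminal position, which reduces the state space to
4 x 4 x 3 = 48 uniquely defined conformations; the merge is a plain
config switch (``reduce_terminal=False`` restores all 64).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import yaml

from .geometry import _wrap_halfopen
from .model import Ensemble, StructureFrame, backbone_dihedrals


class RotamerState(Enum):
    ALPHA_R = "aR"
    ALPHA_L = "aL"
    BETA = "b"
    PPII = "p"

    def __lt__(self, other: "RotamerState") -> bool:
        return self.value < other.value


_TOKEN_TO_STATE = {s.value: s for s in RotamerState}


@dataclass(frozen=True)
class Rect:
    """Half-open rectangle on the Ramachandran torus.

    Closed on the lower phi/psi edge, open on the upper — except that an
    upper bound of exactly 180 is closed, since angles live in
    (-180, 180].
    """

    phi_lo: float
    phi_hi: float
    psi_lo: float
    psi_hi: float

    def contains(self, phi: float, psi: float) -> bool:
        def within(x, lo, hi):
            if hi == 180.0:
                return lo <= x <= 180.0
            return lo <= x < hi

        return within(phi, self.phi_lo, self.phi_hi) and \
            within(psi, self.psi_lo, self.psi_hi)


#: Basin centres used when realizing a state as ideal (phi, psi) targets.
#: The helical centres sit deep in their basins so that ideal
#: helical-helical neighbours are unambiguously syn (|theta| < 60 with
#: margin); at the textbook alpha-helix point (-60, -45) the CA-CB
#: torsion of adjacent residues falls in the excluded 60-115 band.
DEFAULT_CENTERS: dict[RotamerState, tuple[float, float]] = {
    RotamerState.ALPHA_R: (-80.0, -50.0),
    RotamerState.ALPHA_L: (80.0, 50.0),
    RotamerState.BETA: (-120.0, 130.0),
    RotamerState.PPII: (-75.0, 150.0),
}

_DEFAULT_REGIONS: dict[RotamerState, tuple[Rect, ...]] = {
    RotamerState.ALPHA_R: (Rect(-180, 0, -120, 50),),
    RotamerState.ALPHA_L: (Rect(0, 180, -180, 180),),
    RotamerState.BETA: (Rect(-180, -100, 50, 180), Rect(-180, -100, -180, -120)),
    RotamerState.PPII: (Rect(-100, 0, 50, 180), Rect(-100, 0, -180, -120)),
}


@dataclass
class RegionMap:
    """Partition of the (phi, psi) torus into the four rotamer basins.

    The rectangles must be disjoint and jointly cover the torus, so
    classification is a total function.  ``reduce_terminal`` enables the
    beta/PPII merge at the third residue.
    """

    regions: dict[RotamerState, tuple[Rect, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_REGIONS))
    centers: dict[RotamerState, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CENTERS))
    reduce_terminal: bool = True

    @classmethod
    def default(cls, reduce_terminal: bool = True) -> "RegionMap":
        return cls(reduce_terminal=reduce_terminal)

    # -- YAML round trip ---------------------------------------------
    def to_yaml(self, path: str | None = None) -> str:
        data = {
            "reduce_terminal": self.reduce_terminal,
            "centers": {s.value: list(self.centers[s]) for s in self.centers},
            "regions": {
                s.value: [[r.phi_lo, r.phi_hi, r.psi_lo, r.psi_hi]
                          for r in rects]
                for s, rects in self.regions.items()
            },
        }
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "RegionMap":
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, ValueError):
            data = yaml.safe_load(source)
        regions = {
            _TOKEN_TO_STATE[tok]: tuple(Rect(*r) for r in rects)
            for tok, rects in data["regions"].items()
        }
        centers = {_TOKEN_TO_STATE[tok]: tuple(c)
                   for tok, c in data["centers"].items()}
        return cls(regions=regions, centers=centers,
                   reduce_terminal=bool(data["reduce_terminal"]))


@dataclass(frozen=True, order=True)
class ConformationCode:
    """Ordered triple of per-residue rotamer states."""

    states: tuple[RotamerState, RotamerState, RotamerState]

    def __str__(self) -> str:
        return "-".join(s.value for s in self.states)

    @classmethod
    def parse(cls, text: str) -> "ConformationCode":
        tokens = text.split("-")
        if len(tokens) != 3 or any(t not in _TOKEN_TO_STATE for t in tokens):
            raise ValueError(f"not a conformation code: {text!r}")
        return cls(tuple(_TOKEN_TO_STATE[t] for t in tokens))

    @classmethod
    def of(cls, *states: RotamerState) -> "ConformationCode":
        return cls(tuple(states))


def classify_residue(phi: float, psi: float, regions: RegionMap) -> RotamerState:
    """Assign a (phi, psi) pair to its rotamer basin (total, deterministic)."""
    phi = _wrap_halfopen(phi)
    psi = _wrap_halfopen(psi)
    hits = [state for state, rects in regions.regions.items()
            if any(r.contains(phi, psi) for r in rects)]
    if len(hits) != 1:
        raise ValueError(
            f"region map is not a partition at ({phi:.3f}, {psi:.3f}): {hits}")
    return hits[0]


def reduce_code(code: ConformationCode, regions: RegionMap) -> ConformationCode:
    """Apply the terminal beta/PPII merge if enabled."""
    if regions.reduce_terminal and code.states[2] is RotamerState.PPII:
        return ConformationCode.of(code.states[0], code.states[1],
                                   RotamerState.BETA)
    return code


def classify_peptide(frame: StructureFrame, peptide_id: int,
                     regions: RegionMap) -> ConformationCode:
    """Classify one tripeptide from its six backbone dihedrals."""
    d = backbone_dihedrals(frame, peptide_id)
    states = tuple(classify_residue(d[2 * i], d[2 * i + 1], regions)
                   for i in range(3))
    return reduce_code(ConformationCode(states), regions)


def enumerate_codes(regions: RegionMap) -> list[ConformationCode]:
    """All distinct conformation codes under the scheme, sorted.

    64 without terminal reduction; 48 with the default beta/PPII merge
    at the C-terminal position.
    """
    all_states = list(RotamerState)
    seen = set()
    for s1 in all_states:
        for s2 in all_states:
            for s3 in all_states:
                seen.add(reduce_code(ConformationCode.of(s1, s2, s3), regions))
    return sorted(seen, key=lambda c: tuple(s.value for s in c.states))


@dataclass
class PopulationTable:
    """Per-code population fractions with across-run statistics.

    ``per_run`` has one column per run (fractions summing to 1);
    ``summary`` carries mean_fraction, sd_fraction (sample sd across
    runs) and n_obs (total observations of the code).
    """

    per_run: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path: str) -> None:
        out = self.summary.reset_index().rename(columns={"index": "code"})
        out.to_csv(path, index=False)


def population_table(ensemble: Ensemble, regions: RegionMap) -> PopulationTable:
    """Conformation-code populations over peptide x frame observations.

    Fractions are computed per run; the mean and standard deviation
    across independent runs give the error bars.
    """
    if not ensemble.runs or not any(len(r.frames) for r in ensemble.runs):
        raise ValueError("empty ensemble")
    run_fracs = {}
    run_counts = {}
    for run in ensemble.runs:
        counts: dict[str, int] = {}
        total = 0
        for frame in run.frames:
            for pid in frame.peptides():
                code = str(classify_peptide(frame, pid, regions))
                counts[code] = counts.get(code, 0) + 1
                total += 1
        if total == 0:
            raise ValueError(f"run {run.run_id} contains no peptide observations")
        run_fracs[run.run_id] = {c: n / total for c, n in counts.items()}
        run_counts[run.run_id] = counts
    codes = sorted({c for fr in run_fracs.values() for c in fr})
    per_run = pd.DataFrame(
        {rid: [run_fracs[rid].get(c, 0.0) for c in codes] for rid in run_fracs},
        index=codes)
    mean = per_run.mean(axis=1)
    sd = per_run.std(axis=1, ddof=1) if per_run.shape[1] > 1 else \
        pd.Series(0.0, index=per_run.index)
    n_obs = pd.Series({c: sum(rc.get(c, 0) for rc in run_counts.values())
                       for c in codes})
    summary = pd.DataFrame({"mean_fraction": mean, "sd_fraction": sd.fillna(0.0),
                            "n_obs": n_obs})
    return PopulationTable(per_run=per_run, summary=summary)


def most_populated(table: PopulationTable) -> tuple[ConformationCode, float]:
    """Code with the largest mean fraction; ties break lexicographically."""
    s = table.summary["mean_fraction"]
    best = s[s == s.max()].index.sort_values()[0]
    return ConformationCode.parse(best), float(s[best])
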