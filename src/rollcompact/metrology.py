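"""Ribbon quality metrology.

Ribbon porosity from oil-intrusion weighings, tensile strength from
three-point bending, per-material compaction profiles over the hydraulic
pressure grid, and splitting-mode frequency tables.

Porosity is stored as a fraction throughout (the percent form is applied
only when rendering reports), so solid fraction SF = 1 - eps holds exactly
at every pressure point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRESSURE_GRID",
    "SPLITTING_MODES",
    "OilIntrusionRecord",
    "BendingRecord",
    "RibbonSample",
    "CompactionProfile",
    "ribbon_porosity",
    "tensile_strength",
    "splitting_frequency_table",
    "transversal_rate",
    "build_profile",
    "read_ribbon_table",
    "profiles_from_table",
]

#: hydraulic pressure grid used for every material, bar
PRESSURE_GRID = (30, 50, 70, 90, 110)

#: recognized splitting-mode codes: transversal, longitudinal into 2/3
#: pieces, longitudinally joined cracks, crumbles into fragments; NONE =
#: intact ribbon, NO_RIBBON = powder did not compact.
SPLITTING_MODES = ("NONE", "T", "L2", "L3", "LJ", "LN", "NO_RIBBON")
LONGITUDINAL_MODES = ("L2", "L3", "LJ", "LN")

DEFAULT_SUPPORT_SPAN_MM = 15.0


class MetrologyError(ValueError):
    pass


@dataclass(frozen=True)
class OilIntrusionRecord:
    """Weighings for the oil-intrusion porosity measurement of one ribbon piece."""

    m_ribbon: float          # g, dry ribbon
    m_oil_plus_ribbon: float  # g, oil-saturated ribbon
    rho_oil: float           # g/mL, paraffin oil density
    rho_true: float          # g/mL, true density of the (single) raw material

    def __post_init__(self):
        if self.m_ribbon <= 0:
            raise MetrologyError("ribbon mass must be positive")
        if self.m_oil_plus_ribbon < self.m_ribbon:
            raise MetrologyError("oil-saturated mass below dry mass")
        if self.rho_oil <= 0 or self.rho_true <= 0:
            raise MetrologyError("densities must be positive")


@dataclass(frozen=True)
class BendingRecord:
    """Three-point bending measurement of one ribbon piece (N and mm units)."""

    force: float                        # F, N at breakage
    width: float                        # W, mm
    thickness: float                    # T, mm
    span: float = DEFAULT_SUPPORT_SPAN_MM  # L, mm between lower supports

    def __post_init__(self):
        if min(self.force, self.width, self.thickness, self.span) <= 0:
            raise MetrologyError("bending record requires positive F, L, W, T")


@dataclass
class RibbonSample:
    """One ribbon replicate: material x pressure, optional measurements, splitting modes.

    ``modes`` is a set because a single ribbon can show transversal and
    longitudinal splitting simultaneously; tallies count T and L
    independently. NO_RIBBON samples carry no measurement records.
    """

    material_id: str
    pressure: float
    replicate: int = 1
    oil: OilIntrusionRecord | None = None
    bend: BendingRecord | None = None
    modes: frozenset[str] = frozenset({"NONE"})

    def __post_init__(self):
        self.modes = frozenset(self.modes)
        unknown = self.modes - set(SPLITTING_MODES)
        if unknown:
            raise MetrologyError(f"unknown splitting mode(s): {sorted(unknown)}")
        if "NO_RIBBON" in self.modes and (self.oil is not None or self.bend is not None):
            raise MetrologyError("NO_RIBBON samples cannot carry measurements")

    @property
    def tangible(self) -> bool:
        return "NO_RIBBON" not in self.modes


@dataclass
class CompactionProfile:
    """Replicate-averaged (pressure, SF, TS, porosity) profile for one material."""

    material_id: str
    pressures: np.ndarray        # bar, strictly increasing, tangible points only
    porosity: np.ndarray         # fraction
    tensile_strength: np.ndarray  # MPa; NaN where TS untestable
    n_reps: np.ndarray
    porosity_sd: np.ndarray
    ts_sd: np.ndarray
    modes: dict[float, frozenset[str]] = field(default_factory=dict)
    non_compactable: bool = False

    @property
    def solid_fraction(self) -> np.ndarray:
        return 1.0 - self.porosity


def ribbon_porosity(rec: OilIntrusionRecord) -> float:
    """Ribbon porosity (fraction) from oil intrusion.

    V_oil = (m_sat - m_dry)/rho_oil is the pore volume filled by oil,
    V_ribbon = m_dry/rho_true the solid volume; eps = V_oil/(V_oil + V_ribbon).
    """
    v_oil = (rec.m_oil_plus_ribbon - rec.m_ribbon) / rec.rho_oil
    v_ribbon = rec.m_ribbon / rec.rho_true
    total = v_oil + v_ribbon
    if total <= 0:
        raise MetrologyError("zero total volume")
    return v_oil / total


def tensile_strength(rec: BendingRecord) -> float:
    """Three-point-bending tensile strength TS = 3FL/(2WT^2), MPa for N/mm inputs."""
    return 3.0 * rec.force * rec.span / (2.0 * rec.width * rec.thickness**2)


def splitting_frequency_table(samples: Iterable[RibbonSample]) -> pd.DataFrame:
    """Occurrence counts of each splitting mode per pressure.

    Rows: T, L2, L3, LJ, LN, L_total (any longitudinal), n_tangible.
    A sample showing both T and an L mode counts once in each row.
    """
    samples = list(samples)
    pressures = sorted({s.pressure for s in samples}) or list(PRESSURE_GRID)
    rows = ["T", *LONGITUDINAL_MODES, "L_total", "n_tangible"]
    table = pd.DataFrame(0, index=rows, columns=pressures)
    for s in samples:
        if not s.tangible:
            continue
        table.loc["n_tangible", s.pressure] += 1
        for mode in s.modes:
            if mode == "NONE":
                continue
            table.loc[mode, s.pressure] += 1
        if s.modes & set(LONGITUDINAL_MODES):
            table.loc["L_total", s.pressure] += 1
    return table


def transversal_rate(samples: Iterable[RibbonSample]) -> float:
    """Fraction of tangible ribbon samples showing transversal splitting."""
    tangible = [s for s in samples if s.tangible]
    if not tangible:
        return float("nan")
    return sum("T" in s.modes for s in tangible) / len(tangible)


def build_profile(samples: Sequence[RibbonSample]) -> CompactionProfile:
    """Aggregate replicates into a per-pressure mean profile for one material.

    Porosity and TS are averaged arithmetically across replicates; the
    standard deviation is retained as dispersion metadata. Pressures at
    which no ribbon formed are absent from the profile; a material whose
    every pressure yielded NO_RIBBON is flagged non-compactable.
    """
    if not samples:
        raise MetrologyError("no samples")
    mats = {s.material_id for s in samples}
    if len(mats) != 1:
        raise MetrologyError(f"mixed materials in one profile: {sorted(mats)}")
    material_id = samples[0].material_id

    tangible = [s for s in samples if s.tangible]
    if not tangible:
        return CompactionProfile(
            material_id, np.array([]), np.array([]), np.array([]),
            np.array([], dtype=int), np.array([]), np.array([]),
            modes={}, non_compactable=True,
        )

    pressures = sorted({s.pressure for s in tangible})
    eps_mean, eps_sd, ts_mean, ts_sd, nrep, modes = [], [], [], [], [], {}
    for p in pressures:
        group = [s for s in tangible if s.pressure == p]
        eps = [ribbon_porosity(s.oil) for s in group if s.oil is not None]
        ts = [tensile_strength(s.bend) for s in group if s.bend is not None]
        eps_mean.append(np.mean(eps) if eps else np.nan)
        eps_sd.append(np.std(eps, ddof=1) if len(eps) > 1 else 0.0)
        ts_mean.append(np.mean(ts) if ts else np.nan)
        ts_sd.append(np.std(ts, ddof=1) if len(ts) > 1 else 0.0)
        nrep.append(len(group))
        modes[p] = frozenset().union(*(s.modes for s in group)) - {"NONE"}

    return CompactionProfile(
        material_id,
        np.asarray(pressures, dtype=float),
        np.asarray(eps_mean),
        np.asarray(ts_mean),
        np.asarray(nrep, dtype=int),
        np.asarray(eps_sd),
        np.asarray(ts_sd),
        modes=modes,
    )


# ---------------------------------------------------------------------------
# tabular I/O (long format, one row per replicate)

RIBBON_COLUMNS = [
    "material_id", "pressure_bar", "replicate", "m_ribbon_g", "m_oilsat_g",
    "rho_oil", "rho_true", "width_mm", "thickness_mm", "force_N", "span_mm",
    "splitting_modes",
]


def read_ribbon_table(path) -> list[RibbonSample]:
    """Parse a long-format ribbon measurement CSV into RibbonSample records."""
    df = pd.read_csv(path)
    missing = set(RIBBON_COLUMNS) - set(df.columns)
    if missing:
        raise MetrologyError(f"ribbon table missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        modes = frozenset(str(row.splitting_modes).split(";"))
        oil = bend = None
        if "NO_RIBBON" not in modes:
            if np.isfinite(row.m_ribbon_g) and np.isfinite(row.m_oilsat_g):
                oil = OilIntrusionRecord(row.m_ribbon_g, row.m_oilsat_g,
                                         row.rho_oil, row.rho_true)
            if np.isfinite(row.force_N):
                bend = BendingRecord(row.force_N, row.width_mm,
                                     row.thickness_mm, row.span_mm)
        samples.append(RibbonSample(str(row.material_id), float(row.pressure_bar),
                                    int(row.replicate), oil, bend, modes))
    return samples


def profiles_from_table(samples: Iterable[RibbonSample]) -> dict[str, CompactionProfile]:
    """Group samples by material and build a profile for each."""
    by_mat: dict[str, list[RibbonSample]] = {}
    for s in samples:
        by_mat.setdefault(s.material_id, []).append(s)
    return {m: build_profile(v) for m, v in sorted(by_mat.items())}


def profile_table(profiles: dict[str, CompactionProfile]) -> pd.DataFrame:
    """Long-format table (material x pressure) of SF, TS, porosity and dispersion."""
    rows = []
    for mid, prof in profiles.items():
        if prof.non_compactable:
            continue
        for i, p in enumerate(prof.pressures):
            rows.append({
                "material_id": mid, "pressure_bar": p,
                "SF": prof.solid_fraction[i], "TS": prof.tensile_strength[i],
                "porosity": prof.porosity[i], "n_reps": prof.n_reps[i],
                "porosity_sd": prof.porosity_sd[i], "TS_sd": prof.ts_sd[i],
                "modes": ";".join(sorted(prof.modes.get(p, frozenset()))) or "NONE",
            })
    return pd.DataFrame(rows)
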