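"""Powder descriptor computation.

Implements the SeDeM-style characterization arithmetic that turns raw
instrument readings (masses, volumes, cone geometry, moisture weights,
particle-size histograms) into the 22 named material descriptors used as
the X-block of the latent-variable model: particle-size statistics
(D10/D50/D90, span, %Pf, homogeneity index), density and packing indices
(bulk/tapped/true density, solid fraction, porosity, Hausner ratio, Carr
index, inter-particle porosity), flow (angle of repose, flow time),
moisture (%HR, %H), compactability (cohesion index) and texture
(cohesiveness, springiness, springiness coefficient).

Quantities that are measured directly on an instrument (flow time,
moisture content, cohesion index, texture metrics) are validated and
passed through; everything else is computed from the raw readings.
Porosities and solid fractions are stored as fractions in [0, 1]; the
angle of repose is reported in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PSDHistogram",
    "PowderRawMeasurements",
    "InvalidMeasurementError",
    "bulk_and_tapped_density",
    "packing_indices",
    "angle_of_repose",
    "hygroscopicity",
    "true_density",
    "powder_solid_fraction",
    "psd_summary",
    "homogeneity_index",
    "compute_descriptors",
    "DESCRIPTOR_COLUMNS",
]

#: canonical column order of the descriptor table (SeDeM-style symbols)
DESCRIPTOR_COLUMNS = [
    "D10", "D50", "D90", "span", "PfPct", "Itheta",
    "Da", "Dc", "Dt", "SFp", "epsP", "IH", "IC", "Ie",
    "tflow", "AOR", "HRpct", "Hpct", "Icd", "Co", "Sp", "Spco",
]


class InvalidMeasurementError(ValueError):
    """Raised when raw readings violate physical preconditions."""


@dataclass(frozen=True)
class PSDHistogram:
    """Particle-size distribution as a binned histogram plus quantiles.

    Parameters
    ----------
    bin_edges : ascending bin boundaries in micrometres, length nbins+1.
    frequency : percentage of mass per bin; must sum to 100 within 0.01.
    d10, d50, d90 : undersize quantiles in micrometres.
    """

    bin_edges: np.ndarray
    frequency: np.ndarray
    d10: float
    d50: float
    d90: float

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        freq = np.asarray(self.frequency, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "frequency", freq)
        if edges.ndim != 1 or freq.ndim != 1 or edges.size != freq.size + 1:
            raise InvalidMeasurementError("bin_edges must have len(frequency)+1 entries")
        if np.any(np.diff(edges) <= 0):
            raise InvalidMeasurementError("bin edges must be strictly ascending")
        if np.any(freq < 0):
            raise InvalidMeasurementError("bin frequencies must be non-negative")
        if abs(freq.sum() - 100.0) > 0.01:
            raise InvalidMeasurementError(
                f"bin frequencies must sum to 100 +- 0.01, got {freq.sum():.4f}"
            )
        if not (self.d10 <= self.d50 <= self.d90):
            raise InvalidMeasurementError("quantiles must satisfy D10 <= D50 <= D90")

    @property
    def bin_means(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PowderRawMeasurements:
    """Instrument-level readings for one material.

    Texture metrics and other measured-only descriptors are carried as
    given and validated in :func:`compute_descriptors`.
    """

    sample_mass: float            # g, cylinder fill for density
    bulk_volume: float            # Va, mL
    tapped_volume: float          # Vc, mL
    tablet_hardness: float        # Icd, N (0 allowed: non-compactable powder)
    cone_height: float            # h, mm
    cone_diameter: float          # r, mm
    flow_time: float              # t'', s
    moisture_loss_pct: float      # %HR
    hygro_weights: tuple[float, float, float]   # (m1, m2, m3), g
    true_density_mass: float      # m, g (pycnometry fill)
    true_density_volumes: tuple[float, float]   # (V1, V2), mL
    psd: PSDHistogram
    cohesiveness: float = 0.0     # Co
    springiness: float = 0.0      # Sp
    springiness_coeff: float = 0.0  # Sp-co


def bulk_and_tapped_density(m: float, va: float, vc: float) -> tuple[float, float]:
    """Bulk density Da = m/Va and tapped density Dc = m/Vc (g/mL)."""
    if m <= 0 or va <= 0 or vc <= 0:
        raise InvalidMeasurementError("mass and volumes must be positive")
    if vc > va:
        raise InvalidMeasurementError("tapped volume cannot exceed bulk volume")
    return m / va, m / vc


def packing_indices(da: float, dc: float) -> tuple[float, float, float]:
    """Inter-particle porosity Ie, Carr index IC (%) and Hausner ratio IH.

    Ie = (Dc - Da)/(Dc*Da), IC = 100*(Dc - Da)/Dc, IH = Dc/Da.
    Scale-invariant in (Da, Dc) except Ie, which carries the raw
    mL/g dimension of its defining formula.
    """
    if da <= 0 or dc <= 0:
        raise InvalidMeasurementError("densities must be positive")
    if dc < da:
        raise InvalidMeasurementError("tapped density below bulk density")
    ie = (dc - da) / (dc * da)
    ic = (dc - da) / dc * 100.0
    ih = dc / da
    return ie, ic, ih


def angle_of_repose(h: float, r: float) -> float:
    """Angle of repose in degrees from cone height h and diameter r, tan(AOR) = 2h/r."""
    if r <= 0:
        raise InvalidMeasurementError("cone diameter must be positive")
    if h < 0:
        raise InvalidMeasurementError("cone height cannot be negative")
    return math.degrees(math.atan(2.0 * h / r))


def hygroscopicity(m1: float, m2: float, m3: float) -> float:
    """%H = 100*(m3 - m2)/(m2 - m1); may be negative if the sample lost mass."""
    if m2 <= m1:
        raise InvalidMeasurementError("loaded bottle must outweigh empty bottle (m2 > m1)")
    return (m3 - m2) / (m2 - m1) * 100.0


def true_density(m: float, v1: float, v2: float) -> float:
    """True (pycnometric) density Dt = m/(V1 - V2), g/mL."""
    if m <= 0:
        raise InvalidMeasurementError("sample mass must be positive")
    if v1 <= v2:
        raise InvalidMeasurementError("empty-cell volume must exceed loaded volume (V1 > V2)")
    return m / (v1 - v2)


def powder_solid_fraction(da: float, dt: float) -> tuple[float, float]:
    """Powder solid fraction SF_p = Da/Dt and porosity eps_p = 1 - SF_p.

    A bulk density exceeding the true density is physically inconsistent;
    it is reported (warning) but never clamped, to preserve the audit trail.
    """
    if da <= 0 or dt <= 0:
        raise InvalidMeasurementError("densities must be positive")
    if da > dt:
        import warnings

        warnings.warn(
            f"bulk density {da:.4g} exceeds true density {dt:.4g}; "
            "solid fraction > 1 reported unclamped",
            stacklevel=2,
        )
    sfp = da / dt
    return sfp, 1.0 - sfp


def psd_summary(psd: PSDHistogram, fines_cutoff: float = 50.0) -> tuple[float, float]:
    """Distribution width span = (D90 - D10)/D50 and fines fraction %Pf.

    %Pf is the cumulative undersize percentage at ``fines_cutoff`` (um),
    obtained by linear interpolation of the cumulative curve over the
    histogram bins.
    """
    if psd.d50 <= 0:
        raise InvalidMeasurementError("D50 must be positive")
    span = (psd.d90 - psd.d10) / psd.d50
    cum = np.concatenate([[0.0], np.cumsum(psd.frequency)])
    pf = float(np.interp(fines_cutoff, psd.bin_edges, cum, left=0.0, right=cum[-1]))
    return span, pf


def homogeneity_index(psd: PSDHistogram) -> float:
    """Homogeneity index of the size distribution, in (0, 1].

    With the majority bin m (largest frequency, ties resolved toward the
    smaller-diameter bin) of mean diameter d_m and frequency F_m::

        Itheta = F_m / (100 + sum_{n>=1} (d_{m+n} - d_m) F_{m+n}
                              + (d_m - d_{m-n}) F_{m-n})

    so a single occupied bin gives F_m/100 = 1 and spreading mass toward
    farther bins strictly lowers the index.
    """
    freq = psd.frequency
    if freq.sum() <= 0:
        raise InvalidMeasurementError("empty histogram")
    m = int(np.argmax(freq))  # argmax takes the first (smaller-diameter) bin on ties
    d = psd.bin_means
    fm = freq[m]
    denom = 100.0
    for j in range(len(freq)):
        if j == m:
            continue
        denom += abs(d[j] - d[m]) * freq[j]
    return float(fm / denom)


def compute_descriptors(raw: PowderRawMeasurements) -> dict[str, float]:
    """Full descriptor vector for one material, keyed by descriptor symbol.

    Measured-only descriptors (tflow, HRpct, Icd, Co, Sp, Spco) are range-
    validated and passed through; all others are computed from the raw
    readings. Returns a plain dict in :data:`DESCRIPTOR_COLUMNS` order.
    """
    if raw.flow_time < 0 or raw.tablet_hardness < 0:
        raise InvalidMeasurementError("flow time and cohesion index must be >= 0")
    if raw.moisture_loss_pct < 0 or raw.moisture_loss_pct > 100:
        raise InvalidMeasurementError("moisture content must lie in [0, 100] %")

    da, dc = bulk_and_tapped_density(raw.sample_mass, raw.bulk_volume, raw.tapped_volume)
    ie, ic, ih = packing_indices(da, dc)
    aor = angle_of_repose(raw.cone_height, raw.cone_diameter)
    h_pct = hygroscopicity(*raw.hygro_weights)
    dt = true_density(raw.true_density_mass, *raw.true_density_volumes)
    sfp, eps_p = powder_solid_fraction(da, dt)
    span, pf = psd_summary(raw.psd)
    itheta = homogeneity_index(raw.psd)

    return {
        "D10": raw.psd.d10, "D50": raw.psd.d50, "D90": raw.psd.d90,
        "span": span, "PfPct": pf, "Itheta": itheta,
        "Da": da, "Dc": dc, "Dt": dt, "SFp": sfp, "epsP": eps_p,
        "IH": ih, "IC": ic, "Ie": ie,
        "tflow": raw.flow_time, "AOR": aor,
        "HRpct": raw.moisture_loss_pct, "Hpct": h_pct,
        "Icd": raw.tablet_hardness,
        "Co": raw.cohesiveness, "Sp": raw.springiness, "Spco": raw.springiness_coeff,
    }
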