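"""Synthetic material library.

The original 81-material library (53 excipients, 28 natural product
powders compacted at 30-110 bar) is not distributed with its raw
per-material measurements, so this module generates a stand-in with the
same statistical structure: the published property envelopes (true
density 1.145-2.915 g/mL, powder porosity 0.4479-0.8456, cohesion index
0-503 N, springiness 0.1255-0.46), the published category mix, and the
pressure-porosity-strength mechanics the analysis assumes:

    eps(P) = eps_inf + (eps0 - eps_inf) * exp(-P / Pc)
    TS(P)  = TS0 * exp(-kb * eps(P)) * exp(N(0, sigma_TS^2))

Each material's intended RCBCS category is imposed by construction — the
porosity-law parameters are drawn from category-specific windows and TS0
is back-solved from the binding classification inequality — then verified
with the classifier, so generation is rejection-free. Oil-intrusion
masses and bending forces are back-computed so the metrology module
recovers porosity and tensile strength exactly in the noiseless case.

What this emulates and what it does not: the generator reproduces
envelope statistics, the monotone pressure-porosity-strength coupling,
correlated density/flow descriptors driven by two latent factors
(plasticity, packing) and the published splitting-mode trend; it does
not mimic specific named materials, lot-to-lot variability, or
non-monotone compaction profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import (DESCRIPTOR_COLUMNS, PSDHistogram, homogeneity_index,
                          packing_indices, powder_solid_fraction, psd_summary)
from .metrology import PRESSURE_GRID, RIBBON_COLUMNS
from .models import fit_power
from . import rcbcs

__all__ = ["SyntheticConfig", "generate_library", "make_lvm_fixture",
           "DEFAULT_CATEGORY_MIX"]

# printed library envelopes used as generator bounds
TS0_RANGE = (0.8457, 144.8)     # MPa
KB_RANGE = (2.954, 32.28)
G_RANGE = (0.2771, 5.20)
DT_RANGE = (1.145, 2.915)       # g/mL
EPSP_RANGE = (0.4479, 0.8456)
ICD_MAX = 503.0                 # N
SP_RANGE = (0.1255, 0.46)

#: (n_excipients, n_NPPs) per subcategory for the default 81-material library
DEFAULT_CATEGORY_MIX = {
    "IA": (21, 5), "IB": (3, 0), "IIA": (14, 12), "IIB": (7, 8), "III": (8, 3),
}
N_NON_COMPACTABLE = 2   # NPPs in Category III that never form a ribbon

OIL_DENSITY = 0.85      # g/mL, paraffin oil
RIBBON_MASS = 1.5       # g, dry test piece
RIBBON_WIDTH = 30.0     # mm
RIBBON_THICKNESS = 3.0  # mm
SUPPORT_SPAN = 15.0     # mm


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic library."""

    n_materials: int = 81
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    pressures: tuple = PRESSURE_GRID
    sigma_ts: float = 0.05    # multiplicative lognormal sigma on TS
    sigma_sf: float = 0.01    # additive sigma on SF (equivalently porosity)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        total = sum(e + n for e, n in self.category_mix.values())
        if total != self.n_materials:
            raise ValueError(f"category mix sums to {total}, not n_materials="
                             f"{self.n_materials}")
        if min(self.sigma_ts, self.sigma_sf) < 0:
            raise ValueError("noise levels must be >= 0")

    @classmethod
    def with_n(cls, n_materials: int, **kw) -> "SyntheticConfig":
        """Scale the default category mix proportionally to ``n_materials``."""
        flat = [(cat, t) for cat, pair in DEFAULT_CATEGORY_MIX.items()
                for t, c in zip(("excipient", "NPP"), pair) for _ in range(c)]
        reps = [flat[i % len(flat)] for i in range(n_materials)]
        mix = {cat: (sum(1 for c, t in reps if c == cat and t == "excipient"),
                     sum(1 for c, t in reps if c == cat and t == "NPP"))
               for cat in DEFAULT_CATEGORY_MIX}
        return cls(n_materials=n_materials, category_mix=mix, **kw)


def _porosity_curve(eps0, eps_inf, pc, pressures):
    p = np.asarray(pressures, dtype=float)
    return eps_inf + (eps0 - eps_inf) * np.exp(-p / pc)


def _eps_at(eps0, eps_inf, pc, p):
    return eps_inf + (eps0 - eps_inf) * np.exp(-p / pc)


def _draw_ground_truth(rng: np.random.Generator, subcat: str) -> dict:
    """Porosity-law parameters and TS0/kb solving the category inequalities.

    The binding constraint per subcategory (target-region hit at the
    designed qualifying pressure; TS crossing 1 MPa between 70 and 90 bar
    for the B subcategories; TS < 1 MPa at 110 bar for Category III) is
    solved for TS0 (and for the B subcategories a feasible kb window),
    keeping TS0/kb inside the printed library envelopes.
    """
    ts0_cap = 0.95 * TS0_RANGE[1]
    if subcat == "IA":
        eps_inf = rng.uniform(0.18, 0.26)
        eps0 = rng.uniform(0.55, 0.84)
        p_star = rng.choice([30.0, 50.0, 70.0])
        eps_q = rng.uniform(eps_inf + 0.10, 0.37)
        pc = p_star / np.log((eps0 - eps_inf) / (eps_q - eps_inf))
        kb = rng.uniform(5.0, 12.0)
        ts_hi = min(4.0, ts0_cap * np.exp(-kb * eps_q))
        ts_q = rng.uniform(1.25, ts_hi)
        ts0 = ts_q * np.exp(kb * eps_q)
    elif subcat == "IB":
        eps_inf = rng.uniform(0.21, 0.23)
        eps0 = rng.uniform(0.78, 0.84)
        pc = rng.uniform(29.0, 31.0)
        ts70 = rng.uniform(0.78, 0.85)
        e70 = _eps_at(eps0, eps_inf, pc, 70.0)
        e90 = _eps_at(eps0, eps_inf, pc, 90.0)
        kb_lo = max(KB_RANGE[0], np.log(1.12 / ts70) / (e70 - e90))
        kb_hi = min(KB_RANGE[1], np.log(ts0_cap / ts70) / e70)
        kb = rng.uniform(kb_lo, kb_hi)
        ts0 = ts70 * np.exp(kb * e70)
    elif subcat == "IIA":
        # porosity already below 0.185 at 30 bar (SF > 0.8 on the whole
        # grid) but still decaying across it, so the TS-P curve keeps a
        # realistic pressure sensitivity
        eps_inf = rng.uniform(0.06, 0.11)
        drop30 = rng.uniform(0.06, 0.185 - eps_inf)   # eps(30) - eps_inf
        delta = rng.uniform(0.45, 0.72)               # eps0 - eps_inf
        eps0 = eps_inf + delta
        pc = 30.0 / np.log(delta / drop30)
        kb = rng.uniform(9.0, 14.0)
        e30 = _eps_at(eps0, eps_inf, pc, 30.0)
        ts30 = rng.uniform(1.4, min(5.0, ts0_cap * np.exp(-kb * e30)))
        ts0 = ts30 * np.exp(kb * e30)
    elif subcat == "IIB":
        eps_inf = rng.uniform(0.08, 0.11)
        eps0 = rng.uniform(0.65, 0.80)
        pc = rng.uniform(26.0, 30.0)
        ts70 = rng.uniform(0.78, 0.86)
        e70 = _eps_at(eps0, eps_inf, pc, 70.0)
        e90 = _eps_at(eps0, eps_inf, pc, 90.0)
        kb_lo = max(KB_RANGE[0], np.log(1.12 / ts70) / (e70 - e90))
        kb_hi = min(KB_RANGE[1], np.log(ts0_cap / ts70) / e70)
        kb = rng.uniform(kb_lo, kb_hi)
        ts0 = ts70 * np.exp(kb * e70)
    elif subcat == "III":
        eps_inf = rng.uniform(0.28, 0.45)
        eps0 = rng.uniform(min(eps_inf + 0.30, 0.83), 0.84)
        pc = rng.uniform(24.0, 40.0)
        kb = rng.uniform(6.0, 9.0)
        e110 = _eps_at(eps0, eps_inf, pc, 110.0)
        ts110 = rng.uniform(0.45, 0.80)
        ts0 = ts110 * np.exp(kb * e110)
    else:
        raise ValueError(f"unknown subcategory {subcat!r}")
    if not (TS0_RANGE[0] <= ts0 <= TS0_RANGE[1] and KB_RANGE[0] <= kb <= KB_RANGE[1]):
        raise RuntimeError(f"ground-truth draw left the printed envelope: "
                           f"TS0={ts0:.3g}, kb={kb:.3g} ({subcat})")
    return dict(eps0=eps0, eps_inf=eps_inf, pc=pc, kb=kb, ts0=ts0)


def _make_psd(rng: np.random.Generator) -> PSDHistogram:
    """Lognormal PSD binned on geometric edges, quantiles from the cumulative curve."""
    edges = np.geomspace(1.0, 1200.0, 26)
    median = float(np.clip(np.exp(rng.normal(np.log(90.0), 0.55)), 15.0, 420.0))
    sigma = rng.uniform(0.45, 1.05)
    from scipy.stats import lognorm

    cdf = lognorm.cdf(edges, s=sigma, scale=median)
    freq = np.diff(cdf)
    freq = freq / freq.sum() * 100.0
    cum = np.concatenate([[0.0], np.cumsum(freq)])
    d10, d50, d90 = np.interp([10.0, 50.0, 90.0], cum, edges)
    return PSDHistogram(edges, freq, float(d10), float(d50), float(d90))


def _descriptor_row(rng, mid, mtype, subcat, truth) -> dict:
    """Correlated descriptor vector driven by plasticity and packing factors.

    Plasticity is a saturating function of the material's mid-pressure
    strength, so the cohesion index tracks ribbon tensile strength (the
    correlation structure the library exhibits); packing is the complement
    of the initial powder porosity and drives the density/flow block.
    """
    ts70 = truth["ts0"] * np.exp(
        -truth["kb"] * _eps_at(truth["eps0"], truth["eps_inf"], truth["pc"], 70.0))
    plasticity = float(np.clip(ts70 / (ts70 + 2.5) + rng.normal(0, 0.05), 0.0, 1.0))
    eps0 = truth["eps0"]
    packing = (EPSP_RANGE[1] - eps0) / (EPSP_RANGE[1] - EPSP_RANGE[0])
    flow = float(np.clip(0.55 * packing + 0.45 * rng.uniform(0, 1), 0.0, 1.0))

    dt = rng.uniform(2.2, DT_RANGE[1]) if rng.uniform() < 0.05 else rng.uniform(1.15, 1.63)
    da = (1.0 - eps0) * dt
    ih = 1.06 + 0.54 * (1.0 - flow)
    dc = ih * da
    ie, ic, ih = packing_indices(da, dc)
    sfp, eps_p = powder_solid_fraction(da, dt)

    psd = _make_psd(rng)
    span, pf = psd_summary(psd)
    itheta = homogeneity_index(psd)

    icd = ICD_MAX * plasticity**1.2 * rng.uniform(0.75, 1.0)
    row = {
        "material_id": mid, "type": mtype,
        "D10": psd.d10, "D50": psd.d50, "D90": psd.d90,
        "span": span, "PfPct": pf, "Itheta": itheta,
        "Da": da, "Dc": dc, "Dt": dt, "SFp": sfp, "epsP": eps_p,
        "IH": ih, "IC": ic, "Ie": ie,
        "tflow": 5.0 + 40.0 * (1.0 - flow) + rng.uniform(0, 3),
        "AOR": 24.0 + 22.0 * (1.0 - flow) + rng.uniform(-2, 2),
        "HRpct": rng.uniform(1.0, 8.0),
        "Hpct": rng.uniform(2.0, 18.0) if mtype == "NPP" else rng.uniform(0.2, 8.0),
        "Icd": icd,
        "Co": rng.uniform(0.1, 0.9),
        "Sp": rng.uniform(*SP_RANGE),
        "Spco": rng.uniform(0.2, 0.95),
    }
    row["_plasticity"] = plasticity
    row["_packing"] = packing
    return row


# splitting tendencies per pressure level (fractions of samples), shaped
# like the library-scale trend: transversal falls, longitudinal rises
_T_BASE = np.array([0.48, 0.47, 0.40, 0.36, 0.30])
_L_BASE = np.array([0.12, 0.30, 0.50, 0.58, 0.60])
_L_MODE_WEIGHTS = {"L2": 0.55, "L3": 0.02, "LJ": 0.33, "LN": 0.10}


def _draw_modes(rng, main_cat: str, plasticity: float, p_index: int) -> str:
    t_prob = float(np.clip(_T_BASE[p_index] * (0.42 if main_cat == "I" else 1.15), 0, 0.95))
    l_prob = float(np.clip(_L_BASE[p_index] * (0.55 + 0.85 * plasticity), 0, 0.95))
    modes = []
    if rng.uniform() < t_prob:
        modes.append("T")
    if rng.uniform() < l_prob:
        keys = list(_L_MODE_WEIGHTS)
        modes.append(rng.choice(keys, p=np.array(list(_L_MODE_WEIGHTS.values()))))
    return ";".join(modes) if modes else "NONE"


def generate_library(config: SyntheticConfig | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(descriptor_table, ribbon_table, ground_truth_table)``.

    Deterministic under a fixed seed. The descriptor table uses the
    standard descriptor-symbol schema; the ribbon table uses the long replicate-level
    schema consumed by the metrology module; the ground-truth table
    records the latent parameters, the derived power-law coefficients
    (from a noiseless fit) and the intended category of every material,
    which the classifier is guaranteed to recover at zero noise.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    pressures = np.asarray(config.pressures, dtype=float)

    plan: list[tuple[str, str]] = []   # (subcategory, type)
    for subcat, (n_exc, n_npp) in config.category_mix.items():
        plan += [(subcat, "excipient")] * n_exc + [(subcat, "NPP")] * n_npp

    # the last NPPs of Category III never form ribbons (two in the default mix)
    non_comp_ids = set()
    npp_iii = [i for i, (c, t) in enumerate(plan) if c == "III" and t == "NPP"]
    for i in npp_iii[-min(N_NON_COMPACTABLE, len(npp_iii)):]:
        non_comp_ids.add(i)

    desc_rows, ribbon_rows, truth_rows = [], [], []
    glucose_like_done = False
    for i, (subcat, mtype) in enumerate(plan):
        mid = f"M{i + 1:03d}"
        truth = _draw_ground_truth(rng, subcat)
        drow = _descriptor_row(rng, mid, mtype, subcat, truth)
        plasticity = drow.pop("_plasticity")
        drow.pop("_packing")
        # one non-compactable-into-tablet material (cohesion index zero)
        if subcat == "IIB" and not glucose_like_done:
            drow["Icd"] = 0.0
            glucose_like_done = True
        non_compactable = i in non_comp_ids

        eps = _porosity_curve(truth["eps0"], truth["eps_inf"], truth["pc"], pressures)
        ts = truth["ts0"] * np.exp(-truth["kb"] * eps)

        if non_compactable:
            d_coef = g_coef = np.nan
            for p in pressures:
                for rep in range(1, config.replicates + 1):
                    ribbon_rows.append(dict(
                        material_id=mid, pressure_bar=p, replicate=rep,
                        m_ribbon_g=np.nan, m_oilsat_g=np.nan, rho_oil=OIL_DENSITY,
                        rho_true=drow["Dt"], width_mm=np.nan, thickness_mm=np.nan,
                        force_N=np.nan, span_mm=SUPPORT_SPAN,
                        splitting_modes="NO_RIBBON"))
        else:
            pw = fit_power(pressures, ts)
            d_coef, g_coef = pw.d, pw.g
            for j, p in enumerate(pressures):
                modes = _draw_modes(rng, subcat.rstrip("AB"), plasticity, j)
                for rep in range(1, config.replicates + 1):
                    e = eps[j]
                    t = ts[j]
                    if config.sigma_sf > 0:
                        e = float(np.clip(e + rng.normal(0, config.sigma_sf), 0.01, 0.97))
                    if config.sigma_ts > 0:
                        t = float(t * np.exp(rng.normal(0, config.sigma_ts)))
                    v_ribbon = RIBBON_MASS / drow["Dt"]
                    v_oil = e / (1.0 - e) * v_ribbon
                    force = t * 2.0 * RIBBON_WIDTH * RIBBON_THICKNESS**2 / (3.0 * SUPPORT_SPAN)
                    ribbon_rows.append(dict(
                        material_id=mid, pressure_bar=p, replicate=rep,
                        m_ribbon_g=RIBBON_MASS,
                        m_oilsat_g=RIBBON_MASS + OIL_DENSITY * v_oil,
                        rho_oil=OIL_DENSITY, rho_true=drow["Dt"],
                        width_mm=RIBBON_WIDTH, thickness_mm=RIBBON_THICKNESS,
                        force_N=force, span_mm=SUPPORT_SPAN,
                        splitting_modes=modes))
            _verify_intent(mid, subcat, pressures, eps, ts)

        desc_rows.append(drow)
        truth_rows.append(dict(
            material_id=mid, type=mtype, category=subcat,
            TS0=truth["ts0"], kb=truth["kb"], eps0=truth["eps0"],
            eps_inf=truth["eps_inf"], Pc=truth["pc"], d=d_coef, g=g_coef,
            plasticity=plasticity, non_compactable=non_compactable))

    descriptors = pd.DataFrame(desc_rows)[["material_id", "type"] + DESCRIPTOR_COLUMNS]
    ribbons = pd.DataFrame(ribbon_rows)[RIBBON_COLUMNS]
    truth = pd.DataFrame(truth_rows)
    return descriptors, ribbons, truth


def _verify_intent(mid, subcat, pressures, eps, ts):
    """Classifier check of the rejection-free construction (noiseless curve)."""
    from .metrology import CompactionProfile

    prof = CompactionProfile(
        mid, np.asarray(pressures, dtype=float), np.asarray(eps),
        np.asarray(ts), np.ones(len(pressures), dtype=int),
        np.zeros(len(pressures)), np.zeros(len(pressures)))
    got = rcbcs.classify(prof).category
    if got != subcat:
        raise RuntimeError(f"{mid}: constructed for {subcat} but classifies as {got}")


# ---------------------------------------------------------------------------
# PLS fixture with known coefficient structure

LVM_FIXTURE_COLUMNS = ["Da", "Dc", "SFp", "epsP", "Icd",
                       "D50", "IH", "tflow", "Hpct", "Co", "Sp", "P"]

#: true coefficients on scaled predictors; pressure carries the largest
#: weight for both responses, six columns are pure noise
_TRUE_B = pd.DataFrame(
    {
        "TS": {"P": 1.5, "Icd": 1.3, "SFp": -1.1, "Da": -1.0, "Dc": -0.7, "epsP": 0.6},
        "SF": {"P": 1.5, "Dc": 1.2, "epsP": -1.1, "Da": 0.8, "SFp": 0.9, "Icd": 0.6},
    }
).reindex(LVM_FIXTURE_COLUMNS).fillna(0.0)


def make_lvm_fixture(n_materials: int = 81, *, noise: float = 0.3, seed: int = 0,
                     pressures=PRESSURE_GRID):
    """Synthetic PLS dataset with a known linear coefficient structure.

    Y = X_scaled @ B_true + noise, with the pressure column given the
    largest true coefficient for both responses so its VIP is expected to
    rank first, and six predictors truly irrelevant (zero coefficients).
    Returns ``(X, Y, B_true)`` with X and Y as DataFrames in raw units.
    """
    rng = np.random.default_rng(seed)
    cols = LVM_FIXTURE_COLUMNS
    n = n_materials * len(pressures)
    p = len(cols)
    Xs = rng.standard_normal((n, p))
    Xs[:, cols.index("P")] = np.tile(
        (np.asarray(pressures, float) - np.mean(pressures)) / np.std(pressures, ddof=0),
        n_materials)
    Ys = Xs @ _TRUE_B.to_numpy() + noise * rng.standard_normal((n, 2))
    # arbitrary raw units so autoscaling is actually exercised
    x_scale = rng.uniform(0.5, 50.0, p)
    x_loc = rng.uniform(-5.0, 100.0, p)
    X = pd.DataFrame(Xs * x_scale + x_loc, columns=cols)
    Y = pd.DataFrame(Ys * np.array([1.8, 0.07]) + np.array([2.5, 0.75]),
                     columns=["TS", "SF"])
    return X, Y, _TRUE_B.copy()
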