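"""Roll compaction behavior classification system (RCBCS).

Materials are sorted into three categories from their compaction
profiles against the ribbon quality target (0.6 <= SF <= 0.8 together
with TS >= 1 MPa, all boundaries inclusive):

* Category I  — at least one pressure point falls in the target region.
* Category II — no point in the target region, but at least one point
  has SF > 0.8 with TS >= 1 MPa (over-densified but strong).
* Category III — TS < 1 MPa everywhere (or the material cannot be
  compacted / its TS cannot be tested).

Categories I and II carry an A/B subcategory: A when the main criterion
is met at a low pressure (30-70 bar), B when only at high pressure
(90-110 bar). A takes precedence over B; I takes precedence over II.
Missing TS at a pressure point counts as failing TS >= 1 MPa there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .metrology import CompactionProfile, PRESSURE_GRID, transversal_rate

__all__ = ["RCBCSLabel", "classify", "category_summary", "ts_sf_map",
           "SF_MIN", "SF_MAX", "TS_MIN", "LOW_PRESSURES", "HIGH_PRESSURES"]

SF_MIN, SF_MAX, TS_MIN = 0.6, 0.8, 1.0
LOW_PRESSURES = frozenset({30.0, 50.0, 70.0})
HIGH_PRESSURES = frozenset({90.0, 110.0})


@dataclass(frozen=True)
class RCBCSLabel:
    material_id: str
    main: str                       # "I" | "II" | "III"
    sub: str                        # "A" | "B" | ""
    qualifying_pressures: tuple[float, ...]
    rationale: str

    @property
    def category(self) -> str:
        return self.main + self.sub


def _point_ok_I(sf: float, ts: float, sf_min=SF_MIN, sf_max=SF_MAX, ts_min=TS_MIN) -> bool:
    return np.isfinite(ts) and sf_min <= sf <= sf_max and ts >= ts_min


def _point_ok_II(sf: float, ts: float, sf_max=SF_MAX, ts_min=TS_MIN) -> bool:
    return np.isfinite(ts) and sf > sf_max and ts >= ts_min


def classify(profile: CompactionProfile, *, strict: bool = True,
             sf_min: float = SF_MIN, sf_max: float = SF_MAX,
             ts_min: float = TS_MIN) -> RCBCSLabel:
    """Assign the RCBCS label to one compaction profile.

    With ``strict`` (default) the profile's pressures must lie on the
    standard 30-110 bar grid; pass ``strict=False`` to classify ad-hoc
    grids (subcategory A/B is then decided by pressure <= 70 bar).
    """
    if profile.non_compactable or profile.pressures.size == 0:
        return RCBCSLabel(profile.material_id, "III", "", (),
                          "non-compactable: no tangible ribbon at any pressure")
    if strict:
        off = set(profile.pressures) - {float(p) for p in PRESSURE_GRID}
        if off:
            raise ValueError(f"pressures off the standard grid: {sorted(off)} "
                             "(pass strict=False to allow)")

    sf = profile.solid_fraction
    ts = profile.tensile_strength
    p = profile.pressures

    hits_I = [p[i] for i in range(p.size) if _point_ok_I(sf[i], ts[i], sf_min, sf_max, ts_min)]
    hits_II = [p[i] for i in range(p.size) if _point_ok_II(sf[i], ts[i], sf_max, ts_min)]

    if hits_I:
        main, hits = "I", hits_I
        why = f"target region ({sf_min} <= SF <= {sf_max}, TS >= {ts_min} MPa) reached"
    elif hits_II:
        main, hits = "II", hits_II
        why = f"SF > {sf_max} with TS >= {ts_min} MPa reached, never inside target region"
    else:
        return RCBCSLabel(profile.material_id, "III", "", (),
                          f"TS < {ts_min} MPa (or untestable) at every pressure")

    low = any(q <= 70.0 for q in hits)
    sub = "A" if low else "B"
    qualifying = tuple(sorted(hits))
    return RCBCSLabel(profile.material_id, main, sub, qualifying,
                      f"{why} at {qualifying} bar")


def classify_all(profiles: Mapping[str, CompactionProfile], **kw) -> dict[str, RCBCSLabel]:
    return {mid: classify(prof, **kw) for mid, prof in profiles.items()}


def label_table(labels: Mapping[str, RCBCSLabel]) -> pd.DataFrame:
    return pd.DataFrame([
        {"material_id": lab.material_id, "main": lab.main, "sub": lab.sub,
         "category": lab.category,
         "qualifying_pressures": ";".join(f"{q:g}" for q in lab.qualifying_pressures)}
        for lab in labels.values()
    ])


def category_summary(labels: Mapping[str, RCBCSLabel],
                     material_types: Mapping[str, str],
                     samples_by_material: Mapping[str, list] | None = None) -> pd.DataFrame:
    """Contingency table of (sub)category x material type.

    ``material_types`` maps material_id -> "excipient" | "NPP". When
    per-replicate ribbon samples are supplied, a transversal-splitting
    occurrence rate (share of tangible samples showing mode T) is added
    per main category.
    """
    cats = ["IA", "IB", "IIA", "IIB", "III"]
    types = ["excipient", "NPP"]
    table = pd.DataFrame(0, index=cats, columns=types)
    for mid, lab in labels.items():
        mtype = material_types.get(mid, "excipient")
        table.loc[lab.category, mtype] += 1
    table["total"] = table.sum(axis=1)

    if samples_by_material is not None:
        rates = {}
        for main in ["I", "II", "III"]:
            pooled = [s for mid, lab in labels.items() if lab.main == main
                      for s in samples_by_material.get(mid, [])]
            rates[main] = transversal_rate(pooled)
        table["transversal_rate"] = [rates[c[:2].rstrip("AB")] if c != "III" else rates["III"]
                                     for c in cats]
    return table


def ts_sf_map(profiles: Mapping[str, CompactionProfile],
              sf_min: float = SF_MIN, sf_max: float = SF_MAX,
              ts_min: float = TS_MIN) -> pd.DataFrame:
    """Long-format TS vs SF scatter (one row per material x pressure) with
    an inclusive in-target flag, for plotting the classification map."""
    rows = []
    for mid, prof in profiles.items():
        if prof.non_compactable:
            continue
        for i, p in enumerate(prof.pressures):
            sf, ts = prof.solid_fraction[i], prof.tensile_strength[i]
            rows.append({"material_id": mid, "pressure_bar": p, "SF": sf, "TS": ts,
                         "in_target": bool(_point_ok_I(sf, ts, sf_min, sf_max, ts_min))})
    return pd.DataFrame(rows)
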