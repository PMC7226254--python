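"""Screen scoring: viability normalization, differential score, quadrants.

The screen's readout is percent viability anchored to vehicle (DMSO) wells:
``viability = 100 * count / mean(vehicle counts)`` within each plate x line
stratum. For each compound and dose the differential score is

    d = viability(E41K-C481S) - viability(E41K)        [percentage points]

so compounds preferentially active against the ibrutinib-sensitive E41K line
have d > 0 at both doses (upper-right quadrant of the d_100nM vs d_1uM
plane), while collateral-sensitivity compounds — preferentially active
against the resistant C481S line — have d < 0 at both doses (lower-left
quadrant). Candidate hits are compounds with d at or below a negative
threshold at one dose or more.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .config import (
    LINE_RESISTANT,
    LINE_SENSITIVE,
    ROLE_COMPOUND,
    ROLE_POSITIVE_CONTROL,
    ROLE_VEHICLE,
    NormalizationError,
    QCError,
)

__all__ = [
    "QUADRANTS",
    "normalize_viability",
    "aggregate_replicates",
    "differential_score",
    "classify_quadrant",
    "score_compounds",
    "select_candidate_hits",
    "compute_plate_qc",
]

logger = logging.getLogger(__name__)

QUADRANTS = ("upper_right", "lower_left", "upper_left", "lower_right")

SCORE_COLUMNS = [
    "compound_id",
    "v_wt_100",
    "v_mut_100",
    "v_wt_1000",
    "v_mut_1000",
    "d_100",
    "d_1000",
    "quadrant",
    "is_candidate_hit",
]


def normalize_viability(wells: pd.DataFrame) -> pd.DataFrame:
    """Anchor well counts to the vehicle wells of their plate x line stratum.

    ``viability_pct = 100 * count / mean(count of vehicle wells on the same
    plate and line)``. Every record (vehicle and control wells included) gets
    a viability; a stratum without vehicle wells raises
    :class:`NormalizationError` naming it.
    """
    required = {"plate_id", "line", "role", "count"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    out = wells.copy()
    out["viability_pct"] = np.nan
    for (plate, line), idx in out.groupby(["plate_id", "line"], sort=False).groups.items():
        sub = out.loc[idx]
        veh = sub.loc[sub["role"] == ROLE_VEHICLE, "count"]
        if veh.empty:
            raise NormalizationError(f"no vehicle wells in stratum plate={plate!r} line={line!r}")
        out.loc[idx, "viability_pct"] = 100.0 * sub["count"] / veh.mean()
    return out


def aggregate_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Mean viability per compound x line x dose, keeping n and range for QC."""
    comp = records[records["role"] == ROLE_COMPOUND] if "role" in records.columns else records
    g = comp.groupby(["compound_id", "line", "dose_nM"], sort=True)["viability_pct"]
    agg = g.agg(viability_pct="mean", n_replicates="size", viability_range=lambda v: v.max() - v.min())
    return agg.reset_index()


def differential_score(v_mut, v_wt):
    """Differential score d = viability(E41K-C481S) - viability(E41K).

    Antisymmetric under swapping the lines; positive when the compound hits
    the sensitive line harder. Percentage points; vectorized.
    """
    return np.subtract(v_mut, v_wt)


def classify_quadrant(d_100nM: float, d_1uM: float) -> str:
    """Map the sign pair (d at 100 nM, d at 1 uM) to a quadrant label.

    Zero counts as non-negative, making the map total and mutually exclusive
    over the plane. The X axis is the 100 nM score, the Y axis the 1 uM one.
    """
    if np.isnan(d_100nM) or np.isnan(d_1uM):
        raise ValueError("quadrant classification needs both d values")
    if d_100nM >= 0:
        return "upper_right" if d_1uM >= 0 else "lower_right"
    return "upper_left" if d_1uM >= 0 else "lower_left"


def score_compounds(
    aggregated: pd.DataFrame,
    doses: Sequence[float] = (100.0, 1000.0),
    hit_threshold_pct: float = 20.0,
) -> pd.DataFrame:
    """Build the per-compound score table for a two-dose screen.

    Wide columns ``v_wt_<dose>`` / ``v_mut_<dose>`` hold replicate-mean
    viabilities of the E41K ("wt", ibrutinib-sensitive) and E41K-C481S
    ("mut", resistant) lines; d is computed on those means. Compounds missing
    one member of a line pair at a dose get NaN d there, are excluded from
    quadrant assignment, and logged.
    """
    if len(doses) != 2:
        raise ValueError("quadrant scoring is defined for exactly two doses")
    lo, hi = sorted(float(d) for d in doses)
    wide = aggregated.pivot_table(
        index="compound_id", columns=["line", "dose_nM"], values="viability_pct", aggfunc="mean"
    )
    rows = []
    for cid, r in wide.iterrows():
        v = {
            ("wt", lo): r.get((LINE_SENSITIVE, lo), np.nan),
            ("mut", lo): r.get((LINE_RESISTANT, lo), np.nan),
            ("wt", hi): r.get((LINE_SENSITIVE, hi), np.nan),
            ("mut", hi): r.get((LINE_RESISTANT, hi), np.nan),
        }
        d_lo = differential_score(v[("mut", lo)], v[("wt", lo)])
        d_hi = differential_score(v[("mut", hi)], v[("wt", hi)])
        if np.isnan(d_lo) or np.isnan(d_hi):
            logger.warning("compound %s missing a line/dose pair; left unclassified", cid)
            quadrant = ""
        else:
            quadrant = classify_quadrant(d_lo, d_hi)
        is_hit = bool(
            (not np.isnan(d_lo) and d_lo <= -hit_threshold_pct)
            or (not np.isnan(d_hi) and d_hi <= -hit_threshold_pct)
        )
        rows.append(
            dict(
                compound_id=cid,
                v_wt_100=v[("wt", lo)],
                v_mut_100=v[("mut", lo)],
                v_wt_1000=v[("wt", hi)],
                v_mut_1000=v[("mut", hi)],
                d_100=d_lo,
                d_1000=d_hi,
                quadrant=quadrant,
                is_candidate_hit=is_hit,
            )
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS).sort_values("compound_id", ignore_index=True)


def select_candidate_hits(scores: pd.DataFrame, threshold: float = 20.0) -> pd.DataFrame:
    """Compounds with d <= -threshold at one dose or more, strongest first.

    Sorted ascending by the minimum of the two d values, so the most
    collateral-sensitivity-like compound comes first.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive (percentage points)")
    d = scores[["d_100", "d_1000"]].to_numpy(dtype=float)
    selected = np.nanmin(d, axis=1) <= -threshold
    hits = scores.loc[selected].copy()
    hits["min_d"] = np.nanmin(d[selected], axis=1) if selected.any() else []
    return hits.sort_values("min_d", ascending=True, ignore_index=True)


def compute_plate_qc(
    wells: pd.DataFrame,
    positive_control_id: str | None = "pentamidine",
    z_prime_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-plate control statistics and the Z'-factor.

    ``z' = 1 - 3*(sd_vehicle + sd_positive) / |mean_vehicle - mean_positive|``
    (reported as -inf when the means coincide; z' <= 1 always). Plates below
    ``z_prime_floor`` are flagged, never dropped. By default only pentamidine
    wells define the positive control: ibrutinib is inert on the C481S-line
    plates by design, so pooling both controls would inflate sigma there.
    Pass ``positive_control_id=None`` to pool all positive-control wells.
    """
    rows = []
    for plate, sub in wells.groupby("plate_id", sort=True):
        veh = sub.loc[sub["role"] == ROLE_VEHICLE, "count"]
        pos = sub.loc[sub["role"] == ROLE_POSITIVE_CONTROL]
        if positive_control_id is not None:
            pos = pos[pos["compound_id"] == positive_control_id]
        pos = pos["count"]
        if veh.empty or pos.empty:
            raise QCError(f"plate {plate!r} lacks vehicle or positive-control wells")
        mu_v, mu_p = float(veh.mean()), float(pos.mean())
        sd_v = float(veh.std(ddof=1)) if len(veh) > 1 else 0.0
        sd_p = float(pos.std(ddof=1)) if len(pos) > 1 else 0.0
        sep = abs(mu_v - mu_p)
        z_prime = 1.0 - 3.0 * (sd_v + sd_p) / sep if sep > 0 else -np.inf
        rows.append(
            dict(
                plate_id=plate,
                vehicle_mean=mu_v,
                vehicle_cv=sd_v / mu_v if mu_v > 0 else np.nan,
                positive_control_mean=mu_p,
                z_prime=z_prime,
                flagged=bool(z_prime < z_prime_floor),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["plate_id", "vehicle_mean", "vehicle_cv", "positive_control_mean", "z_prime", "flagged"],
    )
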