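"""Synthetic screen generator.

Everything the analysis pipeline consumes can be generated here with known
ground truth: a kinase-inhibitor-like compound library with per-class
pharmacology, 384-well plate layouts with vehicle and positive-control wells,
per-well endpoint counts under multiplicative noise, rendered fluorescence
fields with ground-truth cell positions, dose-response series, and
two-population clonal-competition trajectories.

The generative dose-response model is a four-parameter log-logistic kill
curve: ``kill(dose) = max_kill * dose^h / (dose^h + ic50^h)``, with floor 0
and ceiling ``max_kill``. A resistance (or collateral-sensitivity) mutation
shifts IC50 only; Hill slope and ceiling are shared between the two isogenic
lines.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .config import (
    LINE_RESISTANT,
    LINE_SENSITIVE,
    LINES,
    ROLE_COMPOUND,
    ROLE_POSITIVE_CONTROL,
    ROLE_VEHICLE,
    CompetitionParams,
    CompoundEffectProfile,
    ConfigurationError,
    EffectClass,
    FieldImageSpec,
    GenerationError,
    LayoutError,
    SimulationConfig,
)

__all__ = [
    "CONTROL_PROFILES",
    "PLATEMAP_COLUMNS",
    "allocate_class_counts",
    "generate_library",
    "true_kill_fraction",
    "build_plate_layout",
    "simulate_plate",
    "simulate_screen",
    "render_field",
    "render_well_fields",
    "simulate_dose_response",
    "simulate_competition",
]

PLATEMAP_COLUMNS = ["plate_id", "well", "compound_id", "dose_nM", "line", "replicate", "role"]

_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows
_N_COLS = 24
#: plate columns reserved for controls (1-based): col 1 vehicle, col 2 positive controls.
_VEHICLE_COL = 1
_POSCTRL_COL = 2
_CONTROL_DOSE_NM = 1000.0

#: Positive-control pharmacology. Ibrutinib mirrors the published scenario
#: (IC50 100 nM on E41K, 10 uM on E41K-C481S); pentamidine is an
#: undifferentiated cytotoxic that kills both lines and anchors plate QC.
CONTROL_PROFILES: dict[str, CompoundEffectProfile] = {
    "ibrutinib": CompoundEffectProfile(
        compound_id="ibrutinib",
        effect_class=EffectClass.btk_inhibitor,
        ic50_sensitive_line=100.0,
        ic50_resistant_line=10_000.0,
        hill_slope=1.0,
        max_kill=1.0,
    ),
    "pentamidine": CompoundEffectProfile(
        compound_id="pentamidine",
        effect_class=EffectClass.cytotoxic,
        ic50_sensitive_line=100.0,
        ic50_resistant_line=100.0,
        hill_slope=1.5,
        max_kill=0.98,
    ),
}

# Per-class generative priors: (median IC50 on the more sensitive line [nM],
# geometric SD of that IC50, median IC50 fold-shift to the other line,
# geometric SD of the shift, max_kill range). The 100x BTK shift mirrors the
# ibrutinib scenario; the collateral class is its mirror image.
_CLASS_PRIORS = {
    EffectClass.btk_inhibitor: (100.0, 1.5, 100.0, 1.3, (0.85, 1.0)),
    EffectClass.collateral_sensitive: (100.0, 1.5, 100.0, 1.3, (0.85, 1.0)),
    EffectClass.pi3k_inhibitor: (200.0, 2.0, 5.0, 1.3, (0.70, 0.95)),
    EffectClass.cytotoxic: (300.0, 3.0, 1.0, 1.0, (0.80, 1.0)),
}


def allocate_class_counts(
    proportions: Mapping[EffectClass, float], n: int
) -> dict[EffectClass, int]:
    """Integer class counts summing to ``n`` by largest-remainder rounding.

    Ties on the fractional remainder break towards the class listed first in
    :class:`EffectClass` declaration order, so the allocation is deterministic.
    """
    classes = [c for c in EffectClass if c in proportions]
    quotas = np.array([proportions[c] * n for c in classes])
    counts = np.floor(quotas).astype(int)
    short = n - int(counts.sum())
    order = sorted(range(len(classes)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return {c: int(k) for c, k in zip(classes, counts)}


def generate_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[CompoundEffectProfile]:
    """Draw a compound library with ground-truth per-class pharmacology.

    Class counts follow ``config.class_proportions`` by largest-remainder
    rounding; compound order on the plates is shuffled so plate position does
    not encode class. Deterministic given ``config.rng_seed``.
    """
    total = sum(config.class_proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"class_proportions must sum to 1, got {total}")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    counts = allocate_class_counts(config.class_proportions, config.n_compounds)
    classes: list[EffectClass] = []
    for cls in EffectClass:
        classes.extend([cls] * counts.get(cls, 0))
    rng.shuffle(classes)  # type: ignore[arg-type]

    profiles: list[CompoundEffectProfile] = []
    for i, cls in enumerate(classes):
        cid = f"CPD{i + 1:04d}"
        if cls is EffectClass.inert:
            profiles.append(
                CompoundEffectProfile(
                    compound_id=cid,
                    effect_class=cls,
                    ic50_sensitive_line=1e6,
                    ic50_resistant_line=1e6,
                    hill_slope=1.0,
                    max_kill=0.0,
                )
            )
            continue
        med, gsd, shift_med, shift_gsd, (mk_lo, mk_hi) = _CLASS_PRIORS[cls]
        ic50_low = med * math.exp(rng.normal(0.0, math.log(gsd)))
        shift = shift_med * math.exp(rng.normal(0.0, math.log(shift_gsd))) if shift_med > 1 else 1.0
        hill = math.exp(rng.normal(0.0, math.log(1.2)))
        max_kill = float(rng.uniform(mk_lo, mk_hi))
        if cls is EffectClass.collateral_sensitive:
            ic50_s, ic50_r = ic50_low * shift, ic50_low
        elif cls is EffectClass.cytotoxic:
            ic50_s = ic50_r = ic50_low
        else:  # btk- and pi3k-like: sensitive line is the more sensitive one
            ic50_s, ic50_r = ic50_low, ic50_low * shift
        profiles.append(
            CompoundEffectProfile(
                compound_id=cid,
                effect_class=cls,
                ic50_sensitive_line=ic50_s,
                ic50_resistant_line=ic50_r,
                hill_slope=hill,
                max_kill=max_kill,
            )
        )
    return profiles


def _line_ic50(profile: CompoundEffectProfile, line: str) -> float:
    if line in ("sensitive", LINE_SENSITIVE):
        return profile.ic50_sensitive_line
    if line in ("resistant", LINE_RESISTANT):
        return profile.ic50_resistant_line
    raise ValueError(f"unknown line {line!r}; expected one of {LINES} or sensitive/resistant")


def true_kill_fraction(profile: CompoundEffectProfile, line: str, dose):
    """Ground-truth kill fraction at ``dose`` (nM) on one line.

    ``max_kill * dose^h / (dose^h + ic50^h)``; 0 at dose 0 and monotone
    non-decreasing in dose. Accepts a scalar or array dose.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    ic50 = _line_ic50(profile, line)
    h = profile.hill_slope
    with np.errstate(divide="ignore"):
        dh = np.power(dose, h)
    kill = profile.max_kill * dh / (dh + ic50**h)
    kill = np.where(dose == 0, 0.0, kill)
    return float(kill) if kill.ndim == 0 else kill


def _well_name(row: int, col: int) -> str:
    return f"{_ROWS[row]}{col:02d}"


def build_plate_layout(
    profiles: Sequence[CompoundEffectProfile], config: SimulationConfig
) -> pd.DataFrame:
    """Lay the library out on 384-well plates.

    One plate carries one line at one dose for one replicate: column 1 is
    vehicle (0.5% DMSO), column 2 alternates ibrutinib / pentamidine
    positive-control wells (dosed at 1 uM), columns 3-24 hold compounds
    row-major. Plates are replicated across lines, doses and replicates.
    """
    compound_wells_per_plate = len(_ROWS) * (_N_COLS - 2)
    n_plates = max(1, math.ceil(len(profiles) / compound_wells_per_plate)) if profiles else 1
    records: list[dict] = []
    for line in LINES:
        for dose in config.doses:
            for rep in range(1, config.n_replicates + 1):
                for plate_idx in range(n_plates):
                    plate_id = f"{line}_{dose:g}nM_r{rep}_p{plate_idx + 1}"
                    for r in range(len(_ROWS)):
                        records.append(
                            dict(
                                plate_id=plate_id,
                                well=_well_name(r, _VEHICLE_COL),
                                compound_id="",
                                dose_nM=0.0,
                                line=line,
                                replicate=rep,
                                role=ROLE_VEHICLE,
                            )
                        )
                        ctrl = "ibrutinib" if r % 2 == 0 else "pentamidine"
                        records.append(
                            dict(
                                plate_id=plate_id,
                                well=_well_name(r, _POSCTRL_COL),
                                compound_id=ctrl,
                                dose_nM=_CONTROL_DOSE_NM,
                                line=line,
                                replicate=rep,
                                role=ROLE_POSITIVE_CONTROL,
                            )
                        )
                    start = plate_idx * compound_wells_per_plate
                    chunk = profiles[start : start + compound_wells_per_plate]
                    for j, prof in enumerate(chunk):
                        r, c = divmod(j, _N_COLS - 2)
                        records.append(
                            dict(
                                plate_id=plate_id,
                                well=_well_name(r, c + 3),
                                compound_id=prof.compound_id,
                                dose_nM=float(dose),
                                line=line,
                                replicate=rep,
                                role=ROLE_COMPOUND,
                            )
                        )
    return pd.DataFrame.from_records(records, columns=PLATEMAP_COLUMNS)


def _is_edge(well: str) -> bool:
    row, col = well[0], int(well[1:])
    return row in ("A", _ROWS[-1]) or col in (1, _N_COLS)


def simulate_plate(
    layout: pd.DataFrame,
    profiles: Iterable[CompoundEffectProfile] | Mapping[str, CompoundEffectProfile],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate endpoint live-cell counts for every well of a plate map.

    Expected count = seeded cells x 48 h growth factor x (1 - kill fraction),
    multiplied by lognormal noise of coefficient of variation
    ``cv_well_noise`` (unit mean). Vehicle wells see kill 0; positive-control
    wells use the built-in control pharmacology. Returns the layout with a
    float ``count`` column appended.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    if not isinstance(profiles, Mapping):
        profiles = {p.compound_id: p for p in profiles}

    expected = np.empty(len(layout), dtype=float)
    base = config.cells_seeded_per_well * config.growth_factor
    for i, row in enumerate(layout.itertuples(index=False)):
        if row.role == ROLE_VEHICLE:
            kill = 0.0
        elif row.role == ROLE_POSITIVE_CONTROL:
            prof = CONTROL_PROFILES.get(row.compound_id)
            if prof is None:
                raise LayoutError(f"unknown positive control {row.compound_id!r}")
            kill = true_kill_fraction(prof, row.line, row.dose_nM)
        elif row.role == ROLE_COMPOUND:
            prof = profiles.get(row.compound_id)
            if prof is None:
                raise LayoutError(
                    f"well {row.plate_id}:{row.well} references unknown compound "
                    f"{row.compound_id!r}"
                )
            kill = true_kill_fraction(prof, row.line, row.dose_nM)
        else:
            raise LayoutError(f"unknown well role {row.role!r}")
        e = base * (1.0 - kill)
        if config.edge_effect > 0 and _is_edge(row.well):
            e *= 1.0 - config.edge_effect
        expected[i] = e

    if config.cv_well_noise > 0:
        sigma = math.sqrt(math.log1p(config.cv_well_noise**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(layout))
        expected = expected * noise
    out = layout.copy()
    out["count"] = expected
    return out


def simulate_screen(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[CompoundEffectProfile], pd.DataFrame]:
    """Generate library + layout + counts in one call (tabular route)."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    profiles = generate_library(config, rng)
    layout = build_plate_layout(profiles, config)
    wells = simulate_plate(layout, profiles, config, rng)
    return profiles, wells


# ---------------------------------------------------------------------------
# field-image rendering


def render_field(
    n_cells_in_field: int,
    image_spec: FieldImageSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one fluorescence field with ground truth.

    Cells are non-overlapping bright filled ellipses (rejection-sampled with a
    guaranteed inter-cell and border gap) over a noisy background. Returns a
    uint16 image and a ground-truth table (row, col, major/minor semi-axes,
    orientation, intensity). Raises :class:`GenerationError` when the
    requested density cannot be packed.
    """
    spec = image_spec or FieldImageSpec()
    if n_cells_in_field < 0:
        raise ValueError("n_cells_in_field must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)

    h, w = spec.height, spec.width
    if spec.background_sd > 0:
        img = rng.normal(spec.background_mean, spec.background_sd, size=(h, w))
    else:
        img = np.full((h, w), spec.background_mean, dtype=float)

    placed_rc = np.empty((n_cells_in_field, 2), dtype=float)
    placed_a = np.empty(n_cells_in_field, dtype=float)
    n_placed = 0
    truth: list[dict] = []
    max_tries = 2000
    for _ in range(n_cells_in_field):
        a = float(rng.uniform(spec.cell_radius_min, spec.cell_radius_max))
        b = a / float(rng.uniform(1.0, spec.max_aspect_ratio))
        theta = float(rng.uniform(0.0, math.pi))
        margin = a + spec.min_gap
        if h - 2 * margin <= 0 or w - 2 * margin <= 0:
            raise GenerationError("image too small for requested cell size")
        for attempt in range(max_tries):
            r = float(rng.uniform(margin, h - 1 - margin))
            c = float(rng.uniform(margin, w - 1 - margin))
            d2 = np.sum((placed_rc[:n_placed] - (r, c)) ** 2, axis=1)
            if np.all(d2 >= (a + placed_a[:n_placed] + spec.min_gap) ** 2):
                break
        else:
            raise GenerationError(
                f"could not place cell {n_placed + 1}/{n_cells_in_field}: "
                "requested density exceeds packing feasibility"
            )
        intensity = max(
            float(rng.normal(spec.cell_intensity_mean, spec.cell_intensity_sd)),
            spec.cell_intensity_mean / 2,
        )
        rr, cc = ellipse(r, c, a, b, shape=(h, w), rotation=theta)
        img[rr, cc] = intensity
        placed_rc[n_placed] = (r, c)
        placed_a[n_placed] = a
        n_placed += 1
        truth.append(
            dict(row=r, col=c, semi_major=a, semi_minor=b, orientation=theta, intensity=intensity)
        )

    img = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    truth_df = pd.DataFrame(
        truth, columns=["row", "col", "semi_major", "semi_minor", "orientation", "intensity"]
    )
    return img, truth_df


def render_well_fields(
    well_count: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, pd.DataFrame]]:
    """Render the imaging fields of one well.

    Each of ``fields_per_well`` fields captures a binomial sample of the
    well's cells with probability ``field_capture_fraction`` — field-sampling
    noise on top of the well-level count.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    n_total = max(int(round(well_count)), 0)
    fields = []
    for _ in range(config.fields_per_well):
        n_field = int(rng.binomial(n_total, config.field_capture_fraction))
        fields.append(render_field(n_field, config.image_spec, rng))
    return fields


# ---------------------------------------------------------------------------
# dose-response and competition generators


def simulate_dose_response(
    profile: CompoundEffectProfile,
    line: str,
    doses: Sequence[float],
    n_replicates: int = 3,
    cv: float = 0.05,
    rng: np.random.Generator | None = None,
    il3: bool = False,
) -> pd.DataFrame:
    """Simulate a percent-viability dose series for one compound x line.

    Viability is ``100 * (1 - kill)`` under multiplicative lognormal noise of
    coefficient of variation ``cv``. With ``il3=True`` survival is
    IL3-driven and the BTK-pathway kill is switched off (flat ~100% series),
    emulating the rescue seen when the cytokine is present.
    """
    doses = np.asarray(doses, dtype=float)
    if np.unique(doses).size < 4:
        raise ValueError("need >= 4 distinct doses for downstream fitting")
    if rng is None:
        rng = np.random.default_rng(0)
    kill = np.zeros_like(doses) if il3 else np.asarray(true_kill_fraction(profile, line, doses))
    records = []
    for rep in range(1, n_replicates + 1):
        v = 100.0 * (1.0 - kill)
        if cv > 0:
            sigma = math.sqrt(math.log1p(cv**2))
            v = v * rng.lognormal(-0.5 * sigma**2, sigma, size=doses.shape)
        for d, vi in zip(doses, v):
            records.append(
                dict(
                    compound_id=profile.compound_id,
                    line=line,
                    dose_nM=float(d),
                    replicate=rep,
                    viability_pct=float(vi),
                )
            )
    return pd.DataFrame.from_records(
        records, columns=["compound_id", "line", "dose_nM", "replicate", "viability_pct"]
    )


def simulate_competition(
    params: CompetitionParams, il3: bool = False, n_points: int = 31
) -> pd.DataFrame:
    """Two-population exponential competition trajectory.

    Propagates mutant (GFP+) and wild-type (mCherry+) population sizes
    independently under their exponential growth rates and reports the mutant
    fraction ``N_mut / (N_mut + N_wt)`` on a uniform time grid over
    ``horizon_days``.
    """
    if il3:
        r_mut, r_wt = params.growth_rate_mut_with_il3, params.growth_rate_wt_with_il3
    else:
        r_mut, r_wt = params.growth_rate_mut_no_il3, params.growth_rate_wt_no_il3
    t = np.linspace(0.0, params.horizon_days, n_points)
    n_mut = params.initial_fraction_mut * np.exp(r_mut * t)
    n_wt = (1.0 - params.initial_fraction_mut) * np.exp(r_wt * t)
    return pd.DataFrame({"t_days": t, "fraction_mut": n_mut / (n_mut + n_wt)})
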