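"""Configuration and domain types for the collateral-sensitivity screen.

The screen compares two isogenic Ba/F3 reporter lines that differ only in a
drug-resistance point mutation of the BTK kinase: the parental screening line
carries the activating E41K mutation (ibrutinib-*sensitive*), the second line
additionally carries C481S (ibrutinib-*resistant*). Throughout the package the
lines are named by these genotypes; "sensitive"/"resistant" always refer to
covalent BTK-inhibitor sensitivity.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator

#: Canonical line labels used in every table the package reads or writes.
LINE_SENSITIVE = "E41K"
LINE_RESISTANT = "E41K_C481S"
LINES = (LINE_SENSITIVE, LINE_RESISTANT)

#: Well roles in a plate map.
ROLE_COMPOUND = "compound"
ROLE_VEHICLE = "vehicle"
ROLE_POSITIVE_CONTROL = "positive_control"


class EffectClass(str, enum.Enum):
    """Ground-truth pharmacological class of a simulated library compound."""

    btk_inhibitor = "btk_inhibitor"
    pi3k_inhibitor = "pi3k_inhibitor"
    cytotoxic = "cytotoxic"
    inert = "inert"
    collateral_sensitive = "collateral_sensitive"


class CompoundEffectProfile(BaseModel):
    """Ground truth for one simulated compound.

    Per-line potency is a four-parameter log-logistic kill curve with floor 0
    and ceiling ``max_kill``; the two lines share ``hill_slope`` and
    ``max_kill`` and differ only in IC50, which is how a binding-site mutation
    acts in this model.
    """

    compound_id: str
    effect_class: EffectClass
    ic50_sensitive_line: float = Field(gt=0, description="IC50 on the E41K line, nM")
    ic50_resistant_line: float = Field(gt=0, description="IC50 on the E41K-C481S line, nM")
    hill_slope: float = Field(gt=0)
    max_kill: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _class_consistency(self) -> "CompoundEffectProfile":
        if self.effect_class is EffectClass.btk_inhibitor:
            if not self.ic50_sensitive_line < self.ic50_resistant_line:
                raise ValueError(
                    "btk_inhibitor requires ic50_sensitive_line < ic50_resistant_line "
                    "(the resistance mutation protects)"
                )
        elif self.effect_class is EffectClass.collateral_sensitive:
            if not self.ic50_resistant_line < self.ic50_sensitive_line:
                raise ValueError(
                    "collateral_sensitive requires ic50_resistant_line < ic50_sensitive_line"
                )
        elif self.effect_class is EffectClass.inert:
            if self.max_kill != 0.0:
                raise ValueError("inert compounds must have max_kill = 0")
        return self


class FieldImageSpec(BaseModel):
    """Geometry and photometry of one rendered fluorescence field.

    Defaults emulate a 10x wide-field EGFP acquisition: dim, roughly uniform
    background with additive sensor noise, and compact bright cells rendered
    as filled ellipses of near-unit aspect ratio.
    """

    height: int = Field(default=512, ge=16)
    width: int = Field(default=512, ge=16)
    background_mean: float = Field(default=100.0, ge=0)
    background_sd: float = Field(default=10.0, ge=0)
    cell_intensity_mean: float = Field(default=3000.0, gt=0)
    cell_intensity_sd: float = Field(default=300.0, ge=0)
    cell_radius_min: float = Field(default=2.0, ge=1.0)
    cell_radius_max: float = Field(default=4.0, ge=1.0)
    max_aspect_ratio: float = Field(default=1.25, ge=1.0)
    #: extra empty pixels guaranteed between any two cell boundaries and
    #: between a cell and the image border, so ground truth stays resolvable.
    min_gap: float = Field(default=2.0, ge=1.0)

    @model_validator(mode="after")
    def _radii(self) -> "FieldImageSpec":
        if self.cell_radius_max < self.cell_radius_min:
            raise ValueError("cell_radius_max must be >= cell_radius_min")
        return self


class SimulationConfig(BaseModel):
    """Design of the simulated screen.

    Defaults reproduce the screen's published design: a 590-compound kinase
    inhibitor library tested at 100 nM and 1 uM in duplicate on both lines,
    wells seeded with 10,000 cells, endpoint imaged over 5 fields per well.
    """

    n_compounds: int = Field(default=590, ge=0)
    class_proportions: dict[EffectClass, float] = Field(
        default_factory=lambda: {
            EffectClass.btk_inhibitor: 0.03,
            EffectClass.pi3k_inhibitor: 0.08,
            EffectClass.cytotoxic: 0.25,
            EffectClass.collateral_sensitive: 0.005,
            EffectClass.inert: 0.635,
        }
    )
    doses: list[float] = Field(default_factory=lambda: [100.0, 1000.0])
    n_replicates: int = Field(default=2, ge=1)
    cells_seeded_per_well: int = Field(default=10_000, ge=1)
    #: deterministic 48 h expansion factor per line in drug-free medium;
    #: identical for both lines by default (isogenic growth).
    growth_factor: float = Field(default=4.0, gt=0)
    cv_well_noise: float = Field(default=0.10, ge=0)
    fields_per_well: int = Field(default=5, ge=1)
    #: fraction of a well's cells captured by ONE imaging field.
    field_capture_fraction: float = Field(default=0.01, gt=0, le=1.0)
    #: optional multiplicative depression of edge-well counts (0 = off).
    edge_effect: float = Field(default=0.0, ge=0, lt=1.0)
    rng_seed: int = Field(default=0, ge=0)
    image_spec: FieldImageSpec = Field(default_factory=FieldImageSpec)

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class_proportions must be non-negative")
        if not self.doses:
            raise ValueError("doses must be non-empty")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be strictly positive")
        return self


class CompetitionParams(BaseModel):
    """Two-population exponential competition (GFP+ mutant vs mCherry+ WT).

    Models the clonal-competition assay: a mixed culture of BTK(E41K) (GFP+)
    and BTK(WT) (mCherry+) Ba/F3 cells grown with or without IL3. Without IL3
    the WT line dies (rate <= 0) while the E41K line keeps growing, so the GFP+
    fraction sweeps towards 1.
    """

    growth_rate_wt_with_il3: float = 1.0
    growth_rate_mut_with_il3: float = 1.0
    growth_rate_wt_no_il3: float = -0.18
    growth_rate_mut_no_il3: float = 0.70
    initial_fraction_mut: float = Field(default=0.49, gt=0.0, lt=1.0)
    horizon_days: float = Field(default=3.0, gt=0)

    @model_validator(mode="after")
    def _wt_dies_without_il3(self) -> "CompetitionParams":
        if self.growth_rate_wt_no_il3 > 0:
            raise ValueError("growth_rate_wt_no_il3 must be <= 0 (WT Ba/F3 die without IL3)")
        return self


class SegmentationParams(BaseModel):
    """Detection and filtering parameters for GFP+ cell counting.

    ``intensity_threshold=None`` selects a robust data-driven threshold,
    median + ``threshold_k`` * 1.4826 * MAD of the whole field (with a floor of
    one intensity unit above the median so a noise-free background never
    segments). An absolute threshold may be given instead. Objects are
    8-connected components of the foreground, then filtered on area, roundness
    (isoperimetric ratio 4*pi*A/P^2) and mean intensity; rejected objects are
    returned with ``accepted=False`` rather than dropped.
    """

    intensity_threshold: Optional[float] = Field(default=None, ge=0)
    threshold_k: float = Field(default=6.0, gt=0)
    min_area: int = Field(default=6, ge=1)
    max_area: int = Field(default=400, ge=1)
    min_roundness: float = Field(default=0.4, ge=0.0, le=1.0)
    min_mean_intensity: float = Field(default=0.0, ge=0)
    exclude_border: bool = True

    @model_validator(mode="after")
    def _areas(self) -> "SegmentationParams":
        if self.min_area > self.max_area:
            raise ValueError("min_area must be <= max_area")
        return self


class ConfirmationConfig(BaseModel):
    """Dose-range follow-up design for candidate hits (per line, per compound)."""

    n_doses: int = Field(default=8, ge=4)
    dose_min_nM: float = Field(default=1.0, gt=0)
    dose_max_nM: float = Field(default=100_000.0, gt=0)
    n_replicates: int = Field(default=3, ge=1)
    cv_noise: float = Field(default=0.05, ge=0)

    @model_validator(mode="after")
    def _range(self) -> "ConfirmationConfig":
        if self.dose_max_nM <= self.dose_min_nM:
            raise ValueError("dose_max_nM must exceed dose_min_nM")
        return self


class PipelineConfig(BaseModel):
    """Full configuration of a simulate -> count -> score -> confirm run."""

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    confirmation: ConfirmationConfig = Field(default_factory=ConfirmationConfig)
    #: candidate-hit threshold on d, percentage points (selected if
    #: d <= -threshold at >= 1 dose).
    hit_threshold_pct: float = Field(default=20.0, gt=0)
    #: IC50 fold-change below 1/ratio_threshold calls collateral sensitivity.
    ratio_threshold: float = Field(default=10.0, gt=1)
    #: plates with z' below this are flagged in QC output (never dropped).
    z_prime_floor: float = Field(default=0.0)
    #: render and segment field images instead of tabular counts. Meant for
    #: small layouts; the full 590-compound demo uses tabular counts.
    use_images: bool = False


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


class LayoutError(ValueError):
    """Raised when a plate map references unknown compounds or roles."""


class GenerationError(RuntimeError):
    """Raised when synthetic image generation cannot satisfy its constraints."""


class NormalizationError(ValueError):
    """Raised when a plate/line stratum has no vehicle wells to anchor to."""


class QCError(ValueError):
    """Raised when control wells required for plate QC are missing."""
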