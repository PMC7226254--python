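# Methods

## The screen being modelled

Two isogenic Ba/F3 reporter lines differ only in one BTK residue: the
parental screening line expresses BTK with the activating E41K mutation
(ibrutinib-sensitive), the second additionally carries C481S, which removes
ibrutinib's covalent anchor (resistant). After IL3 withdrawal both lines
survive only through BTK activity, so a live GFP⁺ cell count 48 h after
compound addition is a direct viability readout of drug action on the
kinase. The screen design is 590 compounds × 2 doses (100 nM, 1 µM) ×
2 replicates × 2 lines in 384-well plates seeded at 10,000 cells/well, with
DMSO vehicle wells anchoring normalization and ibrutinib/pentamidine wells
as cell-death controls, quantified by 5-field fluorescence imaging per well.

## Generative model

**Pharmacology.** Each compound's action on a line is a four-parameter
log-logistic kill curve, `kill(x) = max_kill · x^h / (x^h + IC50^h)`, with
floor 0 and ceiling `max_kill`; the two lines share `h` and `max_kill` and
differ only in IC50. That is the minimal mechanism by which a binding-site
point mutation shifts potency, and it matches the sigmoidal survival curves
the confirmation stage fits.

**Effect classes.** Library composition defaults to 3% BTK-inhibitor-like,
8% PI3K-inhibitor-like, 25% broadly cytotoxic, 0.5% spiked
collateral-sensitive and the rest inert. BTK-class compounds draw
IC50(sensitive) from a lognormal with median 100 nM and geometric SD 1.5 —
centred on the ibrutinib scenario — and a 100× resistance shift (geometric
SD 1.3), mirroring the observed 100 nM vs 10 µM separation of the two lines.
The collateral class is the exact mirror image (resistant line 100×
*more* sensitive); it does not exist in real kinase libraries and is spiked
so the hit-calling and confirmation stages have a known positive control.
PI3K-class compounds get a mild 5× shift (an empirical cross-resistance
trend, not a mechanistic claim), cytotoxics identical IC50s, inert
compounds `max_kill = 0`. Class counts follow largest-remainder rounding
(ties to the class declared first) and compound order is shuffled so plate
position does not encode class.

**Counts and noise.** Expected endpoint count = seeded cells × a
deterministic 48 h growth factor (default 4.0, i.e. two doublings; identical
for both lines since they are isogenic) × (1 − kill). Well noise is
multiplicative lognormal with unit mean and configurable CV (default 0.10) —
counts are positive and their spread scales with the mean, which is what
plate readers show. With CV = 0 the normalized viability equals
100·(1 − kill) exactly, a closure the tests rely on. Optional edge-well
depression exists for QC exercises and is off by default.

**Plate layout.** One plate per line × dose × replicate: column 1 is
vehicle (16 wells), column 2 alternates ibrutinib/pentamidine
positive-control wells dosed at 1 µM, columns 3–24 hold compounds
row-major (352/plate, so the full library needs two plates per condition).
The real screen's layout is not public; this one is declared in config, and
both single- and split-plate dose designs can be expressed by editing the
layout table directly.

**Field images.** Each of the 5 fields per well captures a binomial sample
of the well's cells (capture fraction 0.01/field, i.e. the optics see ~5% of
the well). Cells are rendered as non-overlapping bright filled ellipses
(semi-major axis 2–4 px, aspect ≤ 1.25, ≥2 px clearance between cells and
from the border) over Gaussian background noise (100 ± 10) at 16-bit depth,
cell intensity ~3000 ± 300 — a high-contrast EGFP readout at 10×.
Placement is rejection-sampled; infeasible densities raise an explicit
generation error rather than silently overlapping. The renderer emulates
contrast, density and sampling noise, **not** uneven illumination, focus
drift, clumping, debris or apoptotic-body morphology — so passing
segmentation tests demonstrate correctness of the counting logic, not
robustness to every real-microscopy artefact.

**Clonal competition.** The GFP⁺(E41K) vs mCherry⁺(WT) competition assay is
two independent exponential populations; the mutant fraction is
`f₀e^{r_m t} / (f₀e^{r_m t} + (1−f₀)e^{r_w t})`. Defaults (f₀ = 0.49; with
IL3 both rates 1.0/day; without IL3 r_wt = −0.18/day, r_mut = +0.70/day)
hold the GFP⁺ fraction at 49% with IL3 and sweep it to ≈93% by day 3
without it, the qualitative selection signature of an oncogene-addicted
line.

## Image quantification

Segmentation is global threshold → 8-connected components → filters, the
simplest pipeline consistent with a detection parameterized by area,
roundness and intensity. The default threshold is robust to the
cell-sparse background: median + k·1.4826·MAD with k = 6, floored one unit
above the median so a noise-free background never segments; an absolute
threshold is accepted via config. Roundness is the isoperimetric ratio
4πA/P² clipped to [0, 1] (degenerate perimeters count as round). Default
filters: area 6–400 px, roundness ≥ 0.4 (rasterized small ellipses score
high; elongated debris scores low), mean intensity ≥ 0 (the threshold
already enforces brightness), border-touching objects excluded — standard
high-content practice, since clipped objects have biased area/roundness.
Rejected objects are returned with `accepted=False` for QC overlays rather
than dropped. Raising any filter can only shrink the accepted set
(monotonicity), and on noise-free rendered fields the accepted count equals
ground truth exactly up to the packing limit.

## Scoring

Normalization strata are plate × line: anchoring to same-plate vehicle
wells is the safest choice against plate effects, and makes the vehicle
mean exactly 100% per stratum by construction. d is computed on
replicate-mean viabilities (the two orders coincide for means; the choice
is recorded). Viability is not capped at 100 — capping would break the
antisymmetry of d. Quadrant assignment treats zero as non-negative so the
map is total and deterministic. The candidate threshold (d ≤ −20 points at
≥1 dose) has no published value; 20 points is roughly 2× the noise SD of d
at the default well CV, and it is configurable. Plate QC reports
Z′ = 1 − 3(σ_veh + σ_pos)/|μ_veh − μ_pos| against pentamidine wells only,
because ibrutinib is by design inert on the resistant-line plates and
pooling it would wreck σ_pos there; plates under the Z′ floor are flagged,
never dropped.

## Dose–response fitting

The 4PL is fitted on log-dose by trust-region least squares
(`scipy.optimize.curve_fit`, tight tolerances), parameterized in log-IC50
for scale equivariance. Initialization: top/bottom from per-dose-mean
extremes, h = 1, IC50 started at the dose nearest half-range plus two
log-spaced starts across the tested range; best RSS wins. IC50 is the
relative IC50 (curve inflection), stable when `max_kill < 1`. A fit is
reported unconverged when the optimizer fails, the fitted IC50 leaves the
tested dose range, or the fitted span (top − bottom) fails to clear
max(5 percentage points, 3× the residual SD) — the latter guard exists
because a free 4PL happily "fits" flat noise with a small spurious span;
with it, flat series are called non-toxic ~99% of the time at 5% noise
while genuine effects pass untouched. The confirmation call uses
ratio_threshold = 10 (configurable): fold-changes beyond 10× in either
direction are unambiguous against fit error given the ~100× separations of
interest.

## Determinism and problem sizes

All randomness flows through `numpy` Generators; the pipeline spawns one
child generator per stage (library / plate / imaging / confirmation) from
the master seed via `SeedSequence.spawn`, so stages are independently
reproducible and two runs with the same config + seed write byte-identical
tables (the manifest, which carries timestamps, is excluded from that
guarantee and written last). The test suite exercises the full 590-compound
design for tabular stages; imaging tests use 512×512 fields at up to 400
cells (a ~2,000-cell well over 5 fields), and dose–response recovery uses
8-dose triplicates over 1 nM–100 µM with 50–100 seeded replicates — sizes
chosen to match the screen's own design while keeping the suite quick on a
laptop.

## Known limitations

- No biochemistry: BTK/PI3K signalling, IL3 receptor dynamics and compound
  structure are not modelled; effect classes are phenomenological.
- Lognormal well noise and binomial field sampling omit spatial artefacts
  (edge gradients are only a stylized option), carry-over, and pipetting
  failures.
- The segmentation pipeline is a transparent stand-in for a proprietary
  instrument's algorithm; no fidelity to that instrument is claimed beyond
  the three named detection parameters.
- IC50 confidence intervals are not computed; confirmation is a point
  fold-change against a threshold.
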