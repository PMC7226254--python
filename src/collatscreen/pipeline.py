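"""End-to-end orchestration: simulate -> count -> score -> confirm.

One :func:`run_pipeline` call reproduces the whole screen on synthetic data
and leaves a self-describing output directory: ground-truth library, well
counts, normalized viabilities, the per-compound score table, plate QC,
candidate hits, dose-range confirmation, the quadrant scatter, and a run
manifest with checksums written last. Per-stage random generators are spawned
from the master seed, so each stage is independently reproducible and two
runs with identical config + seed produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import LINES, PipelineConfig
from .doseresponse import confirm_hits
from .imaging import FieldImage, count_well
from .plots import plot_screen
from .screen import (
    aggregate_replicates,
    compute_plate_qc,
    normalize_viability,
    score_compounds,
    select_candidate_hits,
)
from .simulate import (
    build_plate_layout,
    generate_library,
    render_well_fields,
    simulate_dose_response,
    simulate_plate,
)

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "stage_rngs"]

logger = logging.getLogger(__name__)

_STAGES = ("library", "plate", "imaging", "confirmation")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial output inventory."""

    def __init__(self, stage: str, written: list[str], cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause} (partial outputs: {written})")
        self.stage = stage
        self.written = written


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    created_utc: str
    files: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def stage_rngs(master_seed: int) -> dict[str, np.random.Generator]:
    """Spawn one independent generator per stage from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _image_route_counts(wells: pd.DataFrame, config: PipelineConfig, rng) -> pd.DataFrame:
    """Replace simulated counts with segmented counts from rendered fields."""
    counts = []
    for row in wells.itertuples(index=False):
        fields = render_well_fields(row.count, config.simulation, rng)
        imgs = [FieldImage(img, row.plate_id, row.well, i + 1) for i, (img, _) in enumerate(fields)]
        counts.append(count_well(imgs, config.segmentation).count)
    out = wells.copy()
    out["count"] = np.asarray(counts, dtype=float)
    return out


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, seed: int | None = None
) -> RunManifest:
    """Run the full screen and write every stage output under ``out_dir``.

    ``seed`` overrides the master seed (default: the simulation config's
    ``rng_seed``). Any stage failure raises :class:`PipelineError` naming the
    stage and listing the outputs already written; the manifest is written
    last, only on success.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config.simulation.rng_seed if seed is None else seed)
    rngs = stage_rngs(master)
    sim = config.simulation
    written: list[str] = []

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    stage = "library"
    try:
        profiles = generate_library(sim, rngs["library"])
        lib = pd.DataFrame(
            [p.model_dump() for p in profiles],
            columns=["compound_id", "effect_class", "ic50_sensitive_line",
                     "ic50_resistant_line", "hill_slope", "max_kill"],
        )
        lib["effect_class"] = lib["effect_class"].map(lambda c: getattr(c, "value", c))
        save(lib, "library.csv")
        logger.info("library: %d compounds (%s)", len(profiles),
                    lib["effect_class"].value_counts().to_dict() if len(lib) else {})

        stage = "plate"
        layout = build_plate_layout(profiles, sim)
        wells = simulate_plate(layout, profiles, sim, rngs["plate"])
        if config.use_images:
            stage = "imaging"
            wells = _image_route_counts(wells, config, rngs["imaging"])
        save(wells, "well_counts.csv")
        logger.info("plate: %d wells on %d plates", len(wells), wells["plate_id"].nunique())

        stage = "score"
        viab = normalize_viability(wells)
        save(viab, "viability.csv")
        agg = aggregate_replicates(viab)
        scores = score_compounds(agg, sim.doses, config.hit_threshold_pct)
        save(scores, "scores.csv")
        qc = compute_plate_qc(wells, z_prime_floor=config.z_prime_floor)
        save(qc, "plate_qc.csv")
        candidates = select_candidate_hits(scores, config.hit_threshold_pct)
        save(candidates, "candidates.csv")
        logger.info("score: %d compounds scored, %d candidates, %d plates flagged",
                    len(scores), len(candidates), int(qc["flagged"].sum()))

        stage = "confirmation"
        cc = config.confirmation
        dr_doses = np.geomspace(cc.dose_min_nM, cc.dose_max_nM, cc.n_doses)
        by_id = {p.compound_id: p for p in profiles}
        dr_parts = []
        for cid in candidates["compound_id"]:
            for line in LINES:
                dr_parts.append(
                    simulate_dose_response(
                        by_id[cid], line, dr_doses, cc.n_replicates, cc.cv_noise,
                        rngs["confirmation"],
                    )
                )
        dr = (
            pd.concat(dr_parts, ignore_index=True)
            if dr_parts
            else pd.DataFrame(columns=["compound_id", "line", "dose_nM", "replicate", "viability_pct"])
        )
        save(dr, "dose_response.csv")
        results = confirm_hits(list(candidates["compound_id"]), dr, config.ratio_threshold)
        conf = pd.DataFrame(
            [r.__dict__ for r in results],
            columns=["compound_id", "ic50_sensitive", "ic50_resistant",
                     "resistance_ratio", "confirmed_collateral", "testable", "message"],
        )
        save(conf, "confirmations.csv")
        logger.info("confirmation: %d candidates tested, %d confirmed",
                    len(conf), int(conf["confirmed_collateral"].sum()) if len(conf) else 0)

        stage = "plot"
        if not scores.empty:
            highlight = lib.loc[lib["effect_class"] == "btk_inhibitor", "compound_id"].tolist()
            fig = plot_screen(scores, highlight=highlight, highlight_label="BTK inhibitors")
            fig.savefig(out / "screen_scatter.png", dpi=150)
            written.append("screen_scatter.png")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, written, exc) from exc

    manifest = RunManifest(
        config_hash=hashlib.sha256(config.model_dump_json().encode()).hexdigest(),
        seed=master,
        version=__version__,
        created_utc=datetime.now(timezone.utc).isoformat(),
        files={
            name: {"sha256": _sha256(out / name), "bytes": (out / name).stat().st_size}
            for name in written
        },
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
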