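"""End-to-end orchestration: fixture study, batch analyses, FEM sweep.

A master seed deterministically derives one child seed per stage through
``numpy.random.SeedSequence(master).spawn``: stage 0 is the fixture, 1 the
dispersion batch, 2 the coordination batch, 3 the zone-slope bootstrap (the
FEM sweep is deterministic and takes no seed).  Re-running any stage with
the same master seed therefore reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coordination as coord
from . import fem, spatial, synthetic
from .leaf_data import pair_surfaces, read_surfaces, stomatal_density, write_surfaces
from .zones import zone_length_slope

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings shared by the fixture generator and the analysis stages."""

    out_dir: str = "amphistoma_run"
    n_pairs: int = 66
    n_sim: int = 1000
    resolution: int = 64
    n_boot: int = 1000
    fem_grid_levels: int = 2
    fem_nx: int = 64
    fem_ny: int = 64
    fem_tol: float = 1e-8
    seed: int = 0
    input_csv: str | None = None   # analyse an existing study instead of the fixture

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed).spawn(stage + 1)[stage]


def run_fixture(config: RunConfig):
    """Write a synthetic study (surfaces CSV + seed manifest); returns records."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.stage_seed(0))
    records = synthetic.synthetic_study(n_pairs=config.n_pairs, seed=rng)
    if not records:
        logger.warning("fixture study is empty (n_pairs=0)")
    write_surfaces(records, out / "surfaces.csv")
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "n_surfaces": len(records),
        "generator": {
            "densities_mm2": synthetic.STUDY_DENSITIES,
            "adaxial_fraction": synthetic.ADAXIAL_FRACTION,
            "length_params": synthetic.STUDY_LENGTH_PARAMS,
        },
        "seed_scheme": "SeedSequence(master).spawn; stage 0=fixture, 1=dispersion, "
                       "2=coordination, 3=zones",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return records


def run_all(config: RunConfig):
    """Run every analysis stage; returns a dict of result tables.

    Writes dispersion (BH-adjusted across all surfaces, one family),
    coordination (BH across all pairs, a second family), per-group zone
    slopes, two-way ANOVA tables for density and dispersion index by
    light x surface, and the FEM sweep, each as CSV stamped with the
    config hash.  Per-stage failures are isolated and logged.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_csv:
        records = read_surfaces(config.input_csv)
    else:
        records = run_fixture(config)
    pairs = pair_surfaces(records)
    tables: dict[str, pd.DataFrame] = {}
    failures: list[str] = []

    try:
        disp = spatial.dispersion_batch(
            records, n_sim=config.n_sim,
            seed=np.random.default_rng(config.stage_seed(1)))
        tables["dispersion"] = disp
    except Exception as exc:
        failures.append(f"dispersion: {exc}")
        logger.exception("dispersion stage failed")

    try:
        tables["coordination"] = coord.coordination_batch(
            pairs, n_sim=config.n_sim, resolution=config.resolution,
            seed=np.random.default_rng(config.stage_seed(2)))
    except Exception as exc:
        failures.append(f"coordination: {exc}")
        logger.exception("coordination stage failed")

    try:
        slopes = zone_length_slope(
            records, n_boot=config.n_boot,
            seed=np.random.default_rng(config.stage_seed(3)))
        tables["zone_slopes"] = pd.DataFrame(
            [{"treatment": g[0], "surface": g[1], "slope": s.slope,
              "ci_low": s.ci_low, "ci_high": s.ci_high,
              "n_boot": s.n_boot, "n_stomata": s.n_stomata}
             for g, s in slopes.items()])
    except Exception as exc:
        failures.append(f"zones: {exc}")
        logger.exception("zone-slope stage failed")

    if "dispersion" in tables and len(records):
        meta = pd.DataFrame(
            [{"surface_id": r.surface_id, "treatment": r.treatment,
              "surface": r.surface, "density": stomatal_density(r)}
             for r in records])
        merged = meta.merge(tables["dispersion"], on="surface_id")
        for value_col, name in (("density", "anova_density"),
                                ("dispersion_index", "anova_di")):
            try:
                tables[name] = spatial.two_way_anova(
                    merged[value_col], merged["treatment"], merged["surface"])
            except Exception as exc:
                failures.append(f"{name}: {exc}")

    try:
        tables["fem_sweep"] = fem.parameter_sweep(
            fem.default_grid(config.fem_grid_levels),
            nx=config.fem_nx, ny=config.fem_ny, tol=config.fem_tol)
    except Exception as exc:
        failures.append(f"fem_sweep: {exc}")
        logger.exception("FEM sweep stage failed")

    stamp = config.hash()
    for name, table in tables.items():
        t = table.copy()
        t["config_hash"] = stamp
        t.to_csv(out / f"{name}.csv",
                 index=name.startswith("anova"))
    (out / "run_log.json").write_text(json.dumps(
        {"config_hash": stamp, "n_surfaces": len(records), "n_pairs": len(pairs),
         "n_sim": config.n_sim, "failures": failures}, indent=2))
    if failures:
        logger.error("run_all completed with failures: %s", failures)
    return tables
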