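"""End-to-end orchestration: synthetic inputs -> severity -> paired
fire/no-fire simulations -> regional ledgers -> reports.

Stage outputs are plain files (CSV/JSON) under the run directory, so each
module remains independently testable, and a deterministic run manifest
(config hash, master seed, package version, output digests) makes
identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, report, severity, synthgen
from .ecosys import Parameters, default_parameters
from .region import (RegionGrid, aggregate, build_cohorts, carbon_balance,
                     run_scenario)
from .severity import SeverityRecord
from .synthgen import FireEvent, ScenePair, SynthConfig

BACKGROUND_DRIFT_SD = 20.0


def severity_from_scene_pair(
    pair: ScenePair, event: FireEvent, mode: str = "buffer"
) -> SeverityRecord:
    """Run the full severity chain on one synthetic scene pair."""
    pre_nbr = severity.composite_summer([pair.pre], event.year - 1)
    post_nbr = severity.composite_summer([pair.post], event.year + 1)
    dnbr_grid = severity.compute_dnbr(pre_nbr, post_nbr)
    raw, bg, corrected = severity.background_correct(
        dnbr_grid, pair.fire_mask, mode=mode,
        pixel_size_m=pair.pre.pixel_size_m,
    )
    return SeverityRecord(
        fire_id=event.fire_id, year=event.year, area_km2=event.area_km2,
        dnbr_raw=raw, dnbr_background=bg, dnbr=corrected,
    )


def extract_severity(
    events: list[FireEvent], seed: int, mode: str = "buffer"
) -> list[SeverityRecord]:
    """Scene-pair severity extraction plus gap-fill for imageless fires."""
    rng = np.random.default_rng([4, seed])
    records = []
    for ev in events:
        if ev.dnbr is None:
            records.append(
                SeverityRecord(
                    fire_id=ev.fire_id, year=ev.year, area_km2=ev.area_km2,
                    dnbr_raw=float("nan"), dnbr_background=float("nan"),
                    dnbr=float("nan"),
                )
            )
            continue
        drift = float(rng.normal(0.0, BACKGROUND_DRIFT_SD))
        pair = synthgen.gen_scene_pair(
            ev, ev.dnbr, seed=seed, background_drift=drift
        )
        records.append(severity_from_scene_pair(pair, ev, mode=mode))
    return severity.gap_fill(records)


def _config_hash(config: SynthConfig) -> str:
    text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: SynthConfig,
    out_dir,
    params: Parameters | None = None,
    with_fire: bool = True,
    spinup_years: int = 120,
) -> dict:
    """Run every stage and write all outputs plus the run manifest.

    Returns the manifest dict.  ``with_fire=False`` disables fire events in
    the disturbance scenario (the paired no-fire run is always produced).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or default_parameters()

    forcing = synthgen.gen_climate(config)
    events = synthgen.gen_fire_history(config)
    records = extract_severity(events, config.seed) if events else []

    grid = RegionGrid(
        ny=config.ny, nx=config.nx,
        cell_area_km2=np.full((config.ny, config.nx), config.cell_area_km2),
        forest_frac=np.full((config.ny, config.nx), config.forest_frac),
        subpixels=config.subpixels,
    )
    pairs = list(zip(events, records)) if with_fire else []
    cohorts = build_cohorts(grid, pairs)
    fire_runs = run_scenario(cohorts, forcing, params, with_fire=True,
                             spinup_years=spinup_years)
    nofire_runs = run_scenario(cohorts, forcing, params, with_fire=False,
                               spinup_years=spinup_years)
    ledger_fire = aggregate(fire_runs, cohorts, grid)
    ledger_nofire = aggregate(nofire_runs, cohorts, grid)
    balance = carbon_balance(ledger_fire, ledger_nofire)

    severity.severity_table(records).to_csv(out / "severity.csv", index=False)
    pd.DataFrame(
        [dict(fire_id=e.fire_id, year=e.year, area_km2=e.area_km2,
              row0=e.bounds[0], row1=e.bounds[1],
              col0=e.bounds[2], col1=e.bounds[3],
              dnbr=e.dnbr) for e in events]
    ).to_csv(out / "fires.csv", index=False)
    ledger_fire.to_csv(out / "ledger_fire.csv", index=False)
    ledger_nofire.to_csv(out / "ledger_nofire.csv", index=False)
    with open(out / "balance.json", "w") as fh:
        json.dump(dataclasses.asdict(balance), fh, indent=2)

    if records:
        regime = report.fire_regime_summary(records)
        regime.table.to_csv(out / "fire_regime.csv", index=False)
    if any(len(c.fires) == 1 for c in cohorts):
        report.chronosequence(fire_runs, nofire_runs, cohorts).to_csv(
            out / "chronosequence.csv", index=False)
        report.emission_partition(fire_runs, cohorts).to_csv(
            out / "emission_partition.csv", index=False)
        report.indirect_ratio(fire_runs, nofire_runs, cohorts).to_csv(
            out / "indirect_ratio.csv", index=False)

    outputs = sorted(p.name for p in out.glob("*.csv")) + ["balance.json"]
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "with_fire": with_fire,
        "outputs": {name: _digest(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_config(path) -> SynthConfig:
    """Read a SynthConfig from YAML (unknown keys are an error)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SynthConfig(**raw)
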