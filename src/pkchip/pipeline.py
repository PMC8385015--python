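"""End-to-end reproducible workflows binding the library modules together.

A :class:`RunConfig` fixes the regimen, discretization and seed;
:func:`run_pipeline` turns the bundled (or user-supplied) PK profiles into a
stepwise reservoir schedule, a pump program, a dilution worklist, exposure
metrics and a simulated response, and writes a manifest with a content hash
for every artifact so identical configurations provably produce identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, dilution, response, schedule
from .pk import ConcentrationSeries, read_series_csv

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]


def derive_seed(seed: int, stream: int) -> int:
    """Per-module seed from the single run seed.

    Stream ``k`` draws one 32-bit word from ``SeedSequence(seed,
    spawn_key=(k,))`` reduced mod 2**31, so modules stay independently
    reproducible under one global seed.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    regimen: str = "combo_gap24"
    n_steps: int = 8
    flow_rate: float = schedule.DEFAULT_FLOW_UL_MIN
    cycle_days: int = 7
    exposure_h: float = 24.0
    seed: int = 0
    out_dir: str | Path = "pkchip_run"
    series_csv: str | Path | None = None  # default: bundled in vivo series
    horizon_days: float = 7.0
    pd_sigma: float = 0.0
    spare_mL: float = 5.0

    def __post_init__(self) -> None:
        if self.regimen not in schedule.REGIMEN_TOKENS:
            raise ValueError(
                f"unknown regimen token {self.regimen!r}; "
                f"valid: {sorted(schedule.REGIMEN_TOKENS)}"
            )
        for name in ("n_steps", "flow_rate", "cycle_days", "exposure_h", "horizon_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def content_hash(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_series(config: RunConfig) -> dict[str, ConcentrationSeries]:
    if config.series_csv is None:
        return {a: datasets.load_invivo_series(a) for a in datasets.ANALYTES}
    path = Path(config.series_csv)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    df = pd.read_csv(path)
    return {
        str(a): read_series_csv(path, analyte=str(a)) for a in df["analyte"].unique()
    }


STOCKS = {
    "SN38": dilution.StockSolution.from_mM("SN38", 0.1),
    "AZD0156": dilution.StockSolution.from_mM("AZD0156", 1.0),
}
# first-step rule per drug: SN38 runs a fixed 1:100 stock dilution (1 µM
# intermediate); AZD0156 a fixed 1:100 second step from the top reservoir
FIRST_STEP_FACTOR = {"SN38": 100.0}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the manifest dictionary.

    Artifacts written to ``config.out_dir``: the stepwise schedule
    (``pump_program.csv`` / ``.json``), per-drug dilution worklists,
    exposure metrics (``exposure_metrics.csv``), simulated response
    trajectories (``pd_trajectories.csv``) and ``manifest.json`` listing
    every file with its SHA-256 hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = _load_series(config)

    sched = schedule.mimic_schedule_from_series(
        series, n_steps=config.n_steps, flow_rate=config.flow_rate
    )
    regimen = schedule.regimen_from_token(config.regimen, config.cycle_days)

    files: dict[str, Path] = {}

    files["pump_program_csv"] = out / "pump_program.csv"
    files["pump_program_csv"].write_text(schedule.serialize_schedule(sched, regimen))
    files["pump_program_json"] = out / "pump_program.json"
    files["pump_program_json"].write_text(
        schedule.serialize_schedule(sched, regimen, fmt="json") + "\n"
    )

    # dilution worklists: reservoir volumes sized from step duration + spare
    for drug, stock in STOCKS.items():
        concs = [s.concentrations.get(drug, 0.0) for s in sched.steps]
        vols = [
            dilution.reservoir_volume_requirement(
                s, flow_rate=config.flow_rate, spare_mL=config.spare_mL
            )
            for s in sched.steps
        ]
        plan = dilution.plan_two_step_dilution(
            stock,
            concs,
            vols,
            first_step_factor=FIRST_STEP_FACTOR.get(drug),
        )
        files[f"dilution_{drug}"] = out / f"dilution_{drug}.csv"
        files[f"dilution_{drug}"].write_text(dilution.plan_to_worklist(plan))

    # exposure metrics of each analyte's stepped day vs its reference profile
    rows = []
    for drug, s in series.items():
        m = schedule.exposure_metrics(sched.timeline(drug), reference=s)
        ref = schedule.exposure_metrics(s)
        rows.append(
            {
                "analyte": drug,
                "schedule_auc_nM_h": m.auc,
                "reference_auc_nM_h": ref.auc,
                "schedule_cmax_nM": m.cmax,
                "reference_cmax_nM": ref.cmax,
                "tmax_h": m.tmax,
                "mismatch_nM_h": m.mismatch,
            }
        )
    metrics = pd.DataFrame(rows).sort_values("analyte")
    files["exposure_metrics"] = out / "exposure_metrics.csv"
    metrics.to_csv(files["exposure_metrics"], index=False, float_format="%.6g")

    # schedule-dependent simulated response (+ control), seeded observation
    timelines = schedule.compose_treatment_timeline(
        regimen, {d: sched for d in regimen.dosing_days}
    )
    params = response.default_pd_params(sigma=config.pd_sigma)
    horizon = min(config.horizon_days, config.cycle_days)
    traj = response.simulate_growth(params, timelines, horizon=horizon)
    control = response.simulate_growth(params, {}, horizon=horizon)
    days = np.arange(0.0, horizon + 1e-9, 1.0)
    obs = response.observe(traj, config.pd_sigma, derive_seed(config.seed, 1), days)
    obs_c = response.observe(control, config.pd_sigma, derive_seed(config.seed, 2), days)
    pd_df = pd.DataFrame(
        {
            "day": days,
            "volume": obs.volumes,
            "damage": obs.damage,
            "viability": obs.viability,
            "control_volume": obs_c.volumes,
        }
    )
    files["pd_trajectories"] = out / "pd_trajectories.csv"
    pd_df.to_csv(files["pd_trajectories"], index=False, float_format="%.8g")

    gi = response.percent_growth_inhibition(traj, control, horizon)
    summary = {
        "regimen": config.regimen,
        "percent_gi_simulated": round(gi, 3),
        "day_final_relative_volume_pct": round(
            100 * traj.volumes[-1] / control.volumes[-1], 3
        ),
        "schedule_max_conc_nM": {
            d: sched.max_concentration(d) for d in sched.analytes
        },
    }
    files["summary"] = out / "summary.json"
    files["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    manifest = {
        "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "files": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in sorted(files.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
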