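"""Schedule-dependent spheroid response simulator and growth-inhibition
metrics.

This is an explicitly synthetic pharmacodynamic stand-in for wet-lab
readouts: a minimal Emax-kill / damage-gate model whose purpose is to
reproduce the *qualitative* schedule dependence of a TOP1-inhibitor + ATM-
inhibitor combination (concurrent beats gapped, short gap beats long gap),
not any measured volume curve.

Model (V = spheroid volume, D = unresolved DNA damage, both unitless unless
volumes are given in µm³):

    dV/dt = V · [ kg − Emax_S·fS·(1 + alpha·D·fA) − Emax_A·D·fA ]
    dD/dt = kin·C_S − kout·D,          D(0) = 0

with Hill occupancies fS = C_S/(EC50_S + C_S), fA = C_A/(EC50_A + C_A).
The TOP1 inhibitor (SN38) kills through fS and deposits damage D; the ATM
inhibitor has no effect alone but converts unresolved damage into additional
kill while it is present (Emax_A·D·fA), and potentiates concurrent SN38 kill
(alpha).  Gapped regimens are sensitive to kout: damage decays between the
SN38 dose and the delayed ATM-inhibitor window.

Integration is fixed-step RK4 on (log V, D), so the drug-free solution
V0·e^{kg·t} is reproduced to round-off and V can never underflow to zero.
Measurement noise is applied only by the separate, seeded :func:`observe`
step.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .schedule import PiecewiseTimeline

__all__ = [
    "PDParams",
    "GrowthTrajectory",
    "default_pd_params",
    "simulate_growth",
    "observe",
    "percent_growth_inhibition",
    "relative_volume",
    "gi_gap_difference",
]

V_FLOOR_FRACTION = 1e-12  # floor on V relative to V0, guards log-state


@dataclass(frozen=True)
class PDParams:
    """Parameters of the Emax-kill / damage-gate response model.

    Rates are per day; concentrations and EC50s in nM.  ``alpha`` couples
    damage and ATM-inhibitor occupancy into the concurrent SN38 kill term;
    ``Emax_A`` scales the damage-mediated kill that acts whenever the ATM
    inhibitor is present, which is what gives gapped schedules an effect.
    ``sigma`` is the log-normal observation noise SD used by :func:`observe`.
    """

    kg: float = 0.30  # net growth rate (1/day)
    Emax_S: float = 1.402  # maximal SN38 kill rate (1/day)
    EC50_S: float = 2.0  # nM
    Emax_A: float = 0.5  # damage-mediated kill scale (1/day per unit D)
    EC50_A: float = 50.0  # nM
    alpha: float = 2.0  # concurrent potentiation coupling (per unit D)
    kin: float = 1.0  # damage production (1/(nM·day))
    kout: float = 0.75  # damage resolution (1/day)
    sigma: float = 0.0  # multiplicative measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kg", "Emax_S", "Emax_A", "alpha", "kin", "kout", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.EC50_S <= 0 or self.EC50_A <= 0:
            raise ValueError("EC50s must be > 0")


@dataclass
class GrowthTrajectory:
    """Simulated spheroid volume, damage state and viability proxy vs time."""

    times: np.ndarray  # days
    volumes: np.ndarray  # relative units (or µm³)
    damage: np.ndarray  # unitless
    viability: np.ndarray  # relative units, V/V_drug-free

    def __post_init__(self) -> None:
        n = {len(self.times), len(self.volumes), len(self.damage), len(self.viability)}
        if len(n) != 1:
            raise ValueError("trajectory arrays must have equal length")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be > 0")

    def volume_at(self, t_day: float) -> float:
        return float(np.interp(t_day, self.times, self.volumes))


def default_pd_params(**overrides) -> PDParams:
    """Calibrated default parameters (see ``data/pd_defaults.yaml``).

    The defaults were fixed once by a coarse grid search
    (``scripts/calibrate_pd.py``) so that the simulated 7-day volumes under
    the standard regimens come out in the order
    control > mono > gap72 > gap24 > combo_1_7 > combo_7_7.
    """
    text = resources.files("pkchip.data").joinpath("pd_defaults.yaml").read_text()
    values = yaml.safe_load(text)["params"]
    values.update(overrides)
    return PDParams(**values)


def simulate_growth(
    pd: PDParams,
    timelines: Mapping[str, PiecewiseTimeline],
    horizon: float = 7.0,
    v0: float = 1.0,
    dt: float = 0.01,
    sn38_key: str = "SN38",
    atmi_key: str = "AZD0156",
) -> GrowthTrajectory:
    """Integrate the response model over ``horizon`` days.

    ``timelines`` maps analyte name to a concentration timeline in hours
    (missing drugs are treated as absent).  Fixed-step RK4 at ``dt`` days
    (default 0.01); output is sampled at every step.  The returned
    ``viability`` proxy is the simulated volume relative to the drug-free
    exponential at the same time.
    """
    if horizon <= 0 or dt <= 0:
        raise ValueError("horizon and dt must be > 0")
    if v0 <= 0:
        raise ValueError("v0 must be > 0")
    tl_s = timelines.get(sn38_key)
    tl_a = timelines.get(atmi_key)
    for tl in (tl_s, tl_a):
        if tl is not None and np.any(tl.concs < 0):
            raise ValueError("negative concentrations in timeline")
    for tl in (tl_s, tl_a):
        if tl is not None and tl.end < horizon * 24.0 - 1e-9:
            raise ValueError("timelines must cover [0, horizon]")

    def conc(tl: PiecewiseTimeline | None, t_day: float) -> float:
        if tl is None:
            return 0.0
        return float(tl.conc_at(np.asarray(t_day * 24.0)))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        _, d = y
        cs = conc(tl_s, t)
        ca = conc(tl_a, t)
        fs = cs / (pd.EC50_S + cs)
        fa = ca / (pd.EC50_A + ca)
        kill = pd.Emax_S * fs * (1.0 + pd.alpha * d * fa) + pd.Emax_A * d * fa
        return np.array([pd.kg - kill, pd.kin * cs - pd.kout * d])

    n = int(round(horizon / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    logv = np.empty(n + 1)
    dmg = np.empty(n + 1)
    y = np.array([np.log(v0), 0.0])
    logv[0], dmg[0] = y
    log_floor = np.log(v0 * V_FLOOR_FRACTION)
    for i in range(n):
        t = times[i]
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        y[0] = max(y[0], log_floor)
        y[1] = max(y[1], 0.0)
        logv[i + 1], dmg[i + 1] = y
    volumes = np.exp(logv)
    viability = volumes / (v0 * np.exp(pd.kg * times))
    return GrowthTrajectory(times=times, volumes=volumes, damage=dmg, viability=viability)


def observe(
    trajectory: GrowthTrajectory,
    sigma: float,
    seed: int,
    sample_times: Sequence[float] | None = None,
) -> GrowthTrajectory:
    """Apply seeded multiplicative log-normal measurement noise.

    The simulator itself is deterministic; noise exists only in this
    explicit observation step, so a fixed ``(sigma, seed)`` is reproducible.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sample_times is None:
        times = trajectory.times
        vols = trajectory.volumes
        dmg = trajectory.damage
        via = trajectory.viability
    else:
        times = np.asarray(sample_times, dtype=float)
        vols = np.interp(times, trajectory.times, trajectory.volumes)
        dmg = np.interp(times, trajectory.times, trajectory.damage)
        via = np.interp(times, trajectory.times, trajectory.viability)
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, sigma, size=times.shape)) if sigma > 0 else 1.0
    return GrowthTrajectory(
        times=times, volumes=vols * noise, damage=dmg, viability=via * noise
    )


def percent_growth_inhibition(treated, control, t: float | None = None) -> float:
    """Percent growth inhibition vs control from treatment start.

    %GI = 100 · (1 − ΔV_treated / ΔV_control), with ΔV the change in volume
    from baseline to time ``t``.  Inputs may be trajectories (``t`` in days,
    default: end of the control trajectory) or ``(v_baseline, v_t)`` pairs.
    Undefined when the control fails to grow (ΔV_control ≤ 0).
    """

    def delta(obj) -> float:
        if isinstance(obj, GrowthTrajectory):
            t_eval = obj.times[-1] if t is None else t
            return obj.volume_at(float(t_eval)) - float(obj.volumes[0])
        v0, vt = obj
        return float(vt) - float(v0)

    dc = delta(control)
    if dc <= 0:
        raise ValueError("control volume change must be > 0 for %GI")
    return 100.0 * (1.0 - delta(treated) / dc)


def relative_volume(
    treated_volumes: Sequence[float], control_volumes: Sequence[float]
) -> np.ndarray:
    """Each treated volume as percent of the control-group mean volume."""
    treated = np.asarray(list(treated_volumes), dtype=float)
    control = np.asarray(list(control_volumes), dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("treated and control lists must be non-empty")
    mean_c = control.mean()
    if mean_c <= 0:
        raise ValueError("control mean volume must be > 0")
    return treated / mean_c * 100.0


def gi_gap_difference(gi_by_schedule: Mapping[str, float]) -> float:
    """Difference in %GI between the 24-h-gap and 72-h-gap combinations."""
    try:
        return float(gi_by_schedule["combo_gap24"]) - float(
            gi_by_schedule["combo_gap72"]
        )
    except KeyError as err:
        raise ValueError(f"missing %GI entry for {err.args[0]!r}") from None
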