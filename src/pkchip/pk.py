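"""Compartmental free-plasma pharmacokinetics.

One-compartment disposition with either instantaneous (bolus) or first-order
(oral / intraperitoneal) absorption, expressed directly in free-drug plasma
concentration (nM).  The closed-form single-dose solution is superposed over
an arbitrary dose history, and profiles are fitted by bounded least squares on
log concentration, which weights the terminal decline the way PK analysts
expect.

Only the composite scale ``fu * F * dose / V`` is identifiable from a
concentration curve alone, so fits return parameters with ``V = F = fu = 1``
and the fitted scale folded into ``dose_amount``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ModelKind",
    "PKParams",
    "DoseEvent",
    "ConcentrationSeries",
    "FitResult",
    "simulate_profile",
    "fit_pk_params",
    "read_series_csv",
    "write_series_csv",
]

_RATE_FLOOR = 1e-4  # lower bound (1/h) on ka, ke during fitting


class ModelKind(str, enum.Enum):
    """Structural model for drug input."""

    FIRST_ORDER_ABSORPTION = "one_compartment_first_order_absorption"
    BOLUS = "one_compartment_bolus"


@dataclass(frozen=True)
class PKParams:
    """One-compartment PK parameters.

    ``ka``/``ke`` are first-order absorption and elimination rate constants
    (1/h); ``V`` is the apparent volume of distribution in units such that
    ``dose_amount / V`` is a concentration in nM; ``F`` is oral/IP
    bioavailability and ``fu`` the free (unbound) fraction, both in (0, 1].
    The flip-flop ambiguity is resolved by the convention ``ka > ke``.
    """

    model_kind: ModelKind = ModelKind.FIRST_ORDER_ABSORPTION
    ka: float = 1.0
    ke: float = 0.1
    V: float = 1.0
    F: float = 1.0
    fu: float = 1.0
    dose_amount: float = 100.0

    def __post_init__(self) -> None:
        if self.ke <= 0:
            raise ValueError(f"ke must be > 0, got {self.ke}")
        if self.V <= 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        if not 0 < self.F <= 1:
            raise ValueError(f"F must be in (0, 1], got {self.F}")
        if not 0 < self.fu <= 1:
            raise ValueError(f"fu must be in (0, 1], got {self.fu}")
        if self.model_kind is ModelKind.FIRST_ORDER_ABSORPTION:
            if self.ka <= 0:
                raise ValueError(f"ka must be > 0, got {self.ka}")
            if math.isclose(self.ka, self.ke, rel_tol=1e-12, abs_tol=0.0):
                raise ValueError("ka == ke is degenerate for the closed form")
            if self.ka < self.ke:
                raise ValueError("flip-flop convention requires ka > ke")

    @property
    def scale_nM(self) -> float:
        """Identifiable concentration scale fu*F*dose/V (nM)."""
        return self.fu * self.F * self.dose_amount / self.V


@dataclass(frozen=True, order=True)
class DoseEvent:
    """A single administration at ``time`` hours of ``amount`` drug."""

    time: float
    amount: float
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")


@dataclass
class ConcentrationSeries:
    """Free-drug concentration (nM) versus time (h) for one analyte."""

    analyte: str
    times: np.ndarray
    concentrations: np.ndarray
    provenance: str = "observed"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if self.times.size == 0:
            raise ValueError("series must contain at least one sample")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.provenance not in ("observed", "simulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def interp(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation inside the support (no extrapolation)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.support
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"time outside series support [{lo}, {hi}]")
        return np.interp(t, self.times, self.concentrations)

    def with_leading_zero(self, t0: float = 0.0) -> "ConcentrationSeries":
        """Prepend a (t0, 0 nM) anchor for post-dose series starting later.

        Useful when the first sample of a profile is taken some time after the
        dose (e.g. at 1 h) and the pre-dose concentration is known to be zero.
        """
        if t0 >= self.times[0]:
            raise ValueError("t0 must precede the first sample")
        return ConcentrationSeries(
            analyte=self.analyte,
            times=np.concatenate(([t0], self.times)),
            concentrations=np.concatenate(([0.0], self.concentrations)),
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "conc_nM": self.concentrations, "analyte": self.analyte}
        )


@dataclass
class FitResult:
    params: PKParams
    residual_norm: float
    converged: bool
    n_iterations: int


def _single_dose_profile(params: PKParams, dose: DoseEvent, t: np.ndarray) -> np.ndarray:
    """Closed-form free concentration for one dose; zero before the dose."""
    tau = t - dose.time
    out = np.zeros_like(tau)
    pos = tau >= 0
    scale = params.fu * params.F * dose.amount / params.V
    if params.model_kind is ModelKind.BOLUS:
        out[pos] = scale * np.exp(-params.ke * tau[pos])
    else:
        ka, ke = params.ka, params.ke
        out[pos] = (
            scale
            * ka
            / (ka - ke)
            * (np.exp(-ke * tau[pos]) - np.exp(-ka * tau[pos]))
        )
    return out


def simulate_profile(
    params: PKParams,
    doses: Sequence[DoseEvent],
    time_grid: Iterable[float],
    analyte: str = "drug",
) -> ConcentrationSeries:
    """Simulate the free plasma profile for a dose history by superposition.

    Parameters
    ----------
    params:
        Structural parameters; dose amounts in ``doses`` override
        ``params.dose_amount``.
    doses:
        Administration events; the grid must cover every dose time.
    time_grid:
        Strictly increasing sample times (h).
    """
    t = np.asarray(list(time_grid), dtype=float)
    if t.size == 0:
        raise ValueError("time_grid must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    doses = sorted(doses)
    if doses and doses[-1].time > t[-1]:
        raise ValueError("time_grid must extend to the last dose time")
    conc = np.zeros_like(t)
    for dose in doses:
        conc += _single_dose_profile(params, dose, t)
    # clip tiny negative round-off from the difference of exponentials
    np.clip(conc, 0.0, None, out=conc)
    return ConcentrationSeries(
        analyte=analyte, times=t, concentrations=conc, provenance="simulated"
    )


def _strip_initial(times: np.ndarray, conc: np.ndarray) -> tuple[float, float, float]:
    """Curve-stripping initial values (scale_nM, ka, ke).

    ke from a log-linear regression on the last four positive points, ka set
    to 5*ke, scale back-calculated from the observed maximum.
    """
    tail_t, tail_c = times[-4:], conc[-4:]
    slope, _ = np.polyfit(tail_t, np.log(tail_c), 1)
    ke = max(-slope, _RATE_FLOOR * 10)
    ka = 5.0 * ke
    cmax = float(conc.max())
    tmax = math.log(ka / ke) / (ka - ke)
    shape_peak = ka / (ka - ke) * (math.exp(-ke * tmax) - math.exp(-ka * tmax))
    return cmax / shape_peak, ka, ke


def fit_pk_params(
    series: ConcentrationSeries,
    model_kind: ModelKind = ModelKind.FIRST_ORDER_ABSORPTION,
    dose: DoseEvent | None = None,
    init: PKParams | None = None,
) -> FitResult:
    """Fit one-compartment parameters to an observed profile.

    Least squares on log concentration over the strictly positive samples.
    The fit works on the identifiable composite scale ``fu*F*dose/V``; the
    returned :class:`PKParams` has ``V = F = fu = 1`` and the scale stored in
    ``dose_amount``.  ``ka > ke`` is enforced by parameterizing
    ``ka = ke + delta`` with ``delta > 0``.  A stalled optimizer is reported
    via ``converged=False`` rather than an exception.
    """
    if dose is None:
        dose = DoseEvent(time=0.0, amount=1.0)
    mask = series.concentrations > 0
    if int(mask.sum()) < 4:
        raise ValueError("need at least 4 positive observations to fit")
    t = series.times[mask] - dose.time
    logc = np.log(series.concentrations[mask])
    if np.any(t < 0):
        raise ValueError("all positive observations must follow the dose")

    if model_kind is ModelKind.BOLUS:
        # log-linear problem: solve directly
        slope, intercept = np.polyfit(t, logc, 1)
        ke = max(-slope, _RATE_FLOOR)
        params = PKParams(
            model_kind=ModelKind.BOLUS,
            ka=ke * 5.0,
            ke=ke,
            dose_amount=float(np.exp(intercept)),
        )
        resid = intercept + slope * t - logc
        return FitResult(params, float(resid @ resid), True, 1)

    if init is not None:
        x0 = [math.log(init.scale_nM), math.log(init.ke), math.log(init.ka - init.ke)]
    else:
        scale, ka, ke = _strip_initial(series.times[mask], series.concentrations[mask])
        x0 = [math.log(scale), math.log(ke), math.log(ka - ke)]

    def residuals(x: np.ndarray) -> np.ndarray:
        scale, ke, delta = np.exp(x)
        ka = ke + delta
        c = scale * ka / delta * (np.exp(-ke * t) - np.exp(-ka * t))
        return np.log(np.clip(c, 1e-300, None)) - logc

    log_floor = math.log(_RATE_FLOOR)
    sol = least_squares(
        residuals,
        x0,
        bounds=([-np.inf, log_floor, log_floor], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    scale, ke, delta = np.exp(sol.x)
    params = PKParams(
        model_kind=ModelKind.FIRST_ORDER_ABSORPTION,
        ka=float(ke + delta),
        ke=float(ke),
        dose_amount=float(scale),
    )
    return FitResult(
        params=params,
        residual_norm=float(2.0 * sol.cost),
        converged=bool(sol.success),
        n_iterations=int(sol.nfev),
    )


def read_series_csv(path: str | Path, analyte: str | None = None) -> ConcentrationSeries:
    """Read a ``time_h,conc_nM,analyte`` delimited file as one series.

    When the file holds several analytes, ``analyte`` selects one.
    """
    df = pd.read_csv(path)
    required = {"time_h", "conc_nM", "analyte"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    labels = df["analyte"].unique()
    if analyte is None:
        if len(labels) != 1:
            raise ValueError(f"{path}: multiple analytes {list(labels)}; pick one")
        analyte = str(labels[0])
    sub = df[df["analyte"] == analyte].sort_values("time_h")
    if sub.empty:
        raise ValueError(f"{path}: no rows for analyte {analyte!r}")
    return ConcentrationSeries(
        analyte=analyte,
        times=sub["time_h"].to_numpy(float),
        concentrations=sub["conc_nM"].to_numpy(float),
    )


def write_series_csv(series: ConcentrationSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)
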