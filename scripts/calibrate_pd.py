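"""Regenerate the calibrated response-model defaults.

Coarse grid search over the damage kinetics (kout), the damage-mediated kill
scale (Emax_A) and the concurrent potentiation coupling (alpha); for each
candidate, Emax_S is tuned by bisection so SN38 monotherapy lands near the
published ~52% growth inhibition at day 7.  A candidate is kept when the
simulated 7-day volumes respect the published schedule ordering

    control > mono > gap72 > gap24 > combo_1_7 > combo_7_7

with a safety margin; among those, the winner minimizes the RMS log-error
against the published day-7 relative volumes (55/40/25/22/17 % of control for
mono/gap72/gap24/combo_1_7/combo_7_7).  Writes src/pkchip/data/pd_defaults.yaml.

Usage:  python scripts/calibrate_pd.py [--write]
"""

from __future__ import annotations

import argparse
import itertools
import math
from pathlib import Path

import numpy as np

from pkchip import datasets, response, schedule

ORDER = ["control", "mono", "combo_gap72", "combo_gap24", "combo_1_7", "combo_7_7"]
TARGET_MONO_GI = 52.0
HORIZON_DAYS = 7.0
DT = 0.01

FIXED = dict(kg=0.30, EC50_S=2.0, EC50_A=50.0, kin=1.0, sigma=0.0, seed=0)


def day7_volumes(params: response.PDParams) -> dict[str, float]:
    sched = datasets.published_reservoir_schedule()
    out = {}
    for token in ORDER:
        regimen = schedule.regimen_from_token(token)
        timelines = schedule.compose_treatment_timeline(
            regimen, {"SN38": sched, "AZD0156": sched}
        )
        traj = response.simulate_growth(params, timelines, horizon=HORIZON_DAYS, dt=DT)
        out[token] = traj.volumes[-1]
    return out


def tune_emax_s(base: dict) -> float:
    """Bisect Emax_S so monotherapy %GI at day 7 is ~TARGET_MONO_GI."""
    sched = datasets.published_reservoir_schedule()
    control_tl = schedule.compose_treatment_timeline(
        schedule.regimen_from_token("control"), {}
    )
    mono_tl = schedule.compose_treatment_timeline(
        schedule.regimen_from_token("mono"), {"SN38": sched, "AZD0156": sched}
    )

    def gi(emax_s: float) -> float:
        p = response.PDParams(Emax_S=emax_s, **base, **FIXED)
        control = response.simulate_growth(p, control_tl, HORIZON_DAYS, dt=DT)
        mono = response.simulate_growth(p, mono_tl, HORIZON_DAYS, dt=DT)
        return response.percent_growth_inhibition(mono, control, HORIZON_DAYS)

    lo, hi = 0.1, 6.0
    for _ in range(40):
        mid = (lo + hi) / 2
        if gi(mid) < TARGET_MONO_GI:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2, 3)


def score(params: response.PDParams) -> tuple[float, dict[str, float]]:
    vols = day7_volumes(params)
    logs = [math.log(vols[k]) for k in ORDER]
    margins = [a - b for a, b in zip(logs, logs[1:])]
    return min(margins), vols


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--write", action="store_true", help="write pd_defaults.yaml")
    args = ap.parse_args()

    grid = {
        "kout": [0.75, 1.0, 1.5, 2.0],
        "Emax_A": [0.5, 1.0, 1.5],
        "alpha": [2.0, 4.0, 6.0],
    }
    published = datasets.reported_response()["relative_volume_day7"]
    min_margin = 0.02  # require clear separation, not a numerical accident
    best = None
    for kout, emax_a, alpha in itertools.product(*grid.values()):
        base = dict(kout=kout, Emax_A=emax_a, alpha=alpha)
        emax_s = tune_emax_s(base)
        params = response.PDParams(Emax_S=emax_s, **base, **FIXED)
        margin, vols = score(params)
        rel = {k: 100 * vols[k] / vols["control"] for k in ORDER}
        rms = math.sqrt(
            np.mean(
                [
                    (math.log(rel[k]) - math.log(published[k])) ** 2
                    for k in ORDER[1:]
                ]
            )
        )
        tag = "OK " if margin > min_margin else "bad"
        print(
            f"{tag} kout={kout:4.2f} Emax_A={emax_a:4.2f} alpha={alpha:4.2f} "
            f"Emax_S={emax_s:5.3f} margin={margin:7.4f} rms={rms:6.3f} "
            + " ".join(f"{k}={rel[k]:5.1f}%" for k in ORDER[1:])
        )
        if margin > min_margin and (best is None or rms < best[0]):
            best = (rms, params)

    if best is None:
        raise SystemExit("no grid point satisfies the schedule ordering")
    _, params = best
    print("\nselected:", params)
    if args.write:
        out = Path(__file__).resolve().parents[1] / "src/pkchip/data/pd_defaults.yaml"
        lines = [
            "# Calibrated defaults for the Emax-kill / damage-gate response model.",
            "# Regenerate with scripts/calibrate_pd.py (coarse grid search over",
            "# alpha, Emax_A, kout with Emax_S tuned to ~52% monotherapy GI at day 7).",
            "params:",
        ]
        for name in (
            "kg", "Emax_S", "EC50_S", "Emax_A", "EC50_A",
            "alpha", "kin", "kout", "sigma", "seed",
        ):
            lines.append(f"  {name}: {getattr(params, name)}")
        out.write_text("\n".join(lines) + "\n")
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
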