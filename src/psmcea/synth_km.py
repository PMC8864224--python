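"""Synthetic pseudo-IPD and digitized-style Kaplan-Meier curves.

The published survival inputs for this model are parametric fits to curve
coordinates read off trial figures; the underlying patient-level data are not
available.  This module generates individual event/censor times from a known
parametric model, computes the Kaplan-Meier estimate, and degrades it the way
graph digitization does (regular time grid, small reading error on the
probability axis), so the fitting and model-selection stages can be exercised
end-to-end with a known ground truth.

The default reconstruction assumes an initial risk set of about 200 patients,
the scale of the sorafenib arm of the trial these parameters come from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import SurvivalCurve

__all__ = [
    "KMCurvePoints",
    "simulate_ipd",
    "km_estimate",
    "digitize_like",
    "ipd_from_km",
    "write_ipd_csv",
    "read_ipd_csv",
]

#: default assumed initial risk set when reconstructing pseudo-IPD from a curve
DEFAULT_N_AT_RISK = 200


@dataclass(frozen=True)
class KMCurvePoints:
    """A step-function survival curve as (time, probability) coordinates.

    ``times`` is strictly increasing and starts at 0; ``surv`` starts at 1 and
    is non-increasing within [0, 1].  ``n_at_risk`` optionally carries the
    risk set just before each time point.
    """

    times: np.ndarray
    surv: np.ndarray
    n_at_risk: Optional[np.ndarray] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.surv, dtype=float)
        if times.ndim != 1 or times.shape != surv.shape:
            raise ValueError("times and surv must be matching 1-D arrays")
        if len(times) == 0 or times[0] != 0.0 or surv[0] != 1.0:
            raise ValueError("curve must start at (t=0, S=1)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((surv < 0) | (surv > 1)) or np.any(np.diff(surv) > 1e-12):
            raise ValueError("surv must be non-increasing within [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "surv", surv)
        if self.n_at_risk is not None:
            nar = np.asarray(self.n_at_risk)
            if nar.shape != times.shape or np.any(np.diff(nar) > 0):
                raise ValueError("n_at_risk must be non-increasing and match times")
            object.__setattr__(self, "n_at_risk", nar)

    def step_eval(self, t):
        """Right-continuous step-function evaluation S(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.surv[np.clip(idx, 0, len(self.surv) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.surv})


def simulate_ipd(
    model: SurvivalCurve,
    n: int,
    admin_time: float = np.inf,
    dropout_rate: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Simulate right-censored pseudo individual patient data.

    Event times are drawn from ``model`` by inversion (S(T) ~ Uniform(0,1));
    each subject additionally has an independent exponential dropout time with
    ``dropout_rate`` per month and administrative censoring at ``admin_time``
    months (the trial follow-up horizon).

    Returns a DataFrame with columns ``time_months`` and ``event`` (1 = event,
    0 = censored), the on-disk pseudo-IPD format of this package.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not admin_time > 0:
        raise ValueError("admin_time must be > 0")
    if dropout_rate < 0:
        raise ValueError("dropout_rate must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    event_t = np.asarray(model.isf(u), dtype=float)
    if dropout_rate > 0:
        dropout_t = rng.exponential(scale=1.0 / dropout_rate, size=n)
    else:
        dropout_t = np.full(n, np.inf)
    censor_t = np.minimum(dropout_t, admin_time)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame({"time_months": time, "event": event})


def km_estimate(ipd: pd.DataFrame) -> KMCurvePoints:
    """Kaplan-Meier product-limit estimate of a pseudo-IPD table."""
    if len(ipd) < 1:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time_months"], event_observed=ipd["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    at_risk = kmf.event_table["at_risk"].reindex(times).bfill().fillna(0)
    return KMCurvePoints(times, np.minimum.accumulate(surv), at_risk.to_numpy(dtype=int))


def digitize_like(
    points: KMCurvePoints,
    grid_step: float = 0.5,
    jitter_sd: float = 0.01,
    seed=None,
) -> KMCurvePoints:
    """Emulate graph digitization of a Kaplan-Meier curve.

    The step function is resampled on a regular time grid of ``grid_step``
    months and Gaussian reading error with standard deviation ``jitter_sd``
    (on the probability axis) is added, then clipped to [0, 1] and
    re-monotonized by a running minimum.  ``jitter_sd=0`` reproduces the exact
    step-function values on the grid.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    t_max = points.times[-1]
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    surv = points.step_eval(grid).astype(float).copy()
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        surv[1:] += rng.normal(scale=jitter_sd, size=len(surv) - 1)
    surv[0] = 1.0
    surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
    return KMCurvePoints(grid, surv)


def ipd_from_km(points: KMCurvePoints, n_at_risk: int = DEFAULT_N_AT_RISK) -> pd.DataFrame:
    """Reconstruct pseudo-IPD from curve coordinates via risk-set accounting.

    Interval event counts are recovered from successive survival drops scaled
    by the running risk set (events in (t_{i-1}, t_i] are
    ``round(N_i * (1 - S_i / S_{i-1}))``); patients still at risk after the
    last coordinate are censored there.  Censoring before the last time point
    is not reconstructed — adequate when digitizing curves whose censoring is
    concentrated at the follow-up boundary.
    """
    if n_at_risk < 1:
        raise ValueError("n_at_risk must be >= 1")
    times, surv = points.times, points.surv
    n = float(n_at_risk)
    rec_t, rec_e = [], []
    for i in range(1, len(times)):
        if n <= 0 or surv[i - 1] <= 0:
            break
        cond = surv[i] / surv[i - 1]
        d = int(round(n * (1.0 - cond)))
        d = min(d, int(n))
        if d > 0:
            rec_t.extend([times[i]] * d)
            rec_e.extend([1] * d)
            n -= d
    n_left = int(round(n))
    if n_left > 0:
        rec_t.extend([times[-1]] * n_left)
        rec_e.extend([0] * n_left)
    return pd.DataFrame({"time_months": rec_t, "event": rec_e})


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    ipd.to_csv(path, index=False, columns=["time_months", "event"])


def read_ipd_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_months", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"pseudo-IPD CSV missing columns: {sorted(missing)}")
    return df
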