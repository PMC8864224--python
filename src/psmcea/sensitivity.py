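"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the full deterministic model at each parameter's
range bounds with everything else at base case and ranks parameters by the
resulting ICER swing.  The probabilistic analysis draws every non-fixed
parameter from its assigned distribution — beta for probabilities and
utilities, gamma for costs, log-normal for hazard ratios — with moments
matched to the printed point estimate and range (ranges are read as 95%
intervals, so sd = (high - low) / (2 * 1.96)), then summarizes the resulting
incremental cost/QALY cloud as a cost-effectiveness acceptability curve
(CEAC): the probability of positive net monetary benefit along a grid of
willingness-to-pay thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "sample_param",
    "owsa",
    "run_psa",
    "ceac",
    "prob_cost_effective",
    "default_wtp_grid",
]

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # normal quantile behind the 95% range reading

DISTRIBUTIONS = ("beta", "gamma", "lognormal", "fixed")


@dataclass(frozen=True)
class ParamSpec:
    """A model parameter with its base value, range and PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str = "fixed"

    def __post_init__(self):
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"{self.name}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )

    @property
    def is_fixed(self) -> bool:
        return self.distribution == "fixed" or self.high == self.low


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram."""

    name: str
    low: float
    high: float
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]
    swing: float
    flagged: bool = False  # model failure or undefined ICER at an extreme


def _beta_params(mean: float, sd: float):
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    if nu <= 0:
        return None
    return mean * nu, (1.0 - mean) * nu


def sample_param(spec: ParamSpec, rng: np.random.Generator, size=None):
    """Draw from a parameter's PSA distribution (moment-matched to its range).

    beta: mean = base, sd = (high - low) / 3.92, support [0, 1]
    gamma: mean = base, same sd, support [0, inf)
    lognormal (hazard ratios): median = base, sigma = (ln high - ln low) / 3.92
    fixed (or zero-width range): returns base.

    Infeasible beta moments (sd too large for the [0,1] support at the given
    mean) fall back to sd = 0.2 * base with a logged warning.
    """
    if spec.is_fixed:
        return np.full(size, spec.base) if size is not None else spec.base
    sd = (spec.high - spec.low) / (2.0 * _Z95)
    if spec.distribution == "beta":
        if not (0 < spec.base < 1):
            return np.full(size, spec.base) if size is not None else spec.base
        ab = _beta_params(spec.base, sd)
        if ab is None:
            logger.warning(
                "%s: beta moments infeasible (mean=%g, sd=%g); falling back to sd=0.2*mean",
                spec.name, spec.base, sd,
            )
            ab = _beta_params(spec.base, 0.2 * spec.base)
        return rng.beta(*ab, size=size)
    if spec.distribution == "gamma":
        shape = (spec.base / sd) ** 2
        scale = sd * sd / spec.base
        return rng.gamma(shape, scale, size=size)
    if spec.distribution == "lognormal":
        sigma = (math.log(spec.high) - math.log(spec.low)) / (2.0 * _Z95)
        return rng.lognormal(mean=math.log(spec.base), sigma=sigma, size=size)
    raise AssertionError("unreachable")


def owsa(model, specs: Optional[Sequence[ParamSpec]] = None) -> pd.DataFrame:
    """One-way sensitivity analysis over every parameter's range.

    Returns a DataFrame (one row per parameter) sorted by descending ICER
    swing; failures at an extreme are flagged rather than dropped.
    """
    if specs is None:
        specs = model.param_specs()
    entries = []
    for spec in specs:
        icers = {}
        flagged = False
        for bound, value in (("low", spec.low), ("high", spec.high)):
            try:
                res = model.evaluate({spec.name: value})
                icers[bound] = res.icer_per_qaly
                if res.icer_per_qaly is None:
                    flagged = True
            except Exception:  # noqa: BLE001 - an extreme may break the model
                logger.warning("OWSA failure for %s at %s=%g", spec.name, bound, value)
                icers[bound] = None
                flagged = True
        lo, hi = icers["low"], icers["high"]
        swing = abs(hi - lo) if (lo is not None and hi is not None) else 0.0
        entries.append(
            TornadoEntry(spec.name, spec.low, spec.high, lo, hi, swing, flagged)
        )
    entries.sort(key=lambda e: (-e.swing, e.name))
    return pd.DataFrame(
        {
            "param": [e.name for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "swing": [e.swing for e in entries],
            "flagged": [e.flagged for e in entries],
        }
    )


def run_psa(
    model,
    n_iter: int = 10_000,
    seed=None,
    specs: Optional[Sequence[ParamSpec]] = None,
    chunk_size: int = 2_000,
) -> pd.DataFrame:
    """Monte-Carlo probabilistic sensitivity analysis.

    Every non-fixed parameter is drawn independently ``n_iter`` times; both
    arms are rebuilt per draw and the incremental cost / life-years / QALYs
    recorded.  Reproducible for a fixed ``seed``.  Returns a DataFrame with
    one row per iteration: ``iter``, ``delta_cost``, ``delta_ly``,
    ``delta_qaly`` and one column per sampled parameter.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if specs is None:
        specs = model.param_specs()
    rng = np.random.default_rng(seed)
    draws = {
        s.name: np.asarray(sample_param(s, rng, size=n_iter), dtype=float)
        for s in specs
        if not s.is_fixed
    }
    if not draws:  # every parameter fixed: all iterations equal the base case
        res = model.evaluate()
        out = pd.DataFrame(
            {
                "cost_comparator": res.comparator.cost,
                "ly_comparator": res.comparator.ly,
                "qaly_comparator": res.comparator.qaly,
                "cost_intervention": res.intervention.cost,
                "ly_intervention": res.intervention.ly,
                "qaly_intervention": res.intervention.qaly,
                "delta_cost": res.incremental_cost,
                "delta_ly": res.incremental_ly,
                "delta_qaly": res.incremental_qaly,
            },
            index=range(n_iter),
        )
        out.insert(0, "iter", np.arange(n_iter))
        return out
    pieces = []
    for start in range(0, n_iter, chunk_size):
        sl = slice(start, min(start + chunk_size, n_iter))
        batch = model.evaluate_batch({k: v[sl] for k, v in draws.items()})
        pieces.append(batch)
    out = pd.concat(pieces, ignore_index=True)
    out.insert(0, "iter", np.arange(n_iter))
    for name, vals in draws.items():
        out[name] = vals
    return out


def default_wtp_grid() -> np.ndarray:
    """WTP grid for the CEAC: $0 to $60,000 per QALY in $1,000 steps."""
    return np.arange(0, 60_001, 1_000, dtype=float)


def ceac(draws: pd.DataFrame, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA draws.

    At each willingness-to-pay value, the fraction of iterations with a
    strictly positive net monetary benefit dQALY * WTP - dCost.
    """
    if len(draws) == 0:
        raise ValueError("need at least one PSA draw")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    d_cost = draws["delta_cost"].to_numpy()
    d_qaly = draws["delta_qaly"].to_numpy()
    nmb = d_qaly[:, None] * wtp_grid[None, :] - d_cost[:, None]
    prob = (nmb > 0).mean(axis=0)
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})


def prob_cost_effective(draws: pd.DataFrame, wtp: float) -> float:
    """P(positive net monetary benefit) at a single WTP threshold."""
    nmb = draws["delta_qaly"].to_numpy() * wtp - draws["delta_cost"].to_numpy()
    return float((nmb > 0).mean())
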