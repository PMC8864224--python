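"""Configuration loading and the assembled two-arm decision model.

A single declarative YAML file carries every model input: the fitted
sorafenib PFS/OS distributions, the hazard ratios that generate the
intervention curves, utilities, adverse-event profiles, per-cycle costs and
the structural assumptions (horizon, caps, second-line duration).  The
:class:`CEModel` built from it exposes

* ``evaluate(overrides)`` — deterministic run returning a
  :class:`~psmcea.economics.CEResult`, used by the base case and the tornado
  analysis;
* ``evaluate_batch(overrides)`` — vectorized run over arrays of parameter
  draws, used by the probabilistic sensitivity analysis;
* ``param_specs()`` — every uncertain parameter with its range and sampling
  distribution.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .economics import ArmTotals, CEResult, icer
from .sensitivity import ParamSpec
from .survival import ParametricSurvival, apply_hazard_ratio
from .trace import (
    AdverseEvent,
    AEProfile,
    ArmSpec,
    CohortTrace,
    ModelConfig,
    build_trace,
    partition_totals,
)

__all__ = ["ConfigError", "load_config", "default_config_path", "config_hash", "CEModel"]


class ConfigError(ValueError):
    """Raised with the full list of offending config fields."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


def default_config_path():
    """Path of the parameter file shipped with the package."""
    return resources.files("psmcea").joinpath("params/orient32.yaml")


def load_config(path=None) -> dict:
    """Read and validate a model configuration YAML file."""
    if path is None:
        text = default_config_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    config = yaml.safe_load(text)
    _validate(config)
    return config


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON rendering of a configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


_RANGED = ("base", "low", "high")


def _check_ranged(problems, config, path):
    node = config
    for key in path.split("."):
        if not isinstance(node, dict) or key not in node:
            problems.append(f"missing field {path}")
            return
        node = node[key]
    if not isinstance(node, dict) or any(k not in node for k in _RANGED):
        problems.append(f"{path} must carry base/low/high")
        return
    try:
        b, lo, hi = (float(node[k]) for k in _RANGED)
    except (TypeError, ValueError):
        problems.append(f"{path} has non-numeric base/low/high")
        return
    if not lo <= b <= hi:
        problems.append(f"{path}: low <= base <= high violated ({lo}, {b}, {hi})")


def _validate(config: dict) -> None:
    problems = []
    if not isinstance(config, dict):
        raise ConfigError(["configuration root must be a mapping"])
    for section in ("model", "survival", "hazard_ratios", "utilities",
                    "ae_costs", "drug_costs", "arms", "assumptions"):
        if section not in config:
            problems.append(f"missing section {section}")
    if problems:
        raise ConfigError(problems)

    for key in ("cycle_days", "horizon_years", "annual_discount",
                "days_per_month", "wtp_per_qaly"):
        if key not in config["model"]:
            problems.append(f"missing field model.{key}")
    for curve in ("sorafenib_pfs", "sorafenib_os"):
        node = config["survival"].get(curve)
        if not isinstance(node, dict) or "family" not in node or "params" not in node:
            problems.append(f"survival.{curve} must carry family and params")
    for hr in ("pfs", "os"):
        _check_ranged(problems, config, f"hazard_ratios.{hr}")
    for u in ("pfd", "pd", "ae_disutility_g12", "ae_disutility_g3plus"):
        _check_ranged(problems, config, f"utilities.{u}")
    for group in ("ae_costs", "drug_costs"):
        for name in config[group]:
            _check_ranged(problems, config, f"{group}.{name}")
    arms = config["arms"]
    if len(arms) != 2:
        problems.append("exactly two arms are required")
    for arm_name, arm in arms.items():
        for key in ("first_line_drugs", "subsequent_therapy", "ae_incidence"):
            if key not in arm:
                problems.append(f"missing field arms.{arm_name}.{key}")
        if "subsequent_therapy" in arm:
            _check_ranged(problems, config, f"arms.{arm_name}.subsequent_therapy.proportion")
            drug = arm["subsequent_therapy"].get("drug")
            if drug not in config.get("drug_costs", {}):
                problems.append(f"arms.{arm_name}.subsequent_therapy.drug not in drug_costs")
        for drug in arm.get("first_line_drugs", []):
            if drug not in config.get("drug_costs", {}):
                problems.append(f"arms.{arm_name}: first-line drug {drug!r} not in drug_costs")
        for ae in arm.get("ae_incidence", {}):
            _check_ranged(problems, config, f"arms.{arm_name}.ae_incidence.{ae}")
            if ae not in config.get("ae_costs", {}):
                problems.append(f"arms.{arm_name}: AE {ae!r} has no cost in ae_costs")
    assum = config["assumptions"]
    for key in ("subsequent_max_cycles", "ae_duration_cycles", "test_cost_in_pd",
                "intervention", "comparator"):
        if key not in assum:
            problems.append(f"missing field assumptions.{key}")
    for role in ("intervention", "comparator"):
        if assum.get(role) not in arms:
            problems.append(f"assumptions.{role} must name one of the arms")
    if problems:
        raise ConfigError(problems)


class CEModel:
    """The assembled two-arm partitioned-survival cost-effectiveness model."""

    def __init__(self, config: dict):
        _validate(config)
        self.config = config
        m = config["model"]
        self.model_config = ModelConfig(
            cycle_days=float(m["cycle_days"]),
            horizon_years=float(m["horizon_years"]),
            annual_discount=float(m["annual_discount"]),
            days_per_month=float(m["days_per_month"]),
            half_cycle_correction=bool(m.get("half_cycle_correction", True)),
            wtp_per_qaly=float(m["wtp_per_qaly"]),
        )
        surv = config["survival"]
        self.ref_pfs = ParametricSurvival(
            surv["sorafenib_pfs"]["family"], tuple(surv["sorafenib_pfs"]["params"])
        )
        self.ref_os = ParametricSurvival(
            surv["sorafenib_os"]["family"], tuple(surv["sorafenib_os"]["params"])
        )
        self.reference_arm = config["assumptions"]["comparator"]
        self.intervention_arm = config["assumptions"]["intervention"]
        self._specs = self._build_specs()
        self._base = {s.name: s.base for s in self._specs}
        # curve values at cycle boundaries for the reference arm (fixed in PSA)
        bounds = np.arange(self.model_config.n_cycles + 1) * self.model_config.cycle_months
        self._bounds = bounds
        self._ref_pfs_b = np.asarray(self.ref_pfs.sf(bounds), dtype=float)
        self._ref_os_b = np.asarray(self.ref_os.sf(bounds), dtype=float)

    # ---------------------------------------------------------------- specs
    def _build_specs(self):
        cfg = self.config
        specs = []

        def add(name, node, dist_default):
            specs.append(
                ParamSpec(
                    name,
                    float(node["base"]),
                    float(node["low"]),
                    float(node["high"]),
                    node.get("dist", dist_default),
                )
            )

        add("hr_pfs", cfg["hazard_ratios"]["pfs"], "lognormal")
        add("hr_os", cfg["hazard_ratios"]["os"], "lognormal")
        add("utility_pfd", cfg["utilities"]["pfd"], "beta")
        add("utility_pd", cfg["utilities"]["pd"], "beta")
        add("disutility_g12", cfg["utilities"]["ae_disutility_g12"], "beta")
        add("disutility_g3plus", cfg["utilities"]["ae_disutility_g3plus"], "beta")
        for name, node in cfg["ae_costs"].items():
            add(f"ae_cost_{name}", node, "gamma")
        for name, node in cfg["drug_costs"].items():
            add(f"cost_{name}", node, "gamma")
        for arm_name, arm in cfg["arms"].items():
            add(f"subsequent_{arm_name}", arm["subsequent_therapy"]["proportion"], "beta")
            for ae, node in arm["ae_incidence"].items():
                add(f"inc_{arm_name}_{ae}", node, "beta")
        return specs

    def param_specs(self):
        """Every uncertain parameter (base, range, PSA distribution)."""
        return list(self._specs)

    def base_values(self) -> Dict[str, float]:
        return dict(self._base)

    # ---------------------------------------------------------- arm assembly
    def _values(self, overrides=None) -> Dict[str, float]:
        values = dict(self._base)
        if overrides:
            unknown = set(overrides) - set(values)
            if unknown:
                raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
            values.update(overrides)
        return values

    def _arm_economics(self, arm_name: str, v: Dict) -> Dict:
        """Per-arm economic inputs from a (possibly vectorized) value map."""
        cfg = self.config
        arm = cfg["arms"][arm_name]
        assum = cfg["assumptions"]
        drug_cost = sum(v[f"cost_{d}"] for d in arm["first_line_drugs"])
        cap_months = arm.get("treatment_cap_months")
        max_cycles = None if cap_months is None else self.model_config.months_to_cycles(cap_months)
        dur = int(assum["ae_duration_cycles"])
        cy = self.model_config.cycle_years
        ae_cost = sum(
            v[f"inc_{arm_name}_{ae}"] * v[f"ae_cost_{ae}"] for ae in arm["ae_incidence"]
        )
        ae_qaly = sum(
            v[f"inc_{arm_name}_{ae}"] * v["disutility_g3plus"] * dur * cy
            for ae in arm["ae_incidence"]
        )
        return dict(
            drug_cost=drug_cost,
            test_cost=v["cost_test"],
            max_treatment_cycles=max_cycles,
            subsequent_proportion=v[f"subsequent_{arm_name}"],
            subsequent_cost=v[f"cost_{arm['subsequent_therapy']['drug']}"],
            subsequent_max_cycles=int(assum["subsequent_max_cycles"]),
            bsc_cost=v["cost_bsc"],
            ae_cost=ae_cost,
            ae_qaly_loss=ae_qaly,
            test_cost_in_pd=bool(assum["test_cost_in_pd"]),
        )

    def arm_spec(self, arm_name: str, overrides=None) -> ArmSpec:
        """Materialize one arm as an :class:`~psmcea.trace.ArmSpec`."""
        v = self._values(overrides)
        econ = self._arm_economics(arm_name, v)
        if arm_name == self.reference_arm:
            pfs, os_ = self.ref_pfs, self.ref_os
        else:
            pfs = apply_hazard_ratio(self.ref_pfs, v["hr_pfs"])
            os_ = apply_hazard_ratio(self.ref_os, v["hr_os"])
        arm = self.config["arms"][arm_name]
        events = tuple(
            AdverseEvent(
                ae,
                float(v[f"inc_{arm_name}_{ae}"]),
                float(v[f"ae_cost_{ae}"]),
                float(v["disutility_g3plus"]),
                int(self.config["assumptions"]["ae_duration_cycles"]),
            )
            for ae in arm["ae_incidence"]
        )
        return ArmSpec(
            name=arm_name,
            pfs_curve=pfs,
            os_curve=os_,
            drug_cost_per_cycle=float(econ["drug_cost"]),
            test_cost_per_cycle=float(econ["test_cost"]),
            u_pfd=float(v["utility_pfd"]),
            u_pd=float(v["utility_pd"]),
            max_treatment_cycles=econ["max_treatment_cycles"],
            ae_profile=AEProfile(events),
            subsequent_proportion=float(econ["subsequent_proportion"]),
            subsequent_drug_cost_per_cycle=float(econ["subsequent_cost"]),
            subsequent_max_cycles=econ["subsequent_max_cycles"],
            bsc_cost_per_cycle=float(econ["bsc_cost"]),
            test_cost_in_pd=econ["test_cost_in_pd"],
        )

    def traces(self, overrides=None) -> Dict[str, CohortTrace]:
        """Cohort traces for both arms."""
        return {
            name: build_trace(self.arm_spec(name, overrides), self.model_config)
            for name in self.config["arms"]
        }

    # ------------------------------------------------------------ evaluation
    def evaluate(self, overrides=None) -> CEResult:
        """Deterministic model run; ``overrides`` maps parameter name -> value."""
        traces = self.traces(overrides)
        totals = {
            name: ArmTotals(name, *trace.totals()) for name, trace in traces.items()
        }
        return icer(
            totals[self.intervention_arm],
            totals[self.reference_arm],
            self.model_config.wtp_per_qaly,
        )

    def evaluate_batch(self, overrides: Dict[str, np.ndarray]) -> pd.DataFrame:
        """Vectorized evaluation over arrays of parameter values.

        All override arrays must share one length ``k``; omitted parameters
        stay at base.  Returns a DataFrame of ``k`` rows with per-arm totals
        and incrementals.  The reference-arm survival parameters are treated
        as fixed (their sampling uncertainty is not tabulated in the source).
        """
        if not overrides:
            raise ValueError("evaluate_batch needs at least one override array")
        k = len(next(iter(overrides.values())))
        unknown = set(overrides) - set(self._base)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        col = {
            name: np.broadcast_to(
                np.asarray(overrides.get(name, base), dtype=float), (k,)
            ).reshape(k, 1)
            for name, base in self._base.items()
        }

        out = {}
        for arm_name in (self.reference_arm, self.intervention_arm):
            if arm_name == self.reference_arm:
                pfs_b, os_b = self._ref_pfs_b, self._ref_os_b
            else:
                pfs_b = self._ref_pfs_b[None, :] ** col["hr_pfs"]
                os_b = self._ref_os_b[None, :] ** col["hr_os"]
            econ = self._arm_economics(arm_name, col)
            cost, ly, qaly = partition_totals(
                pfs_b,
                os_b,
                self.model_config,
                u_pfd=col["utility_pfd"],
                u_pd=col["utility_pd"],
                drug_cost=econ["drug_cost"],
                test_cost=econ["test_cost"],
                max_treatment_cycles=econ["max_treatment_cycles"],
                subsequent_proportion=econ["subsequent_proportion"],
                subsequent_cost=econ["subsequent_cost"],
                subsequent_max_cycles=econ["subsequent_max_cycles"],
                bsc_cost=econ["bsc_cost"],
                ae_cost=econ["ae_cost"],
                ae_qaly_loss=econ["ae_qaly_loss"],
                test_cost_in_pd=econ["test_cost_in_pd"],
            )
            out[arm_name] = (
                np.broadcast_to(cost, (k,)),
                np.broadcast_to(ly, (k,)),
                np.broadcast_to(qaly, (k,)),
            )

        ref, inter = out[self.reference_arm], out[self.intervention_arm]
        return pd.DataFrame(
            {
                "cost_comparator": ref[0],
                "ly_comparator": ref[1],
                "qaly_comparator": ref[2],
                "cost_intervention": inter[0],
                "ly_intervention": inter[1],
                "qaly_intervention": inter[2],
                "delta_cost": inter[0] - ref[0],
                "delta_ly": inter[1] - ref[1],
                "delta_qaly": inter[2] - ref[2],
            }
        )
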