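"""JSON run configuration: schema validation, builders and packaged scenarios.

A run config is a plain JSON object with blocks ``space``, ``mating``,
``kernel``, ``demography``, ``initial`` and ``run`` plus a ``mode`` selecting
the computation (ibm | macro | normalized | stationary | meanfield).  Unknown
keys are rejected before any computation.  ``expand_scenario`` produces the
packaged example setups as complete configs that can be overridden key by key.
"""

from __future__ import annotations

import copy
import json
import math
from typing import Optional

import numpy as np

from . import kernels as K
from .ibm import DemographyParams
from .mating import MatingModel, gaussian_pref, triangular_pref
from .measures import AtomicMeasure, GridDensity, TraitSpace

MODES = ("ibm", "macro", "normalized", "stationary", "meanfield")

_TOP_KEYS = {"scenario", "mode", "space", "mating", "kernel", "demography",
             "initial", "run", "stationary", "log_level"}
_BLOCK_KEYS = {
    "space": {"lower", "upper"},
    "mating": {"variant", "p", "a", "selfing"},
    "kernel": {"family", "noise"},
    "noise": {"shape", "sigma", "halfwidth", "values", "densities"},
    "demography": {"D", "I", "U", "exclude_self_competition"},
    "initial": {"kind", "locations", "weights", "n", "lower", "upper",
                "ncells", "shape", "mean", "sd", "mass", "rate"},
    "run": {"T", "dt", "N", "seed", "snapshots", "Ns", "replicates", "duhamel",
            "compress_cells", "order"},
    "stationary": {"method", "depth", "nsamples", "tol", "max_iter", "q",
                   "lower", "upper", "ncells"},
    "fn": {"kind", "value", "expr", "scale", "eps"},
}


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


def validate_config(cfg: dict) -> dict:
    """Schema-check a raw config dict and fill defaults; returns a copy."""
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a JSON object")
    _check_keys(cfg, _TOP_KEYS, "top level")
    cfg = copy.deepcopy(cfg)
    if "scenario" in cfg:
        base = expand_scenario(cfg.pop("scenario"))
        for key, val in cfg.items():
            if isinstance(val, dict) and isinstance(base.get(key), dict):
                base[key].update(val)
            else:
                base[key] = val
        cfg = base
    mode = cfg.get("mode")
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
    for name in ("space", "mating", "kernel", "demography", "initial", "run",
                 "stationary"):
        block = cfg.get(name)
        if block is None:
            continue
        _check_keys(block, _BLOCK_KEYS.get(name, set()), name)
        if name == "kernel" and "noise" in block and block["noise"] is not None:
            _check_keys(block["noise"], _BLOCK_KEYS["noise"], "kernel.noise")
        if name == "mating":
            for fn_key in ("p", "a"):
                v = block.get(fn_key)
                if isinstance(v, dict):
                    _check_keys(v, _BLOCK_KEYS["fn"], f"mating.{fn_key}")
    run = cfg.setdefault("run", {})
    run.setdefault("seed", 0)
    run.setdefault("N", 1)
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(json.load(fh))


# --- builders ---------------------------------------------------------------

def build_space(block: Optional[dict]) -> TraitSpace:
    block = block or {}
    lo = block.get("lower")
    hi = block.get("upper")
    return TraitSpace(-math.inf if lo is None else float(lo),
                      math.inf if hi is None else float(hi))


def _build_fn(spec, default=1.0):
    if spec is None:
        return default
    if isinstance(spec, (int, float)):
        return float(spec)
    kind = spec.get("kind", "const")
    if kind == "const":
        return float(spec.get("value", default))
    if kind == "expr":
        expr = spec["expr"]
        return lambda x, _e=expr: eval(_e, {"__builtins__": {}},
                                       {"x": x, "np": np})
    if kind == "gaussian_pref":
        return gaussian_pref(spec.get("scale", 1.0))
    if kind == "triangular":
        return triangular_pref(spec.get("scale", 1.0), spec.get("eps", 1e-3))
    raise ConfigError(f"unknown function kind {kind!r}")


def build_mating(block: Optional[dict]) -> MatingModel:
    block = block or {}
    return MatingModel(variant=block.get("variant", "semi_random"),
                       p=_build_fn(block.get("p"), 1.0),
                       a=_build_fn(block.get("a"), 1.0),
                       selfing=bool(block.get("selfing", True)))


def build_noise(block: Optional[dict]) -> K.NoiseSpec:
    block = block or {"shape": "normal", "sigma": 1.0}
    shape = block.get("shape", "normal")
    if shape == "normal":
        return K.normal_noise(block.get("sigma", 1.0))
    if shape == "uniform01":
        return K.uniform01_noise()
    if shape == "uniform_sym":
        return K.uniform_sym_noise(block.get("halfwidth", 1.0))
    if shape == "table":
        return K.table_noise(block["values"], block["densities"])
    raise ConfigError(f"unknown noise shape {shape!r}")


def build_kernel(block: Optional[dict], space: TraitSpace) -> K.OffspringKernel:
    block = block or {"family": "midpoint"}
    family = block.get("family", "midpoint")
    if family == "midpoint":
        return K.make_midpoint(space)
    noise = build_noise(block.get("noise"))
    if family == "additive":
        return K.make_additive(noise, space)
    if family == "multiplicative":
        return K.make_multiplicative(noise)
    if family == "interpolation":
        return K.make_interpolation(noise)
    raise ConfigError(f"unknown kernel family {family!r}")


def build_demography(block: Optional[dict]) -> DemographyParams:
    block = block or {}
    return DemographyParams(
        D=_build_fn(block.get("D"), 0.0),
        I=_build_fn(block.get("I"), 0.0),
        U=_build_fn(block.get("U"), 0.0),
        exclude_self_competition=bool(block.get("exclude_self_competition",
                                                False)))


def build_initial(block: dict, space: TraitSpace):
    """Initial state: atoms (AtomicMeasure) or grid density (GridDensity)."""
    kind = block.get("kind", "atoms")
    if kind == "atoms":
        locs = np.asarray(block["locations"], dtype=float)
        w = np.asarray(block.get("weights", np.ones_like(locs)), dtype=float)
        return AtomicMeasure(locs, w, space)
    if kind == "uniform_atoms":
        n = int(block["n"])
        lo, hi = float(block["lower"]), float(block["upper"])
        locs = np.linspace(lo, hi, n)
        return AtomicMeasure(locs, np.full(n, block.get("mass", 1.0) / n), space)
    if kind == "grid":
        lo, hi = float(block["lower"]), float(block["upper"])
        ncells = int(block.get("ncells", 512))
        shape = block.get("shape", "normal")
        if shape == "normal":
            m, sd = block.get("mean", 0.0), block.get("sd", 1.0)
            fn = lambda z: np.exp(-0.5 * ((z - m) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
        elif shape == "uniform":
            fn = lambda z: np.ones_like(z)
        elif shape == "exponential":
            rate = block.get("rate", 1.0)
            fn = lambda z: np.where(z >= 0, rate * np.exp(-rate * z), 0.0)
        else:
            raise ConfigError(f"unknown initial shape {shape!r}")
        g = GridDensity.from_function(fn, lo, hi, ncells, space, normalize=True)
        from .measures import rescale_to_mass
        return rescale_to_mass(g, float(block.get("mass", 1.0)))
    raise ConfigError(f"unknown initial kind {kind!r}")


# --- packaged scenarios ------------------------------------------------------

SCENARIOS = ("example1_interpolation", "example2_additive_gaussian",
             "example3_tjonwu", "logistic_mass", "assortative_normalized",
             "meanfield_ladder")


def expand_scenario(name: str) -> dict:
    """Complete run config for a packaged example setup."""
    if name == "example1_interpolation":
        # offspring interpolated between parents, Z ~ Uniform(-1, 1);
        # normalized flow from 64 atoms on [0, 1]: variance decays at rate
        # (1 - Var Z)/2 = 1/3 and the profile collapses to the mean
        return {
            "mode": "normalized",
            "space": {"lower": None, "upper": None},
            "mating": {"variant": "semi_random", "p": 1.0, "selfing": True},
            "kernel": {"family": "interpolation",
                       "noise": {"shape": "uniform_sym", "halfwidth": 1.0}},
            "initial": {"kind": "uniform_atoms", "n": 64, "lower": 0.0,
                        "upper": 1.0, "mass": 1.0},
            "run": {"T": 4.0, "dt": 0.01, "seed": 0, "N": 1,
                    "compress_cells": 512, "order": 8},
        }
    if name == "example2_additive_gaussian":
        # additive Gaussian noise on F = R: stationary law Normal(q, 2 sigma^2)
        return {
            "mode": "stationary",
            "space": {"lower": None, "upper": None},
            "mating": {"variant": "semi_random", "p": 1.0, "selfing": True},
            "kernel": {"family": "additive",
                       "noise": {"shape": "normal", "sigma": 1.0}},
            "initial": {"kind": "grid", "lower": -10.0, "upper": 10.0,
                        "ncells": 4096, "shape": "normal", "mean": 0.0,
                        "sd": 1.0, "mass": 1.0},
            "stationary": {"method": "series", "depth": 20,
                           "nsamples": 200000, "lower": -10.0, "upper": 10.0,
                           "ncells": 4096},
            "run": {"seed": 0, "N": 1},
        }
    if name == "example3_tjonwu":
        # multiplicative kernel with h = 1_[0,1]: the Tjon--Wu equation;
        # equilibrium Exp(1/q) with q = 1
        return {
            "mode": "stationary",
            "space": {"lower": 0.0, "upper": None},
            "mating": {"variant": "semi_random", "p": 1.0, "selfing": True},
            "kernel": {"family": "multiplicative",
                       "noise": {"shape": "uniform01"}},
            "initial": {"kind": "grid", "lower": 0.0, "upper": 15.0,
                        "ncells": 2048, "shape": "exponential", "rate": 1.0,
                        "mass": 1.0},
            "stationary": {"method": "tjon-wu", "q": 1.0, "lower": 0.0,
                           "upper": 15.0, "ncells": 2048, "tol": 1e-3,
                           "max_iter": 200},
            "run": {"seed": 0, "N": 1},
        }
    if name == "logistic_mass":
        # constant rates p=2, D=1, I=U=1: carrying capacity Mbar = 1
        return {
            "mode": "macro",
            "space": {"lower": None, "upper": None},
            "mating": {"variant": "semi_random", "p": 2.0, "selfing": True},
            "kernel": {"family": "additive",
                       "noise": {"shape": "normal", "sigma": 0.5}},
            "demography": {"D": 1.0, "I": 1.0, "U": 1.0},
            "initial": {"kind": "grid", "lower": -8.0, "upper": 8.0,
                        "ncells": 512, "shape": "normal", "mean": 0.0,
                        "sd": 1.0, "mass": 0.1},
            "run": {"T": 10.0, "dt": 0.001, "seed": 0, "N": 1},
        }
    if name == "assortative_normalized":
        # symmetric row-sum-one assortative mating via the Fredholm
        # normalization; the solver runs it, no stability is claimed
        return {
            "mode": "normalized",
            "space": {"lower": None, "upper": None},
            "mating": {"variant": "assortative_normalized",
                       "a": {"kind": "gaussian_pref", "scale": 1.0},
                       "selfing": True},
            "kernel": {"family": "interpolation",
                       "noise": {"shape": "uniform_sym", "halfwidth": 1.0}},
            "initial": {"kind": "uniform_atoms", "n": 32, "lower": 0.0,
                        "upper": 1.0, "mass": 1.0},
            "run": {"T": 2.0, "dt": 0.02, "seed": 0, "N": 1,
                    "compress_cells": 128, "order": 6},
        }
    if name == "meanfield_ladder":
        # scaled process at N = 50, 200, 800 against the mean-field density
        return {
            "mode": "meanfield",
            "space": {"lower": None, "upper": None},
            "mating": {"variant": "semi_random", "p": 1.0, "selfing": True},
            "kernel": {"family": "additive",
                       "noise": {"shape": "normal", "sigma": 0.5}},
            "demography": {"D": 0.5, "I": 1.0, "U": 1.0},
            "initial": {"kind": "grid", "lower": -8.0, "upper": 8.0,
                        "ncells": 512, "shape": "normal", "mean": 0.0,
                        "sd": 1.0, "mass": 1.0},
            "run": {"T": 3.0, "dt": 0.002, "seed": 0, "N": 1,
                    "Ns": [50, 200, 800], "replicates": 6},
        }
    raise ConfigError(f"unknown scenario {name!r}; available: {SCENARIOS}")
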