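"""Model-specification files.

A specification is a YAML (or JSON) mapping with blocks ``infectiousness``,
``susceptibility``, ``vaccination``, ``initial`` and optionally ``numerics``,
``r0`` and the multigroup extension ``groups`` + (``alpha`` | ``gamma``).
Unknown keys are rejected.  Example::

    infectiousness:
      family: constant
      beta: 0.5
      duration: {family: exponential, rate: 0.25}
    susceptibility:
      kind: step
      recovery: {family: exponential, rate: 0.1}
    vaccination: {family: gamma, shape: 4, scale: 5}
    initial:
      i0: 0.1
      h_i: {family: stationary}    # stationary age of the T_I renewal
      h_s: {family: stationary}    # stationary age of the T_V renewal
    r0: 2.5                        # optional: rescale beta to match
    numerics: {dt: 0.02, t_max: 150, k_sigma: 16, seed: 1}
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import yaml

from . import kernels
from .kernels import AgeDensity, DurationLaw, ModelSpec
from .multigroup import GroupModel, two_group_contact_matrix

__all__ = ["load_model", "parse_model", "parse_duration", "ConfigError"]


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, where: str):
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {where} "
                          f"(allowed: {sorted(allowed)})")


_DURATION_FIELDS = {
    "exponential": {"rate"},
    "gamma": {"shape", "scale", "shift"},
    "uniform": {"low", "high"},
    "point_mass": {"value"},
    "two_point": {"low", "high", "p_low"},
    "never": set(),
}


def parse_duration(block: dict, where: str = "duration") -> DurationLaw:
    if not isinstance(block, dict) or "family" not in block:
        raise ConfigError(f"{where} must be a mapping with a 'family' key")
    fam = block["family"]
    if fam not in _DURATION_FIELDS:
        raise ConfigError(f"unknown duration family {fam!r} in {where}")
    _check_keys(block, _DURATION_FIELDS[fam] | {"family"}, where)
    kw = {k: v for k, v in block.items() if k != "family"}
    factory = {"exponential": kernels.exponential, "gamma": kernels.gamma_law,
               "uniform": kernels.uniform_law, "point_mass": kernels.fixed,
               "two_point": kernels.two_point, "never": kernels.never}[fam]
    try:
        return factory(**kw)
    except TypeError as e:
        raise ConfigError(f"bad parameters for {fam} in {where}: {e}") from e


def _parse_infectiousness(block: dict) -> kernels.InfectiousnessLaw:
    _check_keys(block, {"family", "beta", "duration"}, "infectiousness")
    fam = block.get("family", "constant")
    if fam != "constant":
        raise ConfigError("only the 'constant' infectiousness family is "
                          "configurable from files; build 'profile' laws "
                          "programmatically")
    dur = parse_duration(block["duration"], "infectiousness.duration")
    return kernels.constant_infectiousness(float(block.get("beta", 1.0)), dur)


def _parse_susceptibility(block: dict) -> kernels.SusceptibilityLaw:
    kind = block.get("kind")
    if kind == "step":
        _check_keys(block, {"kind", "recovery"}, "susceptibility")
        return kernels.step_sigma(parse_duration(block["recovery"],
                                                 "susceptibility.recovery"))
    if kind == "deterministic":
        _check_keys(block, {"kind", "family", "shape", "scale", "value"},
                    "susceptibility")
        fam = block.get("family", "gamma_cdf")
        if fam == "gamma_cdf":
            return kernels.gamma_cdf_sigma(float(block["shape"]),
                                           float(block["scale"]))
        if fam == "constant":
            return kernels.constant_sigma(float(block.get("value", 1.0)))
        raise ConfigError(f"unknown deterministic susceptibility family {fam!r}")
    if kind == "panel":
        _check_keys(block, {"kind", "k", "seed", "shape_range", "scale_range"},
                    "susceptibility")
        kw = {}
        if "k" in block:
            kw["k"] = int(block["k"])
        if "seed" in block:
            kw["seed"] = int(block["seed"])
        for key in ("shape_range", "scale_range"):
            if key in block:
                kw[key] = tuple(block[key])
        return kernels.panel_sigma(**kw)
    raise ConfigError("susceptibility.kind must be one of "
                      "'deterministic', 'step', 'panel'")


def _parse_age_density(block, ref_law: DurationLaw, where: str) -> AgeDensity:
    if block is None or (isinstance(block, dict)
                         and block.get("family") == "stationary"):
        if ref_law.is_infinite:
            raise ConfigError(f"{where}: stationary age density undefined for "
                              "the 'never' law; give an explicit density")
        return AgeDensity.stationary(ref_law)
    return AgeDensity.from_law(parse_duration(block, where))


_TOP_KEYS = {"infectiousness", "susceptibility", "vaccination", "initial",
             "numerics", "r0", "groups", "alpha", "gamma"}
_NUMERIC_KEYS = {"dt", "t_max", "k_sigma", "n_init", "seed", "grid_dt",
                 "mass_tol"}


def parse_model(doc: dict) -> Tuple[ModelSpec, dict, Optional[GroupModel]]:
    """Parse a configuration mapping into (ModelSpec, numerics, GroupModel?)."""
    if not isinstance(doc, dict):
        raise ConfigError("the configuration must be a mapping")
    _check_keys(doc, _TOP_KEYS, "top level")
    for required in ("infectiousness", "susceptibility", "vaccination",
                     "initial"):
        if required not in doc:
            raise ConfigError(f"missing required block {required!r}")
    inf = _parse_infectiousness(doc["infectiousness"])
    sus = _parse_susceptibility(doc["susceptibility"])
    vac = parse_duration(doc["vaccination"], "vaccination")

    init = doc["initial"]
    _check_keys(init, {"i0", "h_i", "h_s"}, "initial")
    i0 = float(init["i0"])
    h_i = _parse_age_density(init.get("h_i"), inf.duration, "initial.h_i")
    h_s = _parse_age_density(init.get("h_s"), vac, "initial.h_s")

    spec = ModelSpec(infectiousness=inf, susceptibility=sus, vaccination=vac,
                     i0=i0, h_i=h_i, h_s=h_s)
    if "r0" in doc:
        spec = spec.with_r0(float(doc["r0"]))

    numerics = dict(doc.get("numerics") or {})
    _check_keys(numerics, _NUMERIC_KEYS, "numerics")

    gm = None
    if "groups" in doc:
        groups = doc["groups"]
        p = []
        vaccs = []
        for gidx, g in enumerate(groups):
            _check_keys(g, {"p", "vaccination"}, f"groups[{gidx}]")
            p.append(float(g["p"]))
            vaccs.append(parse_duration(g["vaccination"],
                                        f"groups[{gidx}].vaccination"))
        if "gamma" in doc:
            gamma = np.asarray(doc["gamma"], float)
        elif "alpha" in doc:
            if len(p) != 2:
                raise ConfigError("'alpha' parametrization requires exactly "
                                  "two groups")
            gamma = two_group_contact_matrix(p[0], float(doc["alpha"]))
        else:
            raise ConfigError("multigroup configs need 'alpha' or 'gamma'")
        gm = GroupModel(p=p, gamma=gamma, vaccinations=vaccs,
                        infectiousness=spec.infectiousness,
                        susceptibility=sus)
    elif "alpha" in doc or "gamma" in doc:
        raise ConfigError("'alpha'/'gamma' given without a 'groups' block")
    return spec, numerics, gm


def load_model(path: str) -> Tuple[ModelSpec, dict, Optional[GroupModel]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_model(doc)
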