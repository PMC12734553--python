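"""JSON run configurations, fixture generation, and tabular output writers."""

from __future__ import annotations

import json
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditions import InitialCondition, make_ic
from .core import TwoCompartmentParams
from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "make_fixtures", "write_outputs"]

_PARAM_KEYS = {"mE", "mI", "KEI", "KIE", "N", "M"}
_SOLVER_DEFAULTS = {"rtol": 1e-8, "atol": None, "grid": 200, "epsilon": 1e-12}
_TOP_KEYS = {"params", "ic", "times", "time_unit", "solver", "out_dir", "seed"}


@dataclass
class RunConfig:
    """Validated run configuration (see ``make_fixtures`` for examples)."""

    params: TwoCompartmentParams
    ic: InitialCondition | None
    times: list[float]
    time_unit: str = "tau"  # "tau" or "absolute"
    solver: dict = field(default_factory=lambda: dict(_SOLVER_DEFAULTS))
    out_dir: str | None = None
    seed: int = 0

    def absolute_times(self) -> np.ndarray:
        t = np.asarray(self.times, dtype=float)
        if self.time_unit == "tau":
            return t * self.params.tau
        return t

    def to_dict(self) -> dict:
        p = self.params
        d = {
            "params": {
                "mE": "inf" if math.isinf(p.mE) else int(p.mE),
                "mI": "inf" if math.isinf(p.mI) else int(p.mI),
                "KEI": p.KEI,
                "KIE": p.KIE,
                "N": int(p.N),
                "M": p.M,
            },
            "times": list(self.times),
            "time_unit": self.time_unit,
            "solver": self.solver,
            "seed": self.seed,
        }
        if self.ic is not None:
            tag = {
                "DeltaIC": "delta",
                "GaussianIC": "gaussian",
                "MixtureIC": "mixture",
                "ProductBinomialIC": "product_binomial",
            }[type(self.ic).__name__]
            icd = {"tag": tag}
            icd.update({k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self.ic).items()})
            d["ic"] = icd
        if self.out_dir is not None:
            d["out_dir"] = self.out_dir
        return d


def _parse(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a JSON object")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "params" not in raw:
        raise ConfigError("missing required block 'params'")
    pblock = raw["params"]
    if not isinstance(pblock, dict):
        raise ConfigError("'params' must be an object")
    missing = _PARAM_KEYS - set(pblock)
    if missing:
        raise ConfigError(f"missing parameter keys: {sorted(missing)}")
    unknown = set(pblock) - _PARAM_KEYS
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")

    def site(v):
        return math.inf if v == "inf" else v

    try:
        params = TwoCompartmentParams(
            mE=site(pblock["mE"]),
            mI=site(pblock["mI"]),
            KEI=float(pblock["KEI"]),
            KIE=float(pblock["KIE"]),
            N=int(pblock["N"]),
            M=float(pblock["M"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid params block: {exc}") from exc

    ic = None
    if "ic" in raw:
        icb = dict(raw["ic"])
        if "tag" not in icb:
            raise ConfigError("'ic' block needs a 'tag' key")
        tag = icb.pop("tag")
        try:
            ic = make_ic(tag, **icb)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid ic block: {exc}") from exc

    times = raw.get("times", [0.0])
    if not isinstance(times, list) or not all(isinstance(t, (int, float)) for t in times):
        raise ConfigError("'times' must be a list of numbers")
    time_unit = raw.get("time_unit", "tau")
    if time_unit not in ("tau", "absolute"):
        raise ConfigError("'time_unit' must be 'tau' or 'absolute'")

    solver = dict(_SOLVER_DEFAULTS)
    sblock = raw.get("solver", {})
    unknown = set(sblock) - set(_SOLVER_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown solver keys: {sorted(unknown)}")
    solver.update(sblock)

    return RunConfig(
        params=params,
        ic=ic,
        times=[float(t) for t in times],
        time_unit=time_unit,
        solver=solver,
        out_dir=raw.get("out_dir"),
        seed=int(raw.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
    return _parse(raw)


def make_fixtures(out_dir) -> list[Path]:
    """Write ready-to-run configs for all standard setups; return the paths."""
    from .examples import FIGURE_TIMES_TAU, figure3_master_setup

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    times = [t for t in FIGURE_TIMES_TAU if math.isfinite(t)]
    written = []

    def dump(name, cfg: RunConfig):
        p = out / f"{name}.json"
        with open(p, "w") as fh:
            json.dump(cfg.to_dict(), fh, indent=2)
            fh.write("\n")
        written.append(p)

    # delta start, continuum-only
    params1 = TwoCompartmentParams(mE=math.inf, mI=math.inf, KEI=1 / 3, KIE=2 / 3, N=100, M=10_000)
    from .examples import example1_ic

    dump("example1", RunConfig(params1, example1_ic(params1), times))

    for scale, name in ((0.1, "fig3_scale01"), (0.2, "fig3_scale02"), (1.0, "fig3_scale1")):
        params, ic = figure3_master_setup(scale)
        dump(name, RunConfig(params, ic, times))

    from .examples import example2_params, example3_ic

    pcont = example2_params()
    for kind, name in (("fig4-left", "fig4_left"), ("fig4-right", "fig4_right")):
        dump(name, RunConfig(pcont, example3_ic(kind, pcont), times))

    # small grid matching the three-carrier schematic (mE=8, mI=5)
    psmall = TwoCompartmentParams(mE=8, mI=5, KEI=1.0, KIE=1.0, N=100, M=300)
    dump(
        "small_grid",
        RunConfig(psmall, make_ic("product_binomial", p0=1 / 8, q0=2 / 5), [0.0, 1.0, 5.0]),
    )
    return written


def write_outputs(results: dict, out_dir, config: RunConfig | None = None) -> list[Path]:
    """Write result tables/grids as CSV plus a JSON provenance record.

    ``results`` maps names to pandas DataFrames (written as ``<name>.csv``)
    or numpy arrays (written in long format).  Output is bit-stable across
    reruns for deterministic solvers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        p = out / f"{name}.csv"
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(p, index=False)
        elif isinstance(obj, np.ndarray) and obj.ndim == 2:
            ii, nn = np.nonzero(np.ones_like(obj))
            pd.DataFrame({"i": ii, "n": nn, "y": obj.ravel()}).to_csv(p, index=False)
        else:
            raise ConfigError(f"cannot serialize result {name!r} of type {type(obj).__name__}")
        written.append(p)
    prov = {
        "package": "flipkin",
        "version": __version__,
        "python": sys.version.split()[0],
    }
    if config is not None:
        prov["config"] = config.to_dict()
    p = out / "provenance.json"
    with open(p, "w") as fh:
        json.dump(prov, fh, indent=2)
        fh.write("\n")
    written.append(p)
    return written
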