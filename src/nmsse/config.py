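"""Plain-text (YAML) run configuration, validation and fixture generation.

Every other module is exercisable from a config file without external
data.  Energies may be given in eV or cm^-1: each section takes a
``units`` key ("eV" default), and any single energy may override it with a
``{value: ..., units: ...}`` mapping — the canonical simulation parameters
mix both conventions (band centres in cm^-1, linewidths in eV).  Unknown
keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .integrator import IntegratorConfig
from .kernels import (
    MarkDistribution,
    PoissonBathSpec,
    SpectralDensitySpec,
    ThermalSpec,
    gaussian_kernel,
)
from .model import DimerSpec, ModelSpec, VibronicSpec, wavenumber_to_ev

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config", "generate_fixtures"]

#: Canonical simulation parameters: energy bias and band centres in cm^-1
#: (eps = 1199.4 cm^-1 ~ 0.1487 eV), linewidth and thermal energy in eV.
TABLE1_MODE_FREQS_CM = (836.0, 1000.0, 1240.0, 1600.0)
TABLE1_EPSILON_EV = 0.1487
TABLE1_LINEWIDTH_EV = 0.005
TABLE1_KBT_EV = 0.025
TABLE1_DELTA_GRID_EV = (1e-4, 1e-3, 1e-2, 1e-1)


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run description (all energies normalized to eV)."""

    model: ModelSpec
    bath_kind: str  # "gaussian" | "poisson" | "none"
    thermal: ThermalSpec
    integrator: IntegratorConfig
    n_traj: int
    master_seed: int
    gaussian_bath: Optional[SpectralDensitySpec] = None
    poisson_bath: Optional[PoissonBathSpec] = None
    t_max: Optional[float] = None
    n_periods: float = 10.0
    kernel_form: str = "full_coth"
    with_kicks: bool = True
    kick_scale: Optional[float] = None  # None: gamma_nj-scaled kick angles
    output_dir: str = "out"

    @property
    def bath(self):
        if self.bath_kind == "gaussian":
            return self.gaussian_bath
        if self.bath_kind == "poisson":
            return self.poisson_bath
        return None

    def spec_hash(self) -> str:
        """Stable hash of the normalized configuration (for run logs)."""
        payload = json.dumps(_normalize(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_keys(section: str, data: dict, allowed: set) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{section}'")


def _energy(value, default_units: str, *, key: str) -> float:
    """Normalize one energy entry to eV."""
    units = default_units
    if isinstance(value, dict):
        _check_keys(key, value, {"value", "units"})
        if "value" not in value or "units" not in value:
            raise ConfigError(f"'{key}': inline unit override needs both 'value' and 'units'")
        units, value = value["units"], value["value"]
    if units not in ("eV", "cm-1"):
        raise ConfigError(f"'{key}': unknown units {units!r} (use 'eV' or 'cm-1')")
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"'{key}': not a number: {value!r}") from exc
    return wavenumber_to_ev(value) if units == "cm-1" else value


def _parse_model(data: dict) -> ModelSpec:
    _check_keys(
        "model",
        data,
        {"units", "epsilon", "delta", "gamma_nj", "negate_epsilon", "vibronic"},
    )
    units = data.get("units", "eV")
    for req in ("epsilon", "delta"):
        if req not in data:
            raise ConfigError(f"section 'model' is missing required key '{req}'")
    eps = _energy(data["epsilon"], units, key="model.epsilon")
    if data.get("negate_epsilon", False):
        eps = -eps
    delta = _energy(data["delta"], units, key="model.delta")
    vib = None
    if data.get("vibronic") is not None:
        vd = data["vibronic"]
        _check_keys("model.vibronic", vd, {"units", "omega", "coupling", "fock_cutoff"})
        vib = VibronicSpec(
            omega=_energy(vd["omega"], vd.get("units", units), key="model.vibronic.omega"),
            coupling=float(vd.get("coupling", 0.0)),
            fock_cutoff=int(vd.get("fock_cutoff", 10)),
        )
    return ModelSpec(
        dimer=DimerSpec(epsilon=eps, delta=delta),
        vibronic=vib,
        gamma_nj=float(data.get("gamma_nj", 0.0)),
    )


def _parse_bath(data: dict):
    _check_keys(
        "bath",
        data,
        {
            "kind",
            "units",
            "mode_freqs",
            "coupling",
            "linewidth",
            "rate",
            "filter_kappa",
            "filter_omega",
            "amplitude",
            "marks",
        },
    )
    if "kind" not in data:
        raise ConfigError("section 'bath' is missing required key 'kind'")
    kind = data["kind"]
    units = data.get("units", "eV")
    if kind == "none":
        return kind, None, None
    if kind == "gaussian":
        spec = SpectralDensitySpec(
            mode_freqs=[
                _energy(w, units, key="bath.mode_freqs") for w in data["mode_freqs"]
            ],
            gamma=_energy(data["coupling"], units, key="bath.coupling"),
            linewidth=_energy(data["linewidth"], units, key="bath.linewidth"),
        )
        return kind, spec, None
    if kind == "poisson":
        marks = MarkDistribution()
        if "marks" in data:
            md = data["marks"]
            _check_keys("bath.marks", md, {"family", "scale"})
            marks = MarkDistribution(
                family=md.get("family", "two_point"), scale=float(md.get("scale", 1.0))
            )
        amp = data.get("amplitude")
        spec = PoissonBathSpec(
            rate=float(data["rate"]),
            marks=marks,
            filter_kappa=_energy(data["filter_kappa"], units, key="bath.filter_kappa"),
            filter_omega=_energy(data.get("filter_omega", 0.0), units, key="bath.filter_omega"),
            amplitude=float(amp) if amp is not None else None,
        )
        return kind, None, spec
    raise ConfigError(f"unknown bath kind {kind!r}")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; energies are
    normalized to eV internally."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(
        "<root>", raw, {"model", "bath", "thermal", "integrator", "ensemble", "run", "output"}
    )
    for req in ("model", "bath"):
        if req not in raw:
            raise ConfigError(f"missing required section '{req}'")

    model = _parse_model(raw["model"])
    bath_kind, gauss, poisson = _parse_bath(raw["bath"])

    th = raw.get("thermal", {"kbt": 0.0})
    _check_keys("thermal", th, {"units", "kbt"})
    thermal = ThermalSpec(kbt=_energy(th.get("kbt", 0.0), th.get("units", "eV"), key="thermal.kbt"))
    if bath_kind == "gaussian" and "thermal" not in raw:
        raise ConfigError("a gaussian bath requires a 'thermal' section")

    integ = raw.get("integrator", {})
    _check_keys(
        "integrator",
        integ,
        {"dt", "scheme", "renormalize_every", "include_g2", "g1_bracket_factor", "enforce_step_limit"},
    )
    config = IntegratorConfig(
        dt=float(integ.get("dt", 0.25)),
        scheme=integ.get("scheme", "heun"),
        renormalize_every=int(integ.get("renormalize_every", 1)),
        include_g2=bool(integ.get("include_g2", False)),
        g1_bracket_factor=float(integ.get("g1_bracket_factor", 2.0)),
        enforce_step_limit=bool(integ.get("enforce_step_limit", True)),
    )

    ens = raw.get("ensemble", {})
    _check_keys("ensemble", ens, {"n_traj", "master_seed"})
    run = raw.get("run", {})
    _check_keys("run", run, {"t_max", "n_periods", "kernel_form", "with_kicks", "kick_scale"})
    out = raw.get("output", {})
    _check_keys("output", out, {"directory"})

    return RunConfig(
        model=model,
        bath_kind=bath_kind,
        gaussian_bath=gauss,
        poisson_bath=poisson,
        thermal=thermal,
        integrator=config,
        n_traj=int(ens.get("n_traj", 2000)),
        master_seed=int(ens.get("master_seed", 0)),
        t_max=float(run["t_max"]) if "t_max" in run else None,
        n_periods=float(run.get("n_periods", 10.0)),
        kernel_form=run.get("kernel_form", "full_coth"),
        with_kicks=bool(run.get("with_kicks", True)),
        kick_scale=float(run["kick_scale"]) if run.get("kick_scale") is not None else None,
        output_dir=str(out.get("directory", "out")),
    )


def _normalize(cfg: RunConfig) -> dict:
    """Canonical eV-normalized mapping of a RunConfig (round-trip form)."""
    model: dict = {
        "units": "eV",
        "epsilon": cfg.model.dimer.epsilon,
        "delta": cfg.model.dimer.delta,
        "gamma_nj": cfg.model.gamma_nj,
    }
    if cfg.model.vibronic is not None:
        v = cfg.model.vibronic
        model["vibronic"] = {
            "units": "eV",
            "omega": v.omega,
            "coupling": v.coupling,
            "fock_cutoff": v.fock_cutoff,
        }
    bath: dict = {"kind": cfg.bath_kind, "units": "eV"}
    if cfg.bath_kind == "gaussian":
        b = cfg.gaussian_bath
        bath.update(
            mode_freqs=list(b.mode_freqs), coupling=b.gamma, linewidth=b.linewidth
        )
    elif cfg.bath_kind == "poisson":
        p = cfg.poisson_bath
        bath.update(
            rate=p.rate,
            filter_kappa=p.filter_kappa,
            filter_omega=p.filter_omega,
            marks={"family": p.marks.family, "scale": p.marks.scale},
        )
        if p.amplitude is not None:
            bath["amplitude"] = p.amplitude
    doc = {
        "model": model,
        "bath": bath,
        "thermal": {"units": "eV", "kbt": cfg.thermal.kbt},
        "integrator": {
            "dt": cfg.integrator.dt,
            "scheme": cfg.integrator.scheme,
            "renormalize_every": cfg.integrator.renormalize_every,
            "include_g2": cfg.integrator.include_g2,
            "g1_bracket_factor": cfg.integrator.g1_bracket_factor,
            "enforce_step_limit": cfg.integrator.enforce_step_limit,
        },
        "ensemble": {"n_traj": cfg.n_traj, "master_seed": cfg.master_seed},
        "run": {
            "n_periods": cfg.n_periods,
            "kernel_form": cfg.kernel_form,
            "with_kicks": cfg.with_kicks,
        },
        "output": {"directory": cfg.output_dir},
    }
    if cfg.kick_scale is not None:
        doc["run"]["kick_scale"] = cfg.kick_scale
    if cfg.t_max is not None:
        doc["run"]["t_max"] = cfg.t_max
    return doc


def save_config(cfg: RunConfig, path) -> None:
    """Write the normalized (all-eV) form of a configuration."""
    with open(path, "w") as fh:
        yaml.safe_dump(_normalize(cfg), fh, sort_keys=False)


def _base_doc(delta_ev: float) -> dict:
    return {
        "model": {
            "units": "eV",
            "epsilon": TABLE1_EPSILON_EV,
            "delta": delta_ev,
            "gamma_nj": 0.02,
            "vibronic": {
                "units": "eV",
                "omega": TABLE1_EPSILON_EV,
                "coupling": 0.2,
                "fock_cutoff": 10,
            },
        },
        "thermal": {"units": "eV", "kbt": TABLE1_KBT_EV},
        "integrator": {"dt": 0.25, "scheme": "heun"},
        "ensemble": {"n_traj": 2000, "master_seed": 2026},
        "run": {"n_periods": 3.0},
        "output": {"directory": "out"},
    }


def generate_fixtures(kind: str, outdir) -> list[Path]:
    """Emit canonical config files; every fixture validates under
    :func:`load_config`.

    ``"table1"``: structured-Gaussian-bath runs over the canonical Delta
    grid; ``"lambda_scan"``: three variance-matched shot-noise runs at
    Lambda in {0.1, 1, 10} sharing alpha(0); ``"rabi"``: closed-dimer
    coherent-oscillation checks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    def _emit(name: str, doc: dict) -> None:
        p = outdir / name
        with open(p, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        paths.append(p)

    if kind == "table1":
        for delta in TABLE1_DELTA_GRID_EV:
            doc = _base_doc(delta)
            doc["bath"] = {
                "kind": "gaussian",
                "units": "cm-1",
                "mode_freqs": list(TABLE1_MODE_FREQS_CM),
                "coupling": {"value": 0.1, "units": "eV"},
                "linewidth": {"value": TABLE1_LINEWIDTH_EV, "units": "eV"},
            }
            _emit(f"table1_delta_{delta:g}.yaml", doc)
    elif kind == "lambda_scan":
        bath = SpectralDensitySpec(
            mode_freqs=[wavenumber_to_ev(w) for w in TABLE1_MODE_FREQS_CM],
            gamma=0.1,
            linewidth=TABLE1_LINEWIDTH_EV,
        )
        import numpy as np

        alpha0 = gaussian_kernel(
            np.array([0.0]), bath, ThermalSpec(TABLE1_KBT_EV)
        ).at_zero
        kappa = TABLE1_LINEWIDTH_EV
        for lam in (0.1, 1.0, 10.0):
            rate = lam * kappa
            doc = _base_doc(1e-3)
            doc["bath"] = {
                "kind": "poisson",
                "units": "eV",
                "rate": rate,
                "filter_kappa": kappa,
                "filter_omega": TABLE1_EPSILON_EV,
                "amplitude": alpha0,
                "marks": {
                    "family": "two_point",
                    "scale": float(np.sqrt(2.0 * kappa * alpha0 / rate)),
                },
            }
            _emit(f"lambda_scan_{lam:g}.yaml", doc)
    elif kind == "rabi":
        for eps, tag in ((0.0, "resonant"), (TABLE1_EPSILON_EV, "biased")):
            doc = _base_doc(1e-3)
            doc["model"]["epsilon"] = eps
            doc["model"]["gamma_nj"] = 0.0
            doc["model"]["vibronic"] = None
            doc["bath"] = {"kind": "none"}
            doc["ensemble"]["n_traj"] = 1
            _emit(f"rabi_{tag}.yaml", doc)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return paths
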