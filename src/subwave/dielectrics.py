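"""Frequency-dependent complex permittivity of the head-model materials.

All permittivities follow the engineering convention

    eps = eps' - j eps''        with time dependence  e^{+j omega t},

so a passive (lossy) material has ``eps'' >= 0``.  The equivalent ionic
conductivity is ``sigma = omega * eps0 * eps''`` (S/m).

Two closed-form dispersion models are provided:

* **Debye** -- single first-order relaxation, used for water (coupling bags),
* **Cole-Cole** -- up to four broadened relaxation terms, the standard
  parametric description of biological tissues (blood, gray matter, cortical
  bone, cerebrospinal fluid).

Spectra are always evaluated analytically on demand; no interpolation tables
are built, which keeps every module on exactly the same dielectric values
regardless of its frequency grid.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
C0 = 299792458.0  # speed of light, m/s

__all__ = [
    "EPS0",
    "C0",
    "DebyeParams",
    "ColeColeTerm",
    "ColeColeParams",
    "DielectricSpectrum",
    "MaterialSet",
    "debye_permittivity",
    "cole_cole_permittivity",
    "material_table",
    "default_material_models",
    "load_material_config",
    "export_spectra_csv",
    "WATER_DEBYE_25C",
    "TISSUE_COLE_COLE",
    "PORT_FILL_EPS",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DebyeParams:
    """Single-pole Debye relaxation: eps_inf + (eps_s - eps_inf)/(1 + j w tau)."""

    eps_static: float
    eps_inf: float
    tau: float  # relaxation time, s
    sigma_ionic: float = 0.0  # S/m

    def __post_init__(self) -> None:
        if not (self.eps_static >= self.eps_inf > 0):
            raise ValueError("require eps_static >= eps_inf > 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma_ionic < 0:
            raise ValueError("sigma_ionic must be non-negative")


@dataclass(frozen=True)
class ColeColeTerm:
    delta_eps: float
    tau: float  # s
    alpha: float = 0.0  # broadening exponent, 0 <= alpha < 1

    def __post_init__(self) -> None:
        if self.delta_eps < 0:
            raise ValueError("delta_eps must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")


@dataclass(frozen=True)
class ColeColeParams:
    """Multi-term Cole-Cole dispersion with ionic conductivity."""

    eps_inf: float
    terms: tuple[ColeColeTerm, ...]
    sigma_ionic: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_inf <= 0:
            raise ValueError("eps_inf must be positive")
        if len(self.terms) > 4:
            raise ValueError("at most 4 dispersion terms supported")
        if self.sigma_ionic < 0:
            raise ValueError("sigma_ionic must be non-negative")


# --------------------------------------------------------------------------
# closed forms
# --------------------------------------------------------------------------

def _check_frequency(frequency) -> np.ndarray:
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    return f


def debye_permittivity(frequency, params: DebyeParams):
    """Complex relative permittivity of a Debye medium.

    eps(f) = eps_inf + (eps_s - eps_inf)/(1 + j w tau) - j sigma/(w eps0)
    """
    f = _check_frequency(frequency)
    w = 2.0 * np.pi * f
    eps = (
        params.eps_inf
        + (params.eps_static - params.eps_inf) / (1.0 + 1j * w * params.tau)
        - 1j * params.sigma_ionic / (w * EPS0)
    )
    return eps if np.ndim(eps) else complex(eps)


def cole_cole_permittivity(frequency, params: ColeColeParams):
    """Complex relative permittivity of a Cole-Cole medium.

    eps(f) = eps_inf + sum_k d_eps_k / (1 + (j w tau_k)^(1-alpha_k))
             - j sigma/(w eps0)
    """
    f = _check_frequency(frequency)
    w = 2.0 * np.pi * f
    eps = np.full(np.shape(w), params.eps_inf, dtype=complex)
    for term in params.terms:
        eps = eps + term.delta_eps / (1.0 + (1j * w * term.tau) ** (1.0 - term.alpha))
    if params.sigma_ionic:
        eps = eps - 1j * params.sigma_ionic / (w * EPS0)
    return eps if np.ndim(eps) else complex(eps)


# --------------------------------------------------------------------------
# published parameter sets
# --------------------------------------------------------------------------

#: Debye parameters of pure water at 25 degC (static/infinite permittivity,
#: relaxation time).  Standard literature values; configurable via JSON.
WATER_DEBYE_25C = DebyeParams(eps_static=78.36, eps_inf=5.2, tau=8.27e-12)

#: 4-term Cole-Cole parameter sets from the published parametric tissue
#: database (Gabriel et al.).  "skull" uses cortical bone.
TISSUE_COLE_COLE: dict[str, ColeColeParams] = {
    "gray_matter": ColeColeParams(
        eps_inf=4.0,
        terms=(
            ColeColeTerm(45.0, 7.958e-12, 0.10),
            ColeColeTerm(400.0, 15.915e-9, 0.15),
            ColeColeTerm(2.0e5, 106.103e-6, 0.22),
            ColeColeTerm(4.5e7, 5.305e-3, 0.00),
        ),
        sigma_ionic=0.02,
    ),
    "blood": ColeColeParams(
        eps_inf=4.0,
        terms=(
            ColeColeTerm(56.0, 8.377e-12, 0.10),
            ColeColeTerm(5200.0, 132.629e-9, 0.10),
        ),
        sigma_ionic=0.70,
    ),
    "skull": ColeColeParams(  # cortical bone
        eps_inf=2.5,
        terms=(
            ColeColeTerm(10.0, 13.263e-12, 0.20),
            ColeColeTerm(180.0, 79.577e-9, 0.20),
            ColeColeTerm(5.0e3, 159.155e-6, 0.20),
            ColeColeTerm(1.0e5, 15.915e-3, 0.00),
        ),
        sigma_ionic=0.02,
    ),
    "csf": ColeColeParams(
        eps_inf=4.0,
        terms=(
            ColeColeTerm(65.0, 7.958e-12, 0.10),
            ColeColeTerm(40.0, 1.592e-9, 0.00),
        ),
        sigma_ionic=2.0,
    ),
}

#: Relative permittivity of the (lossless) parallel-plate port filling.
PORT_FILL_EPS = 20.0

#: Conductivity modelling the metallic port walls (good conductor).
METAL_SIGMA = 1.0e7


# --------------------------------------------------------------------------
# material registry
# --------------------------------------------------------------------------

ModelFn = Callable[[np.ndarray], np.ndarray]


def _constant_model(eps_real: float, sigma: float = 0.0) -> ModelFn:
    def fn(f):
        f = _check_frequency(f)
        w = 2.0 * np.pi * f
        eps = np.full(np.shape(w), eps_real, dtype=complex)
        if sigma:
            eps = eps - 1j * sigma / (w * EPS0)
        return eps if np.ndim(eps) else complex(eps)

    return fn


def default_material_models() -> dict[str, ModelFn]:
    """Analytic permittivity model for every material the geometry uses."""
    models: dict[str, ModelFn] = {
        "air": _constant_model(1.0),
        "metal": _constant_model(1.0, sigma=METAL_SIGMA),
        "port_fill": _constant_model(PORT_FILL_EPS),
        "water": lambda f: debye_permittivity(f, WATER_DEBYE_25C),
    }
    for name, params in TISSUE_COLE_COLE.items():
        models[name] = (lambda p: lambda f: cole_cole_permittivity(f, p))(params)
    return models


def load_material_config(path) -> dict[str, ModelFn]:
    """Override/extend the default registry from a JSON config.

    Schema: ``{material: {"model": "debye"|"cole_cole"|"constant", ...}}`` with
    Debye keys (eps_static, eps_inf, tau, sigma_ionic), Cole-Cole keys
    (eps_inf, terms: [[delta_eps, tau, alpha], ...], sigma_ionic) or constant
    keys (eps_real, sigma).
    """
    with open(path) as fh:
        cfg = json.load(fh)
    models = default_material_models()
    for name, spec in cfg.items():
        kind = spec["model"]
        if kind == "debye":
            p = DebyeParams(
                spec["eps_static"], spec["eps_inf"], spec["tau"],
                spec.get("sigma_ionic", 0.0),
            )
            models[name] = (lambda q: lambda f: debye_permittivity(f, q))(p)
        elif kind == "cole_cole":
            terms = tuple(ColeColeTerm(*t) for t in spec["terms"])
            p = ColeColeParams(spec["eps_inf"], terms, spec.get("sigma_ionic", 0.0))
            models[name] = (lambda q: lambda f: cole_cole_permittivity(f, q))(p)
        elif kind == "constant":
            models[name] = _constant_model(spec["eps_real"], spec.get("sigma", 0.0))
        else:
            raise ValueError(f"unknown material model {kind!r} for {name!r}")
    return models


class MaterialSet:
    """Registry of analytic permittivity models with on-demand evaluation."""

    def __init__(self, models: Mapping[str, ModelFn] | None = None):
        self._models = dict(models) if models is not None else default_material_models()

    @classmethod
    def from_json(cls, path) -> "MaterialSet":
        return cls(load_material_config(path))

    @property
    def names(self) -> list[str]:
        return sorted(self._models)

    def eps(self, material: str, frequency):
        """Complex relative permittivity of ``material`` at ``frequency`` (Hz)."""
        try:
            model = self._models[material]
        except KeyError:
            raise KeyError(f"unknown material {material!r}") from None
        return model(frequency)

    def spectrum(self, material: str, frequencies) -> "DielectricSpectrum":
        f = np.atleast_1d(np.asarray(frequencies, dtype=float))
        return DielectricSpectrum(material, f, np.atleast_1d(self.eps(material, f)))


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

@dataclass
class DielectricSpectrum:
    """Complex relative permittivity of one material on a frequency grid."""

    material_name: str
    frequencies: np.ndarray  # Hz, strictly increasing
    eps_rel: np.ndarray  # complex, convention eps' - j eps''

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eps_rel = np.asarray(self.eps_rel, dtype=complex)
        if self.frequencies.ndim != 1 or self.frequencies.size < 1:
            raise ValueError("frequencies must be a non-empty 1-D array")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.eps_rel.shape != self.frequencies.shape:
            raise ValueError("eps_rel and frequencies must have equal length")
        if np.any(self.eps_rel.real <= 0):
            raise ValueError(f"{self.material_name}: eps' must be positive")
        if np.any(self.eps_rel.imag > 1e-12):
            raise ValueError(f"{self.material_name}: eps'' must be >= 0 (passivity)")

    @property
    def conductivity_equivalent(self) -> np.ndarray:
        """Equivalent conductivity sigma = omega eps0 eps'' (S/m)."""
        w = 2.0 * np.pi * self.frequencies
        return w * EPS0 * (-self.eps_rel.imag)


def material_table(
    frequency_grid: Sequence[float],
    materials: MaterialSet | None = None,
    names: Sequence[str] | None = None,
) -> dict[str, DielectricSpectrum]:
    """Evaluate every registered material on ``frequency_grid``.

    Returns a map material name -> :class:`DielectricSpectrum`.  Unknown names
    raise ``KeyError``.
    """
    grid = np.asarray(frequency_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("frequency_grid must be non-empty and strictly increasing")
    ms = materials if materials is not None else MaterialSet()
    use = list(names) if names is not None else ms.names
    return {name: ms.spectrum(name, grid) for name in use}


def export_spectra_csv(table: Mapping[str, DielectricSpectrum], path) -> None:
    """Write spectra as CSV: material, frequency_Hz, eps_real, eps_imag, sigma_S_per_m."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["material", "frequency_Hz", "eps_real", "eps_imag", "sigma_S_per_m"])
        for name in sorted(table):
            spec = table[name]
            sigma = spec.conductivity_equivalent
            for f, e, s in zip(spec.frequencies, spec.eps_rel, sigma):
                writer.writerow([name, f"{f:.6e}", f"{e.real:.8g}", f"{e.imag:.8g}", f"{s:.8g}"])
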