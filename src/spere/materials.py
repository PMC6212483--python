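"""Material dispersion models and the packaged materials registry.

Every material exposes a real refractive index n(lambda) over a validated
vacuum-wavelength range.  Dispersive entries use standard Sellmeier/Cauchy
fits (coefficients live in ``data/materials.yaml``); thin molecular layers
and liquid-crystal principal indices are non-dispersive constants.  All
indices are real: the probes are lossless dielectrics in the visible band.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from .errors import ConfigError, WavelengthRangeError

REGISTRY_VERSION = 1


class Material:
    """A named dielectric with a real dispersion n(lambda).

    Parameters
    ----------
    name
        Registry identifier.
    index_fn
        Vectorized callable, vacuum wavelength nm -> refractive index.
    valid_range
        ``(lambda_min, lambda_max)`` nm over which the fit is trusted;
        evaluation outside raises :class:`WavelengthRangeError`.
    """

    def __init__(
        self,
        name: str,
        index_fn: Callable[[np.ndarray], np.ndarray],
        valid_range: tuple[float, float],
        model: str = "custom",
    ):
        self.name = name
        self._index_fn = index_fn
        self.valid_range = (float(valid_range[0]), float(valid_range[1]))
        self.model = model

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        lo, hi = self.valid_range
        return f"Material({self.name!r}, model={self.model!r}, valid=[{lo:g}, {hi:g}] nm)"

    def index(self, wavelength_nm) -> np.ndarray | float:
        """Refractive index at the given vacuum wavelength(s) in nm."""
        wl = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.valid_range
        if np.any(wl < lo - 1e-9) or np.any(wl > hi + 1e-9):
            raise WavelengthRangeError(
                f"wavelength outside validated range of material "
                f"'{self.name}' ([{lo:g}, {hi:g}] nm); requested "
                f"[{wl.min():g}, {wl.max():g}] nm"
            )
        n = self._index_fn(wl)
        return float(n) if np.isscalar(wavelength_nm) else np.asarray(n, dtype=float)

    __call__ = index

    def group_index(self, wavelength_nm, step_nm: float = 0.5):
        """Group refractive index n_g = n - lambda * dn/dlambda.

        The derivative is a central difference (one-sided at range edges);
        ``step_nm`` is far below any dispersion feature of these smooth fits.
        """
        wl = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.valid_range
        lo_pts = np.clip(wl - step_nm, lo, hi)
        hi_pts = np.clip(wl + step_nm, lo, hi)
        dn = (self._index_fn(hi_pts) - self._index_fn(lo_pts)) / (hi_pts - lo_pts)
        ng = self._index_fn(wl) - wl * dn
        return float(ng) if np.isscalar(wavelength_nm) else np.asarray(ng, dtype=float)

    @classmethod
    def constant(
        cls, name: str, n: float, valid_range: tuple[float, float] = (300.0, 1500.0)
    ) -> "Material":
        """Non-dispersive pseudo-material of fixed index ``n``."""
        n = float(n)
        if n <= 0:
            raise ValueError(f"refractive index must be positive, got {n}")
        return cls(name, lambda wl: np.full_like(np.asarray(wl, float), n), valid_range, "constant")


def _sellmeier(B: list[float], C: list[float]) -> Callable:
    B = np.asarray(B, float)
    C = np.asarray(C, float)

    def fn(wl_nm):
        L2 = (np.asarray(wl_nm, float) / 1000.0) ** 2  # um^2
        n2 = 1.0 + np.sum(B * L2[..., None] / (L2[..., None] - C), axis=-1)
        return np.sqrt(n2)

    return fn


def _cauchy(A: float, B: float, C: float) -> Callable:
    def fn(wl_nm):
        L2 = (np.asarray(wl_nm, float) / 1000.0) ** 2
        return A + B / L2 + C / L2**2

    return fn


def _build_material(name: str, entry: dict) -> Material:
    model = entry.get("model")
    rng = entry.get("valid_range_nm")
    if model is None or rng is None:
        raise ConfigError(f"registry entry '{name}' lacks model or valid_range_nm")
    if model == "sellmeier":
        fn = _sellmeier(entry["B"], entry["C"])
    elif model == "cauchy":
        fn = _cauchy(entry["A"], entry["B"], entry["C"])
    elif model == "constant":
        return Material.constant(name, entry["n"], tuple(rng))
    else:
        raise ConfigError(f"registry entry '{name}': unknown dispersion model '{model}'")
    return Material(name, fn, tuple(rng), model)


def load_registry(path: str | Path | None = None) -> dict[str, Material]:
    """Load a materials registry (the packaged one when ``path`` is None)."""
    if path is None:
        text = resources.files("spere").joinpath("data/materials.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "materials" not in doc:
        raise ConfigError("materials registry must contain a 'materials' mapping")
    if doc.get("version") != REGISTRY_VERSION:
        raise ConfigError(
            f"materials registry version {doc.get('version')!r} is not the "
            f"supported version {REGISTRY_VERSION}"
        )
    entries = doc["materials"]
    registry: dict[str, Material] = {}
    aliases: dict[str, str] = {}
    for name, entry in entries.items():
        if "alias" in entry:
            aliases[name] = entry["alias"]
        else:
            registry[name] = _build_material(name, entry)
    for name, target in aliases.items():
        if target not in registry:
            raise ConfigError(f"registry alias '{name}' points to unknown '{target}'")
        registry[name] = registry[target]
    return registry


_default_registry: dict[str, Material] | None = None


def get_material(name: str, registry: dict[str, Material] | None = None) -> Material:
    """Look up a material by name (packaged registry by default)."""
    global _default_registry
    if registry is None:
        if _default_registry is None:
            _default_registry = load_registry()
        registry = _default_registry
    try:
        return registry[name]
    except KeyError:
        raise ConfigError(
            f"unknown material '{name}'; registry has: {', '.join(sorted(registry))}"
        ) from None
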