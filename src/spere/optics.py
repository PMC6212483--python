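"""Transfer-matrix reflectance of multilayer stacks at normal incidence.

A ray focused at the center of a dielectric microsphere enters and leaves
the surface normally, so the center-ray interference of a sphere of
diameter d in a medium is that of a plane-parallel slab of thickness d:
``medium | core(d) | medium``.  The coherent normal-incidence reflectance
of such a stack is computed with standard 2x2 characteristic matrices

    M_layer = [[cos(delta),        i sin(delta)/n],
               [i n sin(delta),    cos(delta)    ]],   delta = 2 pi n d / lambda,

multiplied front to back over the internal layers.  With semi-infinite
entry/exit indices n0 and ns, r = (n0 B - C) / (n0 B + C) where
(B, C)^T = M (1, ns)^T.  All media are lossless (real n), so R + T = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StackStructureError
from .materials import Material
from .spectrum import Spectrum


@dataclass(frozen=True)
class Layer:
    """One slab of a stack; ``thickness=None`` marks a semi-infinite medium."""

    material: Material
    thickness: float | None = None  # nm; None only for the two outer media

    @property
    def semi_infinite(self) -> bool:
        return self.thickness is None


class LayerStack:
    """Ordered layers, outermost to outermost.

    Invariants: at least 3 layers; first and last are semi-infinite media;
    internal thicknesses are strictly positive.
    """

    def __init__(self, layers: list[Layer]):
        if len(layers) < 3:
            raise StackStructureError(
                f"a stack needs >= 3 layers (medium | core | medium), got {len(layers)}"
            )
        if not layers[0].semi_infinite or not layers[-1].semi_infinite:
            raise StackStructureError("first and last layers must be semi-infinite media")
        for i, layer in enumerate(layers[1:-1], start=1):
            if layer.semi_infinite or layer.thickness <= 0:
                raise StackStructureError(
                    f"internal layer {i} ('{layer.material.name}') must have "
                    f"positive finite thickness, got {layer.thickness}"
                )
        self.layers = list(layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def internal_thickness(self) -> float:
        """Total physical thickness of the internal layers, nm."""
        return float(sum(l.thickness for l in self.layers[1:-1]))

    def is_mirror_symmetric(self, tol: float = 1e-9) -> bool:
        for a, b in zip(self.layers, reversed(self.layers)):
            if a.material.name != b.material.name:
                return False
            ta = a.thickness or 0.0
            tb = b.thickness or 0.0
            if abs(ta - tb) > tol:
                return False
        return True


def interface_reflectance(n1: float, n2: float) -> float:
    """Normal-incidence Fresnel power reflectance ((n1-n2)/(n1+n2))^2."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"refractive indices must be positive, got n1={n1}, n2={n2}")
    return float(((n1 - n2) / (n1 + n2)) ** 2)


def sphere_stack(
    diameter: float,
    core: Material,
    medium: Material,
    adlayers: list[tuple[float, float | Material]] | None = None,
) -> LayerStack:
    """Slab-equivalent stack of a microsphere, optionally with surface adlayers.

    ``adlayers`` lists ``(thickness_nm, index_or_material)`` pairs applied
    symmetrically (one copy per side, outermost first), e.g. a bound-protein
    film.  A bare sphere gives ``medium | core(d) | medium``.
    """
    if diameter <= 0:
        raise StackStructureError(f"diameter must be positive, got {diameter}")
    coats = []
    for t, n in adlayers or []:
        mat = n if isinstance(n, Material) else Material.constant(f"layer_n{n:g}", n)
        coats.append(Layer(mat, float(t)))
    outer = Layer(medium)
    return LayerStack(
        [outer, *coats, Layer(core, float(diameter)), *reversed(coats), outer]
    )


def _amplitude_coefficients(stack: LayerStack, wl: np.ndarray):
    """Complex r and t amplitude coefficients at each wavelength."""
    indices = [layer.material.index(wl) for layer in stack.layers]
    m11 = np.ones_like(wl, dtype=complex)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    m22 = np.ones_like(m11)
    for layer, n in zip(stack.layers[1:-1], indices[1:-1]):
        delta = 2.0 * np.pi * n * layer.thickness / wl
        c, s = np.cos(delta), np.sin(delta)
        a11, a12 = c, 1j * s / n
        a21, a22 = 1j * n * s, c
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )
    n0, ns = indices[0], indices[-1]
    B = m11 + m12 * ns
    C = m21 + m22 * ns
    denom = n0 * B + C
    r = (n0 * B - C) / denom
    t = 2.0 * n0 / denom
    return r, t, n0, ns


def reflectance_spectrum(stack: LayerStack, wavelengths: np.ndarray) -> Spectrum:
    """Coherent normal-incidence reflectance of ``stack`` on ``wavelengths`` (nm)."""
    wl = np.asarray(wavelengths, dtype=float)
    r, _, _, _ = _amplitude_coefficients(stack, wl)
    R = np.clip(np.abs(r) ** 2, 0.0, 1.0)
    return Spectrum(wl, R, {"kind": "simulated_reflectance"})


def transmittance_spectrum(stack: LayerStack, wavelengths: np.ndarray) -> Spectrum:
    """Coherent normal-incidence transmittance (lossless stacks: T = 1 - R)."""
    wl = np.asarray(wavelengths, dtype=float)
    _, t, n0, ns = _amplitude_coefficients(stack, wl)
    T = np.real(ns) / np.real(n0) * np.abs(t) ** 2
    return Spectrum(wl, T, {"kind": "simulated_transmittance"})


def count_fringe_maxima(values: np.ndarray) -> int:
    """Number of strict interior local maxima (fringe peaks) in a sampled curve."""
    v = np.asarray(values, dtype=float)
    return int(np.sum((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])))
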