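"""Independent oracles used by the test suite.

These are deliberately written without reference to the package's
transfer-matrix code paths, so that agreement between the two is a real
cross-check rather than a tautology.
"""

import numpy as np


def airy_reflectance(n0: float, n1: float, ns: float, thickness_nm: float, wl_nm):
    """Closed-form reflectance of a single film between two semi-infinite media.

    Airy summation of the two interface amplitudes:
        r = (r01 + r1s e^{2 i delta}) / (1 + r01 r1s e^{2 i delta}),
        delta = 2 pi n1 d / lambda.
    """
    wl = np.asarray(wl_nm, dtype=float)
    r01 = (n0 - n1) / (n0 + n1)
    r1s = (n1 - ns) / (n1 + ns)
    phase = np.exp(1j * (4.0 * np.pi * n1 * thickness_nm / wl))  # e^{2 i delta}
    r = (r01 + r1s * phase) / (1.0 + r01 * r1s * phase)
    return np.abs(r) ** 2


def etalon_peak_reflectance(n0: float, n1: float) -> float:
    """Maximum reflectance of a symmetric lossless etalon: 4R1 / (1 + R1)^2."""
    r1 = ((n0 - n1) / (n0 + n1)) ** 2
    return 4.0 * r1 / (1.0 + r1) ** 2


def numeric_group_index(material, wl_nm: float, h: float = 0.25) -> float:
    """n_g = n - lambda dn/dlambda by an independent central difference."""
    n_plus = material.index(wl_nm + h)
    n_minus = material.index(wl_nm - h)
    return material.index(wl_nm) - wl_nm * (n_plus - n_minus) / (2.0 * h)
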