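"""X-ray atomic scattering factors as 4-Gaussian + constant fits.

f(s) = sum_i a_i * exp(-b_i * (sin(theta)/lambda)^2) + c, with
sin(theta)/lambda = 1/(2d). Coefficients for the light elements common in
protein models. The same table feeds the structure-factor generator and
every test oracle, so internal consistency matters more than matching any
particular vendor tabulation at toy scale.
"""

from __future__ import annotations

import numpy as np

# element -> (a[4], b[4], c)
COEFFS: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.86500),
          (20.8439, 10.2075, 0.56870, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.86700),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
}


def supported_elements() -> list[str]:
    return sorted(COEFFS)


def form_factor(element: str, stol2: np.ndarray | float) -> np.ndarray:
    """Scattering factor f(stol2) where stol2 = (sin(theta)/lambda)^2 = 1/(4 d^2)."""
    try:
        a, b, c = COEFFS[element]
    except KeyError:
        raise ValueError(
            f"unknown element {element!r}; supported: {', '.join(supported_elements())}"
        ) from None
    stol2 = np.asarray(stol2, dtype=float)
    f = np.full_like(stol2, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * stol2)
    return f


def electron_count(element: str) -> float:
    """f(0) of the bundled fit: the effective electron count of the element."""
    a, _, c = COEFFS[element]
    return float(sum(a) + c)
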