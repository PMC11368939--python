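"""Physical constants and universal model coefficients for the equation of state.

The dispersion integrals I1, I2 use the universal perturbation-theory
coefficient tables of the perturbed-chain SAFT model; they are properties
of the model, not of any fluid, and are versioned here as immutable arrays.
"""

from __future__ import annotations

import numpy as np

K_B = 1.380649e-23  # J K^-1
N_AV = 6.02214076e23  # mol^-1
E_CHARGE = 1.602176634e-19  # C
EPS_0 = 8.8541878128e-12  # F m^-1

#: Universal dispersion coefficients a_0i, a_1i, a_2i for I1 (i = 0..6).
A_UNIV = np.array(
    [
        [0.9105631445, -0.3084016918, -0.0906148351],
        [0.6361281449, 0.1860531159, 0.4527842806],
        [2.6861347891, -2.5030047259, 0.5962700728],
        [-26.547362491, 21.419793629, -1.7241829131],
        [97.759208784, -65.255885330, -4.1302112531],
        [-159.59154087, 83.318680481, 13.776631870],
        [91.297774084, -33.746922930, -8.6728470368],
    ]
)
A_UNIV.setflags(write=False)

#: Universal dispersion coefficients b_0i, b_1i, b_2i for I2 (i = 0..6).
B_UNIV = np.array(
    [
        [0.7240946941, -0.5755498075, 0.0976883116],
        [2.2382791861, 0.6995095521, -0.2557574982],
        [-4.0025849485, 3.8925673390, -9.1558561530],
        [-21.003576815, -17.215471648, 20.642075974],
        [26.855641363, 192.67226447, -38.804430052],
        [206.55133841, -161.82646165, 93.626774077],
        [-355.60235612, -165.20769346, -29.666905585],
    ]
)
B_UNIV.setflags(write=False)

#: Maximum physical packing fraction (close packing of spheres).
ETA_MAX = 0.7405


def water_relative_permittivity(T: float) -> float:
    """Static relative permittivity of pure liquid water.

    Empirical polynomial correlation in T (K), valid roughly 273-373 K;
    gives 78.4 at 298.15 K.
    """
    return (
        5321.0 / T
        + 233.76
        - 0.9297 * T
        + 1.417e-3 * T * T
        - 8.292e-7 * T * T * T
    )


def water_segment_diameter(T: float, warn_window: tuple[float, float] = (273.0, 373.0)) -> float:
    """Temperature-dependent segment diameter of water in Angstrom.

    sigma(T) = 2.7927 + 10.11 exp(-0.01775 T) - 1.417 exp(-0.01146 T).
    Outside the stated liquid-water validity window the formula is still
    evaluated, with a warning.
    """
    import warnings

    lo, hi = warn_window
    if not (lo < T < hi):
        warnings.warn(
            f"water segment diameter correlation evaluated at T={T} K, "
            f"outside its validity window ({lo}, {hi}) K",
            stacklevel=2,
        )
    return 2.7927 + 10.11 * np.exp(-0.01775 * T) - 1.417 * np.exp(-0.01146 * T)
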