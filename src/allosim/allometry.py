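"""Allometric scaling rules linking consumer body mass to physiology and movement.

All relationships are mass-based power laws (or one affine law) parameterised
for walking/running poikilotherms, chiefly arthropods.  Masses are in
kilograms, energies in joules, times in seconds, distances in metres.  Every
function accepts scalars or NumPy arrays and is the single source of truth for
the corresponding rate throughout the simulator.

The legal adult-genotype range is [0.01 g, 3 g]; the speed and perceptual-range
laws evaluated at those endpoints give the sampling bounds used by the
decoupled (size-independent) movement variant: speeds in [0.0106, 0.0557] m/s
and perceptual ranges in [0.10, 1.0] m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "W_MIN",
    "W_MAX",
    "SECONDS_PER_DAY",
    "AllometryConstants",
    "max_daily_ingestion",
    "basal_metabolic_power",
    "optimal_speed",
    "movement_cost_rate",
    "perceptual_range",
    "clutch_mass",
    "growth_increment",
    "searching_radius",
]

#: absolute physiological bounds on the adult-mass genotype (kg)
W_MIN = 1e-5
W_MAX = 3e-3

SECONDS_PER_DAY = 86_400.0

#: decoupled-model daily sampling bounds: optimal speed of the smallest and
#: largest legal adult (m/s) and their perceptual ranges (m)
SPEED_BOUNDS = (0.3 * W_MIN**0.29, 0.3 * W_MAX**0.29)
PERCEPTION_BOUNDS = (0.10, 1.0)


@dataclass(frozen=True)
class AllometryConstants:
    """Fixed physiological constants of the consumer.

    Parameters
    ----------
    t_f:
        Time devoted to foraging per day, seconds (15 h).
    t_m_cap:
        Maximum time devoted to movement per day, seconds (1 h).
    tissue_energy_density:
        Energetic content of consumer tissue, J per kg; converts reserve
        energy into structural growth and clutch mass.
    growth_coefficient:
        Rate constant ``a`` of the ontogenetic (West) growth model,
        kg^(1/4) per day.  The default makes a 0.01 g genotype mature in
        roughly 20 days when growth is not food-limited.
    """

    t_f: float = 54_000.0
    t_m_cap: float = 3_600.0
    tissue_energy_density: float = 7.0e6
    growth_coefficient: float = 0.06

    def __post_init__(self) -> None:
        for name in ("t_f", "t_m_cap", "tissue_energy_density", "growth_coefficient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _check_mass(W) -> np.ndarray | float:
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("body mass must be strictly positive")
    return W if W.ndim else float(W)


def max_daily_ingestion(W, t_f: float = 54_000.0):
    """Maximum energy (J) an individual of mass ``W`` kg can ingest per day.

    ``i_max = 2 * W**0.80 * t_f`` with ``t_f`` the daily foraging time in
    seconds.  Strictly increasing in both arguments.
    """
    W = _check_mass(W)
    if np.any(np.asarray(t_f) < 0):
        raise ValueError("foraging time must be non-negative")
    return 2.0 * W**0.80 * t_f


def basal_metabolic_power(W):
    """Standard (basal) metabolic rate of a poikilotherm, in watts.

    ``M = 0.14 * W**0.751``.  The daily maintenance cost charged by the
    simulator is this power times 86,400 s.
    """
    W = _check_mass(W)
    return 0.14 * W**0.751


def optimal_speed(W):
    """Optimal walking speed (m/s), ``v_opt = 0.3 * W**0.29``.

    ``W`` excludes the mass of stored resources.  Endpoints of the legal
    adult range give 0.0106 and 0.0557 m/s.
    """
    W = _check_mass(W)
    return 0.3 * W**0.29


def movement_cost_rate(W):
    """Energetic cost of locomotion (J/s) for a running poikilotherm.

    ``c_m = 0.17 * W**0.75 + 3.4 * W``.
    """
    W = _check_mass(W)
    return 0.17 * W**0.75 + 3.4 * W


def perceptual_range(W):
    """Perceptual range (m), affine in mass: ``d_per = 301 * W + 0.097``.

    Calibrated so a 0.01 g individual perceives 0.10 m and a 3 g
    individual 1.0 m.
    """
    W = _check_mass(W)
    return 301.0 * W + 0.097


def clutch_mass(W):
    """Total clutch mass (kg) of an adult of mass ``W``: ``CS = 0.158 * W**0.92``.

    The clutch is divided over a fixed number of eggs (15), so per-egg mass
    is ``CS / 15``.  ``CS(W) < W`` over the whole legal range.
    """
    W = _check_mass(W)
    return 0.158 * W**0.92


def growth_increment(W, W_max, dt: float = 1.0, a: float = 0.06):
    """One explicit-Euler step of the ontogenetic growth model, in kg.

    The underlying ODE is ``dW/dt = a * W**(3/4) * (1 - (W/W_max)**(1/4))``;
    the increment is ``dt`` times the right-hand side, never negative, and
    zero exactly at the asymptotic mass ``W = W_max``.  The step is clipped
    so a single step never overshoots ``W_max``.
    """
    W = _check_mass(W)
    W_max_arr = _check_mass(W_max)
    if np.any(np.asarray(W) > np.asarray(W_max_arr) * (1 + 1e-12)):
        raise ValueError("current mass exceeds asymptotic mass")
    if dt <= 0:
        raise ValueError("dt must be positive")
    dW = a * W**0.75 * (1.0 - (W / W_max_arr) ** 0.25) * dt
    return np.minimum(np.maximum(dW, 0.0), W_max_arr - W)


def searching_radius(d_per, d_max):
    """Radius (m) of the circle with the area an individual prospects in a day.

    A path of length ``d_max`` perceived to ``d_per`` on either side, plus
    circular end caps, sweeps an area ``2*d_per*d_max + pi*d_per**2``; the
    equal-area circle has radius ``sqrt(area/pi)``.  Reduces to ``d_per``
    when ``d_max = 0`` and increases in both arguments.
    """
    d_per = np.asarray(d_per, dtype=float)
    d_max = np.asarray(d_max, dtype=float)
    if np.any(d_per < 0) or np.any(d_max < 0):
        raise ValueError("distances must be non-negative")
    rad = np.sqrt((2.0 * d_per * d_max + np.pi * d_per**2) / np.pi)
    return rad if rad.ndim else float(rad)
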