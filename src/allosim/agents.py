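"""Consumer individuals and the rules of their daily life cycle.

Each consumer is a juvenile or adult with a current body mass ``W``, a
heritable adult-mass genotype ``W_max`` (one gene, mutating at reproduction),
an energy reserve ``E_r`` (J) and a location on the suitable-patch lattice.
Within a day, energy from consumption is spent in strict priority order:
basal metabolism, then movement, then growth (juveniles) or reproduction
(adults).  The species is haploid, parthenogenetic and semelparous: one
clutch of 15 eggs, then death.

Functions here are pure rules operating on scalars or NumPy arrays; the
engine applies them to its array-based population state, and the
:class:`Individual` dataclass offers the same rules one consumer at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .allometry import (
    SECONDS_PER_DAY,
    SPEED_BOUNDS,
    PERCEPTION_BOUNDS,
    W_MAX,
    W_MIN,
    AllometryConstants,
    basal_metabolic_power,
    clutch_mass,
    growth_increment,
    max_daily_ingestion,
    movement_cost_rate,
    optimal_speed,
    perceptual_range,
    searching_radius,
)
from .landscape import Landscape, cells_within_radius

__all__ = [
    "N_EGGS",
    "MUTATION_RATE",
    "Individual",
    "MovementPlan",
    "move_probability",
    "plan_movement",
    "choose_destination",
    "starter_reserve",
    "reproduction_threshold",
    "mutate_genotypes",
    "reproduce",
]

#: eggs per clutch
N_EGGS = 15
#: per-offspring genotype mutation probability
MUTATION_RATE = 0.001


@dataclass
class Individual:
    """One consumer: state, genotype, energy reserve and movement history."""

    id: int
    stage: str  # "juvenile" | "adult"
    W: float  # current body mass, kg
    W_max: float  # genotype: asymptotic adult mass, kg
    E_r: float  # energy reserve, J
    location: tuple[int, int]
    age: int = 0
    moves_made: int = 0
    distance_moved: float = 0.0
    repro_done: bool = False


@dataclass
class MovementPlan:
    """A single day's movement decision variables for one individual."""

    p: float  # probability of moving (cell-level, Eq-style pooled ratio)
    t_m: float  # movement time, s
    v: float  # speed, m/s
    d_max: float  # path length covered, m
    d_per: float  # perceptual range, m
    rad: float  # searching-area radius, m
    cost: float  # energy cost if the move is executed, J


def move_probability(R, sum_imax):
    """Probability of moving for every individual in a cell.

    ``p = 1 - R / sum_imax`` when the pooled daily demand exceeds the
    resources present, else 0.  Equal for all occupants (symmetric
    competition).  A cell with no demand gives ``p = 0``.
    """
    R = np.asarray(R, dtype=float)
    sum_imax = np.asarray(sum_imax, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sum_imax > 0, R / np.where(sum_imax > 0, sum_imax, 1.0), np.inf)
    p = np.where(ratio < 1.0, 1.0 - ratio, 0.0)
    return p if p.ndim else float(p)


def movement_traits(W, mode: str, rng: np.random.Generator | None = None):
    """Daily speed and perceptual range, coupled to mass or resampled.

    Coupled: ``v = v_opt(W)``, ``d_per = d_per(W)``.  Decoupled: both drawn
    fresh each day from the uniform ranges spanned by the smallest and
    largest legal adults — [0.0106, 0.0557] m/s and [0.1, 1] m — severing
    the size-movement link while leaving costs mass-based.
    """
    W = np.asarray(W, dtype=float)
    if mode == "coupled":
        return optimal_speed(W), perceptual_range(W)
    if mode == "decoupled":
        if rng is None:
            raise ValueError("decoupled mode needs a random generator")
        v = rng.uniform(*SPEED_BOUNDS, size=W.shape)
        d_per = rng.uniform(*PERCEPTION_BOUNDS, size=W.shape)
        if W.ndim == 0:
            return float(v), float(d_per)
        return v, d_per
    raise ValueError(f"unknown mode {mode!r}")


def plan_movement(
    ind: Individual,
    mode: str = "coupled",
    rng: np.random.Generator | None = None,
    constants: AllometryConstants = AllometryConstants(),
    p: float = 1.0,
) -> MovementPlan:
    """Assemble one individual's movement plan for the day.

    Movement time is capped at one hour and further limited by the reserve
    (``t_m = min(cap, E_r / c_m)``); the searching radius follows from the
    path length ``v * t_m`` and the perceptual range.  The cost ``t_m*c_m``
    is charged only when the move is actually executed.
    """
    v, d_per = movement_traits(ind.W, mode, rng)
    c_m = movement_cost_rate(ind.W)
    t_m = min(constants.t_m_cap, max(ind.E_r, 0.0) / c_m)
    d_max = v * t_m
    rad = searching_radius(d_per, d_max)
    return MovementPlan(p=p, t_m=t_m, v=v, d_max=d_max, d_per=d_per, rad=rad, cost=t_m * c_m)


def choose_destination(
    landscape: Landscape,
    origin,
    rad: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Pick the richest suitable cell within the searching radius.

    Habitat choice is informed: among suitable cells within ``rad`` metres
    of ``origin`` (origin included if suitable) the one with the most
    resource wins; exact ties are broken uniformly at random.  With no
    suitable cell in range the individual stays put.
    """
    idx = cells_within_radius(landscape, origin, rad)
    if idx.size == 0:
        return tuple(origin)
    vals = landscape.resource[idx]
    ties = idx[vals == vals.max()]
    choice = ties[0] if ties.size == 1 else ties[rng.integers(ties.size)]
    return tuple(landscape.coords[choice])


def starter_reserve(W, constants: AllometryConstants = AllometryConstants()):
    """Energy (J) that lets a consumer of mass ``W`` survive its first day.

    One day of basal metabolism plus one full hour of movement at the
    mass-based cost rate; used for initial adults, immigrants and
    hatchlings.
    """
    return SECONDS_PER_DAY * basal_metabolic_power(W) + constants.t_m_cap * movement_cost_rate(W)


def reproduction_threshold(W_max, constants: AllometryConstants = AllometryConstants()):
    """Reserve (J) an adult must accumulate before producing its clutch.

    Covers the tissue energy of the whole clutch plus the starter reserve
    endowed to each of the 15 hatchlings, so the threshold rises with body
    size and the population energy ledger closes exactly at reproduction.
    """
    cs = clutch_mass(W_max)
    egg_mass = cs / N_EGGS
    return constants.tissue_energy_density * cs + N_EGGS * starter_reserve(egg_mass, constants)


def mutate_genotypes(
    parent_W_max,
    rng: np.random.Generator,
    rate: float = MUTATION_RATE,
) -> np.ndarray:
    """Offspring genotypes: copy of the parent, mutated with probability ``rate``.

    A mutation redraws the gene uniformly from [W_max/2, 3*W_max/2] around
    the parental value; draws outside the physiological limits
    [0.01 g, 3 g] are rejected and resampled.
    """
    parent = np.atleast_1d(np.asarray(parent_W_max, dtype=float)).copy()
    mutate = rng.random(parent.shape) < rate
    pending = np.flatnonzero(mutate)
    while pending.size:
        draw = rng.uniform(parent[pending] / 2.0, 1.5 * parent[pending])
        ok = (draw >= W_MIN) & (draw <= W_MAX)
        parent[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return parent


def reproduce(
    ind: Individual,
    rng: np.random.Generator,
    constants: AllometryConstants = AllometryConstants(),
    next_id: int = 0,
) -> list[Individual]:
    """Semelparous reproduction of one adult, if its reserve suffices.

    Returns the clutch of 15 juveniles placed in the parent's cell (each at
    per-egg mass ``CS/15`` with a first-day starter reserve, genotype
    inherited and possibly mutated); the parent is marked done and dies.
    Below the threshold nothing happens and the adult keeps accumulating.
    """
    if ind.stage != "adult":
        raise ValueError("only adults reproduce")
    threshold = reproduction_threshold(ind.W_max, constants)
    if ind.E_r < threshold:
        return []
    cs = clutch_mass(ind.W_max)
    egg_mass = cs / N_EGGS
    genotypes = mutate_genotypes(np.full(N_EGGS, ind.W_max), rng)
    reserve = starter_reserve(egg_mass, constants)
    ind.E_r -= threshold
    ind.repro_done = True
    return [
        Individual(
            id=next_id + k,
            stage="juvenile",
            W=egg_mass,
            W_max=genotypes[k],
            E_r=reserve,
            location=ind.location,
        )
        for k in range(N_EGGS)
    ]


def pay_bmr(E_r, W, intake=0.0):
    """Apply consumption then the daily basal-metabolic charge.

    Returns ``(E_r_after, alive)``.  An individual whose reserve (including
    today's intake) cannot cover one day of basal metabolism starves and
    dies; survivors carry the remainder forward.  Vectorised.
    """
    E_r = np.asarray(E_r, dtype=float)
    cost = SECONDS_PER_DAY * basal_metabolic_power(W)
    after = E_r + intake - cost
    alive = after >= 0.0
    if after.ndim == 0:
        return float(after), bool(alive)
    return after, alive


def grow_and_mature(
    W,
    W_max,
    E_r,
    constants: AllometryConstants = AllometryConstants(),
):
    """Juvenile growth for one day, limited by energy, then maturation check.

    The ontogenetic-model increment is capped by what the reserve can pay
    at the tissue energy density; the invested energy leaves the reserve.
    Returns ``(W_after, E_r_after, matured)`` with maturation at 99 % of
    the genotype.  Vectorised.
    """
    W = np.asarray(W, dtype=float)
    E_r = np.asarray(E_r, dtype=float)
    dW_target = growth_increment(W, W_max, 1.0, constants.growth_coefficient)
    dW = np.minimum(dW_target, np.maximum(E_r, 0.0) / constants.tissue_energy_density)
    W_after = W + dW
    E_after = E_r - dW * constants.tissue_energy_density
    matured = W_after >= 0.99 * np.asarray(W_max, dtype=float)
    if W_after.ndim == 0:
        return float(W_after), float(E_after), bool(matured)
    return W_after, E_after, matured
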