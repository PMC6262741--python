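"""Simulation engine: initialisation, the daily scheduler, immigration, runs.

The population is held as a structure of NumPy arrays (one row per living
consumer) so that each phase of the day — scramble consumption, basal
metabolism, movement, growth/maturation, reproduction, resource regrowth,
immigration — is applied to everyone at once.  The per-individual rules are
those of :mod:`allosim.agents`; this module only orchestrates them.

Daily event order (identical for both life stages except for the last step):

1. scramble consumption per cell, capped by each individual's daily ingestion
2. basal metabolic charge; consumers that cannot pay starve
3. movement: the cell-level moving probability compares the resources the cell
   held at the start of the day with the pooled daily demand of its surviving
   occupants (a cell that could feed everyone sends no one away); each survivor
   draws independently, movers search the richest reachable cell and pay for
   the searched area
4. juveniles grow and possibly mature; adults above the reproduction
   threshold produce their single clutch and die
5. logistic resource regrowth in every suitable cell
6. at most one immigrant arrives (Bernoulli with rate q)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import agents
from .agents import N_EGGS
from .allometry import (
    SECONDS_PER_DAY,
    basal_metabolic_power,
    clutch_mass,
    growth_increment,
    max_daily_ingestion,
    movement_cost_rate,
    searching_radius,
)
from .config import SimulationConfig
from .landscape import Landscape, generate_landscape
from .observers import distribution_moments, occupancy, variability
from .resource import logistic_update

__all__ = ["Population", "SimulationState", "RunResult", "initialize", "immigrate", "step_day", "run"]

log = logging.getLogger("allosim.engine")

#: log10 bounds of the founder/immigrant genotype distribution (10**u, u uniform)
LOG10_W_BOUNDS = (-5.0, -2.522878745)

#: jitter amplitude (J) used to break exact resource ties uniformly at random
_TIE_EPS = 1e-9

#: movers processed per block when choosing destinations (bounds memory)
_MOVER_BLOCK = 4096


@dataclass
class Population:
    """Structure-of-arrays population state; one row per living consumer."""

    ids: np.ndarray
    W: np.ndarray
    W_max: np.ndarray
    E_r: np.ndarray
    cell: np.ndarray  # index into the landscape's suitable-cell arrays
    adult: np.ndarray
    age: np.ndarray
    moves: np.ndarray
    distance: np.ndarray
    reproduced: np.ndarray
    born: np.ndarray  # day of birth (-1 for founders/immigrants)

    @classmethod
    def empty(cls) -> "Population":
        z = np.zeros(0)
        zi = np.zeros(0, dtype=np.int64)
        zb = np.zeros(0, dtype=bool)
        return cls(zi.copy(), z.copy(), z.copy(), z.copy(), zi.copy(), zb.copy(),
                   zi.copy(), zi.copy(), z.copy(), zb.copy(), zi.copy())

    def __len__(self) -> int:
        return len(self.ids)

    def keep(self, mask: np.ndarray) -> None:
        for name in ("ids", "W", "W_max", "E_r", "cell", "adult", "age", "moves",
                     "distance", "reproduced", "born"):
            setattr(self, name, getattr(self, name)[mask])

    def append(self, other: "Population") -> None:
        for name in ("ids", "W", "W_max", "E_r", "cell", "adult", "age", "moves",
                     "distance", "reproduced", "born"):
            setattr(self, name, np.concatenate([getattr(self, name), getattr(other, name)]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "stage": np.where(self.adult, "adult", "juvenile"),
                "W": self.W,
                "W_max": self.W_max,
                "E_r": self.E_r,
                "cell": self.cell,
                "age": self.age,
                "moves": self.moves,
                "distance": self.distance,
                "reproduced": self.reproduced,
            }
        )


@dataclass
class SimulationState:
    config: SimulationConfig
    landscape: Landscape
    pop: Population
    rng: np.random.Generator
    day: int = 0
    next_id: int = 0
    extinct: bool = False
    ever_empty: bool = False
    # (id, born, moves, distance, reproduced) records of dead window-born consumers
    cohort_records: list[tuple] = field(default_factory=list)
    audit_log: list[dict] = field(default_factory=list)

    def _take_ids(self, n: int) -> np.ndarray:
        ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += n
        return ids


def _sample_adults(state: SimulationState, n: int) -> Population:
    """Founder/immigrant adults: log-uniform genotype, first-day reserve."""
    rng = state.rng
    u = rng.uniform(*LOG10_W_BOUNDS, size=n)
    W_max = 10.0**u
    reserve = agents.starter_reserve(W_max, state.config.allometry)
    return Population(
        ids=state._take_ids(n),
        W=W_max.copy(),
        W_max=W_max,
        E_r=np.asarray(reserve, dtype=float).reshape(n),
        cell=rng.integers(state.landscape.n_suitable, size=n),
        adult=np.ones(n, dtype=bool),
        age=np.zeros(n, dtype=np.int64),
        moves=np.zeros(n, dtype=np.int64),
        distance=np.zeros(n),
        reproduced=np.zeros(n, dtype=bool),
        born=np.full(n, -1, dtype=np.int64),
    )


def initialize(cfg: SimulationConfig) -> SimulationState:
    """Fresh state: resource at carrying capacity, founding adults placed.

    Each founder's genotype is 10**u with u uniform on [-5, -2.522878745]
    (0.01 g to 3 g, equal weight per order of magnitude, hence right-skewed
    on the linear scale), mass already at the genotype, and a reserve
    covering the first day's basal metabolism and movement.
    """
    land = generate_landscape(cfg.landscape)
    state = SimulationState(
        config=cfg,
        landscape=land,
        pop=Population.empty(),
        rng=np.random.default_rng(cfg.seed),
    )
    state.pop = _sample_adults(state, cfg.n_init)
    return state


def immigrate(state: SimulationState) -> float:
    """With probability q, one adult drawn as at initialisation arrives.

    Returns the reserve energy added (an external input to the ledger).
    """
    q = state.config.q
    if q > 0 and state.rng.random() < q:
        newcomer = _sample_adults(state, 1)
        state.pop.append(newcomer)
        return float(newcomer.E_r.sum())
    return 0.0


def _record_dead_cohort(state: SimulationState, mask: np.ndarray, window_start: int) -> None:
    pop = state.pop
    sel = mask & (pop.born >= window_start)
    if not sel.any():
        return
    for i in np.flatnonzero(sel):
        state.cohort_records.append(
            (int(pop.ids[i]), int(pop.born[i]), int(pop.moves[i]),
             float(pop.distance[i]), bool(pop.reproduced[i]))
        )


def step_day(state: SimulationState) -> None:
    """Advance the simulation by one day (see module docstring for the order)."""
    cfg = state.config
    consts = cfg.allometry
    land = state.landscape
    pop = state.pop
    rng = state.rng
    n = len(pop)
    n_suit = land.n_suitable
    window_start = cfg.t_max - cfg.observers.cohort_window
    audit: dict[str, float] = {}
    if cfg.audit:
        audit["day"] = state.day
        audit["E_pop_start"] = float(pop.E_r.sum())
        audit["R_start"] = float(land.resource.sum())
        for key in ("intake", "bmr_paid", "starved_removed", "move_cost",
                    "growth_invest", "repro_invest", "parents_removed", "endow_added"):
            audit[key] = 0.0

    intake = np.zeros(n)
    if n:
        # -- 1. scramble consumption -----------------------------------
        demand = max_daily_ingestion(pop.W, consts.t_f)
        R_pre = land.resource.copy()  # Eq. 3 compares demand with what was present
        sum_demand = np.bincount(pop.cell, weights=demand, minlength=n_suit)
        consumable = np.maximum(land.resource - cfg.landscape.e_nc, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sum_demand > consumable,
                             consumable / np.where(sum_demand > 0, sum_demand, 1.0), 1.0)
        intake = demand * ratio[pop.cell]
        land.resource -= np.bincount(pop.cell, weights=intake, minlength=n_suit)

        # -- 2. basal metabolism ---------------------------------------
        bmr = SECONDS_PER_DAY * basal_metabolic_power(pop.W)
        E_after = pop.E_r + intake - bmr
        alive = E_after >= 0.0
        if cfg.audit:
            audit["intake"] = float(intake.sum())
            audit["bmr_paid"] = float(bmr[alive].sum())
            audit["starved_removed"] = float((pop.E_r + intake)[~alive].sum())
        pop.E_r = np.where(alive, E_after, pop.E_r)
        _record_dead_cohort(state, ~alive, window_start)

        # -- 3. movement ------------------------------------------------
        demand_alive = np.where(alive, demand, 0.0)
        sum_imax = np.bincount(pop.cell, weights=demand_alive, minlength=n_suit)
        p_cell = agents.move_probability(R_pre, sum_imax)
        movers = alive & (rng.random(n) < p_cell[pop.cell])
        move_cost_total = 0.0
        if movers.any():
            mi = np.flatnonzero(movers)
            c_m = movement_cost_rate(pop.W[mi])
            t_m = np.minimum(consts.t_m_cap, pop.E_r[mi] / c_m)
            v, d_per = agents.movement_traits(pop.W[mi], cfg.mode, rng)
            rad = searching_radius(d_per, v * t_m)
            distmat = land.distance_matrix()
            R = land.resource
            for lo in range(0, len(mi), _MOVER_BLOCK):
                blk = slice(lo, lo + _MOVER_BLOCK)
                sub = mi[blk]
                D = distmat[pop.cell[sub]]
                elig = D <= np.asarray(rad)[blk, None]
                score = np.where(elig, R[None, :] + rng.random(D.shape) * _TIE_EPS, -np.inf)
                dest = np.argmax(score, axis=1)
                pop.distance[sub] += D[np.arange(len(sub)), dest]
                pop.cell[sub] = dest
            cost = t_m * c_m
            pop.E_r[mi] -= cost
            pop.moves[mi] += 1
            move_cost_total = float(cost.sum())
        if cfg.audit:
            audit["move_cost"] = move_cost_total

        # -- 4. growth / maturation and reproduction -------------------
        juv = alive & ~pop.adult
        growth_invest = 0.0
        if juv.any():
            ji = np.flatnonzero(juv)
            dW = np.minimum(
                growth_increment(pop.W[ji], pop.W_max[ji], 1.0, consts.growth_coefficient),
                np.maximum(pop.E_r[ji], 0.0) / consts.tissue_energy_density,
            )
            pop.W[ji] += dW
            pop.E_r[ji] -= dW * consts.tissue_energy_density
            growth_invest = float(dW.sum() * consts.tissue_energy_density)
            pop.adult[ji[pop.W[ji] >= 0.99 * pop.W_max[ji]]] = True

        repro = alive & pop.adult & ~pop.reproduced
        offspring = None
        repro_invest = 0.0
        parents_removed = 0.0
        if repro.any():
            ri = np.flatnonzero(repro)
            threshold = agents.reproduction_threshold(pop.W_max[ri], consts)
            ready = pop.E_r[ri] >= threshold
            ri = ri[ready]
            if ri.size:
                threshold = np.asarray(threshold)[ready]
                pop.E_r[ri] -= threshold
                pop.reproduced[ri] = True
                repro_invest = float(np.sum(threshold))
                parents_removed = float(pop.E_r[ri].sum())
                egg_mass = np.repeat(clutch_mass(pop.W_max[ri]) / cfg.n_eggs, cfg.n_eggs)
                genotypes = agents.mutate_genotypes(
                    np.repeat(pop.W_max[ri], cfg.n_eggs), rng, cfg.mutation_rate
                )
                n_off = len(egg_mass)
                offspring = Population(
                    ids=state._take_ids(n_off),
                    W=egg_mass,
                    W_max=genotypes,
                    E_r=np.asarray(agents.starter_reserve(egg_mass, consts), dtype=float),
                    cell=np.repeat(pop.cell[ri], cfg.n_eggs),
                    adult=np.zeros(n_off, dtype=bool),
                    age=np.zeros(n_off, dtype=np.int64),
                    moves=np.zeros(n_off, dtype=np.int64),
                    distance=np.zeros(n_off),
                    reproduced=np.zeros(n_off, dtype=bool),
                    born=np.full(n_off, state.day, dtype=np.int64),
                )
        if cfg.audit:
            audit["growth_invest"] = growth_invest
            audit["repro_invest"] = repro_invest
            audit["parents_removed"] = parents_removed
            audit["endow_added"] = float(offspring.E_r.sum()) if offspring is not None else 0.0

        # -- 5. deaths and births --------------------------------------
        done = pop.adult & pop.reproduced
        _record_dead_cohort(state, done, window_start)
        survivors = alive & ~done
        pop.age[survivors] += 1
        pop.keep(survivors)
        if offspring is not None:
            pop.append(offspring)

    # -- 6. resource regrowth ------------------------------------------
    land.resource = logistic_update(land.resource, cfg.landscape.resource_r, cfg.landscape.resource_K)

    # -- 7. immigration -------------------------------------------------
    immigrant_energy = immigrate(state)

    if len(pop) == 0:
        state.ever_empty = True

    if cfg.audit:
        audit["immigrant_added"] = immigrant_energy
        audit["E_pop_end"] = float(pop.E_r.sum())
        audit["R_end"] = float(land.resource.sum())
        state.audit_log.append(audit)

    state.day += 1


@dataclass
class RunResult:
    """All artifacts of one run, plus the summary row used by the analysis."""

    config: SimulationConfig
    extinct: bool
    final_population: pd.DataFrame
    timeseries: pd.DataFrame
    panel: pd.DataFrame  # biomass (J) of sampled patches x sample days
    panel_mass: pd.DataFrame  # same panel in kg
    occupancy_samples: list[int]
    snapshots: dict[int, np.ndarray]
    cohort: pd.DataFrame
    audit: pd.DataFrame
    n_suitable: int

    @property
    def occupancy(self) -> float:
        if not self.occupancy_samples:
            return 0.0
        return occupancy(self.occupancy_samples, self.n_suitable)

    def stability(self, alpha_form: str = "wang-loreau"):
        return variability(self.panel, alpha_form=alpha_form)

    def summary(self) -> dict[str, Any]:
        """One manifest row: design cell, weight moments, occupancy, stability."""
        cfg = self.config
        row: dict[str, Any] = {
            "mode": cfg.mode,
            "nnd": cfg.landscape.nnd,
            "r": cfg.landscape.resource_r,
            "q": cfg.q,
            "seed": cfg.seed,
            "extinct": self.extinct,
            "n_final": int(len(self.final_population)),
        }
        moments = distribution_moments(self.final_population["W_max"].to_numpy())
        row.update({f"wmax_{k}": v for k, v in moments.items()})
        row["occupancy"] = self.occupancy
        ts = self.timeseries
        tail = ts[ts["day"] >= cfg.t_max - cfg.observers.panel_window]
        row["resource_abundance"] = float(tail["mean_resource"].mean()) if len(tail) else np.nan
        row["resource_variance"] = float(tail["mean_resource"].var(ddof=1)) if len(tail) > 1 else np.nan
        row["consumer_abundance"] = float((tail["n_adults"] + tail["n_juveniles"]).mean()) if len(tail) else np.nan
        try:
            stab = self.stability()
            row["alpha_cv"], row["gamma_cv"], row["beta2"] = stab.alpha_cv, stab.gamma_cv, stab.beta2
        except ValueError:
            row["alpha_cv"] = row["gamma_cv"] = row["beta2"] = np.nan
        return row


def run(cfg: SimulationConfig) -> RunResult:
    """Execute a full run of ``t_max`` days and collect every observer output.

    A run with q = 0 stops as soon as the population is gone (nothing can
    rescue it); with immigration it always completes.  Extinction is an
    empty final population, and such runs are flagged for exclusion from
    downstream analyses.
    """
    state = initialize(cfg)
    obs = cfg.observers
    land = state.landscape

    sample_days = set(range(cfg.t_max - obs.panel_window, cfg.t_max + 1, obs.panel_every))
    panel_idx = state.rng.choice(
        land.n_suitable, size=min(obs.panel_patches, land.n_suitable), replace=False
    )
    panel_cols: dict[int, np.ndarray] = {}
    occupancy_samples: list[int] = []
    ts_rows: list[dict] = []
    snapshots: dict[int, np.ndarray] = {}
    window_start = cfg.t_max - obs.cohort_window

    def record_timeseries(day: int) -> None:
        pop = state.pop
        moments = distribution_moments(pop.W_max) if len(pop) else distribution_moments([])
        ts_rows.append(
            {
                "day": day,
                "mean_resource": float(land.resource.mean()),
                "n_adults": int(pop.adult.sum()),
                "n_juveniles": int((~pop.adult).sum()),
                "wmax_mean": moments["mean"],
                "wmax_cv": moments["cv"],
                "wmax_skewness": moments["skewness"],
                "wmax_kurtosis": moments["kurtosis"],
            }
        )

    def record_samples(day: int) -> None:
        if day in sample_days:
            biomass = np.bincount(
                state.pop.cell, weights=state.pop.W, minlength=land.n_suitable
            )
            panel_cols[day] = biomass[panel_idx]
            occupied = np.bincount(state.pop.cell, minlength=land.n_suitable) > 0
            occupancy_samples.append(int(occupied.sum()))
        if day % obs.snapshot_every == 0 and len(state.pop):
            w = state.pop.W_max
            if len(w) > obs.snapshot_max:
                w = state.rng.choice(w, size=obs.snapshot_max, replace=False)
            snapshots[day] = np.array(w)

    record_timeseries(0)
    record_samples(0)
    for _ in range(cfg.t_max):
        step_day(state)
        if state.day % obs.timeseries_every == 0 or state.day == cfg.t_max:
            record_timeseries(state.day)
        record_samples(state.day)
        if state.day % 1_000 == 0:
            log.info(
                "seed=%s day=%s/%s n=%s mean_R=%.0f",
                cfg.seed, state.day, cfg.t_max, len(state.pop), land.resource.mean(),
            )
        if len(state.pop) == 0 and cfg.q == 0:
            log.info("seed=%s extinct at day %s", cfg.seed, state.day)
            break

    # close the cohort: survivors born in the window
    pop = state.pop
    for i in np.flatnonzero(pop.born >= window_start):
        state.cohort_records.append(
            (int(pop.ids[i]), int(pop.born[i]), int(pop.moves[i]),
             float(pop.distance[i]), bool(pop.reproduced[i]))
        )
    cohort = pd.DataFrame(
        state.cohort_records, columns=["id", "born", "moves", "distance", "reproduced"]
    )
    if len(cohort) > obs.cohort_n:
        keep = state.rng.choice(len(cohort), size=obs.cohort_n, replace=False)
        cohort = cohort.iloc[np.sort(keep)].reset_index(drop=True)

    panel = pd.DataFrame(panel_cols, index=pd.Index(panel_idx, name="patch"))
    mass_panel = panel.copy()
    panel = panel * cfg.allometry.tissue_energy_density  # kg -> J
    extinct = len(state.pop) == 0

    return RunResult(
        config=cfg,
        extinct=extinct,
        final_population=state.pop.to_frame(),
        timeseries=pd.DataFrame(ts_rows),
        panel=panel,
        panel_mass=mass_panel,
        occupancy_samples=occupancy_samples,
        snapshots=snapshots,
        cohort=cohort,
        audit=pd.DataFrame(state.audit_log),
        n_suitable=land.n_suitable,
    )
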