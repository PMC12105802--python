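"""Grid Tobacco Town: a daily-step agent-based model of cigarette purchasing.

The world is a rectangular grid of land plots.  A plot can house any number
of human agents but at most one *object* — either a cigarette outlet or a
workplace.  Each human commutes daily between home and work along a
precomputed route in which every step moves to one of the 8 surrounding
cells (Moore neighbourhood) and strictly decreases the Euclidean distance
to the target.  A smoker whose cigarette inventory has dropped below their
daily smoking rate detours to the outlet nearest their route during the
morning trip and buys the number of packs that minimises the per-pack cost

    C_r(q) = (d_r/s + gamma) * w * zeta + d_r * f/e + (pack cost of q)

— the value of commuting-time lost, the fuel for the detour, and the packs
themselves.  One pack holds 20 cigarettes.  The observed model output is
the *mean spatial purchase*: per plot, the mean number of cigarettes bought
that day by the agents who live there.

Wages enter the purchase in two ways: the value-of-time term above, and a
per-trip purchase budget (a small share of the annual wage) that caps how
many packs an agent can buy at once.  The budget is the channel through
which wage dispersion shows up in the purchase dynamics — with a flat pack
price the amortised per-pack cost always favours the largest feasible
quantity, so only the wage-dependent cap differentiates agents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .indices import MISSING

__all__ = [
    "ModelConfig",
    "RegionDist",
    "HumanAgent",
    "TownState",
    "initialize_town",
    "plan_commute_path",
    "purchase_cost",
    "choose_pack_quantity",
    "step_day",
    "mean_spatial_purchase",
    "run_model",
    "simulate_purchases",
]

CIGS_PER_PACK = 20


class RegionDist(BaseModel):
    """Normal distribution with a region-dependent spread (west vs east)."""

    model_config = ConfigDict(extra="forbid")

    mean: float
    sd_west: float = Field(ge=0)
    sd_east: float = Field(ge=0)


class ModelConfig(BaseModel):
    """Full model configuration; defaults reproduce the reference set-up:

    a 32x32 grid with 302 human agents, 85 outlets and up to 1024
    workplaces (truncated to the cells left free), 30 simulated days with
    days 1 and 30 recorded, wages ~ N(50000, 5000 west / 500 east) per
    year and smoking rates ~ N(20, 10 west / 2 east) cigarettes per day.
    """

    model_config = ConfigDict(extra="forbid")

    grid_width: int = Field(default=32, gt=0)
    grid_height: int = Field(default=32, gt=0)
    n_agents: int = Field(default=302, gt=0)
    n_outlets: int = Field(default=85, gt=0)
    n_workplaces: int = Field(default=1024, gt=0)

    wage_dist: RegionDist = RegionDist(mean=50_000.0, sd_west=5_000.0, sd_east=500.0)
    rate_dist: RegionDist = RegionDist(mean=20.0, sd_west=10.0, sd_east=2.0)

    pack_price: float = Field(default=8.0, gt=0)      # currency per pack (q = 1)
    bulk_prices: Optional[dict[int, float]] = None    # optional per-pack price by q
    fuel_price: float = Field(default=1.5, ge=0)      # currency per litre
    fuel_efficiency: float = Field(default=10.0, gt=0)  # distance units per litre
    travel_speed: float = Field(default=30.0, gt=0)   # distance units per hour
    gamma: float = Field(default=0.1, ge=0)           # hours per purchase stop
    zeta: float = Field(default=1.0 / 2080.0, ge=0)   # annual wage -> hourly value of time

    q_max: int = Field(default=5, ge=1)               # max packs per purchase
    # Share of the annual wage available per purchase trip (None = no cap).
    # Default 7.2e-4 is ~36 currency units at the mean wage: 4.5 packs at
    # the default pack price, so the cap binds around the distribution mean.
    purchase_budget_frac: Optional[float] = 7.2e-4

    days: int = Field(default=30, gt=0)
    record_days: tuple[int, ...] = (1, 30)
    seed: int = 0

    @model_validator(mode="after")
    def _check_feasible(self) -> "ModelConfig":
        cells = self.grid_width * self.grid_height
        if self.n_outlets >= cells:
            raise ValueError(
                f"{self.n_outlets} outlets cannot fit on {cells} cells "
                "with room left for homes"
            )
        if "record_days" not in self.model_fields_set:
            # default recording points clamp to the simulated horizon
            object.__setattr__(
                self, "record_days", tuple(sorted({min(d, self.days) for d in self.record_days}))
            )
        if any(d < 1 or d > self.days for d in self.record_days):
            raise ValueError(f"record_days {self.record_days} outside 1..{self.days}")
        return self

    def pack_unit_price(self, q: int) -> float:
        """Per-pack price when buying ``q`` packs (bulk schedule if any)."""
        if self.bulk_prices:
            return self.bulk_prices.get(q, self.pack_price)
        return self.pack_price


@dataclass
class HumanAgent:
    home: tuple[int, int]
    work: tuple[int, int]
    home_work_route: list[tuple[int, int]]
    nearest_outlet: int          # index into TownState.outlets
    d_r: float                   # out-and-back detour distance, cell-edge units
    wage: float                  # currency per year
    smoking_rate: int            # cigarettes per day
    inventory: float = 0.0       # cigarettes currently owned
    purchased_today: float = 0.0
    transport_type: str = "car"


@dataclass
class TownState:
    config: ModelConfig
    outlets: list[tuple[int, int]]
    workplaces: list[tuple[int, int]]
    agents: list[HumanAgent]
    day: int = 0
    purchase_grids: dict[int, np.ndarray] = dc_field(default_factory=dict)

    # vectorised per-agent views kept in sync by step_day / simulate_purchases
    def agent_arrays(self) -> dict[str, np.ndarray]:
        return {
            "wages": np.array([a.wage for a in self.agents], dtype=float),
            "smoking_rates": np.array([a.smoking_rate for a in self.agents], dtype=float),
            "d_r": np.array([a.d_r for a in self.agents], dtype=float),
            "home_x": np.array([a.home[0] for a in self.agents], dtype=np.intp),
            "home_y": np.array([a.home[1] for a in self.agents], dtype=np.intp),
        }

    @property
    def resident_counts(self) -> np.ndarray:
        counts = np.zeros((self.config.grid_height, self.config.grid_width), dtype=int)
        for a in self.agents:
            counts[a.home[1], a.home[0]] += 1
        return counts

    @property
    def occupied(self) -> np.ndarray:
        return self.resident_counts > 0


def plan_commute_path(
    start: tuple[int, int],
    goal: tuple[int, int],
    rng: np.random.Generator,
    grid_shape: Optional[tuple[int, int]] = None,
) -> list[tuple[int, int]]:
    """Random strictly-descending path from ``start`` to ``goal``.

    Each step moves to one of the 8 Moore neighbours that strictly
    decreases the Euclidean distance to ``goal`` (chosen uniformly among
    the qualifying neighbours), which guarantees termination.  Returns the
    cells visited after ``start``; empty when already at the goal.
    """
    path: list[tuple[int, int]] = []
    cur = start
    gx, gy = goal
    while cur != goal:
        cx, cy = cur
        d2 = (cx - gx) ** 2 + (cy - gy) ** 2
        options = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                nx, ny = cx + dx, cy + dy
                if grid_shape is not None:
                    h, w = grid_shape
                    if not (0 <= nx < w and 0 <= ny < h):
                        continue
                if (nx - gx) ** 2 + (ny - gy) ** 2 < d2:
                    options.append((nx, ny))
        cur = options[rng.integers(len(options))]
        path.append(cur)
    return path


def _chebyshev(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def _nearest_outlet(route_cells: Sequence[tuple[int, int]],
                    outlets: Sequence[tuple[int, int]]) -> tuple[int, float]:
    """Outlet minimising the route->outlet Chebyshev detour; d_r is the
    out-and-back distance (twice the minimum over route cells)."""
    best_idx, best = 0, math.inf
    for idx, o in enumerate(outlets):
        d = min(_chebyshev(c, o) for c in route_cells)
        if d < best:
            best_idx, best = idx, d
    return best_idx, 2.0 * best


def _draw_region_values(
    rng: np.random.Generator,
    dist: RegionDist,
    west_mask: np.ndarray,
) -> np.ndarray:
    sd = np.where(west_mask, dist.sd_west, dist.sd_east)
    return dist.mean + sd * rng.standard_normal(west_mask.shape[0])


def initialize_town(config: ModelConfig, seed: Optional[int] = None) -> TownState:
    """Build a town layout: outlets, homes, workplaces, routes and draws.

    Outlets are placed uniformly on distinct cells; homes are drawn
    uniformly over the remaining object-free cells (plots may house several
    agents); the requested workplace count is truncated to the cells still
    free of outlets and homes, so homes always sit on object-free plots.
    All structure is a function of the layout seed alone, so the spatial
    set-up can be held fixed across ensemble runs.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w, h = config.grid_width, config.grid_height
    cells = [(x, y) for y in range(h) for x in range(w)]

    outlet_idx = rng.choice(len(cells), size=config.n_outlets, replace=False)
    outlets = [cells[i] for i in outlet_idx]
    outlet_set = set(outlets)

    non_outlet = [c for c in cells if c not in outlet_set]
    if not non_outlet:
        raise ValueError("no cells left for homes after outlet placement")
    homes = [non_outlet[i] for i in rng.integers(len(non_outlet), size=config.n_agents)]
    home_set = set(homes)

    free = [c for c in non_outlet if c not in home_set]
    n_work = min(config.n_workplaces, len(free))
    if n_work == 0:
        raise ValueError("no free cells left for workplaces")
    work_idx = rng.choice(len(free), size=n_work, replace=False)
    workplaces = [free[i] for i in work_idx]

    west_mask = np.array([hx < w / 2 for hx, _ in homes])
    wages = np.maximum(_draw_region_values(rng, config.wage_dist, west_mask), 1e-9)
    rates = np.maximum(
        np.rint(_draw_region_values(rng, config.rate_dist, west_mask)), 0
    ).astype(int)

    agents = []
    for i, home in enumerate(homes):
        work = workplaces[rng.integers(len(workplaces))]
        route = plan_commute_path(home, work, rng, grid_shape=(h, w))
        route_cells = [home] + route
        outlet_i, d_r = _nearest_outlet(route_cells, outlets)
        agents.append(
            HumanAgent(
                home=home,
                work=work,
                home_work_route=route,
                nearest_outlet=outlet_i,
                d_r=d_r,
                wage=float(wages[i]),
                smoking_rate=int(rates[i]),
            )
        )
    return TownState(config=config, outlets=outlets, workplaces=workplaces, agents=agents)


def purchase_cost(q: int, d_r: float, agent: HumanAgent, config: ModelConfig) -> float:
    """Total cost of buying ``q`` packs at the route-detour distance ``d_r``.

    Travel-time cost (detour time plus the stop itself, valued at the
    agent's hourly wage) + detour fuel + the packs.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    if d_r < 0:
        raise ValueError(f"d_r must be >= 0, got {d_r}")
    time_cost = (d_r / config.travel_speed + config.gamma) * agent.wage * config.zeta
    fuel_cost = d_r * config.fuel_price / config.fuel_efficiency
    pack_cost = q * config.pack_unit_price(q)
    return time_cost + fuel_cost + pack_cost


def _affordable_packs(wage: float, config: ModelConfig) -> int:
    if config.purchase_budget_frac is None:
        return config.q_max
    budget = wage * config.purchase_budget_frac
    return max(1, min(config.q_max, int(budget // config.pack_price)))


def choose_pack_quantity(agent: HumanAgent, d_r: float, config: ModelConfig) -> int:
    """Quantity minimising the per-pack cost ``C_r(q)/q`` over feasible q.

    Feasible quantities run from 1 up to the smaller of ``q_max`` and the
    agent's wage-linked per-trip budget; ties break toward the smallest q.
    """
    q_hi = _affordable_packs(agent.wage, config)
    best_q, best = 1, math.inf
    for q in range(1, q_hi + 1):
        per_pack = purchase_cost(q, d_r, agent, config) / q
        if per_pack < best - 1e-12:
            best_q, best = q, per_pack
    return best_q


def step_day(state: TownState, rng: Optional[np.random.Generator] = None) -> TownState:
    """Advance the town by one day (in place; returns the state).

    Each agent commutes home->work along its stored route; a smoker whose
    inventory is below their daily rate detours to their nearest outlet on
    the way and buys the cost-optimal quantity; daily consumption is drawn
    down after any purchase; the evening commute retraces the same route.
    """
    cfg = state.config
    grid = np.zeros((cfg.grid_height, cfg.grid_width), dtype=float)
    for agent in state.agents:
        agent.purchased_today = 0.0
        if agent.smoking_rate > 0 and agent.inventory < agent.smoking_rate:
            q = choose_pack_quantity(agent, agent.d_r, cfg)
            bought = CIGS_PER_PACK * q
            agent.inventory += bought
            agent.purchased_today = bought
            grid[agent.home[1], agent.home[0]] += bought
        agent.inventory = max(0.0, agent.inventory - agent.smoking_rate)
    state.day += 1
    counts = state.resident_counts
    with np.errstate(invalid="ignore"):
        state.purchase_grids[state.day] = np.where(
            counts > 0, grid / np.maximum(counts, 1), MISSING
        )
    return state


def mean_spatial_purchase(state: TownState, day: int) -> np.ndarray:
    """Mean cigarettes purchased per resident on ``day``, per plot.

    Plots with no residents carry the missing sentinel.
    """
    if day not in state.purchase_grids:
        raise ValueError(f"day {day} not recorded; have {sorted(state.purchase_grids)}")
    return state.purchase_grids[day]


# ---------------------------------------------------------------------------
# vectorised simulation used by the ensemble pipeline

def _vector_pack_quantities(
    wages: np.ndarray, d_r: np.ndarray, config: ModelConfig
) -> np.ndarray:
    """Per-agent optimal purchase quantity, vectorised over agents.

    The cost parameters are static over the run, so each agent's quantity
    choice is fixed and can be computed once.  Mirrors
    :func:`choose_pack_quantity` exactly (argmin of per-pack cost over the
    budget-feasible range, ties to the smallest q).
    """
    qs = np.arange(1, config.q_max + 1, dtype=float)[:, None]
    time_cost = (d_r / config.travel_speed + config.gamma) * wages * config.zeta
    fuel_cost = d_r * config.fuel_price / config.fuel_efficiency
    unit = np.array([config.pack_unit_price(int(q)) for q in qs[:, 0]])[:, None]
    per_pack = (time_cost + fuel_cost) / qs + unit          # (q_max, n_agents)
    if config.purchase_budget_frac is not None:
        budget = wages * config.purchase_budget_frac
        afford = np.maximum(1, np.minimum(config.q_max,
                                          (budget // config.pack_price).astype(int)))
        per_pack = np.where(qs > afford[None, :], np.inf, per_pack)
    # argmin returns the first (smallest q) minimiser; guard float ties
    rounded = np.round(per_pack, 12)
    return np.argmin(rounded, axis=0) + 1


def simulate_purchases(
    state: TownState,
    wages: np.ndarray,
    rates: np.ndarray,
    days: Optional[int] = None,
    record_days: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Run the purchase dynamics on a fixed layout with given inputs.

    ``wages`` and ``rates`` override the agents' drawn values (one entry
    per agent; wages truncated positive, rates rounded and clipped at 0).
    Returns mean-spatial-purchase grids stacked as (n_record, H, W).  The
    layout (homes, routes, detours) is untouched, so an ensemble can reuse
    one :class:`TownState` across thousands of runs.
    """
    cfg = state.config
    days = cfg.days if days is None else days
    record_days = list(cfg.record_days if record_days is None else record_days)
    n = len(state.agents)
    wages = np.maximum(np.asarray(wages, dtype=float).reshape(-1), 1e-9)
    rates = np.maximum(np.rint(np.asarray(rates, dtype=float).reshape(-1)), 0.0)
    if wages.shape[0] != n or rates.shape[0] != n:
        raise ValueError(
            f"input row length mismatch: {wages.shape[0]}/{rates.shape[0]} values "
            f"for {n} agents"
        )

    arrs = state.agent_arrays()
    qstar = _vector_pack_quantities(wages, arrs["d_r"], cfg)
    flat_home = arrs["home_y"] * cfg.grid_width + arrs["home_x"]
    counts = np.bincount(flat_home, minlength=cfg.grid_height * cfg.grid_width)

    inv = np.zeros(n)
    smoker = rates > 0
    out = np.full((len(record_days), cfg.grid_height * cfg.grid_width), MISSING)
    for day in range(1, days + 1):
        buy = smoker & (inv < rates)
        bought = np.where(buy, CIGS_PER_PACK * qstar, 0.0)
        inv = np.maximum(0.0, inv + bought - rates)
        if day in record_days:
            totals = np.bincount(flat_home, weights=bought,
                                 minlength=counts.shape[0])
            idx = record_days.index(day)
            out[idx, counts > 0] = totals[counts > 0] / counts[counts > 0]
    return out.reshape(len(record_days), cfg.grid_height, cfg.grid_width)


def run_model(
    config: ModelConfig,
    input_row: Optional[dict] = None,
    layout_seed: int = 0,
    run_seed: int = 0,
    record_days: Optional[Sequence[int]] = None,
    town: Optional[TownState] = None,
) -> np.ndarray:
    """One full model run: layout, input overrides, daily dynamics.

    ``input_row`` may override per-agent ``wages`` and ``smoking_rates``
    (the ensemble sample row); all layout structure comes from
    ``layout_seed`` so paired ensembles share it.  ``run_seed`` seeds any
    within-run stochasticity (the purchase dynamics themselves are
    deterministic given layout and inputs, so paired runs with equal seeds
    are exactly comparable).  Returns (n_record, H, W) grids of mean
    spatial purchases.
    """
    if town is None:
        town = initialize_town(config, seed=layout_seed)
    arrs = town.agent_arrays()
    wages = arrs["wages"]
    rates = arrs["smoking_rates"]
    if input_row:
        unknown = set(input_row) - {"wages", "smoking_rates"}
        if unknown:
            raise ValueError(f"unknown input columns: {sorted(unknown)}")
        wages = input_row.get("wages", wages)
        rates = input_row.get("smoking_rates", rates)
    return simulate_purchases(town, wages, rates, record_days=record_days)
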