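"""Serial-dilution PCR recovery of one target clone from a pool.

A pool of ~2000 clones is grown, diluted to a known cell density, and split
over 16-32 culture tubes; PCR screening finds a tube that received at least
one target cell, and the process repeats from that tube at higher dilution
until single colonies can be plated.  The planner gives the exact success
probabilities of each round; the simulator is its stochastic twin.

With target frequency f and (rounded) c cells per tube,
p_tube = 1 - (1 - f)^c and p_round = 1 - (1 - p_tube)^n_tubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import SnrcmError, derive_seed

PLATING_DILUTION_FACTOR = 1e-7  # final round: plate at this dilution for single colonies


@dataclass
class DilutionParams:
    od_to_cells_per_ml: float = 8.0e8  # cells/ml per OD600 unit
    pool_size: int = 2000
    target_frequency: float | None = None  # default 1/pool_size
    pcr_false_negative: float = 0.0  # per-tube miss probability given >=1 target cell
    poisson_cells: bool = False  # draw per-tube cell counts Poisson(c) instead of exact c

    def __post_init__(self):
        if self.od_to_cells_per_ml <= 0:
            raise SnrcmError("od_to_cells_per_ml must be positive")
        if self.target_frequency is None:
            self.target_frequency = 1.0 / self.pool_size
        if not (0.0 < self.target_frequency <= 1.0):
            raise SnrcmError("target_frequency must be in (0, 1]")


@dataclass
class RoundPlan:
    cells_per_ml: float
    inoculum_volume_ml: float
    n_tubes: int
    expected_cells_per_tube: float
    p_tube_positive: float
    p_round_success: float
    target_frequency: float
    plating: bool = False


@dataclass
class RecoveryOutcome:
    rounds_executed: int
    isolated: bool
    trajectory: list[dict] = field(default_factory=list)
    seed: int = 0


def od_to_cell_density(od600: float, params: DilutionParams | None = None) -> float:
    if od600 < 0:
        raise SnrcmError("OD600 cannot be negative")
    params = params or DilutionParams()
    return od600 * params.od_to_cells_per_ml


def p_tube_positive(target_frequency: float, cells_per_tube: float) -> float:
    c = int(round(cells_per_tube))
    if c < 1:
        return 0.0
    return 1.0 - (1.0 - target_frequency) ** c


def plan_round(cells_per_ml: float, volume_ml: float, n_tubes: int,
               params: DilutionParams | None = None,
               target_frequency: float | None = None, plating: bool = False) -> RoundPlan:
    params = params or DilutionParams()
    if cells_per_ml <= 0 or volume_ml <= 0:
        raise SnrcmError("cells_per_ml and volume_ml must be positive")
    if n_tubes < 1:
        raise SnrcmError("n_tubes must be >= 1")
    f = params.target_frequency if target_frequency is None else target_frequency
    c = cells_per_ml * volume_ml
    p_tube = p_tube_positive(f, c) * (1.0 - params.pcr_false_negative)
    return RoundPlan(
        cells_per_ml=cells_per_ml, inoculum_volume_ml=volume_ml, n_tubes=n_tubes,
        expected_cells_per_tube=c, p_tube_positive=p_tube,
        p_round_success=1.0 - (1.0 - p_tube) ** n_tubes,
        target_frequency=f, plating=plating,
    )


def default_protocol(params: DilutionParams | None = None, n_tubes: int = 16) -> list[RoundPlan]:
    """The standard two-round + plating protocol: pool at 2000 cells/ml,
    100 ul per tube (~200 cells); then 200 cells/ml, 200 ul (~40 cells);
    then plating at 1e-7 dilution.  Between rounds the expected target
    frequency is updated to E[K | K >= 1] / c."""
    params = params or DilutionParams()
    plans = []
    f = params.target_frequency
    for cells_per_ml, volume in ((2000.0, 0.1), (200.0, 0.2)):
        plan = plan_round(cells_per_ml, volume, n_tubes, params, target_frequency=f)
        plans.append(plan)
        c = int(round(plan.expected_cells_per_tube))
        p_any = 1.0 - (1.0 - f) ** c
        if p_any > 0:
            f = min(1.0, (c * f / p_any) / c)
    # plating: single colonies at the 1e-7 dilution are screened individually;
    # each colony is one founder cell, i.e. a "tube" with c = 1
    n_colonies = 24
    plans.append(plan_round(10.0, 0.1, n_colonies, params, target_frequency=f, plating=True))
    return plans


def simulate_round(plan: RoundPlan, target_frequency: float, params: DilutionParams,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One inoculation of n_tubes tubes: per-tube founder cells, target-cell
    counts, and the PCR detection mask.  This is the quantity whose success
    probability plan_round predicts analytically."""
    if params.poisson_cells:
        cells = rng.poisson(plan.expected_cells_per_tube, size=plan.n_tubes)
    else:
        cells = np.full(plan.n_tubes, int(round(plan.expected_cells_per_tube)), dtype=np.int64)
    hits = rng.binomial(cells, min(1.0, target_frequency))
    detected = (hits > 0) & (rng.random(plan.n_tubes) >= params.pcr_false_negative)
    return cells, hits, detected


def simulate_recovery(params: DilutionParams, plans: list[RoundPlan], seed: int,
                      max_attempts_per_round: int = 3) -> RecoveryOutcome:
    """Stochastic twin of the planner: binomial draws of target cells into
    tubes each round, carrying the positive tube's composition forward.

    A round with no positive tube is re-attempted from the same stock (the
    diluted culture is not consumed by an attempt) up to
    max_attempts_per_round times, as a bench scientist would; the analytic
    p_round_success of plan_round refers to a single attempt.
    """
    rng = np.random.default_rng(derive_seed(seed, "recovery"))
    f = params.target_frequency
    trajectory = []
    rounds = 0
    for rnd, plan in enumerate(plans):
        success = False
        for attempt in range(max_attempts_per_round):
            rounds += 1
            cells, hits, detected = simulate_round(plan, f, params, rng)
            trajectory.append({"round": rnd, "attempt": attempt, "tube_hits": hits.tolist(),
                               "n_positive_tubes": int(detected.sum()), "target_frequency": f})
            if detected.any():
                success = True
                break
        if not success:
            return RecoveryOutcome(rounds_executed=rounds, isolated=False,
                                   trajectory=trajectory, seed=seed)
        tube = int(np.argmax(detected))  # first detected tube carried forward
        f = hits[tube] / cells[tube] if cells[tube] else 1.0
    return RecoveryOutcome(rounds_executed=rounds, isolated=True,
                           trajectory=trajectory, seed=seed)
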