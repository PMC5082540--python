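"""Canonical-ensemble Metropolis Monte Carlo and the sequential TI protocol.

The sampler stands in for constrained molecular dynamics: only the
torsional degrees of freedom move, and a Markov chain of single-torsion
moves (Gaussian perturbations plus rare uniform "jump" resamples)
generates Boltzmann-distributed configurations at fixed lambda.

The step-count convention maps 1 ns of the original molecular-dynamics
protocol to 200 000 MC steps with every 10th configuration recorded;
the "10x" long-sampling protocol multiplies the production length by
ten.  Equilibration is 5% of the production length and is discarded.
Per-leg seeds are split from a master seed with
``numpy.random.SeedSequence`` so legs are independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import model_system as ms
from ._kernels import KB, mc_kernel
from .model_system import SoftcoreParams, TorsionState, ToyTopology

__all__ = ["MCParams", "Trajectory", "run_mc", "sequential_ti",
           "default_init", "STEPS_PER_NS"]

#: MC steps standing in for 1 ns of sampling ("1x" = 1 ns per lambda).
STEPS_PER_NS = 200_000


@dataclass(frozen=True)
class MCParams:
    """Monte Carlo run lengths and move parameters.

    step_width is the per-torsion Gaussian proposal width in degrees;
    p_jump the probability of proposing a uniform resample of one
    torsion instead.  Jump moves teleport across torsional barriers, so
    they are disabled by default: barrier crossing is the phenomenon
    under study, and any nonzero rate must be kept identical across all
    compared protocols.
    """
    n_prod_steps: int = STEPS_PER_NS
    n_equil_steps: int | None = None       # default: 5% of production
    step_width: float = 30.0
    p_jump: float = 0.0
    record_interval: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.step_width <= 0:
            raise ValueError("step_width must be positive")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")
        if self.n_prod_steps < 1:
            raise ValueError("n_prod_steps must be >= 1")

    @property
    def equil_steps(self) -> int:
        if self.n_equil_steps is not None:
            return self.n_equil_steps
        return max(1, self.n_prod_steps // 20)


@dataclass
class Trajectory:
    """Recorded MC time series at one lambda."""
    states: np.ndarray          # (n, n_dof) degrees
    U: np.ndarray               # kJ/mol
    dUdl: np.ndarray            # kJ/mol
    lam: float
    acceptance_rate: float
    seed_used: int
    variant: str = "standard"
    equil_end_state: np.ndarray | None = None
    final_state: np.ndarray | None = None

    def __post_init__(self):
        if not (len(self.states) == len(self.U) == len(self.dUdl)):
            raise ValueError("trajectory series lengths differ")
        if not 0.0 <= self.acceptance_rate <= 1.0:
            raise ValueError("acceptance rate outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.U)


def _leg_seed(master: int, *key: int) -> int:
    """Deterministic 31-bit stream seed from a master seed and indices."""
    return int(np.random.SeedSequence([int(master), *key]).generate_state(1)[0]
               % (2 ** 31))


def run_mc(top: ToyTopology, lam: float, params: MCParams,
           init: TorsionState | np.ndarray | None = None,
           variant: str = "standard",
           sc: SoftcoreParams | None = None) -> Trajectory:
    """Metropolis MC at fixed lambda; fully determined by ``params.seed``."""
    sc = sc or SoftcoreParams()
    if init is None:
        init = default_init(top, lam, sc, variant)
    ang0 = np.atleast_1d(np.asarray(
        init.angles if isinstance(init, TorsionState) else init, dtype=float))
    t = top.tables()
    beta = 1.0 / (KB * top.temperature_K)
    vcode = ms._variant_code(variant)
    common = (*t.energy_args(), *ms._torsion_arrays(top), float(lam),
              sc.alpha_vdw, sc.alpha_crf, sc.n_power, t.crf, t.rc, vcode)
    seed_eq = _leg_seed(params.seed, 0)
    seed_pr = _leg_seed(params.seed, 1)
    _, _, _, _, ang_eq = mc_kernel(
        *common, params.equil_steps, params.step_width, params.p_jump,
        params.record_interval, beta, ang0, seed_eq, False)
    states, U, dUdl, n_acc, ang_end = mc_kernel(
        *common, params.n_prod_steps, params.step_width, params.p_jump,
        params.record_interval, beta, ang_eq.copy(), seed_pr, True)
    rate = n_acc / params.n_prod_steps
    if n_acc == 0:
        raise RuntimeError(
            f"zero acceptance over {params.n_prod_steps} steps at lambda="
            f"{lam}; step width {params.step_width} deg is pathological")
    return Trajectory(states=states, U=U, dUdl=dUdl, lam=float(lam),
                      acceptance_rate=rate, seed_used=params.seed,
                      variant=variant, equil_end_state=ang_eq,
                      final_state=ang_end)


def default_init(top: ToyTopology, lam: float, sc: SoftcoreParams,
                 variant: str = "standard",
                 scan_deg: float = 5.0) -> TorsionState:
    """Deterministic start state: the minimum of a coarse energy scan."""
    grids = [np.arange(-180.0, 180.0, scan_deg)] * top.n_dof
    mesh = np.meshgrid(*grids, indexing="ij")
    states = np.stack([m.ravel() for m in mesh], axis=1)
    U = ms.batch_energy(top, states, lam, sc, variant)
    return TorsionState(states[int(np.argmin(U))])


def sequential_ti(top: ToyTopology, schedule, direction: str,
                  params: MCParams, sc: SoftcoreParams | None = None,
                  variant: str = "standard",
                  init: TorsionState | np.ndarray | None = None
                  ) -> list[Trajectory]:
    """Sequentially chained per-lambda runs (forward or backward).

    The initial configuration at each lambda is the final configuration
    of the *equilibration* phase at the previous lambda.  A backward
    pass is typically seeded (via ``init``) with the final production
    snapshot of the forward lambda=1 leg.  Trajectories are returned in
    traversal order.
    """
    sc = sc or SoftcoreParams()
    schedule = [float(x) for x in schedule]
    if sorted(schedule) != schedule:
        raise ValueError("lambda schedule must be sorted ascending")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    order = schedule if direction == "forward" else schedule[::-1]
    dflag = 0 if direction == "forward" else 1
    current = init
    out = []
    for leg, lam in enumerate(order):
        leg_params = replace(params, seed=_leg_seed(params.seed, dflag, leg, 7))
        try:
            traj = run_mc(top, lam, leg_params, init=current,
                          variant=variant, sc=sc)
        except RuntimeError as err:
            raise RuntimeError(f"lambda={lam} leg failed: {err}") from err
        out.append(traj)
        current = TorsionState(traj.equil_end_state)
    return out
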