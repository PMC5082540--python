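"""Hamiltonian replica exchange over the lambda ladder.

Parallel replicas sample at different lambda values; at regular
intervals, replicas adjacent on the lambda ladder attempt to exchange
their lambda values (equivalently, their configurations) with the
Metropolis probability

    p = min(1, exp(-[(U_i(x_j) + U_j(x_i)) - (U_i(x_i) + U_j(x_j))]/kT)).

Even/odd neighbour pairs alternate between successive attempts.  After
the run, per-lambda ensembles are assembled by sorting each replica's
trajectory segments according to the lambda they carried, and the free
energy follows from thermodynamic integration over the demultiplexed
ensembles.

Replica dynamics use RNG streams split per (replica, window) from the
master seed; exchange decisions use a separate stream, so per-replica
dynamics between two attempts are reproducible regardless of the
acceptance history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import model_system as ms
from ._kernels import KB, mc_kernel
from .estimators import (FreeEnergyResult, TICurve, block_error_extrapolate,
                         ti_integrate)
from .model_system import SoftcoreParams, TorsionState, ToyTopology
from .sampler import MCParams, _leg_seed, default_init

__all__ = ["ReplicaSegment", "ReplicaRun", "exchange_probability",
           "run_hremd", "demux_and_estimate"]

#: default exchange attempt spacing in MC steps.  Exchange attempts are
#: nearly free in MC, and attempting often is strictly better: the
#: ladder-wide basin population (refreshed only by replicas reaching
#: the barrier-free high-lambda rungs and diffusing back) is the
#: slowest collective mode of the method, and it must complete many
#: relaxations per run for the statistical error of the demultiplexed
#: estimate to be measurable.
DEFAULT_EXCHANGE_INTERVAL = 25


def exchange_probability(U_i_xi: float, U_i_xj: float, U_j_xi: float,
                         U_j_xj: float, T: float) -> float:
    """Metropolis probability for swapping two replica Hamiltonians."""
    delta = (U_i_xj + U_j_xi) - (U_i_xi + U_j_xj)
    if not math.isfinite(delta):
        raise ValueError("non-finite energies in exchange criterion")
    return min(1.0, math.exp(-delta / (KB * T)))


@dataclass
class ReplicaSegment:
    """One between-exchange trajectory slice of one replica."""
    replica: int
    window: int
    lam_index: int
    lam: float
    states: np.ndarray
    U: np.ndarray
    dUdl: np.ndarray


@dataclass
class ReplicaRun:
    """Full HREMD state: segments, exchange log, ladder bookkeeping."""
    lambda_ladder: list[float]
    segments: list[ReplicaSegment]
    # (attempt index, (replica_i, replica_j), (lam_idx_i, lam_idx_j),
    #  accepted, probability)
    exchange_log: list[tuple]
    n_replicas: int
    seed: int
    acceptance_rate: float = 0.0
    lam_traces: np.ndarray = field(default=None)   # (n_windows+1, n_replicas)

    def demuxed(self) -> dict[float, dict[str, np.ndarray]]:
        """Per-lambda ensembles sorted from all replica segments."""
        out = {lam: {"states": [], "U": [], "dUdl": []}
               for lam in self.lambda_ladder}
        for seg in sorted(self.segments, key=lambda s: (s.window, s.replica)):
            d = out[seg.lam]
            d["states"].append(seg.states)
            d["U"].append(seg.U)
            d["dUdl"].append(seg.dUdl)
        return {lam: {k: np.concatenate(v) if v else np.empty(0)
                      for k, v in d.items()}
                for lam, d in out.items()}

    def validate(self) -> None:
        """Check the lambda assignment is a permutation at all times."""
        if self.lam_traces is None:
            return
        want = set(range(len(self.lambda_ladder)))
        for row in self.lam_traces:
            if set(int(i) for i in row) != want:
                raise ValueError("lambda assignment is not a permutation")


def run_hremd(top: ToyTopology, ladder, params: MCParams,
              exchange_interval: int = DEFAULT_EXCHANGE_INTERVAL,
              seed: int | None = None, sc: SoftcoreParams | None = None,
              variant: str = "standard",
              attempt_exchanges: bool = True) -> ReplicaRun:
    """Run Hamiltonian replica exchange on a sorted lambda ladder.

    Each replica advances ``exchange_interval`` MC steps between
    attempts; ``params.n_prod_steps`` is the per-replica production
    length.  Replicas keep their configurations and trade lambda
    values on accepted swaps.
    """
    sc = sc or SoftcoreParams()
    ladder = [float(x) for x in ladder]
    if sorted(ladder) != ladder:
        raise ValueError("lambda ladder must be sorted ascending")
    if exchange_interval < 1:
        raise ValueError("exchange_interval must be >= 1")
    master = params.seed if seed is None else seed
    n_rep = len(ladder)
    t = top.tables()
    beta = 1.0 / (KB * top.temperature_K)
    vcode = ms._variant_code(variant)
    tors = ms._torsion_arrays(top)

    def seg_args(lam):
        return (*t.energy_args(), *tors, lam, sc.alpha_vdw, sc.alpha_crf,
                sc.n_power, t.crf, t.rc, vcode)

    # Replica r starts at ladder[r] from the coarse-scan minimum there.
    # Unlike sequential TI (where each leg inherits a warm configuration
    # from its neighbour), every replica is cold-started, so each one
    # equilibrates at its own lambda for a full production length before
    # exchanges begin; high-lambda replicas need that long to populate
    # their basins with the right weights, and they are the source that
    # feeds rare conformations down the ladder.
    equil = (params.n_equil_steps if params.n_equil_steps is not None
             else params.n_prod_steps)
    lam_idx = list(range(n_rep))
    angs = []
    for r in range(n_rep):
        init = default_init(top, ladder[r], sc, variant)
        _, _, _, _, a = mc_kernel(
            *seg_args(ladder[r]), equil, params.step_width,
            params.p_jump, params.record_interval, beta, init.angles.copy(),
            _leg_seed(master, 2, r, 0), False)
        angs.append(a)

    n_windows = max(1, params.n_prod_steps // exchange_interval)
    xrng = np.random.default_rng(
        np.random.SeedSequence([int(master), 3]))
    segments: list[ReplicaSegment] = []
    log: list[tuple] = []
    traces = np.empty((n_windows + 1, n_rep), dtype=np.int64)
    traces[0] = lam_idx
    n_att = 0
    n_acc = 0
    for w in range(n_windows):
        for r in range(n_rep):
            li = lam_idx[r]
            states, U, D, _, angs[r] = mc_kernel(
                *seg_args(ladder[li]), exchange_interval, params.step_width,
                params.p_jump, params.record_interval, beta, angs[r],
                _leg_seed(master, 2, r, w + 1), True)
            segments.append(ReplicaSegment(
                replica=r, window=w, lam_index=li, lam=ladder[li],
                states=states, U=U, dUdl=D))
        if attempt_exchanges and n_rep > 1:
            holder = {li: r for r, li in enumerate(lam_idx)}
            start = w % 2
            for k in range(start, n_rep - 1, 2):
                ri, rj = holder[k], holder[k + 1]
                xi = np.atleast_2d(angs[ri])
                xj = np.atleast_2d(angs[rj])
                u_i_xi = ms.batch_energy(top, xi, ladder[k], sc, variant)[0]
                u_i_xj = ms.batch_energy(top, xj, ladder[k], sc, variant)[0]
                u_j_xi = ms.batch_energy(top, xi, ladder[k + 1], sc, variant)[0]
                u_j_xj = ms.batch_energy(top, xj, ladder[k + 1], sc, variant)[0]
                p = exchange_probability(u_i_xi, u_i_xj, u_j_xi, u_j_xj,
                                         top.temperature_K)
                accept = xrng.random() < p
                n_att += 1
                if accept:
                    lam_idx[ri], lam_idx[rj] = lam_idx[rj], lam_idx[ri]
                    n_acc += 1
                log.append((w, (ri, rj), (k, k + 1), bool(accept), p))
        traces[w + 1] = lam_idx
    run = ReplicaRun(lambda_ladder=ladder, segments=segments,
                     exchange_log=log, n_replicas=n_rep, seed=master,
                     acceptance_rate=(n_acc / n_att if n_att else 0.0),
                     lam_traces=traces)
    run.validate()
    return run


def demux_and_estimate(run: ReplicaRun):
    """TI curve and dG from the lambda-sorted (demultiplexed) ensembles.

    Per-lambda curve errors come from block averaging of the demuxed
    series.  The error on dG itself is computed differently: replica
    exchange correlates all lambda ensembles through the ladder (the
    population carried by the replicas is a collective slow mode), so
    the dG error is a block-average extrapolation of the per-window dG
    series, which captures those cross-lambda correlations.
    """
    run.validate()
    demux = run.demuxed()
    lams, means, errs, ns = [], [], [], []
    for lam in run.lambda_ladder:
        d = demux[lam]["dUdl"]
        if d.size == 0:
            raise ValueError(f"no demuxed samples at lambda={lam}")
        lams.append(lam)
        means.append(d.mean())
        errs.append(block_error_extrapolate(d) if d.size >= 64
                    else (d.std(ddof=1) / np.sqrt(d.size) if d.size > 1
                          else 0.0))
        ns.append(d.size)
    curve = TICurve(np.array(lams), np.array(means), np.array(errs),
                    np.array(ns))
    result = ti_integrate(curve, method="HREMD")
    # dG error from the per-window dG series
    from .estimators import _trapezoid_weights
    lam_col = {lam: k for k, lam in enumerate(run.lambda_ladder)}
    n_windows = max(s.window for s in run.segments) + 1
    win_means = np.zeros((n_windows, len(run.lambda_ladder)))
    for seg in run.segments:
        if seg.dUdl.size:
            win_means[seg.window, lam_col[seg.lam]] = seg.dUdl.mean()
    series = win_means @ _trapezoid_weights(curve.lambdas)
    if series.size >= 64:
        result.err = block_error_extrapolate(series)
    elif series.size > 1:
        result.err = float(series.std(ddof=1) / np.sqrt(series.size))
    return curve, result
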