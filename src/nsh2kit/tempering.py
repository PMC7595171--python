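"""Simulated tempering coupled to constant-velocity pulling.

A single chain moves on a temperature ladder T_1 < ... < T_M; rung changes
are nearest-neighbor Metropolis moves with acceptance

    min{1, exp[-(beta_j - beta_i) U + (f_j - f_i)]},

so that the chain is canonical at every rung.  With exact weights
f_i = beta_i F_i the rung occupancy is uniform; initial weights come from
the Park-Pande trapezoidal estimate over per-rung mean energies, and the
Wang-Landau scheme adapts them on the fly with a shrinking increment.

Constant-velocity pulling moves the reference of a harmonic bias
U_pull = k/2 (xi - ref(t))^2 at velocity v; the external work is accumulated
exactly per reference increment as W += k (ref_new - ref_old)(ref_mid - xi),
which is the discrete dU/d(ref) increment at fixed configuration.  Forward
and reverse pull ensembles yield WorkSets directly consumable by the
Crooks/BAR estimators.  Frames visited at the base temperature are flagged
for downstream umbrella-window seeding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB
from .model_systems import HarmonicBias, Potential1D, WorkSet, _sampling_domain

__all__ = [
    "TemperatureLadder",
    "ladder_preset",
    "PullSchedule",
    "CvRestraint",
    "WangLandau",
    "park_pande_weights",
    "st_attempt",
    "wl_update",
    "run_simulated_tempering",
    "run_tempered_pull",
    "pull_work_sets",
    "cv_restraint_energy",
    "harmonic_energy_sampler",
    "harmonic_exact_weights",
]


@dataclass
class TemperatureLadder:
    """Ascending temperature rungs with tempering weights and visit counts."""

    temperatures: np.ndarray  # K, strictly ascending
    weights: np.ndarray | None = None  # f_i, dimensionless
    histogram: np.ndarray | None = None  # visit counts

    def __post_init__(self):
        self.temperatures = np.atleast_1d(np.asarray(self.temperatures, float))
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly ascending")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive")
        if self.weights is None:
            self.weights = np.zeros(len(self.temperatures))
        else:
            self.weights = np.asarray(self.weights, dtype=float).copy()
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.histogram is None:
            self.histogram = np.zeros(len(self.temperatures), dtype=float)
        else:
            self.histogram = np.asarray(self.histogram, dtype=float).copy()
        if len(self.weights) != len(self.temperatures) or (
            len(self.histogram) != len(self.temperatures)
        ):
            raise ValueError("weights/histogram length must match the ladder")

    @property
    def betas(self) -> np.ndarray:
        return 1.0 / (KB * self.temperatures)

    @property
    def n_rungs(self) -> int:
        return len(self.temperatures)


#: Named ladder presets: the SHP2-opening protocol (300-400 K in 5 K steps)
#: and the sheet-opening protocol (300-380 K in 10 K steps).
_PRESETS = {
    "shp2_opening": (300.0, 400.0, 5.0),
    "sheet_opening": (300.0, 380.0, 10.0),
}


def ladder_preset(name: str) -> TemperatureLadder:
    if name not in _PRESETS:
        raise ValueError(f"unknown ladder preset {name!r}; have {sorted(_PRESETS)}")
    lo, hi, step = _PRESETS[name]
    n = int(round((hi - lo) / step)) + 1
    return TemperatureLadder(lo + step * np.arange(n))


def park_pande_weights(mean_energies, ladder: TemperatureLadder) -> np.ndarray:
    """Initial tempering weights from per-rung mean potential energies.

    Trapezoidal thermodynamic integration of dE over beta:
    f_1 = 0, f_{i+1} = f_i + (beta_{i+1} - beta_i)(E_i + E_{i+1})/2, which
    approximates f_i = beta_i F_i up to an irrelevant additive constant.
    """
    e = np.asarray(mean_energies, dtype=float)
    if len(e) != ladder.n_rungs or not np.all(np.isfinite(e)):
        raise ValueError("need one finite mean energy per rung")
    b = ladder.betas
    f = np.zeros(ladder.n_rungs)
    for i in range(ladder.n_rungs - 1):
        f[i + 1] = f[i] + (b[i + 1] - b[i]) * 0.5 * (e[i] + e[i + 1])
    return f


def harmonic_exact_weights(ladder: TemperatureLadder, stiffness: float) -> np.ndarray:
    """Exact weights beta_i F_i for the 1-D harmonic oscillator
    (configurational partition function Z = sqrt(2 pi / (beta K)))."""
    b = ladder.betas
    f = 0.5 * np.log(b * stiffness / (2.0 * np.pi))
    return f - f[0]


def harmonic_energy_sampler(stiffness: float):
    """Exact equilibrium potential-energy sampler for a 1-D harmonic well."""

    def sample(temperature, rng):
        x = rng.standard_normal() * math.sqrt(KB * temperature / stiffness)
        return 0.5 * stiffness * x * x

    return sample


def st_attempt(current: int, proposed: int, energy: float,
               ladder: TemperatureLadder, rng) -> int:
    """One Metropolis tempering attempt; returns the rung after the attempt.

    Only nearest-neighbor proposals are allowed; out-of-range proposals
    raise ``ValueError``.
    """
    if not 0 <= proposed < ladder.n_rungs:
        raise ValueError(f"proposed rung {proposed} outside ladder of "
                         f"{ladder.n_rungs} rungs")
    if abs(proposed - current) > 1:
        raise ValueError("only nearest-neighbor rung proposals are allowed")
    b = ladder.betas
    f = ladder.weights
    log_acc = -(b[proposed] - b[current]) * energy + (f[proposed] - f[current])
    if log_acc >= 0 or rng.random() < math.exp(log_acc):
        return proposed
    return current


@dataclass
class WangLandau:
    """Wang-Landau adaptation state: shrinking increment plus flatness test.

    The flatness criterion (min/mean of the visit histogram) is only
    evaluated once the histogram holds at least ``min_visits`` mean visits
    per rung; testing a nearly empty histogram would shrink the increment
    before the weights have equilibrated at the current delta.
    """

    delta: float = 1.0
    flatness: float = 0.8
    scale: float = 0.5
    min_visits: int = 100

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def wl_update(ladder: TemperatureLadder, visited: int, wl: WangLandau) -> WangLandau:
    """One Wang-Landau update after visiting a rung.

    Convention: the visited rung's weight is *decreased* by delta (stationary
    rung occupancy is proportional to Z_i e^{f_i}, so lowering f_i suppresses
    an over-visited rung; equivalently all other weights are raised).  When
    the visit histogram is flat (min/mean >= flatness) the increment shrinks
    by ``scale`` and the histogram resets.  Returns the (possibly updated)
    WangLandau state; the ladder is modified in place.
    """
    ladder.weights[visited] -= wl.delta
    ladder.histogram[visited] += 1
    if ladder.histogram.min() > 0 and ladder.histogram.mean() >= wl.min_visits:
        if ladder.histogram.min() / ladder.histogram.mean() >= wl.flatness:
            ladder.histogram[:] = 0
            return replace(wl, delta=wl.delta * wl.scale)
    return wl


@dataclass
class STResult:
    """Record of a simulated-tempering run."""

    rungs: np.ndarray  # rung index after each attempt
    ladder: TemperatureLadder
    acceptance_rate: float
    final_delta: float | None = None


def run_simulated_tempering(energy_sampler, ladder: TemperatureLadder,
                            n_attempts: int, seed: int = 0,
                            wl: WangLandau | None = None,
                            stop_delta: float | None = None) -> STResult:
    """Simulated-tempering driver with exact configurational sampling.

    ``energy_sampler(temperature, rng)`` must return an equilibrium
    potential-energy sample at the given temperature (between tempering
    attempts the configuration is assumed fully relaxed, as with the exact
    1-D samplers of the model systems).  With ``wl`` set, weights adapt by
    the Wang-Landau scheme; ``stop_delta`` ends the run early once the
    increment has shrunk below it.
    """
    rng = np.random.default_rng(seed)
    rung = 0
    rungs = np.empty(n_attempts, dtype=int)
    accepted = 0
    n_done = 0
    for t in range(n_attempts):
        u = energy_sampler(ladder.temperatures[rung], rng)
        proposed = rung + (1 if rng.random() < 0.5 else -1)
        if 0 <= proposed < ladder.n_rungs:
            new = st_attempt(rung, proposed, u, ladder, rng)
            if new != rung:
                accepted += 1
            rung = new
        if wl is not None:
            wl = wl_update(ladder, rung, wl)
        rungs[t] = rung
        n_done = t + 1
        if wl is not None and stop_delta is not None and wl.delta < stop_delta:
            break
    return STResult(
        rungs=rungs[:n_done], ladder=ladder,
        acceptance_rate=accepted / max(n_done, 1),
        final_delta=None if wl is None else wl.delta,
    )


# ---------------------------------------------------------------------------
# Constant-velocity pulling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PullSchedule:
    """Moving-reference harmonic pull: U = k/2 (xi - ref(t))^2.

    ``velocity`` is the magnitude of the reference speed (nm/ps); the sign
    is taken from end - start.  ``attempt_interval`` (ps) is the spacing of
    tempering attempts.
    """

    k: float  # kJ/mol/nm^2
    velocity: float  # nm/ps, magnitude
    start: float  # nm
    end: float  # nm
    attempt_interval: float = 1.0  # ps

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("pull force constant must be positive")
        if self.end == self.start:
            raise ValueError("pull end must differ from start")
        if self.velocity < 0:
            raise ValueError("velocity is a magnitude; use start/end for direction")


@dataclass(frozen=True)
class CvRestraint:
    """Harmonic restraint on a collective coordinate: E = k/2 (eta - center)^2.

    ``vector`` may be a CollectiveVector for coordinate-space restraints or
    ``None`` when eta is itself the 1-D coordinate.  Only the collective
    direction feels the restraint; all orthogonal degrees of freedom are
    unaffected.
    """

    k: float
    center: float
    vector: object | None = None

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("restraint force constant must be >= 0")


def cv_restraint_energy(value, restraint: CvRestraint):
    """Energy (kJ/mol) and gradient of a collective-variable restraint.

    ``value`` is either the scalar coordinate eta (nm) or, with a
    coordinate-based restraint, an (atoms, 3) configuration; the returned
    gradient then lies entirely along the collective direction.
    """
    if restraint.vector is None:
        eta = np.asarray(value, dtype=float)
        grad = restraint.k * (eta - restraint.center)
        energy = 0.5 * restraint.k * (eta - restraint.center) ** 2
        return energy, grad
    cv = restraint.vector
    vec = np.asarray(cv.vector)
    nrm = np.linalg.norm(vec)
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError("restraint vector must be unit-norm")
    coords = np.asarray(value, dtype=float)
    eta = float(np.sum((coords - cv.mean_structure) * vec))
    energy = 0.5 * restraint.k * (eta - restraint.center) ** 2
    grad = restraint.k * (eta - restraint.center) * vec
    return energy, grad


@dataclass
class TemperedPullResult:
    """Trajectory record of a (possibly tempered, possibly replicated) pull."""

    times: np.ndarray  # ps, recorded steps
    positions: np.ndarray  # (n_rec, n_replicas), nm
    rungs: np.ndarray  # (n_rec, n_replicas), int
    references: np.ndarray  # (n_rec,), nm
    works: np.ndarray  # (n_rec, n_replicas), kJ/mol, accumulated
    final_work: np.ndarray  # (n_replicas,)
    ladder: TemperatureLadder
    at_base: np.ndarray  # (n_rec, n_replicas) bool, frames at the base rung
    acceptance_rate: float


def run_tempered_pull(potential: Potential1D, schedule: PullSchedule,
                      ladder: TemperatureLadder | None = None,
                      restraints=(), n_steps: int | None = None,
                      friction: float = 1.0, dt: float = 1e-4,
                      x0: float | None = None, seed: int = 0,
                      n_replicas: int = 1, wl: WangLandau | None = None,
                      sample_interval: int = 100) -> TemperedPullResult:
    """Constant-velocity pulling under overdamped Langevin dynamics, with
    optional simulated tempering (all replicas share the ladder weights).

    The trajectory runs until the reference reaches ``schedule.end`` (or for
    ``n_steps`` if given); the work is accumulated per reference increment
    at fixed configuration, which is exact for the harmonic pull potential.
    Recorded frames carry the rung so the 300 K (base) sub-ensemble can be
    extracted for window seeding.
    """
    if ladder is None:
        ladder = TemperatureLadder(np.array([300.0]))
    direction = 1.0 if schedule.end > schedule.start else -1.0
    v = schedule.velocity * direction
    if schedule.velocity > 0:
        total_steps = int(math.ceil(abs(schedule.end - schedule.start)
                                    / (schedule.velocity * dt)))
    else:
        if n_steps is None:
            raise ValueError("n_steps is required when velocity is zero")
        total_steps = n_steps
    if n_steps is not None:
        total_steps = n_steps
    attempt_every = max(1, int(round(schedule.attempt_interval / dt)))
    if abs(attempt_every * dt - schedule.attempt_interval) > 1e-9:
        raise ValueError("attempt interval must be a multiple of dt")

    # stability bound as in langevin_trajectory, with bias curvatures added
    biases = [HarmonicBias(schedule.k, schedule.start)] + [
        HarmonicBias(r.k, r.center) for r in restraints if r.vector is None
    ]
    domain = _sampling_domain(potential, biases, float(ladder.temperatures[-1]))
    curv = potential.curvature(domain) + schedule.k + sum(
        r.k for r in restraints if r.vector is None
    )
    max_curv = float(np.max(np.abs(curv)))
    if dt * max_curv / friction > 0.5:
        raise ValueError(
            f"unstable parameters: dt*max|U''|/friction = "
            f"{dt * max_curv / friction:.3g} > 0.5; reduce dt"
        )
    lo_dom, hi_dom = domain[0] - abs(schedule.end - schedule.start), domain[-1] + abs(
        schedule.end - schedule.start
    )
    span = hi_dom - lo_dom

    if any(r.vector is not None for r in restraints):
        raise ValueError("run_tempered_pull supports 1-D (vector-free) restraints only")
    rng = np.random.default_rng(seed)
    m = n_replicas
    if x0 is None:
        x = np.full(m, schedule.start)
    elif np.isscalar(x0):
        x = np.full(m, float(x0))
    else:
        x = np.asarray(x0, dtype=float).copy()
        if x.shape != (m,):
            raise ValueError("x0 array must have length n_replicas")
    rung = np.zeros(m, dtype=int)
    work = np.zeros(m)
    ref = schedule.start
    kt_base = KB * ladder.temperatures
    betas = ladder.betas

    n_rec = total_steps // sample_interval + 1
    times = np.empty(n_rec)
    positions = np.empty((n_rec, m))
    rungs_rec = np.empty((n_rec, m), dtype=int)
    refs_rec = np.empty(n_rec)
    works_rec = np.empty((n_rec, m))
    rec = 0
    attempts = accepted = 0

    def record(step):
        nonlocal rec
        times[rec] = step * dt
        positions[rec] = x
        rungs_rec[rec] = rung
        refs_rec[rec] = ref
        works_rec[rec] = work
        rec += 1

    def total_energy(xv):
        u = potential.energy(xv) + 0.5 * schedule.k * (xv - ref) ** 2
        for r in restraints:
            e, _ = cv_restraint_energy(xv, r)
            u = u + e
        return u

    record(0)
    for step in range(1, total_steps + 1):
        # advance the reference and accumulate work at fixed configuration
        if v != 0.0:
            ref_new = schedule.start + v * step * dt
            if direction > 0:
                ref_new = min(ref_new, schedule.end)
            else:
                ref_new = max(ref_new, schedule.end)
            dref = ref_new - ref
            if dref != 0.0:
                work += schedule.k * dref * (0.5 * (ref + ref_new) - x)
                ref = ref_new
        # Langevin step at each replica's rung temperature
        g = potential.gradient(x) + schedule.k * (x - ref)
        for r in restraints:
            _, gr = cv_restraint_energy(x, r)
            g = g + gr
        sigma = np.sqrt(2.0 * kt_base[rung] * dt / friction)
        x = x - dt * g / friction + sigma * rng.standard_normal(m)
        if np.any(x < lo_dom - span) or np.any(x > hi_dom + span):
            raise RuntimeError(f"pull trajectory diverged at step {step}")
        # tempering attempt
        if ladder.n_rungs > 1 and step % attempt_every == 0:
            u = total_energy(x)
            proposed = rung + np.where(rng.random(m) < 0.5, 1, -1)
            valid = (proposed >= 0) & (proposed < ladder.n_rungs)
            log_acc = np.full(m, -np.inf)
            pv = proposed[valid]
            cv_ = rung[valid]
            log_acc[valid] = (
                -(betas[pv] - betas[cv_]) * u[valid]
                + (ladder.weights[pv] - ladder.weights[cv_])
            )
            accept = np.log(rng.random(m)) < log_acc
            attempts += int(valid.sum())
            accepted += int((accept & valid).sum())
            rung = np.where(accept & valid, proposed, rung)
            if wl is not None:
                for rg in rung:
                    wl = wl_update(ladder, int(rg), wl)
        if step % sample_interval == 0:
            record(step)
    if rec < n_rec:
        times, positions = times[:rec], positions[:rec]
        rungs_rec, refs_rec, works_rec = rungs_rec[:rec], refs_rec[:rec], works_rec[:rec]
    return TemperedPullResult(
        times=times, positions=positions, rungs=rungs_rec,
        references=refs_rec, works=works_rec, final_work=work.copy(),
        ladder=ladder, at_base=rungs_rec == 0,
        acceptance_rate=accepted / attempts if attempts else 0.0,
    )


def pull_work_sets(potential: Potential1D, schedule: PullSchedule,
                   n_pulls: int, temperature: float = 300.0,
                   restraints=(), friction: float = 1.0, dt: float = 1e-4,
                   seed: int = 0, equilibrate: bool = True) -> WorkSet:
    """Forward/reverse pull ensembles -> WorkSet for the Crooks estimators.

    Runs ``n_pulls`` replicas forward (start -> end) and ``n_pulls`` in
    reverse (end -> start) at a single temperature.  Initial configurations
    are drawn from the exact Boltzmann distribution of the restrained end
    states (the pull bias held at its start), so the work values measure the
    free-energy difference between those two restrained states.
    """
    from .model_systems import sample_boltzmann_1d

    reverse = PullSchedule(k=schedule.k, velocity=schedule.velocity,
                           start=schedule.end, end=schedule.start,
                           attempt_interval=schedule.attempt_interval)
    works = []
    for i, sched in enumerate((schedule, reverse)):
        if equilibrate:
            x0 = sample_boltzmann_1d(
                potential, HarmonicBias(sched.k, sched.start), temperature,
                n=n_pulls, seed=seed + 7919 * (i + 1),
            )
        else:
            x0 = np.full(n_pulls, sched.start)
        res = run_tempered_pull(
            potential, sched, restraints=restraints, friction=friction,
            dt=dt, x0=x0, seed=seed + 104729 * (i + 1), n_replicas=n_pulls,
            sample_interval=10**9,
        )
        works.append(res.final_work)
    return WorkSet(works[0], works[1], temperature=temperature)


def write_run_record(result: TemperedPullResult, path, extra=None) -> None:
    doc = {
        "ladder_K": [float(t) for t in result.ladder.temperatures],
        "weights": [float(f) for f in result.ladder.weights],
        "acceptance_rate": result.acceptance_rate,
        "n_recorded": int(len(result.times)),
        "constant_volume": True,  # tempering convention recorded for fidelity
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
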