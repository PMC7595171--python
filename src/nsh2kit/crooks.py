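"""Nonequilibrium free-energy estimation from forward/reverse work sets.

The Crooks fluctuation theorem, P_F(W)/P_R(-W) = exp[beta (W - dG)], links
the work distributions of a forward and a time-reversed switching process to
the equilibrium free-energy difference dG.  Two estimators are provided:

* :func:`bar_solve` — Bennett's acceptance ratio, the maximum-likelihood
  estimator consistent with the Crooks relation (primary);
* :func:`crossing_estimate` — the abscissa where kernel-density estimates of
  P_F(W) and P_R(-W) intersect (diagnostic/cross-check; the Crooks relation
  implies the densities cross exactly at W = dG).

Errors come from bootstrap resampling of the work values, and thermodynamic
cycles compose two alchemical legs into a ddG.  Work sign convention
throughout: forward work is work done on the system for the 0 -> 1 switch,
reverse work for 1 -> 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .constants import KB, beta as _beta
from .model_systems import WorkSet

__all__ = [
    "DeltaG",
    "ThermodynamicCycle",
    "bar_solve",
    "crossing_estimate",
    "work_bootstrap",
    "cycle_ddg",
    "write_delta_g",
]


@dataclass
class DeltaG:
    """A free-energy difference estimate in kJ/mol."""

    value: float
    error: float
    method: str  # "bar" | "crossing"
    n_forward: int
    n_reverse: int
    temperature: float = 300.0

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("error must be non-negative")


def _logistic(x):
    # numerically safe 1/(1+exp(x))
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def bar_solve(work: WorkSet, tolerance: float = 1e-6) -> DeltaG:
    """Bennett acceptance-ratio estimate of dG from a WorkSet.

    Solves the self-consistency condition

        sum_F f(beta (W_i - dG + M)) = sum_R f(beta (W_j + dG - M)),

    with f the logistic function and M = kBT ln(n_F/n_R), by bracketed
    root-finding.  The left side increases and the right side decreases in
    dG, so the root is unique.  The statistical error is not computed here;
    use :func:`work_bootstrap`.
    """
    wf = work.forward_work
    wr = work.reverse_work
    b = _beta(work.temperature)
    kt = 1.0 / b
    n_f, n_r = len(wf), len(wr)
    m = kt * math.log(n_f / n_r)
    lo = min(float(np.min(-wr)), float(np.min(wf)))
    hi = max(float(np.max(-wr)), float(np.max(wf)))
    gap = max(float(np.min(wf)) - float(np.max(-wr)),
              float(np.min(-wr)) - float(np.max(wf)))
    if gap > 50.0 * kt:
        raise ValueError(
            "forward and reversed-reverse work distributions do not overlap "
            f"(gap {gap:.1f} kJ/mol > 50 kBT); more sampling is needed"
        )

    def residual(dg):
        left = _logistic(b * (wf - dg + m)).sum()
        right = _logistic(b * (wr + dg - m)).sum()
        return left - right

    lo -= 10.0 * kt
    hi += 10.0 * kt
    r_lo, r_hi = residual(lo), residual(hi)
    for _ in range(60):
        if r_lo * r_hi <= 0:
            break
        lo -= 10.0 * kt
        hi += 10.0 * kt
        r_lo, r_hi = residual(lo), residual(hi)
    else:  # pragma: no cover - defensive
        raise RuntimeError("could not bracket the BAR root")
    dg = optimize.brentq(residual, lo, hi, xtol=tolerance)
    return DeltaG(value=float(dg), error=0.0, method="bar",
                  n_forward=n_f, n_reverse=n_r, temperature=work.temperature)


def crossing_estimate(work: WorkSet) -> DeltaG:
    """dG from the crossing point of the two work densities.

    Gaussian-kernel density estimates (Silverman bandwidth) of P_F(W) and
    P_R(-W) are intersected within their overlap region; the Crooks relation
    implies the true densities cross exactly at W = dG.  When several
    crossings survive the noise, the one closest to the pooled mean is
    returned.
    """
    wf = work.forward_work
    neg_wr = -work.reverse_work
    lo = max(wf.min(), neg_wr.min())
    hi = min(wf.max(), neg_wr.max())
    if lo >= hi:
        raise ValueError(
            "forward and reversed-reverse work histograms do not overlap; "
            "no crossing point exists"
        )
    if np.std(wf) == 0 and np.std(neg_wr) == 0:
        if np.allclose(wf.mean(), neg_wr.mean()):
            return DeltaG(float(wf.mean()), 0.0, "crossing", len(wf),
                          len(work.reverse_work), work.temperature)
        raise ValueError("degenerate distributions with no crossing")
    kde_f = stats.gaussian_kde(wf)
    kde_r = stats.gaussian_kde(neg_wr)
    grid = np.linspace(lo, hi, 1001)
    diff = kde_f(grid) - kde_r(grid)
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size == 0:
        raise ValueError("work densities do not intersect within the overlap region")
    pooled_mean = 0.5 * (wf.mean() + neg_wr.mean())
    roots = []
    for i in sign_change:
        roots.append(optimize.brentq(lambda w: kde_f(w)[0] - kde_r(w)[0],
                                     grid[i], grid[i + 1]))
    root = min(roots, key=lambda r: abs(r - pooled_mean))
    return DeltaG(value=float(root), error=0.0, method="crossing",
                  n_forward=len(wf), n_reverse=len(work.reverse_work),
                  temperature=work.temperature)


def work_bootstrap(work: WorkSet, estimator=bar_solve, n_boot: int = 100,
                   seed: int = 0) -> float:
    """Bootstrap standard error of a dG estimator on a WorkSet.

    Forward and reverse sets are resampled with replacement independently;
    the error is the standard deviation of the replicate estimates.  Raises
    when the estimator fails on more than 20% of replicates.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    rng = np.random.default_rng(seed)
    wf, wr = work.forward_work, work.reverse_work
    values, failures = [], 0
    for _ in range(n_boot):
        ws = WorkSet(
            rng.choice(wf, size=len(wf), replace=True),
            rng.choice(wr, size=len(wr), replace=True),
            temperature=work.temperature,
        )
        try:
            values.append(estimator(ws).value)
        except (ValueError, RuntimeError):
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(
            f"estimator failed on {failures}/{n_boot} bootstrap replicates"
        )
    return float(np.std(values))


@dataclass
class ThermodynamicCycle:
    """Two alchemical legs composed into a ddG.

    ddG = leg_bound - leg_unbound, with errors added in quadrature.  For the
    ``alpha-vs-beta-preference`` context the sign convention is: positive
    ddG means an augmented preference for the alpha (activating) state;
    negative ddG an augmented preference for the beta state.  For the
    ``binding-affinity`` context, ddG is the change in ligand binding free
    energy introduced by the mutation.
    """

    leg_bound: DeltaG
    leg_unbound: DeltaG
    ddg: float
    error: float
    context: str

    @property
    def interpretation(self) -> str:
        if self.context == "alpha-vs-beta-preference":
            if self.ddg > 0:
                return "augmented preference for the alpha state"
            if self.ddg < 0:
                return "augmented preference for the beta state"
            return "no change in alpha/beta preference"
        return "change in binding affinity upon mutation"


def cycle_ddg(leg_bound: DeltaG, leg_unbound: DeltaG,
              context: str = "binding-affinity") -> ThermodynamicCycle:
    """Compose two legs of a thermodynamic cycle into a ddG."""
    if context not in ("binding-affinity", "alpha-vs-beta-preference"):
        raise ValueError(f"unknown cycle context {context!r}")
    if abs(leg_bound.temperature - leg_unbound.temperature) > 1e-9:
        raise ValueError("cycle legs were estimated at different temperatures")
    return ThermodynamicCycle(
        leg_bound=leg_bound,
        leg_unbound=leg_unbound,
        ddg=leg_bound.value - leg_unbound.value,
        error=math.hypot(leg_bound.error, leg_unbound.error),
        context=context,
    )


def write_delta_g(dg: DeltaG, path, extra=None) -> None:
    doc = {
        "value_kJmol": dg.value,
        "error_kJmol": dg.error,
        "method": dg.method,
        "n_forward": dg.n_forward,
        "n_reverse": dg.n_reverse,
        "temperature_K": dg.temperature,
        "sign_convention": "forward work = work done on the system for 0->1",
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
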