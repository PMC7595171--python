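"""Umbrella sampling -> free-energy profiles via WHAM, with Bayesian
bootstrap of complete histograms for per-bin errors.

The weighted histogram analysis method combines the biased histograms of
overlapping umbrella windows into one unbiased profile by self-consistent
iteration of

    p_j = sum_i n_ij / sum_i N_i exp[beta (F_i - w_i(xi_j))]
    F_i = -kBT ln sum_j p_j exp[-beta w_i(xi_j)]

with w_i(xi) = k_i/2 (xi - ref_i)^2 the window bias evaluated at the bin
center.  Errors are estimated by the Bayesian bootstrap of complete
histograms: each replicate draws one random weight per *window* (i.i.d.
exponential, normalized), so whole histograms — never individual samples —
are treated as the independent unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import KB, beta as _beta

__all__ = [
    "UmbrellaWindow",
    "UmbrellaWindowSet",
    "FreeEnergyProfile",
    "wham_solve",
    "bayesian_bootstrap",
    "align_profiles",
    "write_profile",
    "read_profile",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic reference, force constant, samples."""

    ref: float  # nm
    k: float  # kJ/mol/nm^2
    samples: np.ndarray  # reaction-coordinate values, nm

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(f"window at ref={self.ref} has no samples")


@dataclass
class UmbrellaWindowSet:
    """All windows of one umbrella run, at a single temperature."""

    windows: list
    temperature: float = 300.0

    def __post_init__(self):
        if len(self.windows) == 0:
            raise ValueError("need at least one window")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_windows(self):
        return len(self.windows)

    def sample_range(self):
        lo = min(w.samples.min() for w in self.windows)
        hi = max(w.samples.max() for w in self.windows)
        return lo, hi


@dataclass
class FreeEnergyProfile:
    """Binned free-energy profile G(xi) with per-bin errors.

    ``offset_convention`` records how the arbitrary additive constant was
    fixed; the default "min-zero" shifts the minimum to zero.
    """

    bin_centers: np.ndarray  # nm
    free_energy: np.ndarray  # kJ/mol
    error: np.ndarray  # kJ/mol
    offset_convention: str = "min-zero"
    window_offsets: np.ndarray | None = None  # converged F_i, kJ/mol
    iterations: int = 0

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.error < 0):
            raise ValueError("negative per-bin error")


def _histograms(windows: UmbrellaWindowSet, bins):
    if np.isscalar(bins):
        lo, hi = windows.sample_range()
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack(
        [np.histogram(w.samples, bins=edges)[0] for w in windows.windows]
    ).astype(float)
    return edges, centers, counts


def _check_overlap(windows: UmbrellaWindowSet, centers, counts, log=None):
    """Error when adjacent windows' sampled ranges do not touch at all; warn
    when an adjacent pair merely shares no occupied histogram bin."""
    order = np.argsort([w.ref for w in windows.windows])
    for a, b in zip(order[:-1], order[1:]):
        wa, wb = windows.windows[a], windows.windows[b]
        if wa.samples.max() < wb.samples.min() or wb.samples.max() < wa.samples.min():
            lo = min(wa.samples.max(), wb.samples.max())
            hi = max(wa.samples.min(), wb.samples.min())
            raise ValueError(
                f"umbrella windows at ref={wa.ref:.4g} and ref={wb.ref:.4g} nm do "
                f"not overlap: no samples between xi={lo:.4g} and xi={hi:.4g} nm"
            )
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            msg = (
                f"adjacent windows at ref={wa.ref:.4g} and "
                f"ref={wb.ref:.4g} nm share no occupied bin"
            )
            if log is not None:
                log.append(msg)


def _wham_iterate(counts, bias, n_eff, b, tolerance, max_iter):
    """Core WHAM self-consistency loop.

    counts: (n_win, n_bins) histogram counts (possibly bootstrap-weighted);
    bias: (n_win, n_bins) bias energies at bin centers; n_eff: per-window
    total counts.  Returns (p_normalized, F_i, iterations).
    """
    n_win, n_bins = counts.shape
    numer = counts.sum(axis=0)
    boltz = np.exp(-b * bias)  # (n_win, n_bins)
    f = np.zeros(n_win)
    for it in range(1, max_iter + 1):
        denom = (n_eff * np.exp(b * f)) @ boltz
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, numer / denom, 0.0)
        z = boltz @ p
        f_new = -np.log(z) / b
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            p_sum = p.sum()
            return p / p_sum, f, it
    raise RuntimeError(
        f"WHAM did not converge in {max_iter} iterations (last max|dF| = {delta:.3g})"
    )


def wham_solve(windows: UmbrellaWindowSet, bins=200, tolerance=1e-4,
               max_iter=100_000, window_weights=None,
               log: list | None = None) -> FreeEnergyProfile:
    """Self-consistent WHAM solution for a set of umbrella windows.

    ``bins`` is a bin count over the sampled range or explicit edges.
    ``window_weights`` multiplies whole-window histograms (used by the
    Bayesian bootstrap).  Empty bins are dropped from the returned profile
    rather than reported as infinities; the profile is shifted to min-zero.
    """
    b = _beta(windows.temperature)
    edges, centers, counts = _histograms(windows, bins)
    if window_weights is not None:
        counts = counts * np.asarray(window_weights, dtype=float)[:, None]
    _check_overlap(windows, centers, counts, log=log)
    bias = np.stack([
        0.5 * w.k * (centers - w.ref) ** 2 for w in windows.windows
    ])
    n_eff = counts.sum(axis=1)
    p, f, iters = _wham_iterate(counts, bias, n_eff, b, tolerance, max_iter)
    occupied = p > 0
    g = -np.log(p[occupied]) / b
    g -= g.min()
    return FreeEnergyProfile(
        bin_centers=centers[occupied],
        free_energy=g,
        error=np.zeros(g.shape),
        window_offsets=f,
        iterations=iters,
    )


def bayesian_bootstrap(windows: UmbrellaWindowSet, bins=200, n_boot=100,
                       seed=0, tolerance=1e-4, max_iter=100_000) -> FreeEnergyProfile:
    """WHAM profile with per-bin Bayesian-bootstrap errors.

    Each replicate assigns every complete window histogram an i.i.d.
    exponential weight (normalized over windows, the Dirichlet/Bayesian
    bootstrap), re-solves WHAM, and aligns the replicate to the unweighted
    profile by the mean over shared bins; the per-bin error is the standard
    deviation across replicates.
    """
    if windows.n_windows < 2:
        raise ValueError("Bayesian bootstrap needs at least 2 windows")
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")
    base = wham_solve(windows, bins=bins, tolerance=tolerance, max_iter=max_iter)
    edges, centers, _ = _histograms(windows, bins)
    rng = np.random.default_rng(seed)
    n_bins = len(centers)
    replicates = np.full((n_boot, n_bins), np.nan)
    center_index = {round(float(c), 12): i for i, c in enumerate(centers)}
    for r in range(n_boot):
        w = rng.exponential(1.0, size=windows.n_windows)
        w *= windows.n_windows / w.sum()
        prof = wham_solve(windows, bins=edges, tolerance=tolerance,
                          max_iter=max_iter, window_weights=w)
        idx = np.array([center_index[round(float(c), 12)] for c in prof.bin_centers])
        replicates[r, idx] = prof.free_energy
    base_full = np.full(n_bins, np.nan)
    base_idx = np.array([center_index[round(float(c), 12)] for c in base.bin_centers])
    base_full[base_idx] = base.free_energy
    # align each replicate to the base profile over the bins both resolve
    for r in range(n_boot):
        shared = ~np.isnan(replicates[r]) & ~np.isnan(base_full)
        if shared.any():
            replicates[r] -= np.nanmean(replicates[r][shared] - base_full[shared])
    with np.errstate(invalid="ignore"):
        err = np.nanstd(replicates[:, base_idx], axis=0)
    err = np.where(np.isfinite(err), err, 0.0)
    return FreeEnergyProfile(
        bin_centers=base.bin_centers,
        free_energy=base.free_energy,
        error=err,
        window_offsets=base.window_offsets,
        iterations=base.iterations,
    )


def align_profiles(a: FreeEnergyProfile, b: FreeEnergyProfile,
                   region: tuple[float, float] | None = None):
    """Shift profile b by the constant minimizing its mean offset from a.

    Only an additive shift is applied; shapes are untouched.  Returns the
    shifted profile and the shift (kJ/mol).  ``region`` restricts the
    overlap bins (by coordinate) used to compute the offset.
    """
    common, ia, ib = np.intersect1d(
        np.round(a.bin_centers, 12), np.round(b.bin_centers, 12),
        return_indices=True,
    )
    if region is not None:
        keep = (common >= region[0]) & (common <= region[1])
        ia, ib = ia[keep], ib[keep]
    if len(ia) == 0:
        raise ValueError("profiles share no bins in the requested region")
    shift = float(np.mean(a.free_energy[ia] - b.free_energy[ib]))
    shifted = FreeEnergyProfile(
        bin_centers=b.bin_centers.copy(),
        free_energy=b.free_energy + shift,
        error=b.error.copy(),
        offset_convention=f"aligned(+{shift:.6g} kJ/mol)",
        window_offsets=b.window_offsets,
        iterations=b.iterations,
    )
    return shifted, shift


def write_profile(profile: FreeEnergyProfile, path, run_record_path=None,
                  extra=None) -> None:
    """Three-column profile table (center, G, error) plus optional JSON run record."""
    with open(path, "w") as fh:
        fh.write("# free-energy profile; columns: xi_nm G_kJmol err_kJmol; "
                 f"offset={profile.offset_convention}\n")
        for c, g, e in zip(profile.bin_centers, profile.free_energy, profile.error):
            fh.write(f"{c:.6f} {g:.6f} {e:.6f}\n")
    if run_record_path is not None:
        record = {
            "offset_convention": profile.offset_convention,
            "iterations": profile.iterations,
            "window_offsets_kJmol": (
                None if profile.window_offsets is None
                else [float(x) for x in profile.window_offsets]
            ),
        }
        if extra:
            record.update(extra)
        with open(run_record_path, "w") as fh:
            json.dump(record, fh, indent=1)


def read_profile(path) -> FreeEnergyProfile:
    data = np.loadtxt(path, comments="#")
    return FreeEnergyProfile(
        bin_centers=data[:, 0], free_energy=data[:, 1], error=data[:, 2]
    )
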