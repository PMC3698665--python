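"""MSD construction, anomalous-diffusion fitting, empiric relations and
percolation threshold estimation.

Anomalous diffusion is quantified by the power law MSD(t) = Gamma * t^alpha:
alpha = 1 is normal diffusion, alpha < 1 subdiffusion, alpha -> 0
confinement.  The fit is an ordinary least squares line in log-log space.
The time-dependent effective diffusion coefficient is
D_eff(t) = MSD(t) / (2 d (t - t0)) in d dimensions.

The empiric-relation helpers reproduce the composition of two fitted linear
relations, alpha(D_nro) and alpha(ln r_nro), into the derived
D_nro(ln r_nro) relation by eliminating alpha, and evaluate it at physical
obstacle radii.

The percolation-threshold estimator uses 6-connected site percolation on the
simple cubic lattice: the spanning probability R_L(p) (a cluster touching two
opposite faces along any axis) is measured for two lattice sizes over a grid
of occupancies, each curve is fitted with a Gaussian CDF, and the threshold
is the crossing point of the two fitted curves (located by bisection), which
cancels the leading finite-size shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

__all__ = [
    "MSDSeries", "MSDFit", "EmpiricFit", "PercolationConfig",
    "msd", "fit_anomalous", "effective_diffusion",
    "fit_alpha_vs_D", "fit_alpha_vs_lnr", "compose_D_of_r", "eval_D_of_r",
    "spanning_probability", "percolation_threshold", "logspace_subsample",
]


@dataclass
class MSDSeries:
    """Ensemble mean squared displacement versus time.

    ``times`` may be physical seconds or sweep counts; ``msd`` squared
    displacement in matching units; ``n_eff`` the number of molecules
    contributing at each time point.
    """

    times: np.ndarray
    msd: np.ndarray
    n_eff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.msd.shape:
            raise ValueError("times and msd must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.msd < -1e-12):
            raise ValueError("msd must be non-negative")


@dataclass
class MSDFit:
    """Power-law fit MSD = Gamma * t^alpha with standard errors."""

    Gamma: float
    alpha: float
    se_Gamma: float
    se_alpha: float
    fit_window: tuple[float, float]


@dataclass
class EmpiricFit:
    """A fitted linear relation y = slope * x + intercept.

    ``transform`` records the abscissa: "identity" for y = alpha vs
    x = D_nro, "log" for x = ln(r_nro)."""

    slope: float
    intercept: float
    se_slope: float = float("nan")
    se_intercept: float = float("nan")
    transform: str = "identity"


@dataclass
class PercolationConfig:
    lattice_sizes: tuple[int, ...] = (16, 32)
    replicates: int = 200
    p_grid: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lattice_sizes) < 2:
            raise ValueError("need at least two lattice sizes")
        if self.replicates < 20:
            raise ValueError("need at least 20 replicates")
        if self.p_grid is None:
            self.p_grid = np.arange(0.25, 0.401, 0.01)
        self.p_grid = np.asarray(self.p_grid, dtype=float)


# ---------------------------------------------------------------------------
# MSD and anomalous fit
# ---------------------------------------------------------------------------

def msd(positions: np.ndarray, times: np.ndarray | None = None) -> MSDSeries:
    """Ensemble MSD from a (T, N, 3) position array (or precomputed input).

    Displacements are measured from each molecule's position at the first
    recorded time.  NaN rows (molecules removed by reaction) are excluded
    per time point.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3 or positions.shape[2] != 3:
        raise ValueError("positions must have shape (T, N, 3)")
    if positions.shape[1] == 0:
        raise ValueError("empty ensemble")
    disp = positions - positions[0]
    sq = (disp ** 2).sum(axis=2)                      # (T, N)
    valid = np.isfinite(sq)
    n_eff = valid.sum(axis=1)
    if np.any(n_eff == 0):
        raise ValueError("no surviving molecules at some time point")
    mean = np.where(valid, sq, 0.0).sum(axis=1) / n_eff
    if times is None:
        times = np.arange(positions.shape[0], dtype=float)
    # drop t = t0 where msd is identically zero only if times start there
    return MSDSeries(times=np.asarray(times, float)[1:], msd=mean[1:],
                     n_eff=n_eff[1:])


def logspace_subsample(s: MSDSeries, points_per_decade: int = 50) -> MSDSeries:
    """Thin an MSD series to roughly log-uniform time spacing.

    Dense linear sampling over-weights the last decade in a log-log fit;
    thinning restores equal weight per decade.
    """
    t = s.times
    lo, hi = np.log10(t[0]), np.log10(t[-1])
    n = max(2, int(np.ceil((hi - lo) * points_per_decade)))
    targets = np.logspace(lo, hi, n)
    idx = np.unique(np.searchsorted(t, targets).clip(0, t.size - 1))
    return MSDSeries(times=t[idx], msd=s.msd[idx],
                     n_eff=None if s.n_eff is None else s.n_eff[idx])


def fit_anomalous(s: MSDSeries,
                  window: tuple[float, float] | None = None) -> MSDFit:
    """Fit MSD = Gamma * t^alpha by OLS on (log t, log msd).

    ``window`` restricts the fit to times in [t_lo, t_hi]; by default the
    first decade after the first recorded time is excluded (early-time
    lattice/step transients).  Requires at least 10 strictly positive MSD
    points in the window.
    """
    t, m = s.times, s.msd
    if window is None:
        window = (t[0] * 10.0, t[-1])
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 10:
        raise ValueError("need at least 10 points in the fit window")
    t, m = t[sel], m[sel]
    if np.any(m <= 0):
        raise ValueError("msd must be strictly positive inside the fit window")
    res = stats.linregress(np.log(t), np.log(m))
    gamma = float(np.exp(res.intercept))
    return MSDFit(
        Gamma=gamma,
        alpha=float(res.slope),
        se_Gamma=gamma * float(res.intercept_stderr),
        se_alpha=float(res.stderr),
        fit_window=(float(lo), float(hi)),
    )


def effective_diffusion(s: MSDSeries, d: int = 3,
                        t0: float | None = None) -> MSDSeries:
    """Time-dependent D_eff(t) = MSD(t) / (2 d (t - t0)).

    ``t0`` defaults to one time-grid spacing before the first recorded
    point (displacements in the series are measured from there).  Returns a
    series of D_eff values on the same time grid.
    """
    if d not in (1, 3):
        raise ValueError("d must be 1 (per-axis) or 3")
    t, m = s.times, s.msd
    if t0 is None:
        t0 = t[0] - (t[1] - t[0]) if t.size > 1 else 0.0
    if np.any(t <= t0):
        raise ValueError("all times must exceed t0")
    deff = m / (2.0 * d * (t - t0))
    return MSDSeries(times=t, msd=deff, n_eff=s.n_eff)


# ---------------------------------------------------------------------------
# Empiric relations
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray, transform: str) -> EmpiricFit:
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa (zero variance)")
    res = stats.linregress(x, y)
    return EmpiricFit(slope=float(res.slope), intercept=float(res.intercept),
                      se_slope=float(res.stderr),
                      se_intercept=float(res.intercept_stderr),
                      transform=transform)


def fit_alpha_vs_D(points) -> EmpiricFit:
    """OLS of anomaly exponent alpha on obstacle diffusion coefficient D_nro."""
    pts = np.asarray(points, dtype=float)
    return _ols(pts[:, 0], pts[:, 1], transform="identity")


def fit_alpha_vs_lnr(points) -> EmpiricFit:
    """OLS of alpha on ln(r_nro); radii must be positive."""
    pts = np.asarray(points, dtype=float)
    if np.any(pts[:, 0] <= 0):
        raise ValueError("radii must be positive")
    return _ols(np.log(pts[:, 0]), pts[:, 1], transform="log")


def compose_D_of_r(fit_aD: EmpiricFit, fit_ar: EmpiricFit) -> EmpiricFit:
    """Eliminate alpha between alpha(D) and alpha(ln r) to get D(ln r).

    From alpha = a1 * D + b1 and alpha = a2 * ln r + b2:
    D = (a2 / a1) * ln r + (b2 - b1) / a1.
    """
    if fit_aD.slope == 0:
        raise ValueError("alpha(D) slope is zero; cannot eliminate alpha")
    return EmpiricFit(
        slope=fit_ar.slope / fit_aD.slope,
        intercept=(fit_ar.intercept - fit_aD.intercept) / fit_aD.slope,
        transform="log",
    )


def eval_D_of_r(fit: EmpiricFit, r_nm: float) -> float:
    """Evaluate D(r) = slope * ln(r) + intercept at a radius in nm."""
    if r_nm <= 0:
        raise ValueError("radius must be positive")
    return fit.slope * float(np.log(r_nm)) + fit.intercept


# ---------------------------------------------------------------------------
# Percolation threshold
# ---------------------------------------------------------------------------

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _spans(occupied: np.ndarray) -> bool:
    """True if a 6-connected cluster touches two opposite faces of the cube."""
    labels, n = ndimage.label(occupied, structure=_STRUCT6)
    if n == 0:
        return False
    for ax in range(3):
        first = np.unique(np.take(labels, 0, axis=ax))
        last = np.unique(np.take(labels, -1, axis=ax))
        common = np.intersect1d(first, last, assume_unique=True)
        if common.size and common[-1] > 0:
            return True
    return False


def spanning_probability(p: float, size: int, replicates: int,
                         rng: np.random.Generator) -> float:
    """Monte Carlo estimate of the spanning probability R_L(p)."""
    hits = 0
    for _ in range(replicates):
        occ = rng.random((size, size, size)) < p
        if _spans(occ):
            hits += 1
    return hits / replicates


def percolation_threshold(cfg: PercolationConfig) -> dict:
    """Estimate p_c as the crossing of spanning curves of two lattice sizes.

    Each R_L(p) curve is fitted with a Gaussian CDF Phi((p - mu)/sigma);
    the crossing of the fitted curves of the smallest and largest size is
    located by bisection on their difference.  Returns a dict with the
    estimate and the per-size curves.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.p_grid
    curves: dict[int, np.ndarray] = {}
    for size in cfg.lattice_sizes:
        curves[size] = np.array([
            spanning_probability(p, size, cfg.replicates, rng) for p in grid])
        if np.any(np.diff(curves[size]) < -0.5):
            raise RuntimeError("spanning curve wildly non-monotone")

    def fit_cdf(r: np.ndarray) -> tuple[float, float]:
        def f(p, mu, sig):
            return stats.norm.cdf((p - mu) / sig)
        p0 = (grid[np.argmin(np.abs(r - 0.5))], 0.02)
        popt, _ = optimize.curve_fit(f, grid, r, p0=p0,
                                     bounds=([grid[0] - 0.1, 1e-4],
                                             [grid[-1] + 0.1, 0.5]))
        return float(popt[0]), float(popt[1])

    sizes = sorted(cfg.lattice_sizes)
    mu_s, sig_s = fit_cdf(curves[sizes[0]])
    mu_l, sig_l = fit_cdf(curves[sizes[-1]])

    def diff(p):
        return (stats.norm.cdf((p - mu_l) / sig_l)
                - stats.norm.cdf((p - mu_s) / sig_s))

    lo, hi = float(grid[0]), float(grid[-1])
    if diff(lo) * diff(hi) >= 0:
        raise RuntimeError("no crossing of spanning curves in the scanned range")
    p_c = float(optimize.brentq(diff, lo, hi, xtol=1e-5))
    return {"p_c": p_c, "curves": curves, "p_grid": grid,
            "cdf_params": {sizes[0]: (mu_s, sig_s), sizes[-1]: (mu_l, sig_l)}}
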