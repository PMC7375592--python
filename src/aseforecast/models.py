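"""Stochastic population-dynamics simulators.

Two generators are provided:

* :func:`simulate_linear_response` — a one-dimensional linear response
  model at marginal stability.  In a high-dimensional community with many
  weak interactions, dynamics along the dominant eigenvector reduce to

      x_{t+1} = eta_t * (x_t + lam * (x_s - x_t)),   eta_t ~ N(1, eps)

  where ``lam`` is the dominant restoring eigenvalue and ``x_s`` the
  equilibrium.  As ``lam -> 0`` the restoring force vanishes relative to
  the multiplicative noise and the series develops scale-free excursions
  (avalanches) with duration exponent 3/2, size exponent 4/3 and
  size-duration exponent 3/2.

* :func:`simulate_chaotic_surrogate` — a seasonally forced stochastic
  Ricker map used as a qualitative stand-in for mechanistically chaotic
  community dynamics.  It is NOT a fitted ecosystem model; it exists so
  that robustness of the forecasting stack can be probed on dynamics that
  are chaotic rather than marginally stable.

:func:`reference_shape` turns a long marginal-stability run into the
smooth converged average avalanche shape that the ASE augmentation
stretches to arbitrary durations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import make_interp_spline

from .avalanche import ShapeCurve, average_shape, compute_baseline, segment_avalanches
from .series import UniformSeries

__all__ = [
    "MarginalParams",
    "SurrogateParams",
    "simulate_linear_response",
    "simulate_chaotic_surrogate",
    "reference_shape",
    "SmoothShape",
    "BURN_IN",
]

#: steps discarded before any internal analysis of a simulated run
BURN_IN = 1000


@dataclass(frozen=True)
class MarginalParams:
    """Parameters of the linear response model."""

    lam: float                 # dominant eigenvalue, 0 < lam <= 1
    x_s: float = 1.0           # equilibrium value
    eps: float = 0.01          # sd of the multiplicative noise eta ~ N(1, eps)
    n_steps: int = 100_000
    x0: float | None = None    # default: start at equilibrium
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lam <= 1):
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the seasonally forced stochastic Ricker surrogate."""

    forcing: float = 0.0       # seasonal forcing amplitude
    noise_sd: float = 0.0      # sd of the additive log-scale noise
    period: int = 365          # steps per season
    r: float = 2.6             # intrinsic growth rate (chaotic for r > ~2.69 with forcing)
    n_steps: int = 100_000
    x0: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forcing < 0 or self.noise_sd < 0:
            raise ValueError("forcing and noise_sd must be >= 0")
        if self.period < 1 or self.n_steps < 2:
            raise ValueError("period >= 1 and n_steps >= 2 required")


def simulate_linear_response(params: MarginalParams) -> UniformSeries:
    """Forward-iterate the linear response model (dt = 1 step).

    The update is explicit: ``x_{t+1} = eta_t * (x_t + lam*(x_s - x_t))``
    with ``eta_t`` drawn i.i.d. from N(1, eps).  Reproducible given the
    seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_steps
    x = np.empty(n)
    x[0] = params.x_s if params.x0 is None else params.x0
    eta = rng.normal(1.0, params.eps, size=n - 1) if params.eps > 0 else np.ones(n - 1)
    lam, x_s = params.lam, params.x_s
    one_m_lam = 1.0 - lam
    drift = lam * x_s
    xi = x[0]
    for t in range(n - 1):
        xi = eta[t] * (one_m_lam * xi + drift)
        x[t + 1] = xi
    return UniformSeries(t0=0.0, dt=1.0, values=x,
                         label=f"linear_response(lam={params.lam:g},seed={params.seed})")


def simulate_chaotic_surrogate(params: SurrogateParams) -> UniformSeries:
    """Seasonally forced stochastic Ricker map (dt = 1 step).

        x_{t+1} = x_t * exp( r*(1 + forcing*sin(2*pi*t/period))*(1 - x_t)
                             + noise_t ),   noise_t ~ N(0, noise_sd)

    Positivity is guaranteed by the exponential form.  Large forcing
    drives the map through period doubling into chaos.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_steps
    x = np.empty(n)
    x[0] = params.x0
    noise = (rng.normal(0.0, params.noise_sd, size=n - 1)
             if params.noise_sd > 0 else np.zeros(n - 1))
    w = 2.0 * math.pi / params.period
    r, phi = params.r, params.forcing
    xi = x[0]
    for t in range(n - 1):
        growth = r * (1.0 + phi * math.sin(w * t)) * (1.0 - xi)
        xi = xi * math.exp(growth + noise[t])
        x[t + 1] = xi
    return UniformSeries(t0=0.0, dt=1.0, values=x,
                         label=f"chaotic_surrogate(phi={params.forcing:g},seed={params.seed})")


# ---------------------------------------------------------------------------
# converged reference shape

class SmoothShape:
    """Quadratic-spline representation of an average avalanche shape.

    Evaluable at arbitrary t' in [0, 1]; endpoints pinned to 0; clipped
    to be non-negative.
    """

    def __init__(self, grid: np.ndarray, mean_excess: np.ndarray, n_events: int):
        grid = np.asarray(grid, dtype=float)
        y = np.asarray(mean_excess, dtype=float).copy()
        y[0] = 0.0
        y[-1] = 0.0
        self.grid = grid
        self.mean_excess = y
        self.n_events = int(n_events)
        self._spline = make_interp_spline(grid, y, k=2)

    def __call__(self, t_prime) -> np.ndarray:
        tp = np.clip(np.asarray(t_prime, dtype=float), 0.0, 1.0)
        return np.clip(self._spline(tp), 0.0, None)

    def integral(self) -> float:
        tt = np.linspace(0.0, 1.0, 2001)
        return float(np.trapezoid(self(tt), tt))

    def to_curve(self) -> ShapeCurve:
        return ShapeCurve(grid=self.grid, mean_excess=self.mean_excess,
                          n_events=self.n_events)


def _cache_path(cache_dir: Path, lam: float, n_steps: int, seed: int, n_grid: int) -> Path:
    key = f"refshape_lam{lam:g}_n{n_steps}_seed{seed}_grid{n_grid}.json"
    return cache_dir / key


def reference_shape(lam: float = 1e-3, n_steps: int = 2_000_000, seed: int = 0,
                    n_grid: int = 101, cache_dir: str | Path | None = None,
                    min_events: int = 1000) -> SmoothShape:
    """Converged average avalanche shape of the linear response model.

    Simulates the model, segments excursions above the run mean, averages
    the rescaled trajectories, and wraps the result in a quadratic spline
    evaluable at arbitrary normalized time.  The result is cached to disk
    (JSON keyed by ``(lam, n_steps, seed, n_grid)``) when ``cache_dir`` is
    given, since long runs take seconds to minutes.

    Raises
    ------
    ValueError
        If the run yields fewer than ``min_events`` usable events.
    """
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        path = _cache_path(cache_dir, lam, n_steps, seed, n_grid)
        if path.exists():
            payload = json.loads(path.read_text())
            return SmoothShape(np.array(payload["grid"]),
                               np.array(payload["mean_excess"]),
                               payload["n_events"])

    series = simulate_linear_response(
        MarginalParams(lam=lam, n_steps=n_steps, seed=seed))
    series = series.slice(BURN_IN, len(series))
    catalog = segment_avalanches(series, compute_baseline(series))
    usable = sum(1 for e in catalog.events if e.trajectory.size >= 2)
    if usable < min_events:
        raise ValueError(
            f"only {usable} usable events (need >= {min_events}); "
            f"increase n_steps")
    curve = average_shape(catalog, n_grid=n_grid)
    shape = SmoothShape(curve.grid, curve.mean_excess, curve.n_events)

    if cache_dir is not None:
        payload = {"grid": shape.grid.tolist(),
                   "mean_excess": shape.mean_excess.tolist(),
                   "n_events": shape.n_events,
                   "key": {"lam": lam, "n_steps": n_steps,
                           "seed": seed, "n_grid": n_grid}}
        path.write_text(json.dumps(payload))
    return shape
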