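"""Avalanche segmentation and scaling statistics.

An *avalanche* is a maximal run of consecutive samples strictly above a
reference baseline.  Each event has a duration ``T`` (run length times the
sampling interval), a size ``S`` (rectangle-rule area between the signal
and the baseline), and a trajectory (the excess values).  Critical systems
produce power-law distributions of ``T`` and ``S`` with exponents alpha and
tau, a size-duration law ``<S_T> = b * T**gamma`` with
``gamma = (alpha - 1)/(tau - 1)``, and a universal average event shape
obtained by rescaling every event to unit duration and unit area.

The statistical machinery here follows standard heavy-tail practice:
log-binned densities for display, and binning-free maximum-likelihood fits
of truncated power-law vs. exponential models compared through Akaike
weights for inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .series import UniformSeries

__all__ = [
    "AvalancheEvent",
    "AvalancheCatalog",
    "BinnedDistribution",
    "TruncatedPowerLawFit",
    "ModelComparison",
    "SizeDurationFit",
    "ShapeCurve",
    "compute_baseline",
    "segment_avalanches",
    "log_binned_density",
    "fit_truncated_power_law",
    "compare_power_vs_exponential",
    "bin_average_size_duration",
    "fit_size_duration",
    "average_shape",
    "scaling_relation_gamma",
    "pool_catalogs",
    "sample_truncated_power_law",
    "sample_truncated_exponential",
]

#: sentinel baseline for catalogs pooled from mixed origins
MIXED_BASELINE = float("nan")


@dataclass(frozen=True)
class AvalancheEvent:
    """One excursion above baseline."""

    start_time: float
    duration: float            # run length * dt
    size: float                # sum(excess) * dt, rectangle rule
    trajectory: np.ndarray     # excess amplitudes, all > 0
    truncated: bool = False    # clipped by a series boundary

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectory", np.asarray(self.trajectory, dtype=float))


@dataclass(frozen=True)
class AvalancheCatalog:
    """Segmented events from one series (or pooled from several)."""

    events: tuple[AvalancheEvent, ...]
    baseline: float
    dt: float
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.events)

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events], dtype=float)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([e.size for e in self.events], dtype=float)


@dataclass(frozen=True)
class BinnedDistribution:
    """Log-binned event density (events per unit width, or per admissible
    discrete time point when durations are quantized)."""

    bin_edges: np.ndarray
    densities: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])


@dataclass(frozen=True)
class TruncatedPowerLawFit:
    """MLE of ``p(x) = C * x**(-exponent)`` normalized on [lo, hi]."""

    exponent: float
    support: tuple[float, float]
    loglik: float
    aic: float
    n_used: int
    ci95: float                # half-width from observed Fisher information
    n_discarded: int = 0


@dataclass(frozen=True)
class ModelComparison:
    """Power law vs. exponential on the same support, via AIC."""

    aic_power: float
    aic_exp: float
    akaike_weight_power: float
    power_fit: TruncatedPowerLawFit | None = None
    exp_rate: float = float("nan")


@dataclass(frozen=True)
class SizeDurationFit:
    """Log-log fit of ``<S_T> = b * T**gamma``; b is the unit-duration size."""

    b: float
    gamma: float
    stderr_log10b: float
    fixed_gamma: bool


@dataclass(frozen=True)
class ShapeCurve:
    """Average avalanche trajectory on the unit grid.

    Every event is mapped to normalized time ``t' = t/T`` and rescaled so
    its own trapezoidal integral over [0, 1] is exactly 1, then averaged
    pointwise, so the mean curve also integrates to 1.
    """

    grid: np.ndarray
    mean_excess: np.ndarray
    n_events: int

    def integral(self) -> float:
        return float(np.trapezoid(self.mean_excess, self.grid))


# ---------------------------------------------------------------------------
# segmentation

def compute_baseline(series: UniformSeries, fraction: float = 1.0) -> float:
    """Reference level: ``fraction * mean(values)``.

    ``fraction = 1`` is the default (segment at the series mean); lowering
    it (e.g. to 0.1) admits more small events in sparse data.
    """
    if fraction <= 0:
        raise ValueError(f"baseline fraction must be > 0, got {fraction}")
    return fraction * float(series.values.mean())


def segment_avalanches(series: UniformSeries, baseline: float,
                       include_truncated: bool = False) -> AvalancheCatalog:
    """Cut a series into maximal runs strictly above ``baseline``.

    Duration is the run length times ``dt``; size is the rectangle-rule
    area of the excess, ``sum(x_i - baseline) * dt``.  Runs touching either
    end of the series have censored duration and size; they are flagged
    truncated and dropped unless ``include_truncated`` is set.
    """
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    x = series.values
    above = x > baseline
    # run boundaries: starts where above turns on, stops where it turns off
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [x.size]))

    events = []
    for s, e in zip(starts, stops):
        trunc = (s == 0) or (e == x.size)
        if trunc and not include_truncated:
            continue
        excess = x[s:e] - baseline
        events.append(AvalancheEvent(
            start_time=series.t0 + s * series.dt,
            duration=(e - s) * series.dt,
            size=float(excess.sum()) * series.dt,
            trajectory=excess,
            truncated=trunc,
        ))
    return AvalancheCatalog(events=tuple(events), baseline=baseline,
                            dt=series.dt, source_label=series.label)


def pool_catalogs(catalogs: list[AvalancheCatalog]) -> AvalancheCatalog:
    """Concatenate catalogs that share a sampling interval.

    Used to pool events across species (e.g. within a trophic level) when
    a single series yields too few events for stable fits.  The pooled
    baseline is set to NaN since the origins are mixed.
    """
    if not catalogs:
        raise ValueError("need at least one catalog")
    dt0 = catalogs[0].dt
    for c in catalogs[1:]:
        if abs(c.dt - dt0) > 1e-9 * abs(dt0):
            raise ValueError(f"mismatched dt: {c.dt} vs {dt0}")
    events = sorted((e for c in catalogs for e in c.events),
                    key=lambda e: e.start_time)
    return AvalancheCatalog(events=tuple(events), baseline=MIXED_BASELINE,
                            dt=dt0, source_label="pooled")


# ---------------------------------------------------------------------------
# binned densities

def _log_edges(lo: float, hi: float, bins_per_decade: int) -> np.ndarray:
    """Half-open log bins [edge_i, edge_{i+1}) covering [lo, hi]."""
    if hi == lo:
        # single degenerate bin around the common value
        return np.array([lo, lo * 10 ** (1.0 / bins_per_decade)])
    n = max(1, math.ceil(np.log10(hi / lo) * bins_per_decade - 1e-12))
    edges = lo * 10 ** (np.arange(n + 1) / bins_per_decade)
    while edges[-1] <= hi:            # ensure max strictly inside the last bin
        edges = np.append(edges, lo * 10 ** (edges.size / bins_per_decade))
    return edges


def log_binned_density(values, bins_per_decade: int = 5,
                       discrete_dt: float | None = None) -> BinnedDistribution:
    """Histogram on logarithmic bins, normalized to a density.

    Continuous data: density = count / bin width.  Discrete data (event
    durations quantized at the sampling interval ``discrete_dt``): density
    = count / (number of multiples of ``discrete_dt`` inside the bin), so
    that sparsely populated long-duration bins are weighted correctly.
    Values falling exactly on an edge belong to the right bin.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("no values to bin")
    if np.any(vals <= 0):
        raise ValueError("log binning requires strictly positive values")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    edges = _log_edges(vals.min(), vals.max(), bins_per_decade)
    # np.histogram closes the last bin on the right; emulate half-open bins
    idx = np.searchsorted(edges, vals, side="right") - 1
    counts = np.bincount(idx, minlength=edges.size - 1).astype(float)

    if discrete_dt is None:
        norm = np.diff(edges)
    else:
        norm = np.empty(edges.size - 1)
        for i in range(edges.size - 1):
            k_min = math.ceil(edges[i] / discrete_dt - 1e-12)
            k_max = math.ceil(edges[i + 1] / discrete_dt - 1e-12) - 1
            norm[i] = max(k_max - k_min + 1, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(counts > 0, counts / np.where(norm > 0, norm, np.nan), 0.0)
    dens = np.nan_to_num(dens, nan=0.0)
    return BinnedDistribution(bin_edges=edges, densities=dens, counts=counts)


# ---------------------------------------------------------------------------
# truncated power-law / exponential MLE

def _powerlaw_logC(alpha: float, lo: float, hi: float) -> float:
    """log of the normalization of x**(-alpha) on [lo, hi]."""
    if abs(alpha - 1.0) < 1e-9:
        return -math.log(math.log(hi / lo))
    om = 1.0 - alpha
    # C = om / (hi**om - lo**om); compute in logs to stay stable
    val = hi ** om - lo ** om
    return math.log(abs(om) / abs(val))


def _powerlaw_loglik(alpha: float, n: int, sum_log: float, lo: float, hi: float) -> float:
    return n * _powerlaw_logC(alpha, lo, hi) - alpha * sum_log


def sample_truncated_power_law(alpha: float, lo: float, hi: float, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF samples from ``p(x) ~ x**(-alpha)`` truncated to [lo, hi]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    om = 1.0 - alpha
    return (lo ** om + u * (hi ** om - lo ** om)) ** (1.0 / om)


def sample_truncated_exponential(rate: float, lo: float, hi: float, n: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF samples from ``p(x) ~ exp(-rate*x)`` truncated to [lo, hi]."""
    u = rng.random(n)
    if abs(rate) < 1e-15:
        return lo + u * (hi - lo)
    a, b = math.exp(-rate * lo), math.exp(-rate * hi)
    return -np.log(a - u * (a - b)) / rate


def fit_truncated_power_law(values, lo: float, hi: float) -> TruncatedPowerLawFit:
    """Maximum-likelihood power-law exponent on bounded support [lo, hi].

    The density ``p(x) = C x**(-alpha)`` with ``C = (1-alpha)/(hi**(1-alpha)
    - lo**(1-alpha))`` is normalizable on a bounded support for any real
    alpha, so the exponent is unconstrained.  Values outside the support
    are discarded (and counted); the restriction to a fixed window avoids
    bias from the short-duration resolution limit and the long-duration
    cutoff.  AIC uses one free parameter; the 95% CI half-width comes from
    the observed Fisher information at the optimum.
    """
    if lo >= hi:
        raise ValueError("support must satisfy lo < hi")
    vals = np.asarray(values, dtype=float)
    inside = vals[(vals >= lo) & (vals <= hi)]
    n = inside.size
    if n < 10:
        raise ValueError(f"need >= 10 values inside [{lo:g}, {hi:g}], got {n}")
    sum_log = float(np.log(inside).sum())

    res = minimize_scalar(
        lambda a: -_powerlaw_loglik(a, n, sum_log, lo, hi),
        bounds=(-10.0, 20.0), method="bounded",
        options={"xatol": 1e-10})
    alpha = float(res.x)
    ll = float(-res.fun)
    # observed Fisher information by central second difference
    h = 1e-4
    d2 = (_powerlaw_loglik(alpha + h, n, sum_log, lo, hi)
          - 2 * ll + _powerlaw_loglik(alpha - h, n, sum_log, lo, hi)) / h ** 2
    ci95 = 1.959963984540054 / math.sqrt(max(-d2, 1e-300))
    return TruncatedPowerLawFit(
        exponent=alpha, support=(lo, hi), loglik=ll, aic=2.0 - 2.0 * ll,
        n_used=n, ci95=ci95, n_discarded=int(vals.size - n))


def _exp_loglik(rate: float, n: int, sum_x: float, lo: float, hi: float) -> float:
    """Log-likelihood of C*exp(-rate*x) on [lo, hi] (any real rate)."""
    if abs(rate) < 1e-12:
        logC = -math.log(hi - lo)
    else:
        # C = rate / (exp(-rate*lo) - exp(-rate*hi)); stabilized via lo shift
        val = -math.expm1(-rate * (hi - lo))  # (1 - e^{-r(hi-lo)})
        logC = math.log(abs(rate) / abs(val)) + rate * lo
    return n * logC - rate * sum_x


def fit_truncated_exponential(values, lo: float, hi: float) -> tuple[float, float]:
    """MLE rate and log-likelihood of an exponential truncated to [lo, hi]."""
    vals = np.asarray(values, dtype=float)
    inside = vals[(vals >= lo) & (vals <= hi)]
    n = inside.size
    if n < 10:
        raise ValueError(f"need >= 10 values inside [{lo:g}, {hi:g}], got {n}")
    sum_x = float(inside.sum())
    res = minimize_scalar(
        lambda r: -_exp_loglik(r, n, sum_x, lo, hi),
        bounds=(-50.0 / (hi - lo), 5000.0 / (hi - lo)), method="bounded",
        options={"xatol": 1e-12})
    return float(res.x), float(-res.fun)


def compare_power_vs_exponential(values, lo: float, hi: float,
                                 fixed_exponent: float | None = None) -> ModelComparison:
    """Weight of evidence for a power law over an exponential via AIC.

    Both models are fit by MLE on the same truncated support.  With
    ``fixed_exponent`` given (e.g. the theoretical 3/2), the power-law
    likelihood is evaluated at that exponent with zero free parameters,
    so its AIC is ``-2*loglik``.  The pairwise Akaike weight for the
    power law is ``1/(1 + exp((AIC_pow - AIC_exp)/2))``.
    """
    vals = np.asarray(values, dtype=float)
    inside = vals[(vals >= lo) & (vals <= hi)]
    if fixed_exponent is None:
        pfit = fit_truncated_power_law(inside, lo, hi)
        aic_pow = pfit.aic
    else:
        n = inside.size
        if n < 10:
            raise ValueError(f"need >= 10 values inside [{lo:g}, {hi:g}], got {n}")
        sum_log = float(np.log(inside).sum())
        ll = _powerlaw_loglik(fixed_exponent, n, sum_log, lo, hi)
        pfit = TruncatedPowerLawFit(exponent=fixed_exponent, support=(lo, hi),
                                    loglik=ll, aic=-2.0 * ll, n_used=n, ci95=0.0,
                                    n_discarded=int(vals.size - n))
        aic_pow = pfit.aic
    rate, ll_exp = fit_truncated_exponential(inside, lo, hi)
    aic_exp = 2.0 - 2.0 * ll_exp
    # logistic of half the AIC difference, clipped against overflow
    delta = np.clip((aic_pow - aic_exp) / 2.0, -700, 700)
    weight = 1.0 / (1.0 + math.exp(delta))
    return ModelComparison(aic_power=aic_pow, aic_exp=aic_exp,
                           akaike_weight_power=weight, power_fit=pfit,
                           exp_rate=rate)


# ---------------------------------------------------------------------------
# size-duration scaling

def bin_average_size_duration(catalog: AvalancheCatalog,
                              bins_per_decade: int = 5) -> list[tuple[float, float]]:
    """Mean event size in logarithmic duration bins.

    Each occupied bin contributes a ``(T, <S>)`` pair where ``T`` is the
    geometric mean of the member durations (so noiseless power-law
    catalogs are recovered exactly) and ``<S>`` the arithmetic mean size.
    Averaging within duration bins stops the very numerous small events
    from dominating the log-log regression.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    T = catalog.durations
    S = catalog.sizes
    edges = _log_edges(T.min(), T.max(), bins_per_decade)
    idx = np.searchsorted(edges, T, side="right") - 1
    pairs = []
    for i in range(edges.size - 1):
        mask = idx == i
        if mask.any():
            center = float(np.exp(np.log(T[mask]).mean()))
            pairs.append((center, float(S[mask].mean())))
    return pairs


def fit_size_duration(pairs, gamma: float | None = None) -> SizeDurationFit:
    """OLS of ``log10 <S>`` on ``log10 T``: ``<S_T> = b * T**gamma``.

    With ``gamma`` fixed (the usual mode: gamma = 3/2 is conserved across
    systems) only the intercept ``log10 b`` is estimated, as the mean of
    ``log10 <S> - gamma * log10 T``.
    """
    pairs = list(pairs)
    logT = np.log10([p[0] for p in pairs])
    logS = np.log10([p[1] for p in pairs])
    n = logT.size
    if gamma is None:
        if n < 2:
            raise ValueError("need >= 2 pairs to fit gamma freely")
        A = np.column_stack([np.ones(n), logT])
        coef, *_ = np.linalg.lstsq(A, logS, rcond=None)
        log10b, gamma_hat = float(coef[0]), float(coef[1])
        resid = logS - A @ coef
        if n > 2:
            s2 = float(resid @ resid) / (n - 2)
            cov00 = s2 * np.linalg.inv(A.T @ A)[0, 0]
            stderr = math.sqrt(cov00)
        else:
            stderr = 0.0
        return SizeDurationFit(b=10 ** log10b, gamma=gamma_hat,
                               stderr_log10b=stderr, fixed_gamma=False)
    if n < 1:
        raise ValueError("need >= 1 pair with gamma fixed")
    resid = logS - gamma * logT
    log10b = float(resid.mean())
    stderr = float(resid.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return SizeDurationFit(b=10 ** log10b, gamma=float(gamma),
                           stderr_log10b=stderr, fixed_gamma=True)


def scaling_relation_gamma(alpha: float, tau: float) -> float:
    """Exponent identity ``gamma = (alpha - 1) / (tau - 1)``.

    Links the duration exponent, size exponent and size-duration exponent
    of a self-consistent avalanche ensemble.
    """
    if tau == 1:
        raise ValueError("tau = 1: scaling relation undefined")
    return (alpha - 1.0) / (tau - 1.0)


# ---------------------------------------------------------------------------
# average shape

def _event_unit_curve(trajectory: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """One event rescaled to unit duration and unit area on ``grid``.

    Sample i of an n-sample run sits at t' = (i + 0.5)/n; the curve is
    pinned to 0 at t' = 0 and 1 and linearly interpolated, then divided
    by its own trapezoidal integral.
    """
    n = trajectory.size
    tp = (np.arange(n) + 0.5) / n
    tp = np.concatenate(([0.0], tp, [1.0]))
    y = np.concatenate(([0.0], trajectory, [0.0]))
    curve = np.interp(grid, tp, y)
    integral = np.trapezoid(curve, grid)
    if integral <= 0:
        raise ValueError("degenerate event: non-positive area")
    return curve / integral


def average_shape(catalog: AvalancheCatalog, n_grid: int = 101,
                  min_samples_per_event: int = 2) -> ShapeCurve:
    """Average avalanche trajectory in rescaled coordinates.

    Each qualifying event (at least ``min_samples_per_event`` samples) is
    mapped to normalized time t' in [0, 1], renormalized to unit area, and
    the curves are averaged pointwise.  The result is invariant under
    rescaling every event by (c*S, c*T): shape, not scale, is retained.
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    curves = [
        _event_unit_curve(e.trajectory, grid)
        for e in catalog.events if e.trajectory.size >= min_samples_per_event
    ]
    if not curves:
        raise ValueError(
            f"no events with >= {min_samples_per_event} samples in catalog")
    mean = np.mean(curves, axis=0)
    return ShapeCurve(grid=grid, mean_excess=mean, n_events=len(curves))
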