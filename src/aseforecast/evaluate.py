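"""Error metrics, training-set protocols and benchmark runners.

The benchmarks quantify when scale-extrapolated (ASE) training data helps
a nearest-neighbor forecaster predict extreme events:

* ``lambda_sweep`` — accuracy vs. distance from marginal stability;
* ``length_sweep`` — accuracy vs. amount of historical data;
* ``amplitude_extrapolation`` — train on low-amplitude segments, predict
  the largest few percent of an independent test run (the Black Swan
  setting);
* ``empirical_rank`` — the same low-train/high-test split applied to a
  single externally supplied series cut into consecutive segments.

Every protocol compares the four predictors (raw S-map, ASE-only S-map,
the raw+ASE hybrid, and AR1) on identical training sets and targets, and
reports per-method relative-error summaries plus a paired two-sided
t-test between the hybrid and the raw S-map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .ase import ASEConfig, build_augmented_dataset, default_durations, fit_unit_size
from .avalanche import compute_baseline, segment_avalanches
from .forecast import SmapConfig, forecast_series
from .models import BURN_IN, MarginalParams, SmoothShape, reference_shape, \
    simulate_linear_response
from .series import UniformSeries

__all__ = [
    "ErrorSummary",
    "ExperimentConfig",
    "ConditionResult",
    "BenchmarkResult",
    "relative_error",
    "random_segments",
    "amplitude_rank_protocol",
    "run_benchmark",
]

logger = logging.getLogger("aseforecast")

METHODS = ("smap", "smap_ase", "hybrid", "ar1")


@dataclass(frozen=True)
class ErrorSummary:
    """Distribution summary of relative errors."""

    median: float
    q25: float
    q75: float
    mean: float
    n: int

    @classmethod
    def from_errors(cls, errors: np.ndarray) -> "ErrorSummary":
        errors = np.asarray(errors, dtype=float)
        if errors.size < 1:
            raise ValueError("no errors to summarize")
        q25, med, q75 = np.percentile(errors, [25, 50, 75])
        return cls(median=float(med), q25=float(q25), q75=float(q75),
                   mean=float(errors.mean()), n=int(errors.size))

    def as_dict(self) -> dict:
        return {"median": self.median, "q25": self.q25, "q75": self.q75,
                "mean": self.mean, "n": self.n}


@dataclass(frozen=True)
class ExperimentConfig:
    """One benchmark run.

    ``sim`` sets the generating model for simulated protocols (its
    ``n_steps`` is the training-simulation length); the test simulation
    uses an independent seed.  ``conditions`` is the swept quantity:
    lambda values for ``lambda_sweep``, training lengths for
    ``length_sweep``; ignored otherwise.
    """

    protocol: str
    n_train_sets: int = 100
    train_length: int = 1000
    n_test_points: int = 300
    smap: SmapConfig = field(default_factory=SmapConfig)
    sim: MarginalParams = field(default_factory=lambda: MarginalParams(lam=1e-3))
    seed: int = 0
    target_fraction: float = 0.05
    train_fraction: float = 0.5
    conditions: tuple[float, ...] = ()
    test_length: int | None = None          # default: sim.n_steps
    methods: tuple[str, ...] = METHODS
    gamma: float = 1.5
    series: UniformSeries | None = None     # input for empirical_rank
    shape: SmoothShape | None = None        # reference shape; built if absent
    shape_cache_dir: str | None = None
    ase_t_max: float | None = None          # longest synthetic event duration

    def __post_init__(self) -> None:
        if self.protocol not in ("lambda_sweep", "length_sweep",
                                 "amplitude_extrapolation", "empirical_rank"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not (0 < self.target_fraction <= 1) or not (0 < self.train_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.n_train_sets < 1 or self.n_test_points < 1:
            raise ValueError("counts must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass(frozen=True)
class ConditionResult:
    """One swept condition: per-method error summaries and the paired test."""

    params: dict
    methods: dict                 # name -> ErrorSummary
    p_value: float                # hybrid vs raw S-map, paired two-sided t-test
    n_failed_sets: int = 0

    def as_dict(self) -> dict:
        return {"params": self.params,
                "methods": {k: v.as_dict() for k, v in self.methods.items()},
                "p_value": self.p_value,
                "n_failed_sets": self.n_failed_sets}


@dataclass(frozen=True)
class BenchmarkResult:
    protocol: str
    conditions: tuple[ConditionResult, ...]

    def as_dict(self) -> dict:
        return {"protocol": self.protocol,
                "conditions": [c.as_dict() for c in self.conditions]}


# ---------------------------------------------------------------------------
# metrics and segmentation protocols

def relative_error(prediction: float, truth: float, scale: float) -> float:
    """``|prediction - truth| / scale``.

    ``scale`` is the mean absolute amplitude of the test series: a global
    normalization that keeps the metric finite at near-zero truths.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    return abs(prediction - truth) / scale


def random_segments(series: UniformSeries, length: int, n: int,
                    seed: int) -> list[UniformSeries]:
    """n random contiguous segments of exactly ``length`` samples.

    Start indices are uniform with replacement; reproducible given the
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length > len(series):
        raise ValueError(f"segment length {length} exceeds series length {len(series)}")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(series) - length + 1, size=n)
    return [series.slice(int(s), int(s) + length) for s in starts]


def amplitude_rank_protocol(series: UniformSeries, seg_length: int,
                            train_fraction: float = 0.5,
                            target_fraction: float = 0.05):
    """Low-amplitude training segments and high-amplitude test targets.

    The series is cut into consecutive non-overlapping segments of
    ``seg_length``; the ``train_fraction`` with lowest mean amplitude
    become training sets.  Test indices are the ``ceil(target_fraction *
    n_eligible)`` largest-amplitude points outside every training
    segment.  Returns ``(training segments, test indices)``.
    """
    if not (0 < train_fraction <= 1) or not (0 < target_fraction <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    n_seg = len(series) // seg_length
    if n_seg < 2:
        raise ValueError("series too short for at least 2 segments")
    starts = np.arange(n_seg) * seg_length
    means = np.array([series.values[s:s + seg_length].mean() for s in starts])
    order = np.argsort(means, kind="stable")
    n_train = max(1, int(round(train_fraction * n_seg)))
    train_starts = np.sort(starts[order[:n_train]])
    segments = [series.slice(int(s), int(s) + seg_length) for s in train_starts]

    in_train = np.zeros(len(series), dtype=bool)
    for s in train_starts:
        in_train[s:s + seg_length] = True
    eligible = np.flatnonzero(~in_train)
    n_test = math.ceil(target_fraction * eligible.size)
    amp_order = np.argsort(series.values[eligible], kind="stable")[::-1]
    test_idx = np.sort(eligible[amp_order[:n_test]])
    return segments, test_idx


# ---------------------------------------------------------------------------
# benchmark internals

def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def _admissible_targets(test: UniformSeries, smap: SmapConfig,
                        top_fraction: float | None, n_points: int,
                        seed: int) -> np.ndarray:
    """Query origin indices in the test series.

    ``top_fraction`` set: origins whose horizon-P truth lies in the top
    fraction of test amplitudes; otherwise uniform random origins.  Capped
    at ``n_points`` by seeded subsampling.
    """
    span = (smap.m - 1) * smap.tau_delay
    origins = np.arange(span, len(test) - smap.horizon)
    if top_fraction is not None:
        truths = test.values[origins + smap.horizon]
        n_top = max(1, math.ceil(top_fraction * origins.size))
        order = np.argsort(truths, kind="stable")[::-1]
        origins = np.sort(origins[order[:n_top]])
    rng = np.random.default_rng(seed)
    if origins.size > n_points:
        origins = np.sort(rng.choice(origins, size=n_points, replace=False))
    return origins


def _augment_training_segment(segment: UniformSeries, smap: SmapConfig,
                              gamma: float, shape: SmoothShape,
                              t_max: float | None = None):
    """ASE-augment one training segment; None if it has no usable events."""
    baseline = compute_baseline(segment)
    catalog = segment_avalanches(segment, baseline)
    if len(catalog) == 0:
        return None
    b = fit_unit_size(catalog, gamma=gamma).b
    span = (smap.m - 1) * smap.tau_delay
    if t_max is None:
        longest = float(catalog.durations.max())
        # the ladder must extend well past the embedding+horizon window:
        # only events much longer than the forecast window carry the slow
        # within-event dynamics that horizon-P prediction of large
        # excursions needs
        t_max = max(10.0 * longest, 20.0 * (span + smap.horizon))
    durations = default_durations(segment.dt, t_max)
    cfg = ASEConfig(gamma=gamma, durations=durations, baseline=baseline,
                    dt=segment.dt, pad=span + 1)
    return build_augmented_dataset(segment, cfg, shape, b)


def _evaluate_condition(training_segments, test: UniformSeries,
                        targets: np.ndarray, config: ExperimentConfig,
                        params: dict) -> ConditionResult:
    scale = float(np.mean(np.abs(test.values)))
    shape = config.shape
    if shape is None and ({"smap_ase", "hybrid"} & set(config.methods)):
        shape = reference_shape(cache_dir=config.shape_cache_dir)
    n_sets = len(training_segments)
    per_method: dict[str, list[np.ndarray]] = {m: [] for m in config.methods}
    per_set_mean = {m: np.full(n_sets, np.nan) for m in config.methods}
    n_failed = 0
    for i_set, segment in enumerate(training_segments):
        needs_ase = {"smap_ase", "hybrid"} & set(config.methods)
        augmented = None
        if needs_ase:
            augmented = _augment_training_segment(segment, config.smap,
                                                  config.gamma, shape,
                                                  t_max=config.ase_t_max)
            if augmented is None:
                n_failed += 1
                logger.debug("training segment without events: ASE skipped")
        for method in config.methods:
            train = segment
            if method in ("smap_ase", "hybrid"):
                if augmented is None:
                    continue
                train = augmented
            try:
                out = forecast_series(train, test, method, config.smap,
                                      query_indices=targets)
            except ValueError as exc:
                logger.debug("method %s failed on a training set: %s", method, exc)
                continue
            errs = np.abs(out[:, 2] - out[:, 1]) / scale
            per_method[method].append(errs)
            per_set_mean[method][i_set] = float(errs.mean())

    summaries = {}
    for method in config.methods:
        if per_method[method]:
            summaries[method] = ErrorSummary.from_errors(
                np.concatenate(per_method[method]))
    p_value = float("nan")
    if "hybrid" in per_set_mean and "smap" in per_set_mean:
        # per-training-set mean errors, paired by training set; sets where
        # either method could not run are dropped from the pairing
        a, b = per_set_mean["hybrid"], per_set_mean["smap"]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 2:
            res = stats.ttest_rel(a[ok], b[ok])
            p_value = float(res.pvalue)
    return ConditionResult(params=params, methods=summaries, p_value=p_value,
                           n_failed_sets=n_failed)


def _simulate_pair(sim: MarginalParams, test_length: int,
                   seed: int) -> tuple[UniformSeries, UniformSeries]:
    s_train, s_test = _child_seeds(seed, 2)
    train_sim = simulate_linear_response(replace(sim, seed=s_train))
    test_sim = simulate_linear_response(
        replace(sim, n_steps=test_length + BURN_IN, seed=s_test))
    return (train_sim.slice(BURN_IN, len(train_sim)),
            test_sim.slice(BURN_IN, len(test_sim)))


# ---------------------------------------------------------------------------
# protocol drivers

def run_benchmark(config: ExperimentConfig) -> BenchmarkResult:
    """Run one benchmark protocol; see the module docstring.

    Deterministic given ``config.seed``: training simulations, test
    simulations, segment draws and target subsampling all derive their
    seeds from it.
    """
    logger.info("benchmark protocol=%s seed=%d", config.protocol, config.seed)
    test_length = config.test_length or config.sim.n_steps
    conditions: list[ConditionResult] = []

    if config.protocol == "lambda_sweep":
        lams = config.conditions or (config.sim.lam,)
        for i, lam in enumerate(lams):
            seed_i = _child_seeds(config.seed, i + 1)[-1]
            sim = replace(config.sim, lam=float(lam))
            train_sim, test = _simulate_pair(sim, test_length, seed_i)
            s_seg, s_tgt = _child_seeds(seed_i + 1, 2)
            segments = random_segments(train_sim, config.train_length,
                                       config.n_train_sets, s_seg)
            targets = _admissible_targets(test, config.smap, None,
                                          config.n_test_points, s_tgt)
            conditions.append(_evaluate_condition(
                segments, test, targets, config, {"lam": float(lam)}))

    elif config.protocol == "length_sweep":
        lengths = config.conditions or (config.train_length,)
        train_sim, test = _simulate_pair(config.sim, test_length, config.seed)
        # one fixed target set so the sweep varies only the training length
        s_tgt = _child_seeds(config.seed + 1, 1)[0]
        targets = _admissible_targets(test, config.smap, None,
                                      config.n_test_points, s_tgt)
        for i, length in enumerate(lengths):
            s_seg = _child_seeds(config.seed + i + 2, 1)[0]
            segments = random_segments(train_sim, int(length),
                                       config.n_train_sets, s_seg)
            conditions.append(_evaluate_condition(
                segments, test, targets, config, {"train_length": int(length)}))

    elif config.protocol == "amplitude_extrapolation":
        train_sim, test = _simulate_pair(config.sim, test_length, config.seed)
        s_seg, s_tgt = _child_seeds(config.seed + 1, 2)
        # draw a surplus of segments, keep the low-amplitude fraction
        n_draw = int(math.ceil(config.n_train_sets / config.train_fraction))
        candidates = random_segments(train_sim, config.train_length, n_draw, s_seg)
        means = np.array([c.values.mean() for c in candidates])
        order = np.argsort(means, kind="stable")
        segments = [candidates[j] for j in order[:config.n_train_sets]]
        targets = _admissible_targets(test, config.smap, config.target_fraction,
                                      config.n_test_points, s_tgt)
        conditions.append(_evaluate_condition(
            segments, test, targets, config,
            {"lam": config.sim.lam, "train_length": config.train_length,
             "target_fraction": config.target_fraction}))

    elif config.protocol == "empirical_rank":
        if config.series is None:
            series, _ = _simulate_pair(config.sim, test_length, config.seed)
        else:
            series = config.series
        segments, test_idx = amplitude_rank_protocol(
            series, config.train_length, config.train_fraction,
            config.target_fraction)
        span = (config.smap.m - 1) * config.smap.tau_delay
        origins = test_idx - config.smap.horizon
        origins = origins[(origins >= span) & (origins + config.smap.horizon
                                               < len(series))]
        rng = np.random.default_rng(_child_seeds(config.seed + 1, 1)[0])
        if origins.size > config.n_test_points:
            origins = np.sort(rng.choice(origins, config.n_test_points,
                                         replace=False))
        if origins.size == 0:
            raise ValueError("no admissible high-amplitude targets")
        conditions.append(_evaluate_condition(
            segments, series, origins, config,
            {"seg_length": config.train_length,
             "train_fraction": config.train_fraction,
             "target_fraction": config.target_fraction}))

    return BenchmarkResult(protocol=config.protocol, conditions=tuple(conditions))
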