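"""Delay embedding and nearest-neighbor forecasting.

The predictor is a k-nearest-neighbor variant of the S-map: the series is
embedded as delay vectors ``X_t = {x_t, x_{t-tau}, ..., x_{t-(m-1)tau}}``,
the k training vectors nearest the query (2-norm) are found, and a linear
map ``theta`` is solved from the weighted regression of neighbor targets
on neighbor vectors, with weights ``d**(-q)``.  The prediction is
``query . theta``; there is no intercept, following the literal form of
the local linear map.  With k below the embedding dimension the system is
underdetermined and the minimum-norm least-squares solution is used.

The hybrid predictor pools neighbors from a raw-data embedding and an
ASE-data embedding, weighting the two pools by (1-mu)/k and mu/k_ase so
the synthetic scale-extrapolated events act as a prior where historical
data is sparse.  An AR1 regression (with intercept, over all training
points) is the linear baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ase import AugmentedSeries
from .series import UniformSeries

__all__ = [
    "DelayEmbedding",
    "SmapConfig",
    "Neighbor",
    "embed",
    "nearest_neighbors",
    "smap_predict",
    "hybrid_predict",
    "ar1_fit",
    "forecast_series",
]


@dataclass(frozen=True)
class SmapConfig:
    """Forecasting parameters.

    Defaults: ``q = 1`` (inverse-distance weights) and ``k = 2`` neighbors
    are used for all analyses; ``mu = 0.5`` balances raw against ASE
    neighbors in the hybrid predictor.
    """

    m: int = 10                # embedding dimension
    tau_delay: int = 1         # delay between embedding coordinates (steps)
    horizon: int = 50          # prediction time P (steps)
    k: int = 2                 # neighbors from the raw embedding
    q: float = 1.0             # distance-weight exponent
    mu: float = 0.5            # hybrid weight on the ASE pool
    k_ase: int = 2             # neighbors from the ASE embedding

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau_delay < 1 or self.horizon < 1:
            raise ValueError("m, tau_delay and horizon must be >= 1")
        if self.k < 1 or self.k_ase < 1 or self.q < 0:
            raise ValueError("k, k_ase >= 1 and q >= 0 required")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")


@dataclass(frozen=True)
class DelayEmbedding:
    """Delay vectors with horizon-P targets.

    ``vectors[i]`` is ``{x_t, x_{t-tau}, ..., x_{t-(m-1)tau}}`` for origin
    index ``times[i]`` (most recent coordinate first), ``targets[i]`` is
    ``x_{t+P}``.  No vector's index span crosses a segment boundary.
    """

    vectors: np.ndarray        # (n, m)
    targets: np.ndarray        # (n,)
    times: np.ndarray          # (n,) origin index of each vector
    segment_ids: np.ndarray    # (n,)
    m: int
    tau_delay: int
    horizon: int

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class Neighbor:
    """One training neighbor of a query point."""

    vector: np.ndarray
    target: float
    distance: float
    time: float = 0.0


def _embed_segment(x: np.ndarray, m: int, tau: int, horizon: int,
                   offset: int, seg_id: int):
    """Vectors/targets/times for one contiguous segment (may be empty)."""
    span = (m - 1) * tau
    n_vec = x.size - span - horizon
    if n_vec <= 0:
        return None
    origins = np.arange(span, span + n_vec)
    lags = np.arange(m) * tau
    vectors = x[origins[:, None] - lags[None, :]]
    targets = x[origins + horizon]
    return vectors, targets, origins + offset, np.full(n_vec, seg_id)


def embed(data: UniformSeries | AugmentedSeries | np.ndarray, m: int,
          tau_delay: int = 1, horizon: int = 1,
          sources: tuple[str, ...] | None = None) -> DelayEmbedding:
    """Build delay vectors and horizon-P targets.

    For an :class:`~aseforecast.ase.AugmentedSeries`, each segment is
    embedded independently (no vector straddles a boundary); ``sources``
    restricts to segments with those flags, e.g. ``("ase",)`` for an
    ASE-only embedding.  A segment of length L contributes
    ``L - (m-1)*tau_delay - horizon`` vectors.
    """
    if isinstance(data, AugmentedSeries):
        segs = []
        ends = list(data.boundaries[1:]) + [data.values.size]
        for src, start, end in zip(data.source, data.boundaries, ends):
            if sources is None or src in sources:
                segs.append((start, data.values[start:end]))
    elif isinstance(data, UniformSeries):
        segs = [(0, data.values)]
    else:
        segs = [(0, np.asarray(data, dtype=float))]

    parts = []
    for seg_id, (start, x) in enumerate(segs):
        out = _embed_segment(x, m, tau_delay, horizon, start, seg_id)
        if out is not None:
            parts.append(out)
    if not parts:
        raise ValueError(
            f"no segment admits a delay vector (need length >= "
            f"{(m - 1) * tau_delay + horizon + 1})")
    vectors = np.concatenate([p[0] for p in parts])
    targets = np.concatenate([p[1] for p in parts])
    times = np.concatenate([p[2] for p in parts])
    seg_ids = np.concatenate([p[3] for p in parts])
    return DelayEmbedding(vectors=vectors, targets=targets, times=times,
                          segment_ids=seg_ids, m=m, tau_delay=tau_delay,
                          horizon=horizon)


def _knn_indices(embedding: DelayEmbedding, query: np.ndarray, k: int) -> tuple:
    d = np.linalg.norm(embedding.vectors - query, axis=1)
    if d.size <= k:
        cand = np.arange(d.size)
    else:
        # exact k smallest with the declared tie rule, without a full sort:
        # keep everything not beyond the kth distance, then order those few
        part = np.argpartition(d, k - 1)
        cand = np.flatnonzero(d <= d[part[k - 1]])
    order = cand[np.lexsort((embedding.times[cand], d[cand]))]
    idx = order[:k]
    return idx, d[idx]


def nearest_neighbors(embedding: DelayEmbedding, query, k: int) -> list[Neighbor]:
    """The k training vectors nearest the query by the 2-norm.

    Ties in distance are broken in favor of the earlier origin time, so
    results are deterministic.
    """
    query = np.asarray(query, dtype=float)
    if len(embedding) < k:
        raise ValueError(f"need k={k} neighbors but embedding has only "
                         f"{len(embedding)} vectors")
    idx, dists = _knn_indices(embedding, query, k)
    return [Neighbor(vector=embedding.vectors[i], target=float(embedding.targets[i]),
                     distance=float(di), time=float(embedding.times[i]))
            for i, di in zip(idx, dists)]


def _solve_weighted(vectors: np.ndarray, targets: np.ndarray, weights: np.ndarray,
                    query: np.ndarray, intercept: bool = False) -> float:
    """Minimum-norm weighted least squares; returns query . theta."""
    w = np.sqrt(weights)
    A = vectors * w[:, None]
    y = targets * w
    if intercept:
        A = np.column_stack([w, A])
    if not np.any(np.abs(A) > 0) and np.any(np.abs(y) > 0):
        raise ValueError("degenerate design: all-zero vectors with nonzero targets")
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    if intercept:
        return float(theta[0] + query @ theta[1:])
    return float(query @ theta)


def _zero_distance_value(neighbors: list[Neighbor], threshold: float) -> float | None:
    exact = [nb.target for nb in neighbors if nb.distance <= threshold]
    if exact:
        return float(np.mean(exact))
    return None


def _zero_threshold(query: np.ndarray) -> float:
    qn = float(np.linalg.norm(query))
    return 1e-12 * qn if qn > 0 else 1e-300


def smap_predict(neighbors: list[Neighbor], query, q: float = 1.0,
                 intercept: bool = False) -> float:
    """Locally weighted linear prediction from a neighbor list.

    Each neighbor row is weighted by ``d**(-q)`` and the linear map theta
    is solved by minimum-norm least squares; the prediction is
    ``query . theta``.  If any neighbor coincides with the query (distance
    below 1e-12 of the query norm), the mean target of the coincident
    neighbors is returned directly — the exact-match shortcut that the
    infinite weight would imply.
    """
    if not neighbors:
        raise ValueError("need at least one neighbor")
    query = np.asarray(query, dtype=float)
    shortcut = _zero_distance_value(neighbors, _zero_threshold(query))
    if shortcut is not None:
        return shortcut
    d = np.array([nb.distance for nb in neighbors])
    weights = d ** (-q) if q != 0 else np.ones_like(d)
    vectors = np.array([nb.vector for nb in neighbors])
    targets = np.array([nb.target for nb in neighbors])
    return _solve_weighted(vectors, targets, weights, query, intercept=intercept)


def hybrid_predict(raw_embedding: DelayEmbedding | None,
                   ase_embedding: DelayEmbedding | None,
                   query, config: SmapConfig) -> float:
    """S-map over neighbors pooled from raw and ASE embeddings.

    Raw neighbors carry weight ``d**(-q) * (1-mu)/k``, ASE neighbors
    ``d**(-q) * mu/k_ase``.  ``mu = 0`` reduces exactly to the raw-only
    predictor and ``mu = 1`` to the ASE-only one.
    """
    query = np.asarray(query, dtype=float)
    mu, q = config.mu, config.q
    pools: list[tuple[list[Neighbor], float]] = []
    if mu < 1.0:
        if raw_embedding is None or len(raw_embedding) < config.k:
            raise ValueError("raw embedding unusable and mu < 1")
        pools.append((nearest_neighbors(raw_embedding, query, config.k),
                      (1.0 - mu) / config.k))
    if mu > 0.0:
        if ase_embedding is None or len(ase_embedding) < config.k_ase:
            raise ValueError("ASE embedding unusable and mu > 0")
        pools.append((nearest_neighbors(ase_embedding, query, config.k_ase),
                      mu / config.k_ase))

    thresh = _zero_threshold(query)
    all_nb = [nb for nbs, _ in pools for nb in nbs]
    shortcut = _zero_distance_value(all_nb, thresh)
    if shortcut is not None:
        return shortcut
    vectors, targets, weights = [], [], []
    for nbs, pool_w in pools:
        for nb in nbs:
            vectors.append(nb.vector)
            targets.append(nb.target)
            w = nb.distance ** (-q) if q != 0 else 1.0
            weights.append(w * pool_w)
    return _solve_weighted(np.array(vectors), np.array(targets),
                           np.array(weights), query)


def ar1_fit(series: UniformSeries | np.ndarray, horizon: int = 1) -> tuple[float, float]:
    """First-order autoregression ``x_{t+P} = theta0 + theta1 * x_t`` by OLS.

    All available (x_t, x_{t+P}) pairs are used.  For a constant regressor
    the slope is set to 0 and the intercept to the mean target (with a
    warning) — the regression is otherwise undefined.
    """
    x = series.values if isinstance(series, UniformSeries) else np.asarray(series, dtype=float)
    if x.size < horizon + 3:
        raise ValueError(f"need >= 3 usable pairs; series of {x.size} with "
                         f"horizon {horizon} gives {max(x.size - horizon, 0)}")
    xt = x[:-horizon]
    y = x[horizon:]
    var = float(np.var(xt))
    if var <= 1e-30 * max(1.0, float(np.mean(xt)) ** 2):
        warnings.warn("constant series: AR1 slope set to 0", stacklevel=2)
        return float(np.mean(y)), 0.0
    theta1 = float(np.cov(xt, y, ddof=0)[0, 1] / var)
    theta0 = float(np.mean(y) - theta1 * np.mean(xt))
    return theta0, theta1


def forecast_series(train: UniformSeries | AugmentedSeries,
                    test: UniformSeries, method: str, config: SmapConfig,
                    query_indices: np.ndarray | None = None) -> np.ndarray:
    """Out-of-sample forecasts over a test series.

    Queries are embedded from the test series only; the train data (raw
    series or augmented raw+ASE set) supplies neighbors or the AR1 fit.
    ``method`` is one of ``"smap"`` (raw segments only), ``"smap_ase"``
    (ASE segments only), ``"hybrid"`` or ``"ar1"``.  Returns an array of
    rows ``(origin index, truth, prediction)`` where truth is
    ``test[origin + horizon]``; ``query_indices`` restricts the origins.

    Deterministic: identical inputs give bitwise-identical output.
    """
    m, tau, P = config.m, config.tau_delay, config.horizon
    span = (m - 1) * tau
    x = test.values
    if query_indices is None:
        origins = np.arange(span, x.size - P)
    else:
        origins = np.asarray(query_indices, dtype=int)
        if np.any(origins < span) or np.any(origins + P >= x.size):
            raise ValueError("query index out of admissible range")
    if origins.size == 0:
        raise ValueError("test series too short to embed any query")

    if method == "ar1":
        train_vals = (train.values if isinstance(train, UniformSeries)
                      else np.concatenate([v for s, v in train.segments() if s == "raw"]))
        theta0, theta1 = ar1_fit(train_vals, horizon=P)
        preds = theta0 + theta1 * x[origins]
        return np.column_stack([origins, x[origins + P], preds])

    lags = np.arange(m) * tau
    queries = x[origins[:, None] - lags[None, :]]

    if method == "hybrid":
        raw_emb = embed(train, m, tau, P, sources=("raw",)) if config.mu < 1 else None
        ase_emb = embed(train, m, tau, P, sources=("ase",)) if config.mu > 0 else None
        preds = np.array([hybrid_predict(raw_emb, ase_emb, qv, config)
                          for qv in queries])
    elif method in ("smap", "smap_ase"):
        sources = ("raw",) if method == "smap" else ("ase",)
        if isinstance(train, UniformSeries):
            if method == "smap_ase":
                raise ValueError("smap_ase requires an AugmentedSeries")
            emb = embed(train, m, tau, P)
        else:
            emb = embed(train, m, tau, P, sources=sources)
        preds = np.array([
            smap_predict(nearest_neighbors(emb, qv, config.k), qv, q=config.q)
            for qv in queries])
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.column_stack([origins, x[origins + P], preds])
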