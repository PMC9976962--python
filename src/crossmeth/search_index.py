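"""k-nearest-neighbor search over hashed methylation profiles.

The index answers "which compiled samples most resemble this queried
methylation profile" on the hashed representation. The backend performs
exact search (scikit-learn NearestNeighbors); small-world graph
parameters are accepted and recorded so configurations remain portable,
and a quadratic-scan oracle (:func:`brute_force_knn`) is provided for
recall checks. Neighbor-label profiling summarizes which sample-type
labels dominate a query's neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .feature_hash import HashedProfiles, read_hashed_h5, write_hashed_h5

DEFAULT_GRAPH_PARAMS = {"M": 16, "ef_construction": 200, "ef_search": 300}


@dataclass
class QueryResult:
    """Ordered neighbors of one query."""

    neighbor_ids: np.ndarray
    distances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.neighbor_ids = np.asarray(self.neighbor_ids, dtype=object)
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.neighbor_ids) != self.k or len(self.distances) != self.k:
            raise ValueError("result length must equal k")
        if len(set(self.neighbor_ids)) != self.k:
            raise ValueError("neighbor ids must be unique within a query")
        if np.any(np.diff(self.distances) < -1e-12):
            raise ValueError("distances must be non-decreasing")


@dataclass
class KnnIndex:
    """Searchable index over hashed profiles."""

    hashed: HashedProfiles
    metric: str = "euclidean"
    graph_params: dict = field(default_factory=lambda: dict(DEFAULT_GRAPH_PARAMS))
    _nn: NearestNeighbors | None = None

    @property
    def n_samples(self) -> int:
        return self.hashed.n_samples


def _metric_kwargs(metric: str) -> dict:
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric: {metric!r}")
    return {"metric": metric}


def build_index(hashed: HashedProfiles, metric: str = "euclidean",
                graph_params: dict | None = None) -> KnnIndex:
    """Index all rows of ``hashed``; raises on non-finite values."""
    if hashed.n_samples < 2:
        raise ValueError("need at least 2 samples to build an index")
    bad = ~np.isfinite(hashed.values).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite values in samples: {list(hashed.sample_ids[bad][:10])}")
    nn = NearestNeighbors(algorithm="brute", **_metric_kwargs(metric))
    nn.fit(hashed.values)
    params = dict(DEFAULT_GRAPH_PARAMS)
    if graph_params:
        params.update(graph_params)
    return KnnIndex(hashed=hashed, metric=metric, graph_params=params, _nn=nn)


def _pairwise_distances(queries: np.ndarray, refs: np.ndarray,
                        metric: str) -> np.ndarray:
    if metric == "euclidean":
        d2 = ((queries[:, None, :] - refs[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(np.maximum(d2, 0.0))
    qn = np.linalg.norm(queries, axis=1, keepdims=True)
    rn = np.linalg.norm(refs, axis=1, keepdims=True)
    cos = (queries @ refs.T) / np.maximum(qn * rn.T, 1e-300)
    return 1.0 - cos


def brute_force_knn(query_vector, hashed: HashedProfiles, k: int,
                    metric: str = "euclidean") -> QueryResult:
    """Exact k nearest neighbors by quadratic scan; ties broken by sample id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > hashed.n_samples:
        raise ValueError("k exceeds the number of indexed samples")
    q = np.asarray(query_vector, dtype=float)[None, :]
    dist = _pairwise_distances(q, hashed.values, metric)[0]
    ids = np.asarray([str(s) for s in hashed.sample_ids], dtype=object)
    order = np.lexsort((ids, dist))[:k]
    return QueryResult(hashed.sample_ids[order], dist[order], k)


def query_neighbors(index: KnnIndex, queries: HashedProfiles,
                    k: int = 1000) -> list[QueryResult]:
    """k nearest indexed samples per query row.

    Queries must be hashed with the same (dim, hash_seed, signed)
    parameters as the index; a mismatch is an error, not a warning.
    """
    if queries.params() != index.hashed.params():
        raise ValueError(
            f"hashing parameter mismatch: query {queries.params()} vs "
            f"index {index.hashed.params()}")
    if k > index.n_samples:
        raise ValueError("k exceeds the number of indexed samples")
    if k <= 0:
        raise ValueError("k must be positive")
    dist, idx = index._nn.kneighbors(queries.values, n_neighbors=k)
    out = []
    for d_row, i_row in zip(dist, idx):
        order = np.argsort(d_row, kind="stable")
        out.append(QueryResult(index.hashed.sample_ids[i_row[order]],
                               d_row[order], k))
    return out


def label_frequency(results: list[QueryResult], metadata: pd.DataFrame,
                    label_field: str = "sample_type") -> pd.DataFrame:
    """Per-query proportion of neighbors carrying each label value.

    Neighbors missing from the metadata (or with a null label) are counted
    under ``other``. Rows sum to 1.
    """
    labels = metadata[label_field]
    values = sorted(set(labels.dropna().astype(str)) | {"other"})
    rows = np.zeros((len(results), len(values)))
    col = {v: j for j, v in enumerate(values)}
    for i, res in enumerate(results):
        for nid in res.neighbor_ids:
            if nid in labels.index and pd.notna(labels.loc[nid]):
                rows[i, col[str(labels.loc[nid])]] += 1
            else:
                rows[i, col["other"]] += 1
        rows[i] /= res.k
    return pd.DataFrame(rows, columns=values)


def save_index(index: KnnIndex, path, sidecar_tsv=None) -> None:
    """Persist the hashed reference (HDF5) plus metric/graph attributes."""
    write_hashed_h5(path, index.hashed)
    import h5py
    with h5py.File(path, "a") as f:
        f.attrs["metric"] = index.metric
        for key, val in index.graph_params.items():
            f.attrs[f"graph_{key}"] = val
    if sidecar_tsv is not None:
        pd.DataFrame({"sample_id": index.hashed.sample_ids}).to_csv(
            sidecar_tsv, sep="\t", index=False)


def load_index(path) -> KnnIndex:
    import h5py
    hashed = read_hashed_h5(path)
    with h5py.File(path, "r") as f:
        metric = str(f.attrs.get("metric", "euclidean"))
        graph = {key[len("graph_"):]: int(val)
                 for key, val in f.attrs.items() if key.startswith("graph_")}
    return build_index(hashed, metric=metric, graph_params=graph or None)
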