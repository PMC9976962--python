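"""Feature hashing of probe-dimension Beta vectors (the hashing trick).

Each probe id is hashed to one of ``dim`` buckets with a seeded 32-bit
murmur3 hash; in the signed variant an independent hash bit assigns the
probe a +/-1 sign, which makes hashed inner products unbiased estimates of
the original probe-space inner products. The reduction is deterministic
for a fixed (probe ids, dim, hash_seed, signed) tuple, so indexes built
from hashed profiles are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import sparse

from .containers import BetaMatrix

#: decorrelates the sign hash from the bucket hash
_SIGN_SEED_OFFSET = 0x9E3779B9


def murmur3_32(data: bytes, seed: int = 0) -> int:
    """32-bit murmur3 of ``data``; reference vector: ("hello", 0) -> 0x248bfa47."""
    c1, c2 = 0xCC9E2D51, 0x1B873593
    h = seed & 0xFFFFFFFF
    n = len(data)
    nblocks = n // 4
    for i in range(nblocks):
        k = int.from_bytes(data[4 * i:4 * i + 4], "little")
        k = (k * c1) & 0xFFFFFFFF
        k = ((k << 15) | (k >> 17)) & 0xFFFFFFFF
        k = (k * c2) & 0xFFFFFFFF
        h ^= k
        h = ((h << 13) | (h >> 19)) & 0xFFFFFFFF
        h = (h * 5 + 0xE6546B64) & 0xFFFFFFFF
    k = 0
    tail = data[nblocks * 4:]
    if len(tail) >= 3:
        k ^= tail[2] << 16
    if len(tail) >= 2:
        k ^= tail[1] << 8
    if len(tail) >= 1:
        k ^= tail[0]
        k = (k * c1) & 0xFFFFFFFF
        k = ((k << 15) | (k >> 17)) & 0xFFFFFFFF
        k = (k * c2) & 0xFFFFFFFF
        h ^= k
    h ^= n
    h ^= h >> 16
    h = (h * 0x85EBCA6B) & 0xFFFFFFFF
    h ^= h >> 13
    h = (h * 0xC2B2AE35) & 0xFFFFFFFF
    h ^= h >> 16
    return h


@dataclass
class HashedProfiles:
    """Samples x dim hashed representation plus the hashing parameters."""

    values: np.ndarray
    sample_ids: np.ndarray
    dim: int
    hash_seed: int
    signed: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.values.shape != (len(self.sample_ids), self.dim):
            raise ValueError("values must be samples x dim")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def params(self) -> tuple[int, int, bool]:
        return (self.dim, self.hash_seed, self.signed)


def _projection(probe_ids: np.ndarray, dim: int, hash_seed: int,
                signed: bool) -> sparse.csr_matrix:
    ids = np.asarray(probe_ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate probe ids")
    buckets = np.empty(len(ids), dtype=np.int64)
    signs = np.ones(len(ids))
    for i, pid in enumerate(ids):
        raw = str(pid).encode("utf-8")
        buckets[i] = murmur3_32(raw, hash_seed) % dim
        if signed:
            bit = murmur3_32(raw, (hash_seed + _SIGN_SEED_OFFSET) & 0xFFFFFFFF) & 1
            signs[i] = 1.0 if bit else -1.0
    return sparse.csr_matrix((signs, (np.arange(len(ids)), buckets)),
                             shape=(len(ids), dim))


def hash_features(beta: BetaMatrix, dim: int = 1000, hash_seed: int = 0,
                  signed: bool = True) -> HashedProfiles:
    """Hash a probes x samples Beta matrix to a samples x dim representation.

    out[s, j] = sum over probes p with bucket(p) = j of sign(p) * beta[p, s].
    """
    if dim > beta.n_probes:
        warnings.warn(
            f"target dim {dim} exceeds probe count {beta.n_probes}; "
            "the representation is not reduced", stacklevel=2)
    if np.isnan(beta.values).any():
        raise ValueError("Beta matrix contains NaN; subset to shared probes first")
    S = _projection(beta.probe_ids, dim, hash_seed, signed)
    values = beta.values.T @ S   # samples x dim
    return HashedProfiles(np.asarray(values), beta.sample_ids.copy(),
                          dim, hash_seed, signed)


def write_hashed_h5(path, hashed: HashedProfiles) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=hashed.values, compression="gzip")
        f.create_dataset(
            "sample_ids",
            data=np.asarray(hashed.sample_ids,
                            dtype=h5py.string_dtype(encoding="utf-8")))
        f.attrs["dim"] = hashed.dim
        f.attrs["hash_seed"] = hashed.hash_seed
        f.attrs["signed"] = hashed.signed
        f.attrs["hash_family"] = "murmur3_32"


def read_hashed_h5(path) -> HashedProfiles:
    with h5py.File(path, "r") as f:
        return HashedProfiles(f["values"][:],
                              f["sample_ids"].asstr()[:].astype(object),
                              int(f.attrs["dim"]), int(f.attrs["hash_seed"]),
                              bool(f.attrs["signed"]))
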