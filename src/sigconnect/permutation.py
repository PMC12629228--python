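"""Permutation null distributions for CSS and XSum.

CSS and XSum have no convenient analytic null, so significance comes from a
permutation test: for each reference signature, many random query
extreme-gene sets (2K distinct genes drawn uniformly from the universe,
randomly split into an ordered up list and an ordered down list of K each)
are scored against the fixed reference, and the observed statistic is
compared with this null.  Because the null depends only on the reference,
the backgrounds can be precomputed once (the expensive part of a screen)
and reused for every query; the default permutation count is 10 000.

Substream seeds are derived deterministically from the master seed and the
(sig_id, method, K) triple, so backgrounds can be built in any order, or in
parallel, with identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .core import Signature
from .scoring import reference_extreme_mask

__all__ = [
    "PermutationBackground",
    "build_background",
    "empirical_pvalue",
    "BackgroundStore",
    "substream_seed",
]

_BG_METHODS = ("css", "xsum")


@dataclass(frozen=True)
class PermutationBackground:
    """Null statistics for one (reference, method, K) combination."""

    sig_id: str
    method: str
    K: int
    ref_extreme_n: int | None
    null_values: np.ndarray
    seed: int
    n_perm: int

    def __post_init__(self) -> None:
        if self.method not in _BG_METHODS:
            raise ValueError(f"method must be one of {_BG_METHODS}")
        vals = np.asarray(self.null_values, dtype=float)
        if vals.size != self.n_perm:
            raise ValueError(
                f"{vals.size} null values but n_perm = {self.n_perm}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("null values contain non-finite entries")
        object.__setattr__(self, "null_values", vals)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.sig_id, self.method, self.K)


def substream_seed(master_seed: int, sig_id: str, method: str, K: int) -> int:
    """Deterministic 64-bit substream seed for one background.

    Hash-derived so that backgrounds built in any order (or in parallel)
    from the same master seed are bit-identical.
    """
    digest = hashlib.sha256(
        f"{int(master_seed)}|{sig_id}|{method}|{int(K)}".encode()
    ).digest()
    return int.from_bytes(digest[:8], "little")


def _random_extreme_indices(
    rng: np.random.Generator, n_genes: int, K: int, n_rows: int
) -> np.ndarray:
    """(n_rows, 2K) gene indices: each row a uniform ordered sample without
    replacement; columns [:K] are the up list, [K:] the down list."""
    u = rng.random((n_rows, n_genes))
    return np.argsort(u, axis=1, kind="stable")[:, : 2 * K]


def build_background(
    ref: Signature,
    method: str,
    K: int,
    n_perm: int = 10_000,
    seed: int = 0,
    ref_extreme_n: int | None = None,
) -> PermutationBackground:
    """Monte-Carlo null distribution of CSS or XSum for one reference.

    Each iteration scores a uniformly random ordered query extreme-gene set
    against the fixed reference.  For CSS the query-side importance order is
    randomized too (the signed query ranks are a random signed permutation
    of 1..2K, + on the up side and - on the down side).  The generating
    substream seed is recorded so the background is reproducible.
    """
    if method not in _BG_METHODS:
        raise ValueError(f"method must be one of {_BG_METHODS}")
    n = len(ref)
    if 2 * K > n:
        raise ValueError(f"2*K = {2 * K} exceeds the {n}-gene universe")
    if method == "xsum":
        ref_extreme_n = K if ref_extreme_n is None else ref_extreme_n
        mask = reference_extreme_mask(ref.gene_ids, ref.z, ref_extreme_n)
        zstar = np.where(mask, ref.z, 0.0)
    else:
        ref_extreme_n = None
        signed_ranks = stats.rankdata(np.abs(ref.z)) * np.sign(ref.z)
        abs_ranks = np.abs(signed_ranks)
        top = np.sort(np.partition(abs_ranks, n - 2 * K)[-2 * K:])[::-1]
        qmag_desc = np.arange(2 * K, 0, -1, dtype=float)
        c_max = float(np.dot(top, qmag_desc))

    sub = substream_seed(seed, ref.sig_id, method, K)
    rng = np.random.default_rng(sub)
    out = np.empty(n_perm)
    # chunked so the (rows x n_genes) uniform draw stays modest in memory
    chunk = max(1, int(2e6) // max(n, 1))
    done = 0
    while done < n_perm:
        rows = min(chunk, n_perm - done)
        idx = _random_extreme_indices(rng, n, K, rows)
        if method == "xsum":
            vals = zstar[idx[:, :K]].sum(axis=1) - zstar[idx[:, K:]].sum(axis=1)
        else:
            # random query importance magnitudes: permutation of 1..2K per row
            mag = np.argsort(rng.random((rows, 2 * K)), axis=1).astype(float) + 1.0
            sign = np.ones(2 * K)
            sign[K:] = -1.0
            c = (signed_ranks[idx] * (mag * sign)).sum(axis=1)
            vals = c / c_max
        out[done : done + rows] = vals
        done += rows
    return PermutationBackground(
        sig_id=ref.sig_id,
        method=method,
        K=K,
        ref_extreme_n=ref_extreme_n,
        null_values=out,
        seed=sub,
        n_perm=n_perm,
    )


def empirical_pvalue(
    observed: float,
    background: PermutationBackground,
    tail: str = "upper",
) -> float:
    """One-sided empirical p-value with the add-one rule.

    ``upper``: p = (1 + #{null >= observed}) / (n_perm + 1); ``lower``
    analogous with <=.  Never 0; p = 1/(n_perm+1) at best, 1 at worst.
    """
    if background.null_values.size == 0:
        raise ValueError("empty permutation background")
    if tail == "upper":
        count = int(np.sum(background.null_values >= observed))
    elif tail == "lower":
        count = int(np.sum(background.null_values <= observed))
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return (1 + count) / (background.n_perm + 1)


class BackgroundStore:
    """On-disk store of permutation backgrounds, keyed by (sig_id, method, K).

    One ``.npz`` file per reference signature holds every (method, K) array
    for that reference plus its metadata; a JSON manifest lists coverage.
    The write-then-read roundtrip is exact (float64 preserved bitwise).
    """

    MANIFEST = "manifest.json"

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self._manifest_path = self.directory / self.MANIFEST
        if self._manifest_path.exists():
            self._manifest = json.loads(self._manifest_path.read_text())
        else:
            self._manifest = {"entries": {}}

    @staticmethod
    def _entry_key(sig_id: str, method: str, K: int) -> str:
        return f"{sig_id}::{method}::K{int(K)}"

    def _file_for(self, sig_id: str) -> Path:
        tag = hashlib.sha256(sig_id.encode()).hexdigest()[:16]
        return self.directory / f"bg_{tag}.npz"

    def put(self, *backgrounds: PermutationBackground) -> None:
        by_sig: dict[str, list[PermutationBackground]] = {}
        for bg in backgrounds:
            by_sig.setdefault(bg.sig_id, []).append(bg)
        for sig_id, bgs in by_sig.items():
            path = self._file_for(sig_id)
            arrays: dict[str, np.ndarray] = {}
            meta: dict[str, dict] = {}
            if path.exists():
                with np.load(path, allow_pickle=False) as old:
                    arrays = {k: old[k] for k in old.files if k != "_meta"}
                    meta = json.loads(str(old["_meta"]))
            for bg in bgs:
                slot = self._entry_key(bg.sig_id, bg.method, bg.K)
                arrays[slot] = bg.null_values
                meta[slot] = {
                    "sig_id": bg.sig_id,
                    "method": bg.method,
                    "K": bg.K,
                    "ref_extreme_n": bg.ref_extreme_n,
                    "seed": bg.seed,
                    "n_perm": bg.n_perm,
                }
                self._manifest["entries"][slot] = path.name
            arrays["_meta"] = np.array(json.dumps(meta))
            np.savez(path, **arrays)
        self._manifest_path.write_text(json.dumps(self._manifest, indent=1, sort_keys=True))

    def get(
        self, sig_id: str, method: str, K: int, n_perm: int | None = None
    ) -> PermutationBackground:
        """Fetch a background; raises KeyError on an unknown triple and
        ValueError when a stored background's n_perm differs from the one
        requested (a stale background must be rebuilt, not reused)."""
        slot = self._entry_key(sig_id, method, K)
        name = self._manifest["entries"].get(slot)
        if name is None:
            raise KeyError(f"no background stored for ({sig_id!r}, {method!r}, K={K})")
        path = self.directory / name
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["_meta"]))[slot]
            values = data[slot]
        if n_perm is not None and meta["n_perm"] != n_perm:
            raise ValueError(
                f"background for ({sig_id!r}, {method!r}, K={K}) has "
                f"n_perm={meta['n_perm']}, but n_perm={n_perm} was requested"
            )
        return PermutationBackground(
            sig_id=meta["sig_id"],
            method=meta["method"],
            K=meta["K"],
            ref_extreme_n=meta["ref_extreme_n"],
            null_values=values,
            seed=meta["seed"],
            n_perm=meta["n_perm"],
        )

    def __contains__(self, key: tuple[str, str, int]) -> bool:
        return self._entry_key(*key) in self._manifest["entries"]

    def keys(self) -> list[tuple[str, str, int]]:
        out = []
        for slot in self._manifest["entries"]:
            sig_id, method, k = slot.rsplit("::", 2)
            out.append((sig_id, method, int(k[1:])))
        return out
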