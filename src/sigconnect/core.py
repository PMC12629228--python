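"""Core domain types for signature connectivity analysis.

A *signature* is the genome-wide differential-expression readout of a
perturbation (drug treatment, gene knockdown, disease state), encoded as a
vector of gene-level z-scores: positive z means the gene is up-regulated
relative to control, negative means down-regulated.  A *repository* is a
collection of reference signatures sharing one gene universe, against which
a query signature is screened.

All ranks in this package are 1-based; "rank 1 by z descending" is the most
up-regulated gene.  Gene identifiers are opaque case-sensitive strings; no
symbol/ID conversion is performed.  Ties in z are broken by lexicographic
gene identifier so every ordering is reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Signature",
    "SignatureRepository",
    "ExtremeGeneSet",
    "ScreenConfig",
    "align_query",
    "select_extreme_genes",
]


@dataclass(frozen=True)
class Signature:
    """One perturbation's gene-level z-score vector plus free-text metadata.

    Parameters
    ----------
    sig_id:
        Unique text identifier of the signature.
    gene_ids:
        Ordered gene identifiers; no duplicates allowed.
    z:
        Signed z-scores, same length and order as ``gene_ids``; all finite.
    metadata:
        Optional annotation (compound / perturbagen name, cell line, dose,
        exposure time, perturbation type), stored as free text exactly as
        provided.
    """

    sig_id: str
    gene_ids: tuple[str, ...]
    z: np.ndarray
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 1:
            raise ValueError(f"{self.sig_id}: z must be one-dimensional")
        if len(genes) != z.size:
            raise ValueError(
                f"{self.sig_id}: {len(genes)} gene ids but {z.size} z values"
            )
        if len(genes) < 2:
            raise ValueError(f"{self.sig_id}: a signature needs at least 2 genes")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"{self.sig_id}: duplicate gene ids {dupes[:5]}")
        if not np.all(np.isfinite(z)):
            raise ValueError(f"{self.sig_id}: non-finite z values")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def zmap(self) -> dict[str, float]:
        """Gene identifier → z-score mapping."""
        return dict(zip(self.gene_ids, self.z.tolist()))

    def negated(self) -> "Signature":
        """The signature with every z-score sign-flipped."""
        return Signature(self.sig_id, self.gene_ids, -self.z, self.metadata)


class SignatureRepository:
    """A set of reference signatures aligned to one shared gene universe.

    Stored internally as a genes x signatures matrix so whole-repository
    screens can be vectorized.  Every member signature reports a z value for
    every universe gene (missing genes are disallowed post-alignment; the
    constructors intersect gene sets rather than impute).
    """

    def __init__(
        self,
        gene_universe: Sequence[str],
        sig_ids: Sequence[str],
        matrix: np.ndarray,
        metadata: Sequence[Mapping[str, str]] | None = None,
        backend_descriptor: str = "memory",
    ) -> None:
        self.gene_universe: tuple[str, ...] = tuple(str(g) for g in gene_universe)
        self.sig_ids: tuple[str, ...] = tuple(str(s) for s in sig_ids)
        self.matrix = np.asarray(matrix, dtype=float)
        self.backend_descriptor = backend_descriptor
        if len(set(self.gene_universe)) != len(self.gene_universe):
            raise ValueError("gene universe contains duplicate identifiers")
        if len(set(self.sig_ids)) != len(self.sig_ids):
            raise ValueError("sig_ids are not unique across the repository")
        if self.matrix.shape != (len(self.gene_universe), len(self.sig_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_universe)} genes x {len(self.sig_ids)} signatures"
            )
        if len(self.sig_ids) == 0:
            raise ValueError("repository is empty")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("repository matrix contains non-finite values")
        if metadata is None:
            metadata = [{} for _ in self.sig_ids]
        if len(metadata) != len(self.sig_ids):
            raise ValueError("one metadata record per signature required")
        self.metadata: list[dict[str, str]] = [dict(m) for m in metadata]
        self._col = {s: j for j, s in enumerate(self.sig_ids)}
        self._row = {g: i for i, g in enumerate(self.gene_universe)}

    @classmethod
    def from_signatures(
        cls,
        signatures: Iterable[Signature],
        backend_descriptor: str = "memory",
    ) -> "SignatureRepository":
        """Build a repository from signatures, aligning to the gene
        intersection ordered as in the first signature."""
        sigs = list(signatures)
        if not sigs:
            raise ValueError("cannot build a repository from zero signatures")
        shared = set(sigs[0].gene_ids)
        for s in sigs[1:]:
            shared &= set(s.gene_ids)
        universe = tuple(g for g in sigs[0].gene_ids if g in shared)
        if len(universe) < 2:
            raise ValueError(
                "gene intersection across signatures has fewer than 2 genes"
            )
        matrix = np.empty((len(universe), len(sigs)))
        for j, s in enumerate(sigs):
            zm = s.zmap()
            matrix[:, j] = [zm[g] for g in universe]
        return cls(
            universe,
            [s.sig_id for s in sigs],
            matrix,
            [s.metadata for s in sigs],
            backend_descriptor,
        )

    def __len__(self) -> int:
        return len(self.sig_ids)

    def __contains__(self, sig_id: str) -> bool:
        return sig_id in self._col

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Row indices of ``gene_ids`` in the universe (raises on misses)."""
        try:
            return np.array([self._row[g] for g in gene_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"gene {e.args[0]!r} not in repository universe") from None

    def get(self, sig_id: str) -> Signature:
        try:
            j = self._col[sig_id]
        except KeyError:
            raise KeyError(f"unknown sig_id {sig_id!r}") from None
        return Signature(
            sig_id, self.gene_universe, self.matrix[:, j].copy(), self.metadata[j]
        )

    def __iter__(self):
        return (self.get(s) for s in self.sig_ids)


@dataclass(frozen=True)
class ExtremeGeneSet:
    """The query's K most up-regulated and K most down-regulated genes.

    ``up`` is ordered by descending query z (position 1 = most up-regulated);
    ``down`` by ascending query z (position 1 = most down-regulated).
    ``up_z`` / ``down_z`` carry the corresponding query z-scores, which the
    connection-strength score needs for its query-side importance ranks.
    """

    up: tuple[str, ...]
    down: tuple[str, ...]
    K: int
    up_z: np.ndarray
    down_z: np.ndarray

    def __post_init__(self) -> None:
        if len(self.up) != self.K or len(self.down) != self.K:
            raise ValueError("up and down must each contain exactly K genes")
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets overlap")
        object.__setattr__(self, "up_z", np.asarray(self.up_z, dtype=float))
        object.__setattr__(self, "down_z", np.asarray(self.down_z, dtype=float))

    @property
    def genes(self) -> tuple[str, ...]:
        """Up genes followed by down genes (2K total)."""
        return self.up + self.down

    def swapped(self) -> "ExtremeGeneSet":
        """Exchange the up and down lists (the extreme set of the negated
        query, up to the sign of the stored z values)."""
        return ExtremeGeneSet(self.down, self.up, self.K, self.down_z, self.up_z)


_ALLOWED_DIRECTIONS = ("positive", "negative")


@dataclass
class ScreenConfig:
    """Tunable parameters of a connectivity screen.

    K is the extreme-gene count per side (commonly 50, with 100/150/200 as
    typical alternatives; any positive value with 2K <= universe size is
    accepted).  ``n_perm`` is the permutation count behind the CSS/XSum
    empirical p-values (default 10 000).  ``vote_quantile`` defines a
    method's vote: a reference votes 1 for a method when its directional
    result ranks within the top ``vote_quantile`` fraction of the screen
    (default 5%).  ``ref_extreme_n`` is the reference-side extreme count used
    by XSum.  ``min_overlap_frac`` guards against incompatible gene
    identifier namespaces between query and repository.
    """

    K: int = 50
    n_perm: int = 10_000
    vote_quantile: float = 0.05
    direction: str = "negative"
    seed: int = 0
    ref_extreme_n: int | None = None
    min_overlap_frac: float = 0.8
    gate_rule: str = "votes"  # "votes" | "pvalue"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.vote_quantile < 1.0:
            raise ValueError("vote_quantile must lie in (0, 1)")
        if self.direction not in _ALLOWED_DIRECTIONS:
            raise ValueError(f"direction must be one of {_ALLOWED_DIRECTIONS}")
        if not 0.0 <= self.min_overlap_frac <= 1.0:
            raise ValueError("min_overlap_frac must lie in [0, 1]")
        if self.gate_rule not in ("votes", "pvalue"):
            raise ValueError("gate_rule must be 'votes' or 'pvalue'")
        if self.ref_extreme_n is None:
            self.ref_extreme_n = self.K
        if self.ref_extreme_n < 1:
            raise ValueError("ref_extreme_n must be >= 1")

    def validate_against_universe(self, n_genes: int) -> None:
        if 2 * self.K > n_genes:
            raise ValueError(
                f"2*K = {2 * self.K} exceeds the {n_genes}-gene universe"
            )
        if 2 * self.ref_extreme_n > n_genes:
            raise ValueError(
                f"2*ref_extreme_n = {2 * self.ref_extreme_n} exceeds the "
                f"{n_genes}-gene universe"
            )


def align_query(
    query: Signature,
    repo: SignatureRepository,
    min_overlap_frac: float = 0.8,
) -> Signature:
    """Restrict a query signature to the repository's gene universe.

    Query genes absent from the universe are dropped (never imputed); the
    original z values and the original relative gene order are preserved.
    Raises if the retained fraction falls below ``min_overlap_frac`` — a
    low overlap almost always signals mismatched identifier namespaces.
    """
    universe = set(repo.gene_universe)
    keep = [i for i, g in enumerate(query.gene_ids) if g in universe]
    retained = len(keep) / len(query.gene_ids)
    if not keep:
        raise ValueError(
            f"query {query.sig_id!r} shares no genes with the repository universe"
        )
    if retained < min_overlap_frac:
        raise ValueError(
            f"query {query.sig_id!r}: only {retained:.1%} of genes found in the "
            f"repository universe (minimum {min_overlap_frac:.1%}); check that "
            "query and repository use the same gene identifier namespace"
        )
    aligned = Signature(
        query.sig_id,
        tuple(query.gene_ids[i] for i in keep),
        query.z[keep],
        dict(query.metadata, aligned_fraction=f"{retained:.4f}"),
    )
    return aligned


def rank_order(gene_ids: Sequence[str], z: np.ndarray, descending: bool = True) -> np.ndarray:
    """Indices ordering genes by z (ties broken by gene identifier ascending).

    With ``descending=True`` position 0 is the most up-regulated gene.  The
    tie-break makes the ordering independent of storage order.
    """
    ids = np.asarray(gene_ids, dtype=object)
    z = np.asarray(z, dtype=float)
    key = -z if descending else z
    # np.lexsort sorts by the last key first; gene id is the secondary key.
    return np.lexsort((ids, key))


def select_extreme_genes(query: Signature, K: int) -> ExtremeGeneSet:
    """Select the query's K largest-z (up) and K smallest-z (down) genes.

    The query must already be aligned to the scoring universe so that every
    extreme gene has a reference-side value.  Deterministic under z ties
    (lexicographic gene identifier as secondary key).
    """
    n = len(query)
    if 2 * K > n:
        raise ValueError(
            f"2*K = {2 * K} exceeds the {n} genes of query {query.sig_id!r}"
        )
    if K < 1:
        raise ValueError("K must be >= 1")
    desc = rank_order(query.gene_ids, query.z, descending=True)
    asc = rank_order(query.gene_ids, query.z, descending=False)
    up_idx = desc[:K]
    # ties spanning the middle of the list could otherwise put a gene in
    # both extremes; down is filled from the genes up did not take
    taken = set(up_idx.tolist())
    down_idx = np.array([i for i in asc if i not in taken][:K], dtype=np.intp)
    return ExtremeGeneSet(
        up=tuple(query.gene_ids[i] for i in up_idx),
        down=tuple(query.gene_ids[i] for i in down_idx),
        K=K,
        up_z=query.z[up_idx],
        down_z=query.z[down_idx],
    )
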