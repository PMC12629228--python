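"""The six connectivity scores.

Three whole-list similarities — Pearson correlation, Spearman correlation
and cosine similarity — compare the full matched z-score vectors of query
and reference.  Three extreme-gene methods compare only the query's K most
up- and K most down-regulated genes against the reference:

* **WTCS** (weighted connectivity score): two weighted Kolmogorov–Smirnov
  enrichment scores — one for the up set, one for the down set — against the
  reference ranking; their half-difference when they disagree in sign,
  otherwise 0.
* **CSS** (connection strength score): a signed-rank inner product between
  query-side and reference-side gene importance, normalized to [-1, 1] by
  the best attainable pairing.
* **XSum** (eXtreme Sum): the sum of reference z-scores, restricted to the
  reference's own extremes, over the query up-genes minus the query
  down-genes.

Positive scores suggest the two perturbations share a mechanism of action;
negative scores suggest the reference perturbation reverses the query
pattern (the drug-repurposing signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import ExtremeGeneSet, ScreenConfig, Signature, rank_order, select_extreme_genes

__all__ = [
    "MethodScore",
    "METHODS",
    "FULL_VECTOR_METHODS",
    "EXTREME_METHODS",
    "pearson_score",
    "spearman_score",
    "cosine_score",
    "enrichment_score",
    "wtcs",
    "css",
    "xsum",
    "score_pair",
]

FULL_VECTOR_METHODS = ("pearson", "spearman", "cosine")
EXTREME_METHODS = ("wtcs", "css", "xsum")
METHODS = FULL_VECTOR_METHODS + EXTREME_METHODS


@dataclass(frozen=True)
class MethodScore:
    """One method's score for a query-reference pair.

    ``es_up`` / ``es_down`` are the component enrichment scores (WTCS only).
    ``support`` counts the genes actually used by the method.
    """

    method: str
    value: float
    es_up: float | None = None
    es_down: float | None = None
    support: int = 0


def _as_matched_vectors(q_z: Sequence[float], r_z: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    q = np.asarray(q_z, dtype=float)
    r = np.asarray(r_z, dtype=float)
    if q.shape != r.shape or q.ndim != 1:
        raise ValueError("query and reference vectors must be matched 1-d arrays")
    return q, r


def pearson_score(q_z: Sequence[float], r_z: Sequence[float]) -> float:
    """Product-moment correlation of matched z vectors; raises on
    zero-variance input (a degenerate signature)."""
    q, r = _as_matched_vectors(q_z, r_z)
    if q.size < 3:
        raise ValueError("pearson_score needs at least 3 matched genes")
    if np.std(q) == 0.0 or np.std(r) == 0.0:
        raise ValueError("zero-variance vector: correlation undefined")
    return float(np.corrcoef(q, r)[0, 1])


def spearman_score(q_z: Sequence[float], r_z: Sequence[float]) -> float:
    """Pearson correlation of mid-rank-transformed vectors (average ranks
    for ties)."""
    q, r = _as_matched_vectors(q_z, r_z)
    if q.size < 3:
        raise ValueError("spearman_score needs at least 3 matched genes")
    qr = stats.rankdata(q)
    rr = stats.rankdata(r)
    if np.std(qr) == 0.0 or np.std(rr) == 0.0:
        raise ValueError("zero-variance vector: correlation undefined")
    return float(np.corrcoef(qr, rr)[0, 1])


def cosine_score(q_z: Sequence[float], r_z: Sequence[float]) -> float:
    """Cosine of the angle between the matched z vectors."""
    q, r = _as_matched_vectors(q_z, r_z)
    nq = np.linalg.norm(q)
    nr = np.linalg.norm(r)
    if nq == 0.0 or nr == 0.0:
        raise ValueError("zero-norm vector: cosine similarity undefined")
    return float(np.dot(q, r) / (nq * nr))


def _running_sum(
    gene_set: Sequence[str],
    ref_genes: Sequence[str],
    ref_z: np.ndarray,
    weight_exponent: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted KS running sum of ``gene_set`` along the reference ranking.

    Returns (order, hit mask, running sum), where ``order`` indexes the
    reference genes by z descending (ties by gene id).  A hit at gene g adds
    |z_ref(g)|^w normalized by the set total; a miss adds -1/(N - m).
    """
    ref_genes = tuple(ref_genes)
    ref_z = np.asarray(ref_z, dtype=float)
    n = len(ref_genes)
    m = len(gene_set)
    members = set(gene_set)
    if len(members) != m:
        raise ValueError("gene_set contains duplicates")
    if m < 1:
        raise ValueError("gene_set is empty")
    if m >= n:
        raise ValueError("gene_set must be a proper subset of the reference genes")
    missing = members - set(ref_genes)
    if missing:
        raise KeyError(f"set genes absent from reference: {sorted(missing)[:5]}")
    order = rank_order(ref_genes, ref_z, descending=True)
    hits = np.fromiter((ref_genes[i] in members for i in order), dtype=bool, count=n)
    w = np.abs(ref_z[order]) ** weight_exponent
    hit_total = w[hits].sum()
    if hit_total > 0.0:
        hit_inc = w / hit_total
    else:  # all set genes carry zero weight: fall back to uniform hits
        hit_inc = np.full(n, 1.0 / m)
    steps = np.where(hits, hit_inc, -1.0 / (n - m))
    return order, hits, np.cumsum(steps)


def _signed_extremum(running: np.ndarray) -> float:
    """Max-magnitude deviation of the running sum, signed; at an exact
    magnitude tie the deviation occurring earliest in the ranking wins."""
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    vmax, vmin = float(running[imax]), float(running[imin])
    if abs(vmax) > abs(vmin):
        return vmax
    if abs(vmin) > abs(vmax):
        return vmin
    return vmax if imax <= imin else vmin


def enrichment_score(
    gene_set: Sequence[str],
    ref: Signature,
    weight_exponent: float = 1.0,
) -> float:
    """Weighted Kolmogorov–Smirnov enrichment score of a gene set against
    the reference signature ranked by z descending.

    Walking the ranking, a hit at gene g adds ``|z_ref(g)|^w`` (normalized
    over the set) and a miss adds ``-1/(N - m)``; the score is the running
    sum's maximum-magnitude deviation with its sign.  A score near +1 means
    the set concentrates at the top of the reference ranking, near -1 at the
    bottom.
    """
    _, _, running = _running_sum(gene_set, ref.gene_ids, ref.z, weight_exponent)
    return _signed_extremum(running)


def wtcs(
    extremes: ExtremeGeneSet,
    ref: Signature,
    weight_exponent: float = 1.0,
) -> MethodScore:
    """Weighted connectivity score.

    ``es_up`` and ``es_down`` are the enrichment scores of the query up and
    down sets against the reference ranking; the score is their
    half-difference when they have strictly opposite signs and exactly 0
    otherwise (components agreeing in sign are evidence of neither mimicry
    nor reversal).
    """
    es_up = enrichment_score(extremes.up, ref, weight_exponent)
    es_down = enrichment_score(extremes.down, ref, weight_exponent)
    if es_up * es_down < 0.0:
        value = (es_up - es_down) / 2.0
    else:
        value = 0.0
    return MethodScore("wtcs", value, es_up=es_up, es_down=es_down, support=2 * extremes.K)


def _signed_ranks(z: np.ndarray) -> np.ndarray:
    """Mid-ranks of |z| (ascending) times sign(z)."""
    z = np.asarray(z, dtype=float)
    return stats.rankdata(np.abs(z)) * np.sign(z)


def css_from_ranks(
    ref_signed_ranks: np.ndarray,
    extreme_idx: np.ndarray,
    query_signed_ranks: np.ndarray,
    two_k: int,
) -> float:
    """Connection strength from precomputed signed ranks.

    ``ref_signed_ranks`` covers the whole universe; ``extreme_idx`` indexes
    the 2K query extreme genes in it; ``query_signed_ranks`` are the query's
    signed importance ranks over those genes.  The normalizer pairs the 2K
    largest reference rank magnitudes with the sorted query rank magnitudes,
    largest with largest, so the score attains ±1 exactly when the extremes
    coincide with the reference's strongest genes in matching order/sign.
    """
    c = float(np.dot(ref_signed_ranks[extreme_idx], query_signed_ranks))
    abs_ref = np.abs(ref_signed_ranks)
    top = np.sort(np.partition(abs_ref, abs_ref.size - two_k)[-two_k:])[::-1]
    qmag = np.sort(np.abs(query_signed_ranks))[::-1]
    c_max = float(np.dot(top, qmag))
    if c_max == 0.0:
        raise ValueError("degenerate reference: all signed ranks are zero")
    return c / c_max


def css(extremes: ExtremeGeneSet, ref: Signature) -> MethodScore:
    """Connection strength score (signed-rank formulation).

    Reference genes get signed ranks ``rank(|z_ref|, ascending) * sign(z_ref)``
    over the whole universe; the 2K query extreme genes get signed ranks
    ``rank(|z_query|, ascending among the 2K) * sign(z_query)``.  The raw
    strength is the inner product of the two over the extremes, normalized
    by the maximum attainable pairing.  Ties in |z| receive average ranks.
    """
    ref_ranks = _signed_ranks(ref.z)
    row = {g: i for i, g in enumerate(ref.gene_ids)}
    try:
        idx = np.array([row[g] for g in extremes.genes], dtype=np.intp)
    except KeyError as e:
        raise KeyError(f"extreme gene {e.args[0]!r} absent from reference") from None
    q_z = np.concatenate([extremes.up_z, extremes.down_z])
    q_ranks = _signed_ranks(q_z)
    value = css_from_ranks(ref_ranks, idx, q_ranks, 2 * extremes.K)
    return MethodScore("css", value, support=2 * extremes.K)


def reference_extreme_mask(ref_genes: Sequence[str], ref_z: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of the reference's own top-n and bottom-n genes by z
    (ties by gene id)."""
    ref_z = np.asarray(ref_z, dtype=float)
    if 2 * n > ref_z.size:
        raise ValueError(f"2*ref_extreme_n = {2 * n} exceeds the {ref_z.size}-gene universe")
    order = rank_order(ref_genes, ref_z, descending=True)
    mask = np.zeros(ref_z.size, dtype=bool)
    mask[order[:n]] = True
    mask[order[-n:]] = True
    return mask


def xsum(extremes: ExtremeGeneSet, ref: Signature, ref_extreme_n: int | None = None) -> MethodScore:
    """eXtreme Sum.

    Reference z-scores are zeroed outside the reference's own top/bottom
    ``ref_extreme_n`` genes; the score is the sum of the retained z over the
    query up-genes minus the sum over the query down-genes.  Unbounded;
    large positive values indicate mimicry, large negative values reversal.
    """
    n = extremes.K if ref_extreme_n is None else ref_extreme_n
    mask = reference_extreme_mask(ref.gene_ids, ref.z, n)
    zstar = np.where(mask, ref.z, 0.0)
    row = {g: i for i, g in enumerate(ref.gene_ids)}
    try:
        up_idx = [row[g] for g in extremes.up]
        down_idx = [row[g] for g in extremes.down]
    except KeyError as e:
        raise KeyError(f"extreme gene {e.args[0]!r} absent from reference") from None
    value = float(zstar[up_idx].sum() - zstar[down_idx].sum())
    return MethodScore("xsum", value, support=2 * extremes.K)


def score_pair(
    query: Signature,
    ref: Signature,
    config: ScreenConfig | None = None,
    methods: Sequence[str] = METHODS,
) -> list[MethodScore]:
    """Score one query-reference pair with a subset of the six methods.

    The query must already be aligned to the reference's universe (same gene
    namespace); whole-list methods use the shared genes, extreme methods use
    ``select_extreme_genes(query, K)`` against the full reference.
    """
    config = config or ScreenConfig()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ref_map = ref.zmap()
    shared = [g for g in query.gene_ids if g in ref_map]
    if not shared:
        raise ValueError("query and reference share no genes")
    q_z = np.array([query.zmap()[g] for g in shared])
    r_z = np.array([ref_map[g] for g in shared])

    extremes: ExtremeGeneSet | None = None
    if set(methods) & set(EXTREME_METHODS):
        shared_query = Signature(query.sig_id, tuple(shared), q_z, query.metadata)
        extremes = select_extreme_genes(shared_query, config.K)

    results: list[MethodScore] = []
    errors: list[str] = []
    for m in methods:
        try:
            if m == "pearson":
                results.append(MethodScore(m, pearson_score(q_z, r_z), support=len(shared)))
            elif m == "spearman":
                results.append(MethodScore(m, spearman_score(q_z, r_z), support=len(shared)))
            elif m == "cosine":
                results.append(MethodScore(m, cosine_score(q_z, r_z), support=len(shared)))
            elif m == "wtcs":
                results.append(wtcs(extremes, ref))
            elif m == "css":
                results.append(css(extremes, ref))
            elif m == "xsum":
                results.append(xsum(extremes, ref, config.ref_extreme_n))
        except (ValueError, KeyError) as e:
            errors.append(f"{m}: {e}")
    if errors:
        raise ValueError(
            f"scoring {query.sig_id!r} vs {ref.sig_id!r} failed for "
            + "; ".join(errors)
        )
    return results
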