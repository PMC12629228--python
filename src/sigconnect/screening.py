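"""Full-repository connectivity screens.

A screen compares one query signature with every reference signature in a
repository, in one of two directions:

* **negative** — look for references that *reverse* the query pattern
  (drug-repurposing candidates for a disease query);
* **positive** — look for references that *mimic* the query (mechanism-of-
  action or side-effect inference).

Five methods (Pearson, Spearman, cosine, CSS, XSum) are computed for every
reference.  The weighted connectivity score (WTCS) is the most expensive
method, so it is gated: it is evaluated only for references already deemed
significant by at least one of the other five.  Each method then casts a
vote (1 when a reference's directional result is within the top
``vote_quantile`` of the screen, else 0), and the meta-score — the number
of voting methods, 0 to 6 — measures cross-method consistency.  References
are ranked by meta-score, then by a consensus percentile, then by sig_id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .core import (
    ExtremeGeneSet,
    ScreenConfig,
    Signature,
    SignatureRepository,
    align_query,
    select_extreme_genes,
)
from .permutation import BackgroundStore, empirical_pvalue
from .scoring import (
    EXTREME_METHODS,
    METHODS,
    css,
    wtcs,
    xsum,
)

__all__ = [
    "ConnectivityResult",
    "ScreenReport",
    "run_screen",
    "method_votes",
    "meta_score",
    "wtcs_gate",
]

_META_KEYS = ("compound", "cell_line", "dose", "exposure_time")


@dataclass
class ConnectivityResult:
    """Per-reference outcome of a screen: scores, votes, meta-score, rank."""

    sig_id: str
    scores: dict[str, float]
    pvalues: dict[str, float] = field(default_factory=dict)
    votes: dict[str, int] = field(default_factory=dict)
    meta_score: int = 0
    rank: int = 0
    percentiles: dict[str, float] = field(default_factory=dict)
    gated: bool = False
    metadata: dict[str, str] = field(default_factory=dict)


@dataclass
class ScreenReport:
    """Ranked, annotated screen output plus the configuration snapshot."""

    direction: str
    config: ScreenConfig
    query_id: str
    results: list[ConnectivityResult]
    n_screened: int
    n_gated: int
    n_significant: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"sig_id": r.sig_id}
            for k in _META_KEYS:
                row[k] = r.metadata.get(k, "")
            for m in METHODS:
                row[f"score_{m}"] = r.scores.get(m, np.nan)
            for m in ("pearson", "spearman", "css", "xsum"):
                row[f"p_{m}"] = r.pvalues.get(m, np.nan)
            for m in METHODS:
                row[f"vote_{m}"] = r.votes.get(m, 0)
            for m in METHODS:
                row[f"pct_{m}"] = r.percentiles.get(m, 0.0)
            row["meta_score"] = r.meta_score
            row["consensus_pct"] = round(
                float(np.mean([r.percentiles.get(m, 0.0) for m in METHODS])), 6
            )
            row["gated_wtcs"] = int(r.gated)
            row["rank"] = r.rank
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def summary(self) -> dict:
        cfg = asdict(self.config)
        return {
            "query_id": self.query_id,
            "direction": self.direction,
            "config": cfg,
            "n_screened": self.n_screened,
            "n_gated_for_wtcs": self.n_gated,
            "n_significant": self.n_significant,
            "top": [
                {"sig_id": r.sig_id, "meta_score": r.meta_score, "rank": r.rank}
                for r in self.results[:10]
            ],
        }

    def get(self, sig_id: str) -> ConnectivityResult:
        for r in self.results:
            if r.sig_id == sig_id:
                return r
        raise KeyError(f"sig_id {sig_id!r} not in report")


def meta_score(votes: Sequence[int]) -> int:
    """Sum of the six per-method votes (0–6): 0 means no method placed the
    pair in its top fraction, 6 means all six did."""
    votes = list(votes)
    if len(votes) != 6:
        raise ValueError(f"exactly six votes required, got {len(votes)}")
    if any(v not in (0, 1) for v in votes):
        raise ValueError("votes must be 0 or 1")
    return int(sum(votes))


def method_votes(
    sig_ids: Sequence[str],
    scores: np.ndarray | None = None,
    pvalues: np.ndarray | None = None,
    direction: str = "negative",
    vote_quantile: float = 0.05,
    eligible: np.ndarray | None = None,
    n_total: int | None = None,
) -> np.ndarray:
    """Binary top-quantile votes for one method across the screen.

    A reference votes 1 when its directional effective result ranks within
    the top ``ceil(vote_quantile * S)`` of all ``S`` screened references.
    Ranking is by directional effective score descending (the negated raw
    score in a negative screen), or — when one-sided empirical p-values are
    supplied — by p ascending; ties are broken by sig_id ascending.
    ``eligible`` marks references allowed to vote (used for WTCS gating; the
    cutoff denominator stays the full screen size).
    """
    sig_ids = np.asarray(sig_ids, dtype=object)
    S = n_total if n_total is not None else sig_ids.size
    m = math.ceil(vote_quantile * S)
    if pvalues is not None:
        key = np.asarray(pvalues, dtype=float)
    else:
        if scores is None:
            raise ValueError("either scores or pvalues must be supplied")
        eff = np.asarray(scores, dtype=float)
        if direction == "negative":
            eff = -eff
        key = -eff  # ascending key: best first
    if eligible is None:
        eligible = np.ones(sig_ids.size, dtype=bool)
    else:
        eligible = np.asarray(eligible, dtype=bool)
    key = np.where(eligible, key, np.inf)
    order = np.lexsort((sig_ids, key))
    votes = np.zeros(sig_ids.size, dtype=int)
    winners = [i for i in order[:m] if eligible[i]]
    votes[winners] = 1
    return votes


def wtcs_gate(five_method_votes: np.ndarray) -> np.ndarray:
    """References significant by >= 1 of the five non-WTCS methods.

    ``five_method_votes`` is (S, 5) binary; returns a boolean mask of the
    references admitted to the WTCS computation.
    """
    v = np.asarray(five_method_votes)
    if v.ndim != 2 or v.shape[1] != 5:
        raise ValueError("expected an (S, 5) vote matrix")
    return v.sum(axis=1) >= 1


def _percentiles(
    scores: np.ndarray, direction: str, eligible: np.ndarray | None = None
) -> np.ndarray:
    """Directional percentile ranks in [0, 100]; 100 = strongest in the
    screen direction.  Ineligible entries get 0."""
    eff = np.asarray(scores, dtype=float)
    if direction == "negative":
        eff = -eff
    if eligible is None:
        eligible = np.ones(eff.size, dtype=bool)
    out = np.zeros(eff.size)
    vals = eff[eligible]
    if vals.size == 1:
        out[eligible] = 100.0
    elif vals.size > 1:
        r = stats.rankdata(vals)  # 1 = weakest
        out[eligible] = 100.0 * (r - 1) / (vals.size - 1)
    return out


def _chunk_indices(n: int, n_chunks: int) -> list[np.ndarray]:
    return [c for c in np.array_split(np.arange(n), max(1, n_chunks)) if c.size]


def _extreme_scores_chunk(
    matrix: np.ndarray,
    gene_ids: tuple[str, ...],
    cols: np.ndarray,
    sig_ids: Sequence[str],
    extremes: ExtremeGeneSet,
    ref_extreme_n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """CSS and XSum for a block of reference columns (one worker's share)."""
    css_vals = np.empty(cols.size)
    xsum_vals = np.empty(cols.size)
    for k, j in enumerate(cols):
        ref = Signature(sig_ids[j], gene_ids, matrix[:, j])
        css_vals[k] = css(extremes, ref).value
        xsum_vals[k] = xsum(extremes, ref, ref_extreme_n).value
    return css_vals, xsum_vals


def run_screen(
    query: Signature,
    repo: SignatureRepository,
    config: ScreenConfig | None = None,
    backgrounds: BackgroundStore | None = None,
    n_jobs: int = 1,
) -> ScreenReport:
    """Screen a query against every repository signature.

    Steps: (1) align the query to the repository universe; (2) compute
    Pearson, Spearman, cosine, CSS and XSum for every reference (CSS/XSum
    empirical p-values are added when a background store is supplied);
    (3) gate WTCS to references significant by >= 1 of the five; (4) assign
    per-method top-quantile votes and the meta-score; (5) order by
    (meta-score desc, consensus percentile desc, sig_id asc).

    Work may be partitioned across ``n_jobs`` workers by reference; the
    merged output is deterministically sorted, so results are independent
    of the worker count.
    """
    config = config or ScreenConfig()
    n_genes = len(repo.gene_universe)
    config.validate_against_universe(n_genes)
    S = len(repo)

    aligned = align_query(query, repo, config.min_overlap_frac)
    shared_idx = repo.gene_index(aligned.gene_ids)
    q_z = aligned.z
    sub = repo.matrix[shared_idx, :]  # shared genes x S

    # whole-list methods, vectorized over all references
    if np.std(q_z) == 0.0:
        raise ValueError("degenerate query: zero variance after alignment")
    col_sd = sub.std(axis=0)
    if np.any(col_sd == 0.0):
        bad = [repo.sig_ids[j] for j in np.flatnonzero(col_sd == 0.0)[:5]]
        raise ValueError(f"zero-variance reference signature(s): {bad}")
    qc = (q_z - q_z.mean()) / q_z.std()
    rc = (sub - sub.mean(axis=0)) / col_sd
    pearson_vals = qc @ rc / q_z.size
    q_rank = stats.rankdata(q_z)
    r_rank = stats.rankdata(sub, axis=0)
    qrc = (q_rank - q_rank.mean()) / q_rank.std()
    rr_sd = r_rank.std(axis=0)
    rrc = (r_rank - r_rank.mean(axis=0)) / rr_sd
    spearman_vals = qrc @ rrc / q_z.size
    cosine_vals = (q_z @ sub) / (np.linalg.norm(q_z) * np.linalg.norm(sub, axis=0))

    # extreme-gene methods: extremes from the aligned query, reference side
    # over the full universe
    extremes = select_extreme_genes(aligned, config.K)
    chunks = _chunk_indices(S, n_jobs)
    parts = Parallel(n_jobs=n_jobs, prefer="threads")(
        delayed(_extreme_scores_chunk)(
            repo.matrix, repo.gene_universe, cols, repo.sig_ids, extremes,
            config.ref_extreme_n,
        )
        for cols in chunks
    )
    css_vals = np.concatenate([p[0] for p in parts])
    xsum_vals = np.concatenate([p[1] for p in parts])

    score_mat = {
        "pearson": pearson_vals,
        "spearman": spearman_vals,
        "cosine": cosine_vals,
        "css": css_vals,
        "xsum": xsum_vals,
    }

    # empirical p-values in the screen direction, when backgrounds exist
    tail = "upper" if config.direction == "positive" else "lower"
    pvals: dict[str, np.ndarray] = {}
    if backgrounds is not None:
        for m in ("css", "xsum"):
            p = np.empty(S)
            for j, sid in enumerate(repo.sig_ids):
                bg = backgrounds.get(sid, m, config.K, n_perm=config.n_perm)
                p[j] = empirical_pvalue(score_mat[m][j], bg, tail)
            pvals[m] = p
    # t-approximation p-values for the correlation methods (two-sided)
    for m, vals in (("pearson", pearson_vals), ("spearman", spearman_vals)):
        df = q_z.size - 2
        r = np.clip(vals, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt(df / (1 - r**2))
        pvals[m] = 2 * stats.t.sf(np.abs(t), df)

    # votes of the five non-WTCS methods
    sig_ids = np.asarray(repo.sig_ids, dtype=object)
    votes: dict[str, np.ndarray] = {}
    for m in ("pearson", "spearman", "cosine", "css", "xsum"):
        votes[m] = method_votes(
            sig_ids,
            scores=score_mat[m],
            pvalues=pvals[m] if (m in ("css", "xsum") and m in pvals) else None,
            direction=config.direction,
            vote_quantile=config.vote_quantile,
        )

    # significance flags for the gate
    if config.gate_rule == "pvalue":
        sig_flags = np.stack(
            [
                pvals["pearson"] <= 0.05,
                pvals["spearman"] <= 0.05,
                votes["cosine"].astype(bool),
                (pvals["css"] <= 0.05) if "css" in pvals else votes["css"].astype(bool),
                (pvals["xsum"] <= 0.05) if "xsum" in pvals else votes["xsum"].astype(bool),
            ],
            axis=1,
        ).astype(int)
    else:
        sig_flags = np.stack(
            [votes[m] for m in ("pearson", "spearman", "cosine", "css", "xsum")],
            axis=1,
        )
    gate = wtcs_gate(sig_flags)

    # WTCS only for gated references
    wtcs_vals = np.full(S, np.nan)
    gated_cols = np.flatnonzero(gate)
    gchunks = _chunk_indices(gated_cols.size, n_jobs)

    def _wtcs_chunk(sel: np.ndarray) -> np.ndarray:
        out = np.empty(sel.size)
        for k, j in enumerate(gated_cols[sel]):
            ref = Signature(repo.sig_ids[j], repo.gene_universe, repo.matrix[:, j])
            out[k] = wtcs(extremes, ref).value
        return out

    if gated_cols.size:
        wparts = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(_wtcs_chunk)(sel) for sel in gchunks
        )
        wtcs_vals[gated_cols] = np.concatenate(wparts)

    votes["wtcs"] = method_votes(
        sig_ids,
        scores=np.where(gate, wtcs_vals, 0.0),
        direction=config.direction,
        vote_quantile=config.vote_quantile,
        eligible=gate,
        n_total=S,
    )

    meta = np.stack([votes[m] for m in METHODS], axis=1).sum(axis=1)

    # directional percentiles (radar axes and the consensus tie-breaker)
    pct: dict[str, np.ndarray] = {}
    for m in ("pearson", "spearman", "cosine", "css", "xsum"):
        pct[m] = _percentiles(score_mat[m], config.direction)
    pct["wtcs"] = _percentiles(
        np.where(gate, wtcs_vals, 0.0), config.direction, eligible=gate
    )
    consensus = np.mean([pct[m] for m in METHODS], axis=0)

    order = np.lexsort((sig_ids, -consensus, -meta))
    results: list[ConnectivityResult] = []
    for pos, j in enumerate(order, start=1):
        scores_j = {m: float(score_mat[m][j]) for m in score_mat}
        if gate[j]:
            scores_j["wtcs"] = float(wtcs_vals[j])
        results.append(
            ConnectivityResult(
                sig_id=str(sig_ids[j]),
                scores=scores_j,
                pvalues={m: float(pvals[m][j]) for m in pvals},
                votes={m: int(votes[m][j]) for m in METHODS},
                meta_score=int(meta[j]),
                rank=pos,
                percentiles={m: float(pct[m][j]) for m in METHODS},
                gated=bool(gate[j]),
                metadata=dict(repo.metadata[j]),
            )
        )
    return ScreenReport(
        direction=config.direction,
        config=config,
        query_id=query.sig_id,
        results=results,
        n_screened=S,
        n_gated=int(gate.sum()),
        n_significant=int((meta >= 1).sum()),
    )
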