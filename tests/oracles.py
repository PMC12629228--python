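"""Independent naive evaluators used as oracles in tests.

These deliberately avoid every helper in the package: plain Python loops
and explicit sorting, so a defect in the implementation cannot hide in a
shared code path.
"""

from __future__ import annotations


def naive_average_ranks(values):
    """1-based mid-ranks (ascending) by pairwise counting."""
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def _sign(x: float) -> float:
    return 0.0 if x == 0 else (1.0 if x > 0 else -1.0)


def naive_enrichment_score(gene_set, ref_genes, ref_z, weight_exponent=1.0):
    """Position-by-position weighted KS running sum, earliest tie wins."""
    n = len(ref_genes)
    m = len(gene_set)
    members = set(gene_set)
    ranking = sorted(zip(ref_genes, ref_z), key=lambda gz: (-gz[1], gz[0]))
    denom = sum(abs(z) ** weight_exponent for g, z in ranking if g in members)
    running = 0.0
    best = 0.0
    best_abs = -1.0
    for g, z in ranking:
        if g in members:
            running += (abs(z) ** weight_exponent / denom) if denom > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > best_abs:
            best_abs = abs(running)
            best = running
    return best


def naive_css(up, down, up_z, down_z, ref_genes, ref_z):
    """Signed-rank connection strength evaluated literally."""
    ref_rank = {
        g: r * _sign(z)
        for g, z, r in zip(
            ref_genes, ref_z, naive_average_ranks([abs(z) for z in ref_z])
        )
    }
    genes = list(up) + list(down)
    q_z = list(up_z) + list(down_z)
    q_rank = {
        g: r * _sign(z)
        for g, z, r in zip(genes, q_z, naive_average_ranks([abs(z) for z in q_z]))
    }
    c = sum(ref_rank[g] * q_rank[g] for g in genes)
    two_k = len(genes)
    top_ref = sorted((abs(v) for v in ref_rank.values()), reverse=True)[:two_k]
    top_q = sorted((abs(q_rank[g]) for g in genes), reverse=True)
    c_max = sum(a * b for a, b in zip(top_ref, top_q))
    return c / c_max


def naive_xsum(up, down, ref_genes, ref_z, ref_extreme_n):
    """Query-extreme sums over the reference-extreme-restricted z."""
    ranking = sorted(zip(ref_genes, ref_z), key=lambda gz: (-gz[1], gz[0]))
    kept = {g for g, _ in ranking[:ref_extreme_n]} | {
        g for g, _ in ranking[-ref_extreme_n:]
    }
    zmap = dict(zip(ref_genes, ref_z))
    zstar = lambda g: zmap[g] if g in kept else 0.0
    return sum(zstar(g) for g in up) - sum(zstar(g) for g in down)
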