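"""Synthetic signature repositories with known ground truth.

Real reference repositories (hundreds of thousands of compound-induced
level-5 z-score signatures) are far too large for desk testing, so this
module emulates their structure at small scale: a shared gene universe,
null signatures with i.i.d. standard-normal z (the simplest null consistent
with z-score semantics; no gene-gene correlation), and planted signatures
with a known relationship to a chosen query:

* a **mimic** is ``alpha * standardize(q) + eps``,
* a **reversal** is ``-alpha * standardize(q) + eps``,

with ``eps`` i.i.d. normal(0, noise_sd).  The query is standardized before
planting so ``alpha`` is comparable across queries.  A truth table records
every planted signature's kind and parameters, making screens verifiable
end to end.  Everything is reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Signature, SignatureRepository

__all__ = ["PlantedSignal", "SimulationSpec", "simulate_query", "simulate_repository"]

_KINDS = ("mimic", "reversal")


@dataclass(frozen=True)
class PlantedSignal:
    """One planted signature: its relationship to the query and noise level."""

    kind: str
    alpha: float = 1.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimulationSpec:
    """Parameters of a synthetic repository."""

    n_genes: int = 1000
    n_signatures: int = 500
    planted: tuple[PlantedSignal, ...] = ()
    seed: int = 0
    compounds: Sequence[str] = ("cmpd-A", "cmpd-B", "cmpd-C", "cmpd-D")
    cell_lines: Sequence[str] = ("MCF7", "PC3", "A375")
    doses: Sequence[str] = ("10 uM", "1 uM")
    times: Sequence[str] = ("6 h", "24 h")

    def __post_init__(self) -> None:
        self.planted = tuple(self.planted)
        if self.n_genes < 4:
            raise ValueError("n_genes must be >= 4")
        if len(self.planted) >= self.n_signatures:
            raise ValueError("planted count must be < n_signatures")


def _gene_universe(n_genes: int) -> tuple[str, ...]:
    width = max(5, len(str(n_genes)))
    return tuple(f"G{i:0{width}d}" for i in range(1, n_genes + 1))


def simulate_query(n_genes: int = 1000, seed: int = 0, sig_id: str = "query") -> Signature:
    """An i.i.d. standard-normal query signature over a generated universe."""
    if n_genes < 4:
        raise ValueError("n_genes must be >= 4")
    rng = np.random.default_rng(seed)
    return Signature(sig_id, _gene_universe(n_genes), rng.standard_normal(n_genes))


def _standardize(z: np.ndarray) -> np.ndarray:
    sd = z.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant query")
    return (z - z.mean()) / sd


def simulate_repository(
    spec: SimulationSpec,
    query: Signature | None = None,
) -> tuple[SignatureRepository, pd.DataFrame]:
    """Generate a repository of null signatures plus any planted signals.

    When ``spec.planted`` is non-empty a query is required (planted
    signatures are defined relative to it) and the repository universe is
    the query's gene list; otherwise a fresh universe is generated.  The
    returned truth table has one row per repository signature with columns
    (sig_id, kind, alpha, noise_sd); kind is "null" for unplanted ones.
    """
    if spec.planted and query is None:
        raise ValueError("planted signals require a query signature")
    rng = np.random.default_rng(spec.seed)
    if query is not None:
        universe = query.gene_ids
        if len(universe) != spec.n_genes:
            raise ValueError(
                f"query has {len(universe)} genes but spec.n_genes = {spec.n_genes}"
            )
    else:
        universe = _gene_universe(spec.n_genes)

    n_null = spec.n_signatures - len(spec.planted)
    matrix = np.empty((spec.n_genes, spec.n_signatures))
    sig_ids: list[str] = []
    metadata: list[dict[str, str]] = []
    truth_rows: list[dict] = []

    width = max(4, len(str(spec.n_signatures)))
    for j in range(n_null):
        sid = f"SIG_{j + 1:0{width}d}"
        matrix[:, j] = rng.standard_normal(spec.n_genes)
        sig_ids.append(sid)
        metadata.append(
            {
                "compound": spec.compounds[j % len(spec.compounds)],
                "cell_line": spec.cell_lines[j % len(spec.cell_lines)],
                "dose": spec.doses[j % len(spec.doses)],
                "exposure_time": spec.times[j % len(spec.times)],
                "perturbation_type": "compound",
            }
        )
        truth_rows.append({"sig_id": sid, "kind": "null", "alpha": np.nan, "noise_sd": np.nan})

    if spec.planted:
        base = _standardize(query.z)
        for k, plant in enumerate(spec.planted):
            j = n_null + k
            sid = f"PLANT_{plant.kind.upper()}_{k + 1:03d}"
            sign = 1.0 if plant.kind == "mimic" else -1.0
            eps = rng.standard_normal(spec.n_genes) * plant.noise_sd
            matrix[:, j] = sign * plant.alpha * base + eps
            sig_ids.append(sid)
            metadata.append(
                {
                    "compound": f"planted-{plant.kind}",
                    "cell_line": spec.cell_lines[0],
                    "dose": spec.doses[0],
                    "exposure_time": spec.times[0],
                    "perturbation_type": "planted",
                }
            )
            truth_rows.append(
                {
                    "sig_id": sid,
                    "kind": plant.kind,
                    "alpha": plant.alpha,
                    "noise_sd": plant.noise_sd,
                }
            )

    repo = SignatureRepository(universe, sig_ids, matrix, metadata, "memory")
    truth = pd.DataFrame(truth_rows, columns=["sig_id", "kind", "alpha", "noise_sd"])
    return repo, truth
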