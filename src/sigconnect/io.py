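"""Readers and writers for signature formats and repository backends.

Supported formats:

* **GCT 1.2 / 1.3** — the standard text matrix format for gene-expression
  signature collections (genes as rows, signatures as columns; the 1.3
  dialect adds row/column metadata blocks).
* **signature JSON** — one record per signature with parallel gene/value
  arrays; schema: ``{"sig_id": str, "gene_ids": [str], "z": [float],
  "metadata": {"compound"|"pert_iname", "cell_line", "dose", "time"|
  "exposure_time", "pert_type", "smiles": str}}``.  A directory of such
  records forms a repository.
* **query TSV** — two tab-separated columns (gene_id, z), optional header.

All readers reject malformed input rather than silently coercing it, and
every writer/reader pair round-trips valid data losslessly.

Repository backends (in-memory, GCT file, JSON directory, or any object
honoring the remote-endpoint protocol below) all satisfy one read
contract — list signature ids, fetch a signature by id, report the gene
universe — so no downstream operation behaves differently by backend.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .core import Signature, SignatureRepository

__all__ = [
    "read_gct",
    "write_gct",
    "read_signature_json",
    "write_signature_json",
    "read_json_directory",
    "read_query_tsv",
    "load_repository",
    "RemoteRepositoryProtocol",
    "repository_from_remote",
]

_JSON_META_KEYS = ("pert_iname", "compound", "cell_line", "dose", "time",
                   "exposure_time", "pert_type", "perturbation_type", "smiles")


class GctParseError(ValueError):
    """Malformed GCT content; the message carries the offending line number."""


def read_gct(path: str | Path) -> SignatureRepository:
    """Parse a GCT 1.2 or 1.3 text matrix into a repository.

    Genes are rows and signatures are columns; in the 1.3 dialect the
    column-metadata rows are mapped into per-signature metadata.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GctParseError(f"{path}: fewer than 3 lines, not a GCT file")
    version = lines[0].strip()
    if version not in ("#1.2", "#1.3"):
        raise GctParseError(f"{path} line 1: unsupported version line {version!r}")
    dims = lines[1].split()
    try:
        dims = [int(d) for d in dims]
    except ValueError:
        raise GctParseError(f"{path} line 2: non-integer dimension line") from None
    if version == "#1.2":
        if len(dims) != 2:
            raise GctParseError(f"{path} line 2: GCT 1.2 needs 2 dimensions, got {len(dims)}")
        n_rows, n_cols = dims
        n_rmeta, n_cmeta = 1, 0  # the Description column
    else:
        if len(dims) != 4:
            raise GctParseError(f"{path} line 2: GCT 1.3 needs 4 dimensions, got {len(dims)}")
        n_rows, n_cols, n_rmeta, n_cmeta = dims

    header = lines[2].rstrip("\n").split("\t")
    expected_header = 1 + n_rmeta + n_cols
    if len(header) != expected_header:
        raise GctParseError(
            f"{path} line 3: header has {len(header)} fields, expected {expected_header}"
        )
    sig_ids = header[1 + n_rmeta :]

    col_meta: list[dict[str, str]] = [{} for _ in range(n_cols)]
    body_start = 3
    for k in range(n_cmeta):
        ln = body_start + k
        fields = lines[ln].rstrip("\n").split("\t")
        if len(fields) != expected_header:
            raise GctParseError(
                f"{path} line {ln + 1}: metadata row has {len(fields)} fields, "
                f"expected {expected_header}"
            )
        name = fields[0]
        for j, v in enumerate(fields[1 + n_rmeta :]):
            col_meta[j][name] = v
    body_start += n_cmeta

    data_lines = [l for l in lines[body_start:] if l.strip()]
    if len(data_lines) != n_rows:
        raise GctParseError(
            f"{path}: dimension line declares {n_rows} data rows but body has "
            f"{len(data_lines)}"
        )
    genes: list[str] = []
    matrix = np.empty((n_rows, n_cols))
    for i, line in enumerate(data_lines):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != expected_header:
            raise GctParseError(
                f"{path} line {body_start + i + 1}: data row has {len(fields)} "
                f"fields, expected {expected_header}"
            )
        genes.append(fields[0])
        try:
            matrix[i, :] = [float(v) for v in fields[1 + n_rmeta :]]
        except ValueError:
            raise GctParseError(
                f"{path} line {body_start + i + 1}: non-numeric cell"
            ) from None
    return SignatureRepository(genes, sig_ids, matrix, col_meta, f"gct-file:{path}")


def write_gct(repo: SignatureRepository, path: str | Path) -> None:
    """Write a repository as GCT (1.3 when any signature carries metadata,
    else 1.2)."""
    path = Path(path)
    meta_keys: list[str] = []
    for m in repo.metadata:
        for k in m:
            if k not in meta_keys:
                meta_keys.append(k)
    n_rows, n_cols = repo.matrix.shape
    with path.open("w") as fh:
        if meta_keys:
            fh.write("#1.3\n")
            fh.write(f"{n_rows}\t{n_cols}\t1\t{len(meta_keys)}\n")
            fh.write("id\tdesc\t" + "\t".join(repo.sig_ids) + "\n")
            for key in meta_keys:
                vals = [repo.metadata[j].get(key, "") for j in range(n_cols)]
                fh.write(key + "\tna\t" + "\t".join(vals) + "\n")
        else:
            fh.write("#1.2\n")
            fh.write(f"{n_rows}\t{n_cols}\n")
            fh.write("Name\tDescription\t" + "\t".join(repo.sig_ids) + "\n")
        for i, g in enumerate(repo.gene_universe):
            row = "\t".join(repr(float(v)) for v in repo.matrix[i, :])
            fh.write(f"{g}\tna\t{row}\n")


def read_signature_json(path: str | Path) -> Signature:
    """Read one signature record from a JSON file."""
    path = Path(path)
    try:
        record = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: invalid JSON ({e})") from None
    for key in ("sig_id", "gene_ids", "z"):
        if key not in record:
            raise ValueError(f"{path}: missing required key {key!r}")
    genes = record["gene_ids"]
    z = record["z"]
    if len(genes) != len(z):
        raise ValueError(
            f"{path}: gene_ids has {len(genes)} entries but z has {len(z)}"
        )
    meta = record.get("metadata", {})
    if not isinstance(meta, dict):
        raise ValueError(f"{path}: metadata must be an object")
    try:
        return Signature(str(record["sig_id"]), genes, z, {str(k): str(v) for k, v in meta.items()})
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_signature_json(sig: Signature, path: str | Path) -> None:
    record = {
        "sig_id": sig.sig_id,
        "gene_ids": list(sig.gene_ids),
        "z": [float(v) for v in sig.z],
        "metadata": dict(sig.metadata),
    }
    Path(path).write_text(json.dumps(record, indent=1))


def read_json_directory(directory: str | Path) -> SignatureRepository:
    """Aggregate every ``*.json`` record in a directory into a repository
    (gene universe = intersection, ordered as in the first record)."""
    directory = Path(directory)
    files = sorted(directory.glob("*.json"))
    if not files:
        raise ValueError(f"{directory}: no .json signature records found")
    sigs = [read_signature_json(f) for f in files]
    repo = SignatureRepository.from_signatures(sigs, f"json-directory:{directory}")
    return repo


def read_query_tsv(path: str | Path) -> Signature:
    """Read a two-column (gene_id, z) query; a header row is detected by a
    non-numeric second field.  The signature id is the file stem."""
    path = Path(path)
    genes: list[str] = []
    zs: list[float] = []
    with path.open() as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path} row {row_no}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            gene, val = fields[0].strip(), fields[1].strip()
            if row_no == 1:
                try:
                    float(val)
                except ValueError:
                    continue  # header row
            try:
                z = float(val)
            except ValueError:
                raise ValueError(
                    f"{path} row {row_no}: unparseable z value {val!r}"
                ) from None
            if gene in genes:
                raise ValueError(f"{path} row {row_no}: duplicate gene {gene!r}")
            genes.append(gene)
            zs.append(z)
    if len(genes) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    return Signature(path.stem, tuple(genes), np.array(zs))


@runtime_checkable
class RemoteRepositoryProtocol(Protocol):
    """Read contract any remote signature endpoint client must honor.

    Implementations return the same JSON dialect as the on-disk records;
    tests exercise the contract with an in-process stub, and a screen over
    a remote backend must be indistinguishable from one over local files.
    """

    def list_sig_ids(self) -> list[str]: ...
    def gene_universe(self) -> list[str]: ...
    def fetch(self, sig_id: str) -> dict: ...


def repository_from_remote(client: RemoteRepositoryProtocol) -> SignatureRepository:
    """Materialize a repository through the remote read contract."""
    sig_ids = client.list_sig_ids()
    sigs = []
    for sid in sig_ids:
        record = client.fetch(sid)
        meta = record.get("metadata", {})
        sigs.append(Signature(record["sig_id"], record["gene_ids"], record["z"], meta))
    repo = SignatureRepository.from_signatures(sigs, "http-endpoint")
    universe = tuple(client.gene_universe())
    if tuple(repo.gene_universe) != universe:
        # re-align to the endpoint's declared universe order
        idx = repo.gene_index(universe)
        repo = SignatureRepository(
            universe, repo.sig_ids, repo.matrix[idx, :], repo.metadata, "http-endpoint"
        )
    return repo


def load_repository(location: str | Path) -> SignatureRepository:
    """Open a repository from a GCT file or a directory of JSON records."""
    location = Path(location)
    if location.is_dir():
        return read_json_directory(location)
    if location.suffix.lower() == ".gct":
        return read_gct(location)
    raise ValueError(
        f"{location}: expected a .gct file or a directory of .json records"
    )
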