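"""CSV readers/writers, run configuration, and paired fixtures."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .generator import GenerativeParams, generate_true_data
from .matrix import OrdinalMatrix
from .replacement import Direction, ReplacementParams, perturb_matrix

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "make_fixture",
    "RunConfig",
]


class IngestError(ValueError):
    """Raised when a response-matrix CSV fails validation."""


def _looks_like_header(row: list[str]) -> bool:
    for cell in row:
        try:
            float(cell)
        except ValueError:
            return True
    return False


def read_response_matrix(path: str | Path, q: int) -> OrdinalMatrix:
    """Read and validate an integer response matrix from CSV.

    A header row is auto-detected (any non-numeric cell in the first row).
    Every cell must be an integer in ``{1..q}``; violations raise
    :class:`IngestError` naming the offending row and column.  Missing cells
    are rejected, never imputed.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise IngestError(f"{path}: empty file")
    if _looks_like_header(rows[0]):
        rows = rows[1:]
        if not rows:
            raise IngestError(f"{path}: header only, no data rows")
    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=np.int64)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise IngestError(
                f"{path}: row {i} has {len(row)} cells, expected {width}"
            )
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell == "":
                raise IngestError(f"{path}: missing cell at row {i}, column {j}")
            try:
                value = int(cell)
            except ValueError:
                try:
                    fval = float(cell)
                except ValueError:
                    raise IngestError(
                        f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                    ) from None
                if fval != int(fval):
                    raise IngestError(
                        f"{path}: non-integer cell {cell!r} at row {i}, column {j}"
                    ) from None
                value = int(fval)
            if not (1 <= value <= q):
                raise IngestError(
                    f"{path}: value {value} at row {i}, column {j} outside 1..{q}"
                )
            data[i, j] = value
    return OrdinalMatrix(data, q)


def write_response_matrix(
    data: OrdinalMatrix, path: str | Path, header: bool = True
) -> None:
    """Write a response matrix as CSV with ``item1..itemM`` header columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow([f"item{j + 1}" for j in range(data.m)])
        writer.writerows(data.values.tolist())


def make_fixture(
    kind: str,
    gen: GenerativeParams,
    corruption: ReplacementParams | None = None,
    seed: int | None = None,
):
    """Generate test fixtures: honest data, fake data, or an (honest, fake) pair.

    ``true_data`` returns an honest matrix from the generative model;
    ``fake_data`` returns that matrix after a forward fake-good corruption;
    ``paired`` returns the ``(D, F)`` tuple.  Deterministic under the seed
    (``gen.seed`` for generation, ``seed`` or ``gen.seed + 1`` for the
    corruption draws).
    """
    if kind not in ("true_data", "fake_data", "paired"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    D = generate_true_data(gen)
    if kind == "true_data":
        return D
    if corruption is None:
        raise ValueError(f"fixture kind {kind!r} requires corruption params")
    if Direction(corruption.direction) is not Direction.FORWARD:
        raise ValueError("fixture corruption must use the forward direction")
    perturb_seed = gen.seed + 1 if seed is None else seed
    F = perturb_matrix(D, corruption, perturb_seed)
    return F if kind == "fake_data" else (D, F)


@dataclass
class RunConfig:
    """Serializable configuration for a full experiment run."""

    input: str = ""
    control: str = "self"
    output: str = "results"
    scenarios: list[str] = field(
        default_factory=lambda: ["uninformative", "slight", "extreme"]
    )
    pi_grid: list[float] = field(default_factory=lambda: [0.25, 0.5, 0.75, 1.0])
    B: int = 2000
    q: int = 5
    seed: int = 0
    generative: dict | None = None
    cfa_max_iter: int = 500

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        return cls(**payload)

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
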