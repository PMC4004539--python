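"""Readers, writers, and run manifests.

All artifacts are plain text: CSV for matrices and tidy tables, TSV for
edge lists, JSON for manifests and summaries, ASCII PGM for checkerboard
images.  Files are written with Unix newlines and UTF-8 so re-running a
seeded experiment overwrites its outputs byte-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .experiments import CheckerboardResult, SweepResult
from .metrics import classify_outcome
from .model import FeelingConfiguration, Trajectory

__all__ = [
    "FormatError",
    "RunManifest",
    "read_feeling_matrix",
    "write_feeling_matrix",
    "write_outputs",
]


class FormatError(ValueError):
    """Raised when an input file violates the feeling-matrix format."""


@dataclass
class RunManifest:
    """Record of one invocation: parameters, seeds, and artifacts written.

    Together with the package version the manifest suffices to reproduce a
    run bit-identically (the ``created`` timestamp is informational and is
    the only field that varies between identical re-runs).
    """

    parameters: dict
    artifacts: List[str] = field(default_factory=list)
    terminal_status: Optional[str] = None
    version: str = __version__
    created: str = ""

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "created": self.created,
            "parameters": self.parameters,
            "terminal_status": self.terminal_status,
            "artifacts": self.artifacts,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def read_feeling_matrix(path: Union[str, Path]) -> FeelingConfiguration:
    """Load an N x N feeling matrix from headerless CSV.

    Entries must be +1/-1; a zero diagonal (a common adjacency convention)
    is coerced to +1 with a warning.  Non-square files, off-diagonal values
    outside {+1, -1}, or N < 2 raise :class:`FormatError` naming the cell.
    """
    path = Path(path)
    rows = []
    with path.open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(v) for v in line.split(",")])
            except ValueError as exc:
                raise FormatError(f"{path}: row {line_no + 1} is not numeric") from exc
    if not rows:
        raise FormatError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths.pop() != len(rows):
        raise FormatError(
            f"{path}: matrix must be square, got {len(rows)} rows of widths "
            f"{sorted({len(r) for r in rows})}"
        )
    matrix = np.asarray(rows)
    n = matrix.shape[0]
    if n < 2:
        raise FormatError(f"{path}: at least 2 agents required, got {n}")

    diag = np.diagonal(matrix)
    if (diag == 0).any():
        warnings.warn(
            f"{path}: zero diagonal coerced to +1", stacklevel=2
        )
        matrix = matrix.copy()
        np.fill_diagonal(matrix, np.where(diag == 0, 1, diag))
        diag = np.diagonal(matrix)
    bad_diag = np.flatnonzero(diag != 1)
    if bad_diag.size:
        i = int(bad_diag[0])
        raise FormatError(f"{path}: diagonal entry at row {i + 1}, column {i + 1} must be +1")
    off = ~np.eye(n, dtype=bool)
    bad = np.argwhere(off & ~np.isin(matrix, (-1, 1)))
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"{path}: entry at row {r + 1}, column {c + 1} is "
            f"{matrix[r, c]!r}, expected +1 or -1"
        )
    return FeelingConfiguration(matrix.astype(np.int8))


def write_feeling_matrix(config: FeelingConfiguration, path: Union[str, Path]) -> None:
    """Write a configuration as headerless CSV of +1/-1 (round-trips exactly)."""
    np.savetxt(path, config.matrix, fmt="%d", delimiter=",", newline="\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _write_edge_lists(config: FeelingConfiguration, out_dir: Path) -> List[str]:
    """Mutual-friendship graph (undirected TSV) and signed directed feelings."""
    adj = config.mutual_adjacency()
    n = config.n_agents
    names = []

    mutual_path = out_dir / "mutual_edges.tsv"
    with mutual_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("agent_a\tagent_b\n")
        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j]:
                    fh.write(f"{i + 1}\t{j + 1}\n")
    names.append(mutual_path.name)

    signed_path = out_dir / "feeling_edges.tsv"
    with signed_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tsign\n")
        for i in range(n):
            for j in range(n):
                if i != j:
                    fh.write(f"{i + 1}\t{j + 1}\t{int(config.matrix[i, j]):+d}\n")
    names.append(signed_path.name)
    return names


def write_pgm(codes: np.ndarray, path: Union[str, Path]) -> None:
    """Render a class-code matrix as an ASCII portable graymap.

    0 (unified) maps to white 255, 1 (ostracism) to black 0, and
    2 (fragmented) to mid-gray 128.
    """
    gray = np.select([codes == 0, codes == 1], [255, 0], default=128)
    lines = [f"P2", f"{codes.shape[1]} {codes.shape[0]}", "255"]
    lines += [" ".join(str(v) for v in row) for row in gray]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_outputs(
    result: Union[Trajectory, SweepResult, CheckerboardResult],
    out_dir: Union[str, Path],
    parameters: Optional[dict] = None,
) -> RunManifest:
    """Write a result's artifact set plus a JSON manifest to ``out_dir``.

    Trajectories yield a tidy group-size CSV, the final-state edge lists,
    and the terminal feeling matrix; sweeps yield their table as CSV;
    checkerboards yield the class-code CSV and a PGM image.  Re-running
    with identical inputs overwrites the same files with identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        parameters=parameters or {},
        created=datetime.now(timezone.utc).isoformat(),
    )

    if isinstance(result, Trajectory):
        n_times, n_agents = result.group_sizes.shape
        table = pd.DataFrame(
            {
                "t": np.repeat(np.arange(n_times), n_agents),
                "agent": np.tile(np.arange(1, n_agents + 1), n_times),
                "group_size": result.group_sizes.ravel(),
            }
        )
        _write_csv(table, out_dir / "trajectory.csv")
        manifest.artifacts.append("trajectory.csv")
        write_feeling_matrix(result.final, out_dir / "final_matrix.csv")
        manifest.artifacts.append("final_matrix.csv")
        manifest.artifacts += _write_edge_lists(result.final, out_dir)
        outcome = classify_outcome(result.final)
        (out_dir / "outcome.json").write_text(
            json.dumps(outcome.to_record(result.final), indent=2, sort_keys=True)
            + "\n",
            encoding="utf-8",
        )
        manifest.artifacts.append("outcome.json")
        manifest.terminal_status = result.terminal_status
    elif isinstance(result, SweepResult):
        if len(result.table) == 0:
            warnings.warn("empty sweep grid: no artifacts written", stacklevel=2)
        else:
            _write_csv(result.table, out_dir / "sweep.csv")
            manifest.artifacts.append("sweep.csv")
        manifest.parameters.setdefault("seed", result.seed)
        manifest.parameters.setdefault("replicates", result.replicates)
        manifest.parameters.update(result.metadata)
    elif isinstance(result, CheckerboardResult):
        np.savetxt(
            out_dir / "checkerboard.csv",
            result.codes,
            fmt="%d",
            delimiter=",",
            newline="\n",
        )
        manifest.artifacts.append("checkerboard.csv")
        write_pgm(result.codes, out_dir / "checkerboard.pgm")
        manifest.artifacts.append("checkerboard.pgm")
        manifest.parameters.setdefault("base_seed", result.base_seed)
        manifest.parameters.setdefault("p_base", result.p_base)
        manifest.parameters.update(result.metadata)
    else:
        raise TypeError(f"cannot write outputs for {type(result).__name__}")

    manifest.write(out_dir / "manifest.json")
    return manifest
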