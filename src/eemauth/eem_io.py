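"""Containers and plain-text I/O for excitation-emission matrix (EEM) data.

An EEM cube is a three-way array: samples (mode 1) x excitation wavelengths
(mode 2) x emission wavelengths (mode 3).  On disk a cube is a CSV manifest
``sample_id,file,label`` plus one delimited matrix file per sample whose
first row is the emission axis and first column the excitation axis.  The
delimiter (comma or tab) is auto-detected.  Wavelengths are written with two
decimals so that sub-nanometre grids survive a round trip.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthAxis",
    "EEMSample",
    "EEMCube",
    "read_cube",
    "write_cube",
    "write_matrix_csv",
    "write_report_json",
]

_AXIS_TOL = 1e-9


class EEMError(ValueError):
    """Base class for EEM container and parsing errors."""


class AxisMismatchError(EEMError):
    """Raised when samples in one cube do not share identical axes."""


@dataclass(frozen=True)
class WavelengthAxis:
    """A strictly increasing wavelength grid in nm.

    Acquisition grids are uniformly spaced; preprocessed axes may carry a
    gap where an excitation band was removed, so uniformity is reported
    (`is_uniform`) but not required.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise EEMError("wavelength axis must be a non-empty 1-D array")
        if np.any(vals < 200.0) or np.any(vals > 800.0):
            raise EEMError("wavelengths must lie within [200, 800] nm")
        if vals.size > 1 and np.any(np.diff(vals) <= 0):
            raise EEMError("wavelength axis must be strictly increasing")

    @property
    def step(self) -> float:
        """Smallest consecutive spacing (the acquisition step), nm."""
        v = self.values
        return float(np.min(np.diff(v))) if v.size > 1 else 0.0

    @property
    def is_uniform(self) -> bool:
        v = self.values
        if v.size < 2:
            return True
        d = np.diff(v)
        return bool(np.all(np.abs(d - d[0]) < _AXIS_TOL))

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with ndarray field
        return hash((self.values.shape, self.values.tobytes()))


@dataclass
class EEMSample:
    """One sample's J x K fluorescence landscape with its axes."""

    sample_id: str
    matrix: np.ndarray
    ex_axis: WavelengthAxis
    em_axis: WavelengthAxis
    label: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ex_axis), len(self.em_axis)):
            raise EEMError(
                f"sample {self.sample_id!r}: matrix shape {self.matrix.shape} does not "
                f"match axes ({len(self.ex_axis)}, {len(self.em_axis)})"
            )


@dataclass
class EEMCube:
    """I x J x K intensity cube with shared axes, sample ids and labels.

    ``data[i, j, k]`` is the intensity of sample ``i`` at excitation
    ``ex.values[j]`` and emission ``em.values[k]``.
    """

    data: np.ndarray
    ex: WavelengthAxis
    em: WavelengthAxis
    sample_ids: list[str] = field(default_factory=list)
    labels: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise EEMError("cube data must be a 3-way array (I, J, K)")
        i, j, k = self.data.shape
        if i < 1:
            raise EEMError("cube must contain at least one sample")
        if j != len(self.ex) or k != len(self.em):
            raise EEMError(
                f"cube shape {self.data.shape} does not match axes "
                f"({len(self.ex)}, {len(self.em)})"
            )
        if not self.sample_ids:
            self.sample_ids = [f"sample{n:03d}" for n in range(i)]
        if len(self.sample_ids) != i:
            raise EEMError("sample_ids length must equal number of samples")
        if self.labels is not None and len(self.labels) != i:
            raise EEMError("labels length must equal number of samples")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def sample(self, i: int) -> EEMSample:
        lab = self.labels[i] if self.labels is not None else None
        return EEMSample(self.sample_ids[i], self.data[i], self.ex, self.em, lab)

    def with_data(self, data: np.ndarray) -> "EEMCube":
        """Copy of the cube with replaced intensities (same axes/metadata)."""
        return replace(self, data=np.asarray(data, dtype=float))

    def subset(self, idx: np.ndarray | list[int]) -> "EEMCube":
        """Cube restricted to the given sample positions (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        labels = [self.labels[i] for i in idx] if self.labels is not None else None
        return EEMCube(
            self.data[idx],
            self.ex,
            self.em,
            [self.sample_ids[i] for i in idx],
            labels,
        )

    def label_vector(self, positive: str) -> np.ndarray:
        """0/1 vector with 1 for samples whose label equals ``positive``."""
        if self.labels is None:
            raise EEMError("cube carries no labels")
        return np.array([1 if l == positive else 0 for l in self.labels], dtype=int)


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def _parse_matrix_file(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse one matrix file -> (ex values, em values, J x K intensities)."""
    text = path.read_text().strip().splitlines()
    if len(text) < 2:
        raise EEMError(f"{path}: matrix file needs a header row and at least one data row")
    delim = _sniff_delimiter(text[0])
    header = text[0].split(delim)
    try:
        em = np.array([float(x) for x in header[1:]], dtype=float)
    except ValueError as exc:
        raise EEMError(f"{path}: non-numeric emission wavelength in header: {exc}") from exc
    ex = np.empty(len(text) - 1)
    body = np.empty((len(text) - 1, em.size))
    for r, line in enumerate(text[1:], start=1):
        cells = line.split(delim)
        if len(cells) != em.size + 1:
            raise EEMError(f"{path}: row {r} has {len(cells)} cells, expected {em.size + 1}")
        for c, cell in enumerate(cells):
            try:
                v = float(cell)
            except ValueError as exc:
                raise EEMError(f"{path}: non-numeric cell at row {r}, column {c}") from exc
            if c == 0:
                ex[r - 1] = v
            else:
                body[r - 1, c - 1] = v
    return ex, em, body


def read_cube(manifest_path: str | Path) -> EEMCube:
    """Read an EEM cube from a manifest CSV.

    The manifest must have columns ``sample_id,file,label`` (label may be
    empty); ``file`` paths are resolved relative to the manifest.  All
    samples must share bit-identical wavelength axes.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise EEMError(f"{manifest_path}: empty manifest")
    for col in ("sample_id", "file"):
        if col not in rows[0]:
            raise EEMError(f"{manifest_path}: manifest missing column {col!r}")

    ids: list[str] = []
    labels: list[str | None] = []
    mats: list[np.ndarray] = []
    ex_ref: np.ndarray | None = None
    em_ref: np.ndarray | None = None
    for row in rows:
        sid = row["sample_id"]
        ex, em, mat = _parse_matrix_file(root / row["file"])
        if ex_ref is None:
            ex_ref, em_ref = ex, em
        elif not (np.array_equal(ex, ex_ref) and np.array_equal(em, em_ref)):
            raise AxisMismatchError(
                f"sample {sid!r} ({row['file']}) has wavelength axes that differ "
                "from the first sample"
            )
        if not np.all(np.isfinite(mat)):
            raise EEMError(f"sample {sid!r}: non-finite intensities on read")
        ids.append(sid)
        labels.append(row.get("label") or None)
        mats.append(mat)

    has_labels = any(l is not None for l in labels)
    return EEMCube(
        np.stack(mats),
        WavelengthAxis(ex_ref),
        WavelengthAxis(em_ref),
        ids,
        labels if has_labels else None,
    )


_SAFE_ID = re.compile(r"[^A-Za-z0-9._-]")


def _safe_filename(sample_id: str) -> str:
    safe = _SAFE_ID.sub("_", sample_id)
    if not safe or safe in {".", ".."}:
        raise EEMError(f"sample_id {sample_id!r} cannot be sanitized to a file name")
    return safe + ".csv"


def write_cube(cube: EEMCube, out_dir: str | Path) -> Path:
    """Write one matrix CSV per sample plus a ``manifest.csv``; return its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = [_safe_filename(sid) for sid in cube.sample_ids]
    if len(set(names)) != len(names):
        raise EEMError("sanitized sample file names collide; make sample_ids distinct")
    em_header = "," + ",".join(f"{w:.2f}" for w in cube.em.values)
    for i, name in enumerate(names):
        lines = [em_header]
        for j, exw in enumerate(cube.ex.values):
            row = ",".join(repr(float(v)) for v in cube.data[i, j])
            lines.append(f"{exw:.2f},{row}")
        (out_dir / name).write_text("\n".join(lines) + "\n")
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "file", "label"])
        for i, name in enumerate(names):
            lab = cube.labels[i] if cube.labels is not None else ""
            w.writerow([cube.sample_ids[i], name, lab or ""])
    return manifest


def write_matrix_csv(
    path: str | Path,
    matrix: np.ndarray,
    row_labels: list | np.ndarray,
    col_labels: list | np.ndarray,
    corner: str = "",
) -> None:
    """Write a labelled 2-D matrix (loadings, scores, VIP maps) as CSV."""
    matrix = np.asarray(matrix)
    lines = [corner + "," + ",".join(str(c) for c in col_labels)]
    for r, row in zip(row_labels, matrix):
        lines.append(str(r) + "," + ",".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_report_json(path: str | Path, report: dict) -> None:
    """Serialize a diagnostics report to JSON (ndarray-safe)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")
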