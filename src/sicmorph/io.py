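"""Height-map file I/O and study manifests.

Three plain-text-friendly dialects are supported:

``ascii_matrix``
    Self-describing text format compatible with common SPM text exports:
    ``#``-prefixed header lines (``key: value``) followed by whitespace-
    separated height rows in nm.  Round-trips bit-for-bit.
``float_tiff``
    One 32-bit float grid per file, metadata in a JSON sidecar ``<name>.json``.
``csv``
    Bare CSV matrix of heights, metadata in the same JSON sidecar.

Sidecar / header keys: ``pitch_x_nm``, ``pitch_y_nm``, ``direction`` plus the
optional record keys ``t_prep_h``, ``specimen``, ``isolation``, ``complete``,
``id``.  A loader manifest (CSV) lists forward/backward file pairs per
measurement.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import (
    MeasurementRecord,
    MetadataError,
    ParseError,
    ScanPair,
    Topography,
    TopographyError,
)

DIALECTS = ("ascii_matrix", "float_tiff", "csv")

_SUFFIX_DIALECT = {
    ".asc": "ascii_matrix",
    ".txt": "ascii_matrix",
    ".tif": "float_tiff",
    ".tiff": "float_tiff",
    ".csv": "csv",
}


def infer_dialect(path) -> str:
    suffix = Path(path).suffix.lower()
    try:
        return _SUFFIX_DIALECT[suffix]
    except KeyError:
        raise MetadataError(f"cannot infer dialect from suffix {suffix!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _require_pitch(meta: dict, overrides: dict) -> tuple[float, float, str]:
    merged = dict(meta)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    try:
        px = float(merged["pitch_x_nm"])
        py = float(merged["pitch_y_nm"])
    except (KeyError, TypeError, ValueError):
        raise MetadataError("pitch_x_nm and pitch_y_nm are required metadata")
    direction = str(merged.get("direction", "forward"))
    return px, py, direction


def read_topography(
    path,
    dialect: str | None = None,
    *,
    pitch_x_nm: float | None = None,
    pitch_y_nm: float | None = None,
    direction: str | None = None,
) -> Topography:
    """Read a height map, returning a validated :class:`Topography` in nm.

    Metadata can be overridden (or supplied for files lacking it) through the
    keyword arguments.  Missing mandatory metadata raises
    :class:`~sicmorph.core.MetadataError`; unparseable numeric content raises
    :class:`~sicmorph.core.ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or infer_dialect(path)
    overrides = {
        "pitch_x_nm": pitch_x_nm,
        "pitch_y_nm": pitch_y_nm,
        "direction": direction,
    }
    if dialect == "ascii_matrix":
        meta, heights = _read_ascii_matrix(path)
    elif dialect == "float_tiff":
        heights = tifffile.imread(path).astype(float)
        meta = _read_sidecar(path)
    elif dialect == "csv":
        try:
            heights = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        meta = _read_sidecar(path)
    else:
        raise MetadataError(f"unsupported dialect {dialect!r}")
    px, py, dirn = _require_pitch(meta, overrides)
    return Topography(heights, pitch_x=px, pitch_y=py, direction=dirn)


def write_topography(t: Topography, path, dialect: str | None = None, metadata: dict | None = None) -> Path:
    """Write ``t`` so that :func:`read_topography` recovers equal content."""
    path = Path(path)
    dialect = dialect or infer_dialect(path)
    meta = {
        "pitch_x_nm": t.pitch_x,
        "pitch_y_nm": t.pitch_y,
        "direction": t.direction,
    }
    if metadata:
        meta.update(metadata)
    if dialect == "ascii_matrix":
        _write_ascii_matrix(t, path, meta)
    elif dialect == "float_tiff":
        tifffile.imwrite(path, t.heights.astype(np.float32))
        _write_sidecar(path, meta)
    elif dialect == "csv":
        np.savetxt(path, t.heights, delimiter=",", fmt="%.17g")
        _write_sidecar(path, meta)
    else:
        raise MetadataError(f"unsupported dialect {dialect!r}")
    return path


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return {}
    with open(sidecar) as fh:
        return json.load(fh)


def _write_sidecar(path: Path, meta: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _read_ascii_matrix(path: Path) -> tuple[dict, np.ndarray]:
    meta: dict = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                payload = stripped.lstrip("#").strip()
                if ":" in payload:
                    key, _, value = payload.partition(":")
                    meta[key.strip()] = value.strip()
            elif stripped:
                body_lines.append(stripped)
    if not body_lines:
        raise ParseError(f"{path}: no height rows found")
    try:
        heights = np.loadtxt(_io.StringIO("\n".join(body_lines)), ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return meta, heights


def _write_ascii_matrix(t: Topography, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        # %.17g preserves float64 values exactly through the round trip
        np.savetxt(fh, t.heights, fmt="%.17g")


# ---------------------------------------------------------------------------
# Manifests

MANIFEST_COLUMNS = (
    "id",
    "forward",
    "backward",
    "t_prep_h",
    "specimen",
    "isolation",
    "complete",
)


def write_manifest(rows: list[dict], path) -> Path:
    """Write a loader manifest (CSV) from dicts with :data:`MANIFEST_COLUMNS`."""
    frame = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    frame.to_csv(path, index=False)
    return Path(path)


def manifest_rows(path) -> list[dict]:
    """Parse a manifest CSV into per-measurement row dicts (no file I/O)."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise MetadataError(f"manifest is missing columns: {sorted(missing)}")
    return frame.to_dict(orient="records")


def load_record(row: dict, base_dir) -> MeasurementRecord:
    """Load one manifest row; paths are relative to ``base_dir``."""
    base_dir = Path(base_dir)
    fwd = read_topography(base_dir / str(row["forward"]), direction="forward")
    bwd = read_topography(base_dir / str(row["backward"]), direction="backward")
    return MeasurementRecord(
        id=str(row["id"]),
        pair=ScanPair(fwd, bwd),
        t_prep=float(row["t_prep_h"]),
        specimen=str(row["specimen"]),
        isolation=str(row["isolation"]),
        complete=bool(row["complete"]),
    )


def read_manifest(path) -> list[MeasurementRecord]:
    """Load every measurement listed in a manifest CSV.

    File paths in the manifest are taken relative to the manifest location.
    Errors while loading any record propagate; the pipeline layer loads
    row-by-row instead to isolate per-record failures.
    """
    path = Path(path)
    return [load_record(row, path.parent) for row in manifest_rows(path)]
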