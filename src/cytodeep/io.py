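"""Reading, writing and transforming cell x marker expression tables.

Mass-cytometry intensities arrive as non-negative event-by-marker matrices,
either as delimited text (CSV/TSV with a header row of marker names) or as
FCS 3.0/3.1 files.  The variance-stabilising transform used throughout the
field is ``asinh(x / cofactor)``; raw and transformed tables are kept
distinct via a flag so the transform cannot be applied twice.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel label for cells without a gated population.
UNASSIGNED = "unassigned"
#: Label for cells that no stable density cluster claims.
NOISE = "noise"

#: Tokens in a label file that map to :data:`UNASSIGNED`.
_UNASSIGNED_TOKENS = {"", "na", "nan", "none", "unassigned", "unknown"}

#: Default arcsinh cofactor; the community convention for CyTOF intensities.
DEFAULT_COFACTOR = 5.0


@dataclass(frozen=True)
class MarkerTable:
    """Cells x markers expression matrix with marker names and transform state."""

    values: np.ndarray
    marker_names: list[str]
    cell_ids: list[str]
    transformed: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D cells x markers matrix")
        if values.shape[1] != len(self.marker_names):
            raise ValueError(
                f"{values.shape[1]} columns but {len(self.marker_names)} marker names"
            )
        if values.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"{values.shape[0]} rows but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if not self.transformed and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative intensity {values[i, j]} at cell {self.cell_ids[i]!r}, "
                f"marker {self.marker_names[j]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: np.ndarray) -> "MarkerTable":
        """Row-subset preserving marker names and transform state."""
        indices = np.asarray(indices)
        return MarkerTable(
            values=self.values[indices],
            marker_names=list(self.marker_names),
            cell_ids=[self.cell_ids[i] for i in np.atleast_1d(indices)],
            transformed=self.transformed,
        )


@dataclass(frozen=True)
class LabelVector:
    """Per-cell categorical population labels with an UNASSIGNED sentinel."""

    labels: np.ndarray
    population_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        object.__setattr__(self, "labels", labels)
        known = set(self.population_names)
        if UNASSIGNED in known:
            raise ValueError("population names may not include the UNASSIGNED sentinel")
        bad = {l for l in labels if l != UNASSIGNED and l not in known}
        if bad:
            raise ValueError(f"unknown population label(s): {sorted(bad)}")
        if self.n_labeled > 0 and len(self.population_names) < 2:
            raise ValueError("at least 2 populations required when any cell is labeled")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNASSIGNED

    @property
    def n_labeled(self) -> int:
        return int(np.sum(self.labels != UNASSIGNED))

    @property
    def n_populations(self) -> int:
        return len(self.population_names)


def read_matrix(path: str | Path, format: str | None = None,
                transformed: bool = False) -> MarkerTable:
    """Read an expression matrix from CSV, TSV or FCS into a MarkerTable.

    ``format`` defaults to the file suffix.  FCS input follows the 3.0/3.1
    standard, taking $PnS (falling back to $PnN) as marker names.  Raw
    intensities must be non-negative; pass ``transformed=True`` for files
    already on the arcsinh scale (which may contain negative values).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in {"csv", "tsv", "fcs"}:
        raise ValueError(f"unsupported format {format!r}")
    if format == "fcs":
        names, values = _read_fcs(path)
    else:
        sep = "," if format == "csv" else "\t"
        try:
            frame = pd.read_csv(path, sep=sep)
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise ValueError(f"could not parse {path}: {exc}") from exc
        if frame.shape[0] == 0:
            raise ValueError(f"{path}: no cells (empty data section)")
        names = [str(c) for c in frame.columns]
        values = frame.to_numpy(dtype=float)
    if values.shape[0] == 0:
        raise ValueError(f"{path}: no cells (empty data section)")
    cell_ids = [f"cell_{i}" for i in range(values.shape[0])]
    return MarkerTable(values=values, marker_names=names, cell_ids=cell_ids,
                       transformed=transformed)


def arcsinh_transform(table: MarkerTable, cofactor: float = DEFAULT_COFACTOR) -> MarkerTable:
    """Apply the variance-stabilising transform x -> asinh(x / cofactor)."""
    if table.transformed:
        raise ValueError("table is already arcsinh-transformed")
    if not cofactor > 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return replace(table, values=np.arcsinh(table.values / cofactor), transformed=True)


def read_labels(path: str | Path, population_names: list[str] | None = None) -> LabelVector:
    """Read a one-column label file; blank/NA tokens become UNASSIGNED.

    Population names are inferred in first-appearance order unless supplied,
    in which case an unlisted label is an error.
    """
    tokens = Path(path).read_text().splitlines()
    labels = []
    seen: list[str] = []
    for tok in tokens:
        tok = tok.strip()
        if tok.lower() in _UNASSIGNED_TOKENS:
            labels.append(UNASSIGNED)
            continue
        labels.append(tok)
        if tok not in seen:
            seen.append(tok)
    if population_names is not None:
        unknown = [t for t in seen if t not in population_names]
        if unknown:
            raise ValueError(f"unknown population(s) in {path}: {unknown}")
    else:
        population_names = seen
    return LabelVector(labels=np.array(labels, dtype=object),
                       population_names=list(population_names))


def write_assignments(assignment, embedding, path: str | Path) -> None:
    """Write the final per-cell table: id, label, source, coordinates, Z index.

    Column order is fixed (cell_id, label, source, x, y, z); a 3-D embedding
    supplies its own z and the label-axis index moves to ``z_label``.
    """
    from .calibrate import ClusterAssignment  # local import to avoid cycle

    assert isinstance(assignment, ClusterAssignment)
    coords = np.asarray(embedding.coords, dtype=float)
    if coords.shape[0] != len(assignment.labels):
        raise ValueError(
            f"embedding covers {coords.shape[0]} cells but assignment has "
            f"{len(assignment.labels)}"
        )
    z_index = assignment.label_indices()
    data = {
        "cell_id": assignment.cell_ids,
        "label": assignment.labels,
        "source": assignment.source,
        "x": coords[:, 0] if coords.size else np.array([]),
        "y": coords[:, 1] if coords.size else np.array([]),
    }
    data["z"] = coords[:, 2] if coords.shape[1] >= 3 else z_index
    if coords.shape[1] >= 3:
        data["z_label"] = z_index
    pd.DataFrame(data).to_csv(path, index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Re-read a table produced by :func:`write_assignments`."""
    return pd.read_csv(path, dtype={"cell_id": str, "label": str, "source": str})


# ---------------------------------------------------------------------------
# Minimal FCS 3.0 / 3.1 reader (read-only; compensation keywords are ignored)
# ---------------------------------------------------------------------------

def _read_fcs(path: Path) -> tuple[list[str], np.ndarray]:
    blob = path.read_bytes()
    if len(blob) < 58 or blob[:3] != b"FCS":
        raise ValueError(f"{path}: not an FCS file")
    version = blob[:6].decode("ascii", "replace")
    if version not in {"FCS3.0", "FCS3.1"}:
        raise ValueError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        return int(blob[lo:hi].decode("ascii").strip() or 0)

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    text = blob[text_begin:text_end + 1].decode("latin-1")
    if not text:
        raise ValueError(f"{path}: empty TEXT segment")
    delim = text[0]
    parts = text[1:].rstrip(delim).split(delim)
    kw = {parts[i].strip().upper(): parts[i + 1]
          for i in range(0, len(parts) - 1, 2)}

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise ValueError(f"{path}: missing required FCS keyword {exc}") from exc
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if n_tot == 0:
        raise ValueError(f"{path}: no cells ($TOT=0)")

    little = byteord.startswith("1")
    order = "<" if little else ">"
    if datatype == "F":
        fmt, width = "f", 4
    elif datatype == "D":
        fmt, width = "d", 8
    elif datatype == "I":
        widths = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if widths != {32}:
            raise ValueError(f"{path}: only uniform 32-bit integer data supported")
        fmt, width = "I", 4
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_values = n_par * n_tot
    raw = blob[data_begin:data_begin + n_values * width]
    if len(raw) < n_values * width:
        raise ValueError(f"{path}: DATA segment truncated")
    values = np.array(struct.unpack(f"{order}{n_values}{fmt}", raw), dtype=float)
    values = values.reshape(n_tot, n_par)

    names = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}"
        names.append(name.strip())
    # resolve duplicate stains deterministically
    seen: dict[str, int] = {}
    unique = []
    for name in names:
        if name in seen:
            seen[name] += 1
            unique.append(f"{name}_{seen[name]}")
        else:
            seen[name] = 0
            unique.append(name)
    return unique, values
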