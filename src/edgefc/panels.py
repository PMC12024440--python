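"""Reading, validation, and z-scoring of parcellated component time series.

A *panel* is one subject's components-by-timepoints matrix.  Components are
node-level signals (e.g. independent-component time courses); downstream
modules require panels to be z-scored row-wise before edge construction.

The z-score uses the population variance convention (divide by T, not T-1),
so that the time average of the product of two z-scored rows equals their
Pearson correlation exactly.  That identity is relied on throughout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesPanel",
    "NetworkAtlas",
    "SubjectTable",
    "read_panel",
    "write_panel",
    "zscore_panel",
    "read_atlas",
    "read_subjects",
]

_MEAN_TOL = 1e-10


@dataclasses.dataclass
class TimeSeriesPanel:
    """One subject's component x time matrix.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    values : ndarray of shape (n_components, n_timepoints)
        Signal matrix; arbitrary units before z-scoring, dimensionless after.
    component_ids : list of str
        Ordered component labels, one per row.
    zscored : bool
        Whether rows have been normalized to mean 0 / population SD 1.
    """

    subject_id: str
    values: np.ndarray
    component_ids: list[str]
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("panel values must be a 2-D matrix")
        n, t = self.values.shape
        if n < 3:
            raise ValueError(f"panel needs at least 3 components, got {n}")
        if t < 2:
            raise ValueError(f"panel needs at least 2 timepoints, got {t}")
        if len(self.component_ids) != n:
            raise ValueError(
                f"{len(self.component_ids)} component ids for {n} rows"
            )
        if len(set(self.component_ids)) != n:
            raise ValueError("component ids must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at component {self.component_ids[bad[0]]!r}, "
                f"timepoint {bad[1]}"
            )
        if self.zscored:
            mu = self.values.mean(axis=1)
            sd = self.values.std(axis=1, ddof=0)
            if np.abs(mu).max() > _MEAN_TOL or np.abs(sd - 1.0).max() > 1e-8:
                raise ValueError("zscored flag set but rows are not normalized")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def zscore_panel(panel: TimeSeriesPanel) -> TimeSeriesPanel:
    """Return a new panel with each row normalized to mean 0, SD 1.

    Uses the population standard deviation (``ddof=0``).  Raises
    ``ValueError`` if the panel is already z-scored or any row is constant.
    """
    if panel.zscored:
        raise ValueError("panel is already z-scored")
    mu = panel.values.mean(axis=1, keepdims=True)
    sd = panel.values.std(axis=1, ddof=0, keepdims=True)
    zero = np.flatnonzero(sd[:, 0] == 0.0)
    if zero.size:
        names = ", ".join(panel.component_ids[i] for i in zero[:5])
        raise ValueError(f"zero variance (constant) component(s): {names}")
    z = (panel.values - mu) / sd
    return TimeSeriesPanel(
        subject_id=panel.subject_id,
        values=z,
        component_ids=list(panel.component_ids),
        zscored=True,
    )


def _parse_matrix(path: Path, delimiter: str) -> tuple[np.ndarray, list[str] | None]:
    """Parse a delimited numeric matrix, returning (matrix, header-or-None).

    Errors name the offending cell by 1-based row/column of the file.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            rows.append(line.split(delimiter))
    if not rows:
        raise ValueError(f"{path}: empty file")
    width = len(rows[0])
    for r, cells in enumerate(rows, start=1):
        if len(cells) != width:
            raise ValueError(
                f"{path}: row {r} has {len(cells)} cells, expected {width}"
            )

    def _is_number(s: str) -> bool:
        try:
            float(s)
        except ValueError:
            return False
        return True

    header: list[str] | None = None
    body = rows
    if not all(_is_number(c) for c in rows[0]):
        header = [c.strip() for c in rows[0]]
        body = rows[1:]
        if not body:
            raise ValueError(f"{path}: header but no data rows")

    mat = np.empty((len(body), width), dtype=np.float64)
    offset = 2 if header is not None else 1
    for r, cells in enumerate(body):
        for c, cell in enumerate(cells):
            s = cell.strip()
            if s == "" or s.upper() in ("NA", "NAN", "NULL"):
                raise ValueError(
                    f"{path}: missing value at row {r + offset}, column {c + 1}"
                )
            try:
                mat[r, c] = float(s)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {r + offset}, "
                    f"column {c + 1}"
                ) from None
    if not np.all(np.isfinite(mat)):
        r, c = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"{path}: non-finite value at row {int(r) + offset}, column {int(c) + 1}"
        )
    return mat, header


def read_panel(
    path: str | Path,
    delimiter: str = "\t",
    orientation: str = "components-in-rows",
    subject_id: str | None = None,
) -> TimeSeriesPanel:
    """Read a delimited numeric matrix as an un-z-scored panel.

    ``orientation`` declares the layout of the file and is never guessed:
    ``"components-in-rows"`` (default) or ``"components-in-columns"``.  An
    optional non-numeric first line is treated as a header of component ids
    (only meaningful for the columns orientation); otherwise ordinal labels
    ``C1..CN`` are generated.
    """
    path = Path(path)
    if orientation not in ("components-in-rows", "components-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    mat, header = _parse_matrix(path, delimiter)
    component_ids: list[str] | None = None
    if orientation == "components-in-columns":
        mat = mat.T
        if header is not None:
            component_ids = header
    if component_ids is None:
        component_ids = [f"C{i + 1}" for i in range(mat.shape[0])]
    return TimeSeriesPanel(
        subject_id=subject_id if subject_id is not None else path.stem,
        values=mat,
        component_ids=component_ids,
        zscored=False,
    )


def write_panel(
    panel: TimeSeriesPanel,
    path: str | Path,
    delimiter: str = "\t",
    fmt: str = "%.17g",
) -> None:
    """Write a panel components-in-rows, no header (round-trips read_panel)."""
    np.savetxt(path, panel.values, delimiter=delimiter, fmt=fmt)


@dataclasses.dataclass
class NetworkAtlas:
    """Mapping of component labels to named networks."""

    mapping: dict[str, str]
    network_order: list[str]

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(self.mapping.values()))
        for name in self.network_order:
            if name not in seen:
                raise ValueError(f"network {name!r} has no components")
        extra = [n for n in seen if n not in self.network_order]
        if extra:
            raise ValueError(f"networks missing from network_order: {extra}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "NetworkAtlas":
        order = list(dict.fromkeys(mapping.values()))
        return cls(mapping=dict(mapping), network_order=order)

    def networks_for(self, component_ids: Sequence[str]) -> list[str]:
        missing = [c for c in component_ids if c not in self.mapping]
        if missing:
            raise KeyError(
                f"components missing from atlas: {', '.join(missing[:5])}"
            )
        return [self.mapping[c] for c in component_ids]

    def members(self, network: str, component_ids: Sequence[str]) -> list[int]:
        idx = [
            i for i, c in enumerate(component_ids) if self.mapping.get(c) == network
        ]
        if not idx:
            raise ValueError(f"network {network!r} has no member components")
        return idx


def read_atlas(path: str | Path, delimiter: str = "\t") -> NetworkAtlas:
    """Read a two-column (component_id, network) table with header."""
    df = pd.read_csv(path, sep=delimiter)
    required = {"component_id", "network"}
    if not required.issubset(df.columns):
        raise ValueError(f"atlas must have columns {sorted(required)}")
    if df["component_id"].duplicated().any():
        dup = df.loc[df["component_id"].duplicated(), "component_id"].iloc[0]
        raise ValueError(f"duplicate component_id in atlas: {dup!r}")
    mapping = dict(
        zip(df["component_id"].astype(str), df["network"].astype(str))
    )
    return NetworkAtlas.from_mapping(mapping)


@dataclasses.dataclass
class SubjectTable:
    """Subject table with exactly two group labels plus covariate columns."""

    frame: pd.DataFrame  # columns: subject_id, group, covariates...

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise ValueError(f"subject table missing column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id: {dup!r}")
        groups = sorted(df["group"].astype(str).unique())
        if len(groups) != 2:
            raise ValueError(
                f"expected exactly 2 group labels, got {len(groups)}: {groups}"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.frame["subject_id"].astype(str).tolist()

    @property
    def groups(self) -> list[str]:
        """The two group labels, sorted; index 0 is 'group 1' in statistics."""
        return sorted(self.frame["group"].astype(str).unique())

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("subject_id", "group")]

    def covariates(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"covariate columns not found: {missing}")
        arr = self.frame[list(names)].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValueError("covariate columns contain missing/non-finite values")
        return arr

    def group_mask(self) -> np.ndarray:
        """Boolean mask: True for the second (sorted) group label."""
        return (self.frame["group"].astype(str) == self.groups[1]).to_numpy()


def read_subjects(path: str | Path, delimiter: str = "\t") -> SubjectTable:
    """Read a subject/covariate table (header: subject_id, group, ...)."""
    df = pd.read_csv(path, sep=delimiter)
    df["subject_id"] = df["subject_id"].astype(str)
    return SubjectTable(frame=df)
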