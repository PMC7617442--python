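"""Domain types and I/O for household-level mixed data and areal adjacency.

The model operates on household observations ``y_ijk`` (household *j* in
area *i*, manifest variable *k*), where each variable is declared either
continuous or dichotomous (0/1), plus a neighbour structure over the areas
used by the spatially structured priors.

Conventions
-----------
* Areas are re-indexed densely ``0..N-1`` in first-appearance order; the
  mapping to the original labels is retained in ``MixedDataset.area_labels``.
* Continuous variables are centered by their global (all-household) mean
  during :func:`preprocess`; an optional log transform precedes centering.
* Missing values are rejected outright — no imputation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "VariableMeta",
    "MixedDataset",
    "AdjacencyStructure",
    "FormatError",
    "ValidationError",
    "read_households",
    "write_households",
    "read_variable_meta",
    "read_adjacency_gal",
    "write_adjacency_gal",
    "read_adjacency_json",
    "preprocess",
]


class FormatError(ValueError):
    """Malformed input file (missing columns, bad GAL structure, ...)."""


class ValidationError(ValueError):
    """Well-formed input violating a model invariant (NA cells, non-0/1 ...)."""


@dataclass(frozen=True)
class VariableMeta:
    """Declaration of one manifest variable.

    Parameters
    ----------
    name
        Column label in the household table.
    kind
        ``"continuous"`` or ``"dichotomous"``.
    log_transform
        Apply ``log`` before centering (continuous variables only); requires
        strictly positive raw values.
    """

    name: str
    kind: str
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "dichotomous"):
            raise ValidationError(f"unknown variable kind: {self.kind!r}")
        if self.log_transform and self.kind != "continuous":
            raise ValidationError(
                f"log_transform declared for dichotomous variable {self.name!r}"
            )

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"


@dataclass
class MixedDataset:
    """Household-level observations with area membership.

    Attributes
    ----------
    area_ids : ndarray of int, shape (H,)
        Dense area index in ``0..N-1`` for each household row.
    y : ndarray of float, shape (H, p)
        Observation table; dichotomous columns hold 0/1.
    meta : list of VariableMeta
        Per-variable declarations, in column order.
    area_labels : list
        Original area label for each dense index.
    preprocessed : bool
        Whether continuous columns have been (log-)centered.
    centering : dict
        Per-variable global means subtracted (empty until preprocessing).
    """

    area_ids: np.ndarray
    y: np.ndarray
    meta: list[VariableMeta]
    area_labels: list = field(default_factory=list)
    preprocessed: bool = False
    centering: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.area_ids = np.asarray(self.area_ids, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.ndim != 2 or self.y.shape[0] != self.area_ids.shape[0]:
            raise ValidationError("y must be (households, variables) matching area_ids")
        if len(self.meta) != self.y.shape[1]:
            raise ValidationError("meta length must equal number of columns of y")
        if not self.area_labels:
            self.area_labels = list(range(self.n_areas))
        self.validate()

    # -- derived sizes -----------------------------------------------------
    @property
    def n_households(self) -> int:
        return self.y.shape[0]

    @property
    def n_variables(self) -> int:
        return self.y.shape[1]

    @property
    def n_areas(self) -> int:
        return int(self.area_ids.max()) + 1 if self.area_ids.size else 0

    @property
    def households_per_area(self) -> np.ndarray:
        """n_i: household count per area, length N."""
        return np.bincount(self.area_ids, minlength=self.n_areas)

    @property
    def is_dichotomous(self) -> np.ndarray:
        return np.array([not m.is_continuous for m in self.meta])

    @property
    def is_continuous(self) -> np.ndarray:
        return ~self.is_dichotomous

    def validate(self) -> None:
        if np.isnan(self.y).any():
            rows = np.unique(np.nonzero(np.isnan(self.y))[0])
            raise ValidationError(
                f"missing values in rows {rows[:20].tolist()}; only complete "
                "records are accepted (no imputation)"
            )
        if self.area_ids.size and (self.area_ids.min() < 0):
            raise ValidationError("negative area index")
        if self.area_ids.size:
            present = np.unique(self.area_ids)
            if present.size != self.n_areas:
                raise ValidationError("area indices must be dense 0..N-1")
        for k, m in enumerate(self.meta):
            col = self.y[:, k]
            if not m.is_continuous:
                bad = ~np.isin(col, (0.0, 1.0))
                if bad.any():
                    rows = np.nonzero(bad)[0]
                    raise ValidationError(
                        f"dichotomous variable {m.name!r} has non-0/1 values "
                        f"in rows {rows[:20].tolist()}"
                    )


@dataclass
class AdjacencyStructure:
    """0-1 areal adjacency: neighbour lists, W, and degrees.

    ``W`` is a symmetric sparse 0/1 matrix with zero diagonal; ``degrees``
    holds the row sums d_i (number of neighbours of area i).
    """

    neighbours: list[list[int]]
    area_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.neighbours)
        for i, nbrs in enumerate(self.neighbours):
            for j in nbrs:
                if j < 0 or j >= n:
                    raise FormatError(f"neighbour id {j} of area {i} out of range")
                if j == i:
                    raise FormatError(f"area {i} listed as its own neighbour")
        # symmetrize by union, warning if input was asymmetric
        sets = [set(nbrs) for nbrs in self.neighbours]
        asym = False
        for i, s in enumerate(sets):
            for j in s:
                if i not in sets[j]:
                    asym = True
                    sets[j].add(i)
        if asym:
            warnings.warn(
                "asymmetric neighbour list symmetrized by union", stacklevel=2
            )
        self.neighbours = [sorted(s) for s in sets]
        if not self.area_labels:
            self.area_labels = list(range(n))

    @property
    def n_areas(self) -> int:
        return len(self.neighbours)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nbrs) for nbrs in self.neighbours], dtype=np.int64)

    @property
    def W(self) -> csr_matrix:
        """Symmetric sparse 0-1 adjacency matrix."""
        rows = [i for i, nbrs in enumerate(self.neighbours) for _ in nbrs]
        cols = [j for nbrs in self.neighbours for j in nbrs]
        data = np.ones(len(rows))
        return csr_matrix((data, (rows, cols)), shape=(self.n_areas, self.n_areas))

    def has_islands(self) -> bool:
        return bool((self.degrees == 0).any())

    def is_connected(self) -> bool:
        if self.n_areas == 0:
            return True
        ncomp, _ = connected_components(self.W, directed=False)
        return ncomp == 1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_variable_meta(path) -> list[VariableMeta]:
    """Read the metadata JSON: a list of {name, kind, log_transform} objects."""
    with open(path) as fh:
        entries = json.load(fh)
    return [
        VariableMeta(
            name=e["name"], kind=e["kind"], log_transform=e.get("log_transform", False)
        )
        for e in entries
    ]


def read_households(path, meta: list[VariableMeta]) -> MixedDataset:
    """Read a household CSV (columns: ``area_id`` + one per declared variable).

    Areas are re-indexed densely in first-appearance order; original labels
    are kept in ``area_labels``. Dichotomous columns must contain only 0/1
    and no cell may be missing.
    """
    df = pd.read_csv(path)
    if "area_id" not in df.columns:
        raise FormatError("household CSV must contain an 'area_id' column")
    missing = [m.name for m in meta if m.name not in df.columns]
    if missing:
        raise FormatError(f"household CSV missing declared columns: {missing}")
    if df["area_id"].isna().any():
        raise ValidationError("missing area_id values")
    labels, codes = np.unique(df["area_id"].to_numpy(), return_inverse=True)
    # np.unique sorts; re-map to first-appearance order
    seen = np.full(labels.size, -1, dtype=np.int64)
    order = []
    for c in codes:
        if seen[c] < 0:
            seen[c] = len(order)
            order.append(c)
    dense = seen[codes]
    area_labels = [labels[c] for c in order]
    y = df[[m.name for m in meta]].to_numpy(dtype=np.float64)
    return MixedDataset(
        area_ids=dense, y=y, meta=list(meta), area_labels=list(area_labels)
    )


def write_households(data: MixedDataset, path) -> None:
    """Write a dataset back to the household CSV format (original labels)."""
    df = pd.DataFrame(data.y, columns=[m.name for m in data.meta])
    df.insert(0, "area_id", [data.area_labels[i] for i in data.area_ids])
    # full float precision so continuous columns round-trip to ~1e-17 relative
    df.to_csv(path, index=False, float_format="%.17g")


def read_adjacency_gal(path) -> AdjacencyStructure:
    """Read a GAL neighbour-list file.

    Format: a header line whose last token is the number of areas, then for
    each area a line ``<id> <degree>`` followed by a line of neighbour ids.
    Ids may be arbitrary labels; they are densified in file order.
    Asymmetric lists are symmetrized by union with a warning.
    """
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_by_line:
        raise FormatError("empty GAL file")
    header = tokens_by_line[0]
    try:
        n = int(header[-1]) if len(header) == 1 else int(header[1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"bad GAL header: {' '.join(header)}") from exc
    body = tokens_by_line[1:]
    ids: list[str] = []
    raw: dict[str, list[str]] = {}
    pos = 0
    for _ in range(n):
        if pos >= len(body):
            raise FormatError("GAL file truncated")
        head = body[pos]
        if len(head) != 2:
            raise FormatError(f"expected '<id> <degree>' line, got: {' '.join(head)}")
        area, deg = head[0], int(head[1])
        pos += 1
        if deg > 0:
            if pos >= len(body):
                raise FormatError(f"GAL file truncated in neighbours of {area}")
            nbrs = body[pos]
            if len(nbrs) != deg:
                raise FormatError(
                    f"area {area}: declared degree {deg} but "
                    f"{len(nbrs)} neighbours listed"
                )
            pos += 1
        else:
            nbrs = []
        ids.append(area)
        raw[area] = nbrs
    index = {a: i for i, a in enumerate(ids)}
    neighbours = []
    for a in ids:
        out = []
        for b in raw[a]:
            if b not in index:
                raise FormatError(f"area {a} lists unknown neighbour {b}")
            out.append(index[b])
        neighbours.append(out)
    return AdjacencyStructure(neighbours=neighbours, area_labels=list(ids))


def write_adjacency_gal(adj: AdjacencyStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{adj.n_areas}\n")
        for i, nbrs in enumerate(adj.neighbours):
            fh.write(f"{adj.area_labels[i]} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(str(adj.area_labels[j]) for j in nbrs) + "\n")


def read_adjacency_json(path) -> AdjacencyStructure:
    """JSON alternative: {"neighbours": [[...], ...], "labels": [...]}."""
    with open(path) as fh:
        obj = json.load(fh)
    return AdjacencyStructure(
        neighbours=[list(map(int, nbrs)) for nbrs in obj["neighbours"]],
        area_labels=list(obj.get("labels", [])),
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(data: MixedDataset) -> MixedDataset:
    """(Log-)center continuous columns by their global mean.

    Dichotomous columns are untouched. The subtracted means (and whether a
    log was applied) are recorded in ``centering`` for reporting. Idempotent:
    preprocessing an already-preprocessed dataset subtracts means that are
    zero to floating precision.
    """
    y = data.y.copy()
    centering: dict = dict(data.centering)
    for k, m in enumerate(data.meta):
        if not m.is_continuous:
            continue
        col = y[:, k]
        logged = False
        if m.log_transform and not data.preprocessed:
            if (col <= 0).any():
                raise ValidationError(
                    f"log transform of {m.name!r} requires positive values"
                )
            col = np.log(col)
            logged = True
        mu = float(col.mean())
        y[:, k] = col - mu
        prev = centering.get(m.name, {"mean": 0.0, "logged": False})
        centering[m.name] = {
            "mean": prev["mean"] + mu,
            "logged": prev["logged"] or logged,
        }
    out = replace(data, y=y, preprocessed=True, centering=centering)
    return out
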