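"""Domain types for odor-mixture datasets and their CSV on-disk format.

An electronic nose represents one odor sample as a vector of ``m`` sensor
responses.  A sample may carry a *component-set* label (which pure compounds
are present, e.g. ``"ME"`` for a methanol/ethanol mixture) and/or the true
concentration of every component in ppm.  The CSV schema is::

    sample_id,label,c_M,c_E,c_A,s_1,...,s_m

with ``label`` and the ``c_<name>`` columns optional.  Empty cells mean the
label or the concentration vector is absent for that row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentUniverse",
    "ComponentSet",
    "OdorSample",
    "Dataset",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
]


class DatasetFormatError(ValueError):
    """Raised when a dataset file violates the CSV schema."""


@dataclass(frozen=True)
class ComponentUniverse:
    """Ordered set of pure-compound identifiers.

    The ordering is fixed and defines the coordinate order of every
    concentration vector in a dataset.
    """

    names: tuple[str, ...]

    def __init__(self, names: Iterable[str]):
        names = tuple(names)
        if len(names) == 0:
            raise ValueError("universe must contain at least one component")
        if any(not n for n in names):
            raise ValueError("component names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError(f"component names must be unique, got {names}")
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown component {name!r}; universe is {self.names}")

    def subset(self, members: Iterable[str]) -> "ComponentSet":
        """Canonical component set from members given in any order."""
        return ComponentSet(self, members)

    def set_from_label(self, label: str) -> "ComponentSet":
        """Parse a concatenated label string such as ``"EM"`` -> set {M, E}.

        Component names are matched greedily, longest first, so multi-letter
        names are supported as long as no name is a prefix ambiguity.
        """
        remaining = label
        members: list[str] = []
        by_len = sorted(self.names, key=len, reverse=True)
        while remaining:
            for name in by_len:
                if remaining.startswith(name):
                    members.append(name)
                    remaining = remaining[len(name):]
                    break
            else:
                raise KeyError(
                    f"label {label!r} contains unknown component near {remaining!r}"
                )
        return ComponentSet(self, members)

    def all_subsets(self) -> list["ComponentSet"]:
        """All 2^n - 1 non-empty component sets, in canonical label order by size."""
        out = []
        for k in range(1, self.n + 1):
            for combo in itertools.combinations(self.names, k):
                out.append(ComponentSet(self, combo))
        return out

    def set_from_concentrations(self, c: Sequence[float]) -> "ComponentSet":
        members = [name for name, v in zip(self.names, c) if v > 0]
        return ComponentSet(self, members)


@dataclass(frozen=True)
class ComponentSet:
    """Non-empty subset of a universe, with a canonical concatenated label.

    The label concatenates member names in universe order, so ``{E, M}`` and
    ``{M, E}`` both canonicalize to ``"ME"`` for the universe (M, E, A).
    """

    universe: ComponentUniverse
    members: tuple[str, ...]

    def __init__(self, universe: ComponentUniverse, members: Iterable[str]):
        mem = set(members)
        if not mem:
            raise ValueError("component set must be non-empty")
        for name in mem:
            if name not in universe.names:
                raise KeyError(f"unknown component {name!r}; universe is {universe.names}")
        ordered = tuple(n for n in universe.names if n in mem)
        object.__setattr__(self, "universe", universe)
        object.__setattr__(self, "members", ordered)

    @property
    def label(self) -> str:
        return "".join(self.members)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(self.universe.index(n) for n in self.members)

    def __contains__(self, name: str) -> bool:
        return name in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        return self.label

    # label order gives the deterministic tie-break used by the classifiers
    def __lt__(self, other: "ComponentSet") -> bool:
        return self.label < other.label


@dataclass
class OdorSample:
    """One odor measurement: sensor features plus optional label / truth."""

    sample_id: str
    features: np.ndarray
    label: ComponentSet | None = None
    concentrations: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise ValueError("features must be a 1-d vector")
        if self.concentrations is not None:
            self.concentrations = np.asarray(self.concentrations, dtype=float)
            if np.any(self.concentrations < 0):
                raise ValueError(
                    f"sample {self.sample_id!r}: negative concentration"
                )
        if self.label is not None and self.concentrations is not None:
            implied = {
                name
                for name, c in zip(self.label.universe.names, self.concentrations)
                if c > 0
            }
            if implied != set(self.label.members):
                raise ValueError(
                    f"sample {self.sample_id!r}: label {self.label.label!r} does not "
                    f"match positive concentrations {sorted(implied)}"
                )

    @property
    def m(self) -> int:
        return self.features.shape[0]


@dataclass
class Dataset:
    """A collection of samples sharing one universe and feature count."""

    universe: ComponentUniverse
    samples: list[OdorSample] = field(default_factory=list)

    def __post_init__(self):
        ms = {s.m for s in self.samples}
        if len(ms) > 1:
            raise ValueError(f"samples disagree on feature count: {sorted(ms)}")
        for s in self.samples:
            if s.concentrations is not None and s.concentrations.shape[0] != self.universe.n:
                raise ValueError(
                    f"sample {s.sample_id!r}: concentration vector length "
                    f"{s.concentrations.shape[0]} != universe size {self.universe.n}"
                )

    @property
    def m(self) -> int:
        if not self.samples:
            return 0
        return self.samples[0].m

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[OdorSample]:
        return iter(self.samples)

    def feature_matrix(self) -> np.ndarray:
        return np.array([s.features for s in self.samples], dtype=float).reshape(
            len(self.samples), self.m
        )

    def concentration_matrix(self) -> np.ndarray:
        """(N, n) matrix of true concentrations; raises if any are absent."""
        rows = []
        for s in self.samples:
            if s.concentrations is None:
                raise ValueError(f"sample {s.sample_id!r} has no concentrations")
            rows.append(s.concentrations)
        return np.array(rows, dtype=float)

    def labels(self) -> list[ComponentSet | None]:
        return [s.label for s in self.samples]

    def subset(self, predicate) -> "Dataset":
        return Dataset(self.universe, [s for s in self.samples if predicate(s)])


def read_dataset(path: str | Path, universe: ComponentUniverse) -> Dataset:
    """Read a CSV dataset, canonicalizing labels to universe order.

    Errors (negative concentrations, unknown label components, missing sensor
    values) are reported with the 1-based data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "label": str})
    cols = list(df.columns)
    if "sample_id" not in cols:
        raise DatasetFormatError(f"{path}: missing required column 'sample_id'")

    sensor_cols = [c for c in cols if c.startswith("s_")]
    expected = [f"s_{i}" for i in range(1, len(sensor_cols) + 1)]
    if sensor_cols != expected or not sensor_cols:
        raise DatasetFormatError(
            f"{path}: sensor columns must be consecutive s_1..s_m, got {sensor_cols}"
        )

    conc_cols = [f"c_{name}" for name in universe.names]
    have_conc = all(c in cols for c in conc_cols)
    have_label = "label" in cols

    samples: list[OdorSample] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        rowd = row._asdict() if hasattr(row, "_asdict") else dict(zip(cols, row))
        feats = np.array([rowd[c] for c in sensor_cols], dtype=float)
        if np.any(~np.isfinite(feats)):
            raise DatasetFormatError(f"{path}: row {pos}: missing/non-finite sensor value")

        label = None
        if have_label:
            raw = rowd["label"]
            if isinstance(raw, str) and raw.strip():
                try:
                    label = universe.set_from_label(raw.strip())
                except KeyError as exc:
                    raise DatasetFormatError(f"{path}: row {pos}: {exc}") from exc

        conc = None
        if have_conc:
            vals = np.array([rowd[c] for c in conc_cols], dtype=float)
            if not np.all(np.isnan(vals)):
                if np.any(np.isnan(vals)):
                    raise DatasetFormatError(
                        f"{path}: row {pos}: partially missing concentrations"
                    )
                if np.any(vals < 0):
                    raise DatasetFormatError(
                        f"{path}: row {pos}: negative concentration"
                    )
                conc = vals

        try:
            samples.append(
                OdorSample(str(rowd["sample_id"]), feats, label=label, concentrations=conc)
            )
        except ValueError as exc:
            raise DatasetFormatError(f"{path}: row {pos}: {exc}") from exc

    return Dataset(universe, samples)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset so that ``read_dataset`` reproduces it exactly.

    Floats are written with 17 significant digits, which round-trips IEEE
    doubles through text.
    """
    path = Path(path)
    any_label = any(s.label is not None for s in ds.samples)
    any_conc = any(s.concentrations is not None for s in ds.samples)
    m = ds.m

    records = []
    for s in ds.samples:
        rec: dict = {"sample_id": s.sample_id}
        if any_label:
            rec["label"] = s.label.label if s.label is not None else ""
        if any_conc:
            for j, name in enumerate(ds.universe.names):
                rec[f"c_{name}"] = (
                    s.concentrations[j] if s.concentrations is not None else np.nan
                )
        for i in range(m):
            rec[f"s_{i+1}"] = s.features[i]
        records.append(rec)

    columns = ["sample_id"]
    if any_label:
        columns.append("label")
    if any_conc:
        columns += [f"c_{name}" for name in ds.universe.names]
    # header for an empty dataset still needs sensor columns; use m=0 -> none
    columns += [f"s_{i+1}" for i in range(m)]
    if not records and m == 0:
        # degenerate: emit a minimal valid header with one sensor column
        columns = ["sample_id", "s_1"]
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(path, index=False, float_format="%.17g")
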