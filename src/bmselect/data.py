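"""Cohort container and partition encoding.

A :class:`Dataset` holds a P x N concentration matrix (proteins in rows,
individuals in columns) together with the binary biological statuses.  A
:class:`Partition` is the decision variable: a length-P boolean mask
marking each protein discriminant (``+``) or non-discriminant (``-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .conjugate import GroupStats

__all__ = [
    "Dataset",
    "Partition",
    "group_stats",
    "all_partitions",
    "partitions_with_m",
]

HEALTHY = "H"
PATHOLOGICAL = "P"


@dataclass(frozen=True)
class Dataset:
    """Protein concentrations and statuses for a cohort of individuals.

    Parameters
    ----------
    concentrations : (P, N) float array
        One row per protein, one column per individual (e.g. ug/ml).
    statuses : (N,) array of {"H", "P"}
        Biological status of each individual.
    protein_names : sequence of str, optional
        Defaults to ``protein_1 .. protein_P``.
    """

    concentrations: np.ndarray
    statuses: np.ndarray
    protein_names: tuple = field(default=None)

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        b = np.asarray(self.statuses)
        if x.ndim != 2:
            raise ValueError("concentrations must be a 2-D matrix")
        if b.shape != (x.shape[1],):
            raise ValueError(
                f"statuses length {b.shape} inconsistent with "
                f"{x.shape[1]} individuals"
            )
        if not np.isfinite(x).all():
            raise ValueError("concentrations contain non-finite values")
        bad = set(np.unique(b).tolist()) - {HEALTHY, PATHOLOGICAL}
        if bad:
            raise ValueError(
                f"statuses must be '{HEALTHY}' or '{PATHOLOGICAL}'; got {bad}"
            )
        names = self.protein_names
        if names is None:
            names = tuple(f"protein_{i + 1}" for i in range(x.shape[0]))
        else:
            names = tuple(str(n) for n in names)
            if len(names) != x.shape[0]:
                raise ValueError("protein_names length != number of proteins")
        object.__setattr__(self, "concentrations", x)
        object.__setattr__(self, "statuses", b)
        object.__setattr__(self, "protein_names", names)

    @property
    def n_proteins(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.concentrations.shape[1]

    @property
    def pathological_mask(self) -> np.ndarray:
        return self.statuses == PATHOLOGICAL

    @property
    def n_pathological(self) -> int:
        return int(self.pathological_mask.sum())

    @property
    def n_healthy(self) -> int:
        return self.n_individuals - self.n_pathological

    @classmethod
    def from_xy(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        protein_names: Sequence[str] | None = None,
    ) -> "Dataset":
        """Build from scikit-learn style arrays: X (N, P), y binary.

        ``y`` may use {0, 1} (1 = pathological) or {"H", "P"} labels.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        if y.dtype.kind in "biuf":
            vals = set(np.unique(y).tolist())
            if not vals <= {0, 1, 0.0, 1.0, True, False}:
                raise ValueError("numeric y must be binary 0/1")
            statuses = np.where(np.asarray(y).astype(bool), PATHOLOGICAL, HEALTHY)
        else:
            statuses = y.astype(str)
        return cls(X.T, statuses, protein_names)

    def permute_proteins(self, order: Sequence[int]) -> "Dataset":
        order = np.asarray(order)
        return Dataset(
            self.concentrations[order],
            self.statuses,
            tuple(self.protein_names[i] for i in order),
        )

    # -- I/O -----------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        path,
        status_column: str = "status",
        sep: str | None = None,
        healthy_label: str = HEALTHY,
        pathological_label: str = PATHOLOGICAL,
    ) -> "Dataset":
        """Read a cohort table: one row per individual, one column per
        protein plus a status column."""
        if sep is None:
            # sniff the delimiter from the header line, then parse with
            # the correctly-rounded (round-trip) float reader
            with open(path) as fh:
                first = fh.readline()
                while first.startswith("#"):
                    first = fh.readline()
            sep = "\t" if "\t" in first else ","
        df = pd.read_csv(
            path, sep=sep, comment="#", float_precision="round_trip"
        )
        if status_column not in df.columns:
            raise ValueError(f"missing status column '{status_column}'")
        raw = df[status_column].astype(str)
        mapping = {str(healthy_label): HEALTHY, str(pathological_label): PATHOLOGICAL}
        unknown = set(raw.unique()) - set(mapping)
        if unknown:
            raise ValueError(f"unrecognized status labels: {sorted(unknown)}")
        statuses = raw.map(mapping).to_numpy()
        proteins = df.drop(columns=[status_column])
        return cls(proteins.to_numpy(dtype=float).T, statuses, tuple(proteins.columns))

    def to_csv(self, path, status_column: str = "status", sep: str = ",") -> None:
        df = pd.DataFrame(self.concentrations.T, columns=list(self.protein_names))
        df[status_column] = self.statuses
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclass(frozen=True)
class Partition:
    """Assignment of each protein to the discriminant (+) subset.

    Encodable as an integer bitmask (bit i set = protein i discriminant),
    a bijection onto 0 .. 2^P - 1.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool).ravel()
        if mask.size == 0:
            raise ValueError("partition over zero proteins")
        object.__setattr__(self, "mask", mask)

    @property
    def n_proteins(self) -> int:
        return self.mask.size

    @property
    def p_plus(self) -> int:
        return int(self.mask.sum())

    @property
    def p_minus(self) -> int:
        return self.n_proteins - self.p_plus

    @property
    def bitmask(self) -> int:
        return int(np.sum(np.left_shift(1, np.nonzero(self.mask)[0])))

    @classmethod
    def from_bitmask(cls, value: int, n_proteins: int) -> "Partition":
        if not 0 <= value < (1 << n_proteins):
            raise ValueError(f"bitmask {value} out of range for P={n_proteins}")
        return cls(np.array([(value >> i) & 1 for i in range(n_proteins)], dtype=bool))

    def names(self, protein_names: Sequence[str]) -> tuple:
        return tuple(n for n, m in zip(protein_names, self.mask) if m)

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and np.array_equal(self.mask, other.mask)

    def __hash__(self) -> int:
        return hash((self.n_proteins, self.bitmask))


def all_partitions(n_proteins: int) -> list:
    """All 2^P partitions in ascending bitmask order."""
    return [Partition.from_bitmask(v, n_proteins) for v in range(1 << n_proteins)]


def partitions_with_m(n_proteins: int, n_biomarkers: int) -> list:
    """The C(P, M) partitions with exactly M discriminant proteins,
    ascending bitmask order."""
    if not 0 <= n_biomarkers <= n_proteins:
        raise ValueError("need 0 <= M <= P")
    parts = []
    for combo in combinations(range(n_proteins), n_biomarkers):
        mask = np.zeros(n_proteins, dtype=bool)
        mask[list(combo)] = True
        parts.append(Partition(mask))
    return sorted(parts, key=lambda p: p.bitmask)


_INDEX_SETS = ("pathological", "healthy", "all")


def group_stats(dataset: Dataset, index_set: str) -> GroupStats:
    """Sufficient statistics (count, mean, divisor-n covariance) of one of
    the three index sets, at full protein dimension.

    Partition-specific subsets are obtained downstream by removing rows
    and columns (``GroupStats.restrict``), so the covariance is computed
    once per cohort.
    """
    if index_set not in _INDEX_SETS:
        raise ValueError(f"index_set must be one of {_INDEX_SETS}")
    if index_set == "all":
        cols = slice(None)
    elif index_set == "pathological":
        cols = dataset.pathological_mask
    else:
        cols = ~dataset.pathological_mask
    return GroupStats.from_samples(
        dataset.concentrations[:, cols], dataset.n_proteins
    )
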