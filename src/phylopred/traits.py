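"""Species x trait tables: reading, transforms, and alignment with a tree.

A :class:`TraitTable` wraps a pandas DataFrame indexed by species binomial
(labels normalized as in :mod:`phylopred.tree`), with a per-column transform
record (``raw`` or natural ``log``, optionally with an offset delta for
``log(x + delta)``). Missing measurements are NaN. Typical columns are
nutrient concentrations per 100 g edible portion (protein g, total fat g,
omega-3/6 g, iron mg, zinc mg, vitamins A/B12/D ug) and continuous life
history covariates (maximum length cm, trophic level, maximum/minimum depth
m, the length-weight parameters a and b), but the container is agnostic.

Units are carried as metadata only and never converted.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import DataError
from .tree import Phylogeny, normalize_label

__all__ = ["TraitTable", "read_traits", "transform_column", "align"]


class TraitTable:
    """Species-indexed numeric trait matrix with transform bookkeeping.

    Parameters
    ----------
    df : DataFrame
        Numeric columns indexed by species label. Copied on construction.
    transforms : dict, optional
        column -> ("raw", None) or ("log", offset or None).
    units : dict, optional
        column -> unit string (metadata only).
    """

    def __init__(self, df: pd.DataFrame, transforms=None, units=None):
        idx = [normalize_label(s) for s in df.index]
        if len(set(idx)) != len(idx):
            dup = sorted({s for s in idx if idx.count(s) > 1})
            raise DataError(f"duplicate species rows: {dup}")
        self.df = df.copy()
        self.df.index = pd.Index(idx, name="species")
        for col in self.df.columns:
            try:
                self.df[col] = pd.to_numeric(self.df[col])
            except (ValueError, TypeError) as exc:
                raise DataError(f"non-numeric value in column {col!r}: {exc}") from None
        self.transforms = dict(transforms or {})
        self.units = dict(units or {})

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise DataError(f"no column {name!r} (have {self.columns})")
        return self.df[name]

    def n_measured(self, column: str) -> int:
        return int(self.column(column).notna().sum())

    # -------------------------------------------------------------- transforms
    def transform(self, column: str, mode: str, offset: float | None = None) -> "TraitTable":
        """Return a new table with ``column`` transformed.

        ``mode='log'`` applies the natural log (optionally ``log(x + offset)``);
        values must be strictly positive after the offset. ``mode='raw'``
        undoes a previous log. The transform is recorded so predictions can be
        reported back on the original scale.
        """
        if mode not in ("raw", "log"):
            raise DataError(f"unknown transform mode {mode!r}")
        new = TraitTable(self.df, self.transforms, self.units)
        cur = self.transforms.get(column, ("raw", None))
        x = new.df[column]
        if mode == "log":
            if cur[0] == "log":
                return new
            shifted = x + (offset or 0.0)
            if (shifted <= 0).any():
                bad = list(x.index[shifted <= 0])[:5]
                raise DataError(
                    f"log transform of non-positive values in {column!r} "
                    f"(e.g. species {bad}); supply a positive offset"
                )
            new.df[column] = np.log(shifted)
            new.transforms[column] = ("log", offset)
        else:
            if cur[0] == "log":
                new.df[column] = np.exp(x) - (cur[1] or 0.0)
            new.transforms[column] = ("raw", None)
        return new

    def back_transform(self, column: str, values):
        """Map model-scale values of ``column`` back to the original scale."""
        mode, offset = self.transforms.get(column, ("raw", None))
        if mode == "log":
            return np.exp(values) - (offset or 0.0)
        return values

    def to_csv(self, path) -> None:
        self.df.to_csv(path)

    def __repr__(self):  # pragma: no cover
        return f"<TraitTable {self.df.shape[0]} species x {self.df.shape[1]} traits>"


def read_traits(path, species_col: str = "species") -> TraitTable:
    """Read a trait CSV (header row; one species column; numeric cells).

    Empty cells become missing values. Duplicate species or non-numeric
    cells raise :class:`~phylopred.errors.DataError` naming the offender.
    """
    df = pd.read_csv(path, comment="#")
    if species_col not in df.columns:
        raise DataError(f"species column {species_col!r} not in header {list(df.columns)}")
    df = df.set_index(species_col)
    return TraitTable(df)


def transform_column(table: TraitTable, column: str, mode: str, offset=None) -> TraitTable:
    """Functional wrapper over :meth:`TraitTable.transform`."""
    return table.transform(column, mode, offset)


def align(table: TraitTable, tree: Phylogeny, column: str, verbose: bool = False):
    """Intersect tree tips with species measured for ``column``.

    Returns ``(pruned_tree, values)`` where ``values`` is a Series over the
    common species (tree preorder order) and ``pruned_tree`` is the tree
    restricted to them. Raises on empty intersection.
    """
    measured = set(table.df.index[table.column(column).notna()])
    common = [t for t in tree.tip_labels if t in measured]
    if not common:
        raise DataError(f"no overlap between tree tips and species measured for {column!r}")
    if verbose:  # pragma: no cover
        import sys

        print(
            f"align[{column}]: {len(common)} species kept, "
            f"{tree.n_tips - len(common)} tree tips unmeasured, "
            f"{len(measured) - len(common)} measured species off-tree",
            file=sys.stderr,
        )
    pruned = tree.prune(common)
    values = table.df.loc[common, column]
    return pruned, values
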