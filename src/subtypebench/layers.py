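"""Core omics-layer container and tabular I/O.

An :class:`OmicsLayer` is one molecular data modality — mRNA expression,
miRNA expression, DNA methylation beta values, copy-number log-ratios —
stored as a features x samples matrix with string identifiers on both
axes.  Missing measurements are represented by NaN in memory and by an
empty cell on disk, so matrices round-trip through ordinary TSV/CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "OmicsLayer",
    "read_layer",
    "write_layer",
]


class ValidationError(ValueError):
    """An input object violates one of its documented invariants."""


class ParseError(ValueError):
    """A file on disk is not a valid matrix/table for this platform."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OmicsLayer:
    """One omics matrix (features x samples) with identifiers.

    Parameters
    ----------
    name
        Layer name, e.g. ``"mrna"`` or ``"methylation"``.
    feature_ids
        Unique feature identifiers, one per matrix row.
    sample_ids
        Unique sample (patient) identifiers, one per matrix column.
    values
        Real matrix of shape ``(n_features, n_samples)``; NaN marks a
        missing measurement.
    """

    name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"layer {self.name!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def subset_samples(self, sample_ids: list[str]) -> "OmicsLayer":
        """Return a copy restricted to ``sample_ids``, in that order."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(
                f"layer {self.name!r} lacks samples: {missing[:5]}"
            )
        cols = [pos[s] for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            values=self.values[:, cols].copy(),
        )

    def subset_features(self, rows: list[int]) -> "OmicsLayer":
        """Return a copy keeping the feature rows at integer positions ``rows``."""
        return replace(
            self,
            feature_ids=[self.feature_ids[i] for i in rows],
            values=self.values[rows, :].copy(),
        )

    def copy(self) -> "OmicsLayer":
        return replace(self, values=self.values.copy())


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_layer(path: str | Path, name: str | None = None) -> OmicsLayer:
    """Read a features x samples matrix from TSV (or CSV by extension).

    The first column holds feature ids, the header row holds sample ids.
    Empty cells become missing entries (NaN).  Duplicate sample or feature
    ids are rejected with a :class:`ParseError`.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicated sample id(s) in header: {dups}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated feature id(s): {dups}")
    if not all(df.dtypes.apply(lambda t: np.issubdtype(t, np.number))):
        bad = [c for c, t in df.dtypes.items() if not np.issubdtype(t, np.number)]
        raise ParseError(f"{path}: non-numeric column(s): {bad}")
    return OmicsLayer(
        name=name if name is not None else path.stem,
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_layer(layer: OmicsLayer, path: str | Path) -> Path:
    """Write a layer as TSV/CSV; NaN becomes an empty cell."""
    path = Path(path)
    df = pd.DataFrame(layer.values, index=layer.feature_ids, columns=layer.sample_ids)
    df.to_csv(path, sep=_sep_for(path), na_rep="")
    return path
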