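"""Core container for methylation matrices and the TSV dialect used on disk.

Internally a methylation matrix is always oriented rows = samples,
columns = CpG sites.  On disk the conventional orientation is the
opposite (CpGs as rows, one column per sample), so I/O translates
between the two.  Missing entries are carried as NaN; the boolean
``mask`` view marks them explicitly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Scale", "MethylMatrix", "read_matrix_tsv", "write_matrix_tsv"]


class Scale(str, enum.Enum):
    """Which of the two methylation-level representations a matrix holds."""

    BETA = "beta"
    M = "M"


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files or inconsistent containers."""


@dataclass
class MethylMatrix:
    """A samples x CpGs methylation-level matrix with an explicit missing mask.

    Parameters
    ----------
    values
        Real array of shape (n_samples, n_cpgs).  NaN marks a missing entry.
        On the beta scale observed entries must lie in [0, 1].
    sample_ids, cpg_ids
        Unique row / column identifiers.
    scale
        Whether ``values`` are beta-values or M-values.
    """

    values: np.ndarray
    sample_ids: list[str]
    cpg_ids: list[str]
    scale: Scale = Scale.BETA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.scale = Scale(self.scale)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D array (samples x CpGs)")
        if self.values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise MatrixFormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.cpg_ids)} CpGs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MatrixFormatError("sample identifiers are not unique")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise MatrixFormatError("CpG identifiers are not unique")
        if self.scale is Scale.BETA:
            obs = self.values[~np.isnan(self.values)]
            if obs.size and (obs.min() < 0.0 or obs.max() > 1.0):
                raise MatrixFormatError("beta-scale entries must lie in [0, 1]")

    # -- basic views ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the entry is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "MethylMatrix":
        return MethylMatrix(
            self.values.copy(), list(self.sample_ids), list(self.cpg_ids), self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples-as-rows DataFrame view."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MethylMatrix({self.n_samples} samples x {self.n_cpgs} CpGs, "
            f"scale={self.scale.value}, missing={self.n_missing})"
        )


def write_matrix_tsv(
    x: MethylMatrix,
    path: str | Path,
    *,
    na_rep: str = "NA",
    cpgs_as_rows: bool = True,
    header_comments: Iterable[str] = (),
) -> None:
    """Write a matrix in the tab-separated dialect: first column CpG id,
    header row sample ids, ``na_rep`` for missing entries.

    ``header_comments`` lines are prefixed with ``#`` (provenance headers).
    """
    path = Path(path)
    df = x.to_frame()
    if cpgs_as_rows:
        df = df.T
    with open(path, "w") as fh:
        fh.write(f"# scale={x.scale.value}\n")
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", na_rep=na_rep, index_label="cpg_id" if cpgs_as_rows else "sample_id")


def read_matrix_tsv(
    path: str | Path,
    *,
    na_values: str | Sequence[str] = "NA",
    cpgs_as_rows: bool = True,
    scale: Scale | str | None = None,
) -> MethylMatrix:
    """Read a matrix written by :func:`write_matrix_tsv`.

    The scale is taken from a ``# scale=...`` comment header when present,
    otherwise from the ``scale`` argument (beta by default).
    """
    path = Path(path)
    parsed_scale: Scale | None = None
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("scale="):
                parsed_scale = Scale(body.split("=", 1)[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(
            fh,
            sep="\t",
            index_col=0,
            na_values=na_values,
            keep_default_na=False,
            float_precision="round_trip",
        )
    if cpgs_as_rows:
        df = df.T
    use_scale = parsed_scale if parsed_scale is not None else (Scale(scale) if scale else Scale.BETA)
    return MethylMatrix(
        df.to_numpy(dtype=float),
        sample_ids=list(df.index.astype(str)),
        cpg_ids=list(df.columns.astype(str)),
        scale=use_scale,
    )
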