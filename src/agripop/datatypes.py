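"""Shared data model for diploid biallelic SNP panels.

The universal input is a :class:`GenotypeMatrix`: samples x markers dosages
of the designated ALT allele (0/1/2) plus a boolean missing mask.  Marker
positions, group assignments and the adaptation-gene catalog travel as
validated pandas DataFrames; trees are ``skbio.TreeNode``; distance matrices
are ``skbio.DistanceMatrix``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "validate_marker_map",
    "validate_sample_groups",
    "validate_gene_catalog",
]


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (n_samples x n_markers) with a missing mask.

    Parameters
    ----------
    sample_ids, marker_ids : sequences of unique labels.
    dosages : integer array with values in {0, 1, 2}; entries under the
        missing mask are ignored (conventionally 0).
    missing_mask : boolean array, True where no call was made.
    """

    sample_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.dosages.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosages.shape
        if self.sample_ids.shape[0] != n:
            raise ValueError(
                f"{self.sample_ids.shape[0]} sample ids for {n} matrix rows"
            )
        if self.marker_ids.shape[0] != m:
            raise ValueError(
                f"{self.marker_ids.shape[0]} marker ids for {m} matrix columns"
            )
        if self.missing_mask.shape != self.dosages.shape:
            raise ValueError("missing_mask shape differs from dosages shape")
        for name, labels in (("sample", self.sample_ids), ("marker", self.marker_ids)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {name} ids")
        called = self.dosages[~self.missing_mask]
        if called.size and not np.isin(called, (0, 1, 2)).all():
            bad = sorted(set(called.tolist()) - {0, 1, 2})
            raise ValueError(f"dosages outside {{0,1,2}}: {bad}")
        self.dosages = self.dosages.astype(np.int8, copy=False)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with NaN at missing calls."""
        out = self.dosages.astype(float)
        out[self.missing_mask] = np.nan
        return out

    def marker_index(self, marker_ids) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown marker id {exc.args[0]!r}") from None

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def take_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.sample_ids,
            self.marker_ids[index],
            self.dosages[:, index],
            self.missing_mask[:, index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.sample_ids[index],
            self.marker_ids,
            self.dosages[index, :],
            self.missing_mask[index, :],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.marker_ids, other.marker_ids)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(
                self.dosages[~self.missing_mask], other.dosages[~other.missing_mask]
            )
        )


def validate_marker_map(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a marker map table (marker_id, chromosome, position_cM)."""
    required = ["marker_id", "chromosome", "position_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    df = df[required].copy()
    if df["marker_id"].duplicated().any():
        dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValueError(f"duplicate marker ids in map: {dups[:5]}")
    df["position_cM"] = df["position_cM"].astype(float)
    if not np.isfinite(df["position_cM"]).all():
        raise ValueError("non-finite marker positions")
    if (df["position_cM"] < 0).any():
        raise ValueError("negative marker positions")
    return df


def validate_sample_groups(df: pd.DataFrame, gm: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Validate a sample->group assignment, optionally against a panel."""
    required = ["sample_id", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample groups missing columns: {missing}")
    df = df[required].copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"samples assigned to more than one group: {dups[:5]}")
    if gm is not None:
        known = set(gm.sample_ids)
        unknown = [s for s in df["sample_id"] if s not in known]
        if unknown:
            raise ValueError(f"grouped samples absent from genotype matrix: {unknown}")
    return df


def validate_gene_catalog(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene catalog (gene_id, chromosome, position_cM).

    Slash-joined gene blocks such as ``eps2/HvHOX2/HvGID2`` are single
    catalog entries: one mapped genetic factor, one gene_id.
    """
    required = ["gene_id", "chromosome", "position_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene catalog missing columns: {missing}")
    df = df[required].copy()
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    df["position_cM"] = df["position_cM"].astype(float)
    if not np.isfinite(df["position_cM"]).all():
        raise ValueError("non-finite gene positions")
    return df
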