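"""Marker-level quality control: call-rate and MAF gates.

Markers are dropped when call rate or minor allele frequency falls strictly
below the configured threshold (equality passes), mirroring the removal of
markers with call rate <0.95 and MAF <0.05 common to array-based panels.
Call rate is tested first; a marker failing both rules is attributed to the
call-rate rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix

__all__ = [
    "marker_call_rate",
    "minor_allele_frequency",
    "alt_allele_frequency",
    "MarkerFilter",
    "apply_marker_filters",
    "FilterReport",
]


class EmptyPanelError(ValueError):
    """No markers survived filtering."""


def marker_call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of samples with a call, per marker."""
    if gm.n_markers == 0 or gm.n_samples == 0:
        raise ValueError("empty genotype matrix")
    return 1.0 - gm.missing_mask.mean(axis=0)


def alt_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """ALT-allele frequency p = sum(dosage) / (2 * n_called); NaN if no calls."""
    called = ~gm.missing_mask
    n_called = called.sum(axis=0)
    alt = np.where(called, gm.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return p


def minor_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """min(p, 1-p) per marker, in [0, 0.5]; NaN where no sample is called."""
    p = alt_allele_frequency(gm)
    return np.minimum(p, 1.0 - p)


@dataclass
class FilterReport:
    """Per-marker QC metrics plus drop-reason bookkeeping."""

    table: pd.DataFrame  # marker_id, call_rate, maf, kept, reason
    n_dropped_call_rate: int
    n_dropped_maf: int
    n_dropped_no_calls: int
    n_kept: int

    @property
    def n_total(self) -> int:
        return len(self.table)


class MarkerFilter(BaseEstimator):
    """Marker QC gate as a transformer over :class:`GenotypeMatrix`.

    Parameters
    ----------
    min_call_rate : float in [0, 1], default 0.95
        Markers with call rate strictly below this are dropped.
    min_maf : float in [0, 0.5], default 0.05
        Markers with MAF strictly below this are dropped.

    Attributes (after fit)
    ----------------------
    call_rate_, maf_ : per-marker metrics.
    kept_mask_ : boolean array of retained markers.
    report_ : :class:`FilterReport`.
    """

    def __init__(self, min_call_rate: float = 0.95, min_maf: float = 0.05):
        self.min_call_rate = min_call_rate
        self.min_maf = min_maf

    def _validate(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")

    def fit(self, gm: GenotypeMatrix, y=None) -> "MarkerFilter":
        self._validate()
        call_rate = marker_call_rate(gm)
        maf = minor_allele_frequency(gm)
        no_calls = np.isnan(maf)
        fail_cr = call_rate < self.min_call_rate
        fail_maf = ~no_calls & ~fail_cr & (maf < self.min_maf)
        reason = np.full(gm.n_markers, "", dtype=object)
        reason[fail_cr] = "call_rate"
        reason[no_calls & ~fail_cr] = "no_calls"
        reason[fail_maf] = "maf"
        kept = ~(fail_cr | fail_maf | no_calls)
        self.call_rate_ = call_rate
        self.maf_ = maf
        self.kept_mask_ = kept
        self.report_ = FilterReport(
            table=pd.DataFrame(
                {
                    "marker_id": gm.marker_ids,
                    "call_rate": call_rate,
                    "maf": maf,
                    "kept": kept,
                    "reason": reason,
                }
            ),
            n_dropped_call_rate=int(fail_cr.sum()),
            n_dropped_maf=int(fail_maf.sum()),
            n_dropped_no_calls=int((no_calls & ~fail_cr).sum()),
            n_kept=int(kept.sum()),
        )
        return self

    def transform(self, gm: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "kept_mask_"):
            raise RuntimeError("MarkerFilter not fitted")
        if self.kept_mask_.shape[0] != gm.n_markers:
            raise ValueError("matrix shape differs from fitted panel")
        if not self.kept_mask_.any():
            raise EmptyPanelError(
                "no markers satisfy "
                f"call_rate >= {self.min_call_rate} and maf >= {self.min_maf}"
            )
        return gm.take_markers(self.kept_mask_)

    def fit_transform(self, gm: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.fit(gm).transform(gm)


def apply_marker_filters(
    gm: GenotypeMatrix, min_call_rate: float = 0.95, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Filter markers; returns (filtered panel, report). Sample set unchanged."""
    f = MarkerFilter(min_call_rate=min_call_rate, min_maf=min_maf)
    out = f.fit_transform(gm)
    return out, f.report_
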