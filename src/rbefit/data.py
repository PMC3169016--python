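"""Domain types and CSV I/O for dose-response rosette-count data.

The experimental unit is one embryo; the measurement is the number of
rosette-shaped apoptotic clusters counted in its optic tectum (OT).  A
:class:`DoseGroup` holds all embryos irradiated at one dose, either as raw
per-embryo counts or as the summary triple (mean, SD, n); a
:class:`DoseResponseDataset` is the ordered collection of groups for one
radiation quality (e.g. iron-ions at 200 keV/um, or X-rays).

Two CSV dialects are supported:

* raw:      header ``dose_gy,count`` — one row per embryo;
* summary:  header ``dose_gy,mean,sd,n`` — one row per dose group.

Sample SD always uses the n-1 denominator, matching the pooled-variance
ANOVA downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataFormatError, DataValidationError

__all__ = [
    "DoseGroup",
    "DoseResponseDataset",
    "summarize",
    "read_dataset",
    "write_dataset",
]

_SUMMARY_TOL = 1e-9

RAW_HEADER = ("dose_gy", "count")
SUMMARY_HEADER = ("dose_gy", "mean", "sd", "n")


def _sample_stats(counts: Sequence[int]) -> tuple[float, float, int]:
    """Mean, SD (ddof=1; 0 when n=1) and n of a count sample."""
    arr = np.asarray(counts, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


@dataclass(frozen=True)
class DoseGroup:
    """One irradiation dose level.

    Parameters
    ----------
    dose:
        Absorbed dose in Gy, >= 0.
    counts:
        Optional per-embryo rosette counts (non-negative integers).  When
        present, ``mean``/``sd``/``n`` must agree with the sample statistics
        of ``counts`` (they are filled in automatically if omitted).
    mean, sd, n:
        Group summary: mean and sample SD (n-1 denominator) of clusters/OT,
        and the number of embryos.
    """

    dose: float
    counts: Optional[tuple[int, ...]] = None
    mean: float = field(default=None)  # type: ignore[assignment]
    sd: float = field(default=None)  # type: ignore[assignment]
    n: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dose < 0 or not math.isfinite(self.dose):
            raise DataValidationError(f"dose must be a finite value >= 0 Gy, got {self.dose}")
        if self.counts is not None:
            counts = tuple(int(c) for c in self.counts)
            if len(counts) == 0:
                raise DataValidationError("counts must be non-empty when present")
            if any(c < 0 for c in counts):
                raise DataValidationError(f"negative count in group at dose {self.dose} Gy")
            object.__setattr__(self, "counts", counts)
            mean, sd, n = _sample_stats(counts)
            for name, derived in (("mean", mean), ("sd", sd), ("n", n)):
                stated = getattr(self, name)
                if stated is None:
                    object.__setattr__(self, name, derived)
                elif abs(stated - derived) > _SUMMARY_TOL:
                    raise DataValidationError(
                        f"{name}={stated} inconsistent with counts (expected {derived}) "
                        f"at dose {self.dose} Gy"
                    )
        else:
            if self.mean is None or self.sd is None or self.n is None:
                raise DataValidationError(
                    "a DoseGroup needs either counts or the full (mean, sd, n) summary"
                )
        if self.n < 1:
            raise DataValidationError("n must be >= 1")
        if self.mean < 0 or self.sd < 0:
            raise DataValidationError("mean and sd must be non-negative")
        if self.n == 1 and self.sd != 0:
            raise DataValidationError("sd must be 0 when n = 1")

    @classmethod
    def from_counts(cls, dose: float, counts: Sequence[int]) -> "DoseGroup":
        return cls(dose=float(dose), counts=tuple(int(c) for c in counts))

    @classmethod
    def from_summary(cls, dose: float, mean: float, sd: float, n: int) -> "DoseGroup":
        return cls(dose=float(dose), mean=float(mean), sd=float(sd), n=int(n))

    @property
    def has_counts(self) -> bool:
        return self.counts is not None


def summarize(group: DoseGroup) -> DoseGroup:
    """Recompute ``mean``/``sd``/``n`` from raw counts.  Idempotent.

    Raises
    ------
    DataValidationError
        If the group carries no raw counts.
    """
    if group.counts is None:
        raise DataValidationError("summarize requires raw counts")
    mean, sd, n = _sample_stats(group.counts)
    return replace(group, mean=mean, sd=sd, n=n)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Ordered dose groups for one radiation quality.

    ``label`` names the quality (e.g. ``"iron-ion"``, ``"X-ray"``);
    ``let_kev_um`` is descriptive metadata only and plays no role in any
    computation.
    """

    label: str
    groups: tuple[DoseGroup, ...]
    let_kev_um: Optional[float] = None
    endpoint: str = "rosette-shaped clusters/OT"

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        if len(groups) == 0:
            raise DataValidationError("dataset needs at least one dose group")
        object.__setattr__(self, "groups", groups)
        doses = [g.dose for g in groups]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise DataValidationError(f"doses must be strictly increasing, got {doses}")
        if self.let_kev_um is not None and self.let_kev_um <= 0:
            raise DataValidationError("let_kev_um must be positive when given")

    @property
    def doses(self) -> np.ndarray:
        return np.array([g.dose for g in self.groups])

    @property
    def means(self) -> np.ndarray:
        return np.array([g.mean for g in self.groups])

    @property
    def sds(self) -> np.ndarray:
        return np.array([g.sd for g in self.groups])

    @property
    def ns(self) -> np.ndarray:
        return np.array([g.n for g in self.groups])

    @property
    def total_n(self) -> int:
        return int(self.ns.sum())

    @property
    def has_counts(self) -> bool:
        return all(g.has_counts for g in self.groups)


def read_dataset(path: str | Path, label: str = "") -> DoseResponseDataset:
    """Read a dose-response CSV in either dialect.

    Raw rows sharing a dose are pooled into one group; groups are returned
    sorted by dose.  Summaries are always recomputed from counts when the
    raw dialect is read.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file") from exc
    cols = tuple(str(c).strip() for c in df.columns)
    if cols == RAW_HEADER:
        return _dataset_from_raw(df, label or path.stem, path)
    if cols == SUMMARY_HEADER:
        return _dataset_from_summary(df, label or path.stem, path)
    raise DataFormatError(
        f"{path}: unrecognised header {cols}; expected {','.join(RAW_HEADER)} "
        f"or {','.join(SUMMARY_HEADER)}"
    )


def _check_nonnegative(df: pd.DataFrame, col: str, path: Path) -> None:
    bad = df.index[(df[col] < 0) | df[col].isna()]
    if len(bad) > 0:
        # +2: 1-based data rows below the header line
        raise DataValidationError(f"{path}: invalid {col} at row {int(bad[0]) + 2}")


def _dataset_from_raw(df: pd.DataFrame, label: str, path: Path) -> DoseResponseDataset:
    _check_nonnegative(df, "dose_gy", path)
    _check_nonnegative(df, "count", path)
    if not np.allclose(df["count"], np.round(df["count"])):
        bad = df.index[df["count"] != np.round(df["count"])][0]
        raise DataValidationError(f"{path}: non-integer count at row {int(bad) + 2}")
    groups = [
        DoseGroup.from_counts(dose, sub["count"].astype(int).tolist())
        for dose, sub in df.groupby("dose_gy", sort=True)
    ]
    return DoseResponseDataset(label=label, groups=tuple(groups))


def _dataset_from_summary(df: pd.DataFrame, label: str, path: Path) -> DoseResponseDataset:
    for col in ("dose_gy", "mean", "sd"):
        _check_nonnegative(df, col, path)
    if df["dose_gy"].duplicated().any():
        dup = df["dose_gy"][df["dose_gy"].duplicated()].iloc[0]
        raise DataValidationError(f"{path}: duplicate dose {dup} Gy in summary dialect")
    df = df.sort_values("dose_gy")
    groups = [
        DoseGroup.from_summary(r.dose_gy, r.mean, r.sd, int(r.n))
        for r in df.itertuples(index=False)
    ]
    return DoseResponseDataset(label=label, groups=tuple(groups))


def write_dataset(ds: DoseResponseDataset, path: str | Path) -> None:
    """Write a dataset as CSV: raw dialect when every group carries counts,
    summary dialect otherwise.  Round-trips through :func:`read_dataset`."""
    path = Path(path)
    if ds.has_counts:
        rows = [(g.dose, c) for g in ds.groups for c in g.counts]
        df = pd.DataFrame(rows, columns=list(RAW_HEADER))
    else:
        df = pd.DataFrame(
            [(g.dose, g.mean, g.sd, g.n) for g in ds.groups],
            columns=list(SUMMARY_HEADER),
        )
    df.to_csv(path, index=False)
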