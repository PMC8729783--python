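"""Localization-table I/O and fit-quality filtering.

The native dialect is headered comma-separated text with nm coordinates
(columns ``x_nm``/``y_nm`` mandatory, fit-quality columns optional, unknown
columns preserved).  A column-mapping dictionary adapts foreign dialects.
Quality filtering keeps localizations with precision in 0.5-30 nm and fitted
PSF width in 50-150 nm (closed ranges); an optional log-likelihood cut is off
by default since its scale depends on the fitting engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = ("x_nm", "y_nm")


@dataclass(frozen=True)
class FilterSpec:
    """Closed acceptance ranges for localization fit-quality columns."""

    precision_nm: tuple[float, float] = (0.5, 30.0)
    psf_sigma_nm: tuple[float, float] = (50.0, 150.0)
    loglik_min: float | None = None
    loglik_max: float | None = None

    def __post_init__(self):
        for name in ("precision_nm", "psf_sigma_nm"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must have lo < hi, got ({lo}, {hi})")


@dataclass(frozen=True)
class FilterResult:
    """Filtered table plus per-criterion drop counts (a row may fail several)."""

    table: pd.DataFrame
    n_input: int
    n_kept: int
    dropped_by: dict = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


def read_localizations(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a localization table from delimited text.

    ``column_map`` renames foreign column headers to the native ones
    (e.g. ``{"x [nm]": "x_nm"}``).  Raises ``KeyError`` naming the first
    missing mandatory coordinate column.
    """
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"localization table lacks mandatory column {col!r}")
    return table


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a localization table as headered comma-separated text."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise KeyError(f"localization table lacks mandatory column {col!r}")
    table.to_csv(path, index=False)


def filter_localizations(table: pd.DataFrame, spec: FilterSpec | None = None) -> FilterResult:
    """Apply fit-quality filters; endpoints are inclusive.

    Criteria whose column is absent from the table are skipped.  The result
    reports, per criterion, how many rows fail it (independently), alongside
    the kept count; filtering is idempotent.
    """
    if spec is None:
        spec = FilterSpec()
    n = len(table)
    keep = pd.Series(True, index=table.index)
    dropped_by: dict[str, int] = {}
    ranges = {
        "precision_nm": spec.precision_nm,
        "psf_sigma_nm": spec.psf_sigma_nm,
    }
    for col, (lo, hi) in ranges.items():
        if col not in table.columns:
            continue
        ok = table[col].between(lo, hi, inclusive="both")
        dropped_by[col] = int((~ok).sum())
        keep &= ok
    if "loglik" in table.columns:
        ok = pd.Series(True, index=table.index)
        if spec.loglik_min is not None:
            ok &= table["loglik"] >= spec.loglik_min
        if spec.loglik_max is not None:
            ok &= table["loglik"] <= spec.loglik_max
        if spec.loglik_min is not None or spec.loglik_max is not None:
            dropped_by["loglik"] = int((~ok).sum())
            keep &= ok
    out = table[keep].reset_index(drop=True)
    return FilterResult(table=out, n_input=n, n_kept=len(out), dropped_by=dropped_by)
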