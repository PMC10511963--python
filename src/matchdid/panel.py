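"""Long-format panel container with wave indexing and lag/lead navigation.

A :class:`Panel` holds one row per person-wave of a longitudinal ageing
cohort: a unit identifier, the interview calendar year, a binary employment
status, a bounded integer cognitive score (MMSE-like 0-30 or TICS-like 0-27)
and any number of covariate columns.  Waves are indexed by their position in
``wave_years`` rather than by calendar arithmetic, so non-biennial designs
work unchanged.  Missingness is first-class: an absent row means the unit was
not interviewed that wave, and within a row employment, outcome and
covariates may each be individually missing (NaN) — never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CORE_COLUMNS = ("unit", "year", "employed", "outcome")

DEFAULT_WAVE_YEARS = tuple(range(2006, 2021, 2))


class PanelError(ValueError):
    """A panel violated a structural invariant (duplicates, range, schema)."""


@dataclass
class Panel:
    """One person-wave-per-row longitudinal cohort.

    Parameters
    ----------
    data
        Long-format frame with at least the columns ``unit``, ``year``,
        ``employed`` and ``outcome``.  Every other column is treated as a
        covariate.  Employment must be 0/1/NaN; the outcome must lie inside
        ``instrument_range`` when present.
    wave_years
        Ordered calendar years of the study waves (default biennial
        2006-2020).  Every row's year must be one of these.
    instrument_range
        Closed bounds of the cognition instrument, ``(0, 30)`` for an
        MMSE-like scale, ``(0, 27)`` for a TICS-like scale.
    """

    data: pd.DataFrame
    wave_years: tuple = DEFAULT_WAVE_YEARS
    instrument_range: tuple = (0, 30)
    _mats: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        wy = tuple(int(y) for y in self.wave_years)
        if list(wy) != sorted(set(wy)):
            raise PanelError("wave_years must be strictly increasing")
        self.wave_years = wy
        df = self.data.copy()
        missing_cols = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise PanelError(f"panel is missing required columns {missing_cols}")
        bad_years = sorted(set(df["year"].astype(int)) - set(wy))
        if bad_years:
            raise PanelError(f"years {bad_years} are not in wave_years {wy}")
        df["year"] = df["year"].astype(int)
        df["wave"] = df["year"].map({y: i for i, y in enumerate(wy)})
        dup = df.duplicated(["unit", "year"], keep=False)
        if dup.any():
            first = df.loc[dup, ["unit", "year"]].iloc[0]
            raise PanelError(
                f"duplicate record for unit {first['unit']!r} in year {first['year']}"
            )
        emp = pd.to_numeric(df["employed"], errors="raise")
        ok = emp.isna() | emp.isin([0, 1])
        if not ok.all():
            bad = emp[~ok].iloc[0]
            raise PanelError(f"employed must be 0, 1 or missing; got {bad!r}")
        out = pd.to_numeric(df["outcome"], errors="raise")
        lo, hi = self.instrument_range
        bad = out.notna() & ((out < lo) | (out > hi))
        if bad.any():
            raise PanelError(
                f"outcome value {out[bad].iloc[0]!r} outside instrument range [{lo}, {hi}]"
            )
        df["employed"] = emp.astype(float)
        df["outcome"] = out.astype(float)
        df = df.sort_values(["unit", "wave"], kind="stable").reset_index(drop=True)
        self.data = df
        self._units = np.array(sorted(df["unit"].unique(), key=str))
        self._uidx = {u: i for i, u in enumerate(self._units)}
        self._mats = {}

    # -- basic geometry -------------------------------------------------

    @property
    def units(self) -> np.ndarray:
        """Unit identifiers in canonical (string-sorted) order."""
        return self._units

    @property
    def n_units(self) -> int:
        return len(self._units)

    @property
    def n_waves(self) -> int:
        return len(self.wave_years)

    @property
    def covariate_columns(self) -> list:
        skip = set(CORE_COLUMNS) | {"wave"}
        return [c for c in self.data.columns if c not in skip]

    def unit_rows(self, units) -> np.ndarray:
        """Canonical row positions of ``units`` in the unit×wave matrices."""
        return np.array([self._uidx[u] for u in np.atleast_1d(units)])

    def matrix(self, fld: str) -> np.ndarray:
        """A dense (n_units, n_waves) float matrix of ``fld``, NaN = missing.

        Rows follow :attr:`units` order; columns follow wave index.  Cached.
        """
        if fld not in self._mats:
            wide = (
                self.data.pivot(index="unit", columns="wave", values=fld)
                .reindex(index=self._units, columns=range(self.n_waves))
                .to_numpy(dtype=float)
            )
            self._mats[fld] = wide
        return self._mats[fld]

    # -- navigation -----------------------------------------------------

    def value(self, unit, wave: int, fld: str):
        """Value of ``fld`` for ``unit`` at ``wave`` (NaN if unobserved)."""
        if unit not in self._uidx:
            raise KeyError(f"unknown unit {unit!r}")
        if not 0 <= wave < self.n_waves:
            raise PanelError(f"wave {wave} outside 0..{self.n_waves - 1}")
        return self.matrix(fld)[self._uidx[unit], wave]

    def subset_units(self, keep) -> "Panel":
        """New panel restricted to the units in ``keep``."""
        keep = set(keep)
        df = self.data[self.data["unit"].isin(keep)].drop(columns="wave")
        return Panel(df.reset_index(drop=True), self.wave_years, self.instrument_range)


def get_lagged(panel: Panel, unit, t: int, k: int, fld: str):
    """Value of ``fld`` for ``unit`` at wave ``t - k``; NaN when unobserved.

    Raises :class:`PanelError` when the lag reaches before the first wave.
    """
    if k < 0:
        raise PanelError("lag k must be non-negative")
    if k > t:
        raise PanelError(f"lag {k} reaches before wave 0 (t={t})")
    return panel.value(unit, t - k, fld)


def read_panel(path, schema: dict | None = None, wave_years=None,
               instrument_range=(0, 30)) -> Panel:
    """Read a long-format CSV (header row, UTF-8) into a :class:`Panel`.

    ``schema`` maps the logical names ``unit``, ``year``, ``employed``,
    ``outcome`` (and optionally covariates) to the file's column names;
    unmapped extra columns come along as covariates under their own names.
    Rows whose year is outside ``wave_years`` are dropped.  Missing cells
    stay missing — they are never coerced to zero.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {csv_col: logical for logical, csv_col in schema.items()}
        missing = [c for c in rename if c not in df.columns]
        if missing:
            raise PanelError(f"schema columns {missing} not found in {path}")
        df = df.rename(columns=rename)
    for col in CORE_COLUMNS:
        if col not in df.columns:
            raise PanelError(f"column {col!r} missing from {path}")
    for col in ("year", "employed", "outcome"):
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise PanelError(f"non-numeric {col} value {raw[bad].iloc[0]!r} "
                             f"at line {row} of {path}")
        df[col] = coerced
    if wave_years is None:
        wave_years = tuple(sorted(df["year"].dropna().astype(int).unique()))
    else:
        wave_years = tuple(int(y) for y in wave_years)
        df = df[df["year"].isin(wave_years)].reset_index(drop=True)
    return Panel(df, wave_years, instrument_range)


def write_panel(panel: Panel, path) -> None:
    """Write the panel back to CSV (blank cells for missing values)."""
    out = panel.data.drop(columns="wave")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
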