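"""Occurrence-record cleaning with per-reason removal bookkeeping.

Implements the standard filter battery applied to aggregated occurrence
data (GBIF-style Darwin Core) before range estimation: basis-of-record and
collection-year filters, coordinate validity / precision / uncertainty
checks, pre-existing issue flags, proximity to country or capital
centroids and biological institutions, an optional land mask, and
duplicate removal.

Filters are applied in a fixed, documented order and each removed record
is attributed to the *first* filter it fails, so the removal log
partitions the input exactly: kept + sum(removed per reason) = input.
Cleaning is idempotent.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

__all__ = ["CleaningConfig", "RemovalLog", "clean_occurrences", "deduplicate",
           "FILTER_ORDER", "haversine_m"]

#: attribution order; a record is charged to the first filter it fails
FILTER_ORDER = (
    "not_georeferenced",
    "basis_of_record",
    "pre_1900",
    "zero_coordinate",
    "out_of_bounds",
    "low_precision",
    "high_uncertainty",
    "issue_flag",
    "sea",
    "centroid_proximity",
    "capital_proximity",
    "institution_proximity",
    "duplicate",
)

_EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclasses.dataclass
class CleaningConfig:
    """Thresholds and reference data for the occurrence filters.

    ``min_year`` keeps records with ``year >= min_year`` (the default 1901
    reads "post-1900" strictly). ``allowed_bases`` is the basis-of-record
    whitelist. Precision is judged on verbatim coordinate text columns
    (``lon_text`` / ``lat_text``) when present; otherwise a float coordinate
    counts as low-precision when it equals its 1-decimal rounding within
    1e-9 (trailing zeros are unrecoverable from floats). Uncertainty uses a
    strict ``>`` comparison, so exactly ``max_uncertainty_m`` is kept.
    Proximity filters (great-circle, metres) run only when their reference
    point sets are supplied; the land mask, a callable ``(lon, lat) ->
    bool array`` (True = on land), runs only when supplied.
    """

    min_year: int = 1901
    allowed_bases: frozenset[str] = frozenset(
        {"HUMAN_OBSERVATION", "PRESERVED_SPECIMEN", "LIVING_SPECIMEN"}
    )
    min_decimal_digits: int = 2
    max_uncertainty_m: float = 10_000.0
    bad_issues: frozenset[str] = frozenset(
        {"COUNTRY_COORDINATE_MISMATCH", "RECORDED_DATE_UNLIKELY"}
    )
    centroid_points: np.ndarray | None = None      # (n, 2) lon, lat
    capital_points: np.ndarray | None = None
    institution_points: np.ndarray | None = None
    centroid_radius_m: float = 2_000.0
    institution_radius_m: float = 2_000.0
    land_mask: object | None = None  # callable (lon, lat) -> bool array
    duplicate_key: tuple[str, ...] = (
        "species", "decimalLongitude", "decimalLatitude", "year"
    )

    def __post_init__(self) -> None:
        if self.min_decimal_digits < 0:
            raise ValueError("min_decimal_digits must be >= 0")
        if self.centroid_radius_m < 0 or self.institution_radius_m < 0:
            raise ValueError("proximity radii must be >= 0")


@dataclasses.dataclass
class RemovalLog:
    """Per-reason removal counts; partitions the input record count."""

    input_count: int
    kept_count: int
    removed: dict[str, int]

    def __post_init__(self) -> None:
        assert self.kept_count + sum(self.removed.values()) == self.input_count

    @property
    def percent_removed(self) -> float:
        return 100.0 * (self.input_count - self.kept_count) / self.input_count

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "removed": n} for r, n in self.removed.items()]
        rows.append({"reason": "<kept>", "removed": self.kept_count})
        return pd.DataFrame(rows)


def _decimal_digits(text: str) -> int:
    s = str(text).strip()
    if "." not in s:
        return 0
    return len(s.split(".", 1)[1].rstrip())


def _low_precision_float(values: np.ndarray, min_digits: int) -> np.ndarray:
    # a float whose value survives rounding to (min_digits - 1) decimals is
    # indistinguishable from a low-precision entry
    rounded = np.round(values, min_digits - 1)
    return np.abs(values - rounded) <= 1e-9


def _require(df: pd.DataFrame, cols: list[str], filter_name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"filter '{filter_name}' requires missing column(s): {missing}"
        )


def clean_occurrences(
    records: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, RemovalLog]:
    """Apply the filter battery; return kept records and the removal log.

    Record order is preserved. A record is removed iff it fails at least one
    enabled filter, attributed to the first failure in :data:`FILTER_ORDER`.
    """
    config = config or CleaningConfig()
    df = records.reset_index(drop=True)
    n = len(df)
    reason = np.full(n, "", dtype=object)

    def mark(mask: np.ndarray, code: str) -> None:
        mask = np.asarray(mask, dtype=bool) & (reason == "")
        reason[mask] = code

    _require(df, ["decimalLongitude", "decimalLatitude"], "not_georeferenced")
    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce").to_numpy(dtype=float)
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce").to_numpy(dtype=float)
    mark(np.isnan(lon) | np.isnan(lat), "not_georeferenced")

    _require(df, ["basisOfRecord"], "basis_of_record")
    mark(~df["basisOfRecord"].isin(config.allowed_bases).to_numpy(), "basis_of_record")

    _require(df, ["year"], "pre_1900")
    year = pd.to_numeric(df["year"], errors="coerce").to_numpy(dtype=float)
    mark(np.isnan(year) | (year < config.min_year), "pre_1900")

    mark((lon == 0.0) | (lat == 0.0), "zero_coordinate")
    with np.errstate(invalid="ignore"):
        mark((np.abs(lat) > 90) | (np.abs(lon) > 180), "out_of_bounds")

    if "lon_text" in df.columns and "lat_text" in df.columns:
        digits = np.minimum(
            df["lon_text"].map(_decimal_digits).to_numpy(),
            df["lat_text"].map(_decimal_digits).to_numpy(),
        )
        low = digits < config.min_decimal_digits
    else:
        with np.errstate(invalid="ignore"):
            low = (_low_precision_float(lon, config.min_decimal_digits)
                   | _low_precision_float(lat, config.min_decimal_digits))
    mark(low, "low_precision")

    if "coordinateUncertaintyInMeters" in df.columns:
        unc = pd.to_numeric(
            df["coordinateUncertaintyInMeters"], errors="coerce"
        ).to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            mark(unc > config.max_uncertainty_m, "high_uncertainty")

    if "issue" in df.columns:
        def has_bad(s) -> bool:
            if pd.isna(s) or not str(s):
                return False
            return bool(set(str(s).replace(",", ";").split(";")) & config.bad_issues)
        mark(df["issue"].map(has_bad).to_numpy(), "issue_flag")

    if config.land_mask is not None:
        ok = reason == ""
        on_land = np.asarray(config.land_mask(lon[ok], lat[ok]), dtype=bool)
        sea = np.zeros(n, dtype=bool)
        sea[np.flatnonzero(ok)[~on_land]] = True
        mark(sea, "sea")

    for points, radius, code in (
        (config.centroid_points, config.centroid_radius_m, "centroid_proximity"),
        (config.capital_points, config.centroid_radius_m, "capital_proximity"),
        (config.institution_points, config.institution_radius_m, "institution_proximity"),
    ):
        if points is None:
            continue
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        near = np.zeros(n, dtype=bool)
        for plon, plat in pts:
            near |= haversine_m(lon, lat, plon, plat) <= radius
        mark(near, code)

    # duplicates among surviving records: keep the first per key
    key_cols = [c for c in config.duplicate_key]
    _require(df, key_cols, "duplicate")
    alive = reason == ""
    dup = df.loc[alive].duplicated(subset=key_cols, keep="first")
    dup_idx = dup.index[dup.to_numpy()]
    mark(np.isin(np.arange(n), dup_idx), "duplicate")

    kept = df.loc[reason == ""].copy()
    removed = {code: int((reason == code).sum()) for code in FILTER_ORDER
               if (reason == code).any()}
    log = RemovalLog(input_count=n, kept_count=len(kept), removed=removed)
    return kept, log


def deduplicate(
    records: pd.DataFrame,
    key: tuple[str, ...] = ("species", "decimalLongitude", "decimalLatitude", "year"),
) -> tuple[pd.DataFrame, int]:
    """Drop exact duplicates on ``key``, keeping the first occurrence.

    Returns the deduplicated table and the number of rows removed.
    """
    _require(records, list(key), "duplicate")
    out = records.drop_duplicates(subset=list(key), keep="first")
    return out, len(records) - len(out)
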