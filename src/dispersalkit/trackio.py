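"""Reading and writing Movebank-style tracking CSV.

A track set is kept as a single tidy :class:`pandas.DataFrame` with columns
``individual_id`` (str), ``t`` (tz-aware UTC datetime), ``lon`` and ``lat``
(decimal degrees, WGS84), sorted by individual then time, with duplicate
``(individual_id, t)`` records removed.  Malformed rows are never silently
dropped: they are logged with a reason and counted, and the reader guarantees
``rows_in == rows_kept + rows_rejected``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: default column mapping for Movebank CSV exports
MOVEBANK_DIALECT = {
    "individual_id": "individual-local-identifier",
    "t": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
}

TRACK_COLUMNS = ["individual_id", "t", "lon", "lat"]

__all__ = ["TrackSet", "read_tracks", "write_tracks", "MOVEBANK_DIALECT"]


@dataclass
class TrackSet:
    """Tidy per-individual GPS fix table plus ingest provenance."""

    fixes: pd.DataFrame
    source: str | None = None
    rows_in: int = 0
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )

    @property
    def rows_kept(self) -> int:
        return len(self.fixes)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejected)

    @property
    def individuals(self) -> list[str]:
        return list(self.fixes["individual_id"].unique())

    def track(self, individual_id: str) -> pd.DataFrame:
        """Time-ordered fixes of one individual."""
        return self.fixes[self.fixes["individual_id"] == individual_id].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)


def _normalise(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate, sort and de-duplicate a raw fix frame; return (kept, rejected)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    t = pd.to_datetime(df["t"], utc=True, errors="coerce", format="mixed")
    reasons[t.isna() & df["t"].notna()] = "unparseable timestamp"
    reasons[df["t"].isna()] = "missing timestamp"

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad_coord = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    reasons[(reasons == "") & bad_coord] = "invalid coordinate"
    reasons[(reasons == "") & df["individual_id"].isna()] = "missing individual id"

    clean = pd.DataFrame(
        {
            "individual_id": df["individual_id"].astype(str),
            "t": t,
            "lon": lon,
            "lat": lat,
        }
    )[reasons == ""]
    clean = clean.sort_values(["individual_id", "t"], kind="mergesort")
    dup = clean.duplicated(subset=["individual_id", "t"], keep="first")
    reasons[dup[dup].index] = "duplicate (id, t)"
    kept = clean[~dup].reset_index(drop=True)

    rejected = pd.DataFrame(
        {"row": reasons.index[reasons != ""], "reason": reasons[reasons != ""].to_numpy()}
    ).reset_index(drop=True)
    return kept, rejected


def read_tracks(path, dialect: dict[str, str] | None = None) -> TrackSet:
    """Read a Movebank-style CSV of GPS fixes.

    Parameters
    ----------
    path
        CSV file with one row per fix.
    dialect
        Mapping from canonical names (``individual_id``, ``t``, ``lon``,
        ``lat``) to the column names used in the file.  Defaults to the
        Movebank export names.

    Raises
    ------
    ValueError
        If a required column is missing from the file.
    """
    dialect = dict(dialect or MOVEBANK_DIALECT)
    raw = pd.read_csv(path, dtype=str)
    missing = [src for src in dialect.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = raw.rename(columns={v: k for k, v in dialect.items()})[TRACK_COLUMNS]
    kept, rejected = _normalise(df)
    return TrackSet(fixes=kept, source=str(path), rows_in=len(raw), rejected=rejected)


def tracks_from_frame(df: pd.DataFrame) -> TrackSet:
    """Build a TrackSet from an in-memory frame with canonical columns."""
    kept, rejected = _normalise(df[TRACK_COLUMNS].copy())
    return TrackSet(fixes=kept, source=None, rows_in=len(df), rejected=rejected)


def write_tracks(trackset: TrackSet, path) -> None:
    """Write fixes back out in Movebank column names (ISO-8601 UTC times)."""
    out = trackset.fixes.rename(columns=MOVEBANK_DIALECT).copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%d %H:%M:%S"
    )
    out.to_csv(path, index=False)
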