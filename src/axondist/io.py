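"""Reading measurement tables and writing selection reports.

Measurement files are CSV/TSV with a required ``diameter_um`` column and
optional ``region`` / ``specimen`` labels; a headerless one-diameter-per-line
dialect is supported for raw measurement dumps.  Units are micrometres
throughout.  Rows with missing or non-positive diameters are dropped with a
counted warning rather than failing the whole file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import DiameterSample
from .selection import SelectionTable

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """The input file does not match any supported measurement layout."""


@dataclass(frozen=True)
class MeasurementTable:
    """Validated measurement records plus a count of rejected rows."""

    frame: pd.DataFrame  # columns: diameter_um, region, specimen
    n_rejected: int

    def regions(self) -> tuple[str, ...]:
        return tuple(self.frame["region"].unique())

    def sample(self, region: str | None = None) -> DiameterSample:
        """One region's diameters, or the pooled data when region is None."""
        df = self.frame
        if region is not None:
            df = df[df["region"] == region]
            if df.empty:
                raise KeyError(f"no measurements for region {region!r}")
        specimens = df["specimen"].unique()
        return DiameterSample(
            df["diameter_um"].to_numpy(),
            region=region or "whole",
            specimen=specimens[0] if len(specimens) == 1 else "pooled",
        )


def read_measurements(
    path: str | Path, format: str = "csv", headerless: bool = False
) -> MeasurementTable:
    """Load a diameter measurement table.

    ``format`` selects the delimiter (csv or tsv).  With ``headerless`` the
    file is read as one diameter per line with no header and no labels.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"format must be csv or tsv, got {format!r}")
    if headerless:
        df = pd.read_csv(path, sep=sep, header=None, names=["diameter_um"])
    else:
        df = pd.read_csv(path, sep=sep)
        if "diameter_um" not in df.columns:
            raise FormatError(
                f"{path}: required column 'diameter_um' missing "
                f"(found {list(df.columns)}); for raw single-column files "
                "use the headerless dialect"
            )
    if "region" not in df.columns:
        df["region"] = "whole"
    if "specimen" not in df.columns:
        df["specimen"] = "unknown"
    df["diameter_um"] = pd.to_numeric(df["diameter_um"], errors="coerce")
    ok = df["diameter_um"].notna() & (df["diameter_um"] > 0) & np.isfinite(df["diameter_um"])
    n_rejected = int((~ok).sum())
    if n_rejected:
        log.warning("%s: rejected %d rows with missing/non-positive diameters",
                    path, n_rejected)
    df = df.loc[ok, ["diameter_um", "region", "specimen"]].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no valid measurements after filtering")
    return MeasurementTable(df, n_rejected)


def _table_payload(table: SelectionTable) -> dict:
    return {
        "sample": table.sample_label,
        "rows": [
            {
                "family": r.family,
                "rank": r.rank,
                "k": r.k,
                "aicc": r.aicc,
                "aicc_rounded": int(round(r.aicc)),
                "bic": r.bic,
                "nll": r.nll,
            }
            for r in table.rows
        ],
        "excluded": [{"family": f, "reason": why} for f, why in table.excluded],
    }


def write_selection_report(
    tables: list[SelectionTable], path: str | Path, format: str = "csv"
) -> Path:
    """Write ranked selection tables as CSV or JSON (deterministic layout)."""
    if not tables:
        raise ValueError("no selection tables to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        payload = [_table_payload(t) for t in tables]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        frames = []
        for t in tables:
            df = t.to_frame()[["family", "rank", "k", "aicc", "bic", "nll"]].copy()
            df.insert(0, "sample", t.sample_label)
            df["aicc_rounded"] = df["aicc"].round().astype(int)
            frames.append(df)
            for fam_name, why in t.excluded:
                log.warning("%s: %s excluded from ranking (%s)",
                            t.sample_label, fam_name, why)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValueError(f"format must be csv or json, got {format!r}")
    return path


def read_selection_report(path: str | Path) -> list[dict]:
    """Re-read a JSON selection report (inverse of write_selection_report)."""
    return json.loads(Path(path).read_text())


def rank_matrix_frame(tables: list[SelectionTable]) -> pd.DataFrame:
    """Samples x families wide rank table, ready for the Friedman/Nemenyi step."""
    data = {t.sample_label: {r.family: r.rank for r in t.rows} for t in tables}
    return pd.DataFrame(data).T.astype(float)


def write_error_profiles(profiles, path: str | Path) -> Path:
    """CSV of the CDF-error grid with one column per family."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame({"diameter_um": profiles[0].grid})
    for p in profiles:
        if not np.array_equal(p.grid, profiles[0].grid):
            raise ValueError("error profiles must share a grid")
        out[p.family] = p.errors
    out.to_csv(path, index=False)
    return path
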