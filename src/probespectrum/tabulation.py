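"""Detection-survey tabulation (site x species analyzed/positive counts).

Turns a long-format detection table — one row per (site, species) with the
number of plant samples analyzed and the number PCR-positive — into
per-site, per-species and overall totals with integer percentages under
round-half-up (the convention matching published survey tables, e.g.
16.7 -> 17, 42.9 -> 43).  Zero-analyzed groups report their percentage as
"NA", never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = ["DetectionTable", "DetectionSummary", "tabulate",
           "read_detection_table", "load_table1_fixture", "percent"]

DETECTION_COLUMNS = ["site", "species", "n_analyzed", "n_positive"]


def percent(positive: int, analyzed: int, decimals: int = 0) -> float | None:
    """Round-half-up percentage; None (rendered NA) when nothing was analyzed."""
    if analyzed == 0:
        return None
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100 * positive) / Decimal(analyzed)
    out = float(value.quantize(quantum, rounding=ROUND_HALF_UP))
    return int(out) if decimals == 0 else out


@dataclass
class DetectionTable:
    """Validated long-format detection counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DETECTION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"detection table missing columns: {missing}")
        df = self.data[DETECTION_COLUMNS].copy()
        df["n_analyzed"] = df["n_analyzed"].astype(int)
        df["n_positive"] = df["n_positive"].astype(int)
        if (df["n_analyzed"] < 0).any() or (df["n_positive"] < 0).any():
            raise ValidationError("counts must be non-negative")
        bad = df[df["n_positive"] > df["n_analyzed"]]
        if not bad.empty:
            row = bad.iloc[0]
            raise ValidationError(
                f"n_positive > n_analyzed for site {row['site']!r}, "
                f"species {row['species']!r}"
            )
        dup = df.duplicated(subset=["site", "species"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate (site, species) row: ({row['site']!r}, {row['species']!r})"
            )
        self.data = df


@dataclass
class DetectionSummary:
    """Per-site, per-species and overall totals with rounded percentages."""

    per_site: pd.DataFrame     # site, n_analyzed, n_positive, percent
    per_species: pd.DataFrame  # species, n_analyzed, n_positive, percent
    overall: dict              # n_analyzed, n_positive, percent

    def site_percent(self, site: str) -> int | None:
        row = self.per_site.set_index("site").loc[site]
        return row["percent"] if pd.notna(row["percent"]) else None

    def species_percent(self, species: str) -> int | None:
        row = self.per_species.set_index("species").loc[species]
        return row["percent"] if pd.notna(row["percent"]) else None


def _group_summary(df: pd.DataFrame, by: str) -> pd.DataFrame:
    agg = (
        df.groupby(by, sort=True)[["n_analyzed", "n_positive"]]
        .sum()
        .reset_index()
    )
    agg["percent"] = [
        percent(p, a) for p, a in zip(agg["n_positive"], agg["n_analyzed"])
    ]
    agg["percent"] = agg["percent"].astype("Int64")
    return agg


def tabulate(table: DetectionTable | pd.DataFrame) -> DetectionSummary:
    """Summarize a detection table; totals conserve column sums exactly."""
    if isinstance(table, pd.DataFrame):
        table = DetectionTable(table)
    df = table.data
    n_analyzed = int(df["n_analyzed"].sum())
    n_positive = int(df["n_positive"].sum())
    return DetectionSummary(
        per_site=_group_summary(df, "site"),
        per_species=_group_summary(df, "species"),
        overall={
            "n_analyzed": n_analyzed,
            "n_positive": n_positive,
            "percent": percent(n_positive, n_analyzed),
        },
    )


def read_detection_table(path: str | Path) -> DetectionTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return DetectionTable(df)


def load_table1_fixture() -> DetectionTable:
    """Packaged white-truffle detection survey (three fruiting sites, 100 samples).

    Counts reconstructed from the published per-site totals and per-species
    percentages; species never found positive are aggregated per site as
    "other species" rows.
    """
    ref = resources.files("probespectrum.data") / "table1_detections.tsv"
    with resources.as_file(ref) as path:
        return read_detection_table(path)


def write_summary(summary: DetectionSummary, path: str | Path) -> None:
    """Write site, species and overall blocks to one TSV."""
    per_site = summary.per_site.copy()
    per_site.insert(0, "level", "site")
    per_site = per_site.rename(columns={"site": "key"})
    per_species = summary.per_species.copy()
    per_species.insert(0, "level", "species")
    per_species = per_species.rename(columns={"species": "key"})
    overall = pd.DataFrame(
        [{"level": "overall", "key": "all",
          "n_analyzed": summary.overall["n_analyzed"],
          "n_positive": summary.overall["n_positive"],
          "percent": summary.overall["percent"]}]
    )
    out = pd.concat([per_site, per_species, overall], ignore_index=True)
    out["percent"] = out["percent"].astype(object).where(out["percent"].notna(), "NA")
    out.to_csv(path, sep="\t", index=False)
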