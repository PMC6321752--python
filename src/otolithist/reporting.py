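"""Cohort-level summaries of life-history calls and Sr:Ca distributions.

Aggregates per-fish calls into per-population percentage tables (one row
per species × location × year, percentages over the six categories) and
pools per-point Sr:Ca values by species for distribution summaries
(mean, SD, median, quartiles). Percentages are rounded half-up to one
decimal; zero categories are blank in the rendered table but 0.0 in the
data model.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .classification import CATEGORIES, LifeHistoryCall
from .errors import EmptyInputError, JoinError
from .raw_io import ElementProfile

__all__ = ["CohortSummary", "summarize_cohort", "species_ratio_summary", "round_half_up"]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 12.25 → 12.3), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Percentage of individuals per migratory strategy, by cohort."""

    table: pd.DataFrame  # columns: species, location, year, N, FW, B, ANA, CAT, AMPH, O

    def row(self, species: str, location: str, year=None) -> pd.Series:
        t = self.table
        mask = (t["species"] == species) & (t["location"] == location)
        if year is not None:
            mask &= t["year"] == year
        match = t[mask]
        if match.empty:
            raise KeyError(f"no cohort row for {species} / {location}")
        return match.iloc[0]

    def to_text(self) -> str:
        """Rendered table with zero percentages left blank."""
        shown = self.table.copy()
        for cat in CATEGORIES:
            shown[cat] = shown[cat].map(lambda v: "" if v == 0 else f"{v:g}")
        return shown.to_string(index=False)


def _lookup(metadata, fish_id: str) -> tuple:
    if isinstance(metadata, pd.DataFrame):
        rows = metadata[metadata["fish_id"] == fish_id]
        if rows.empty:
            raise JoinError(f"no metadata for fish_id {fish_id!r}")
        r = rows.iloc[0]
        return r["species"], r["location"], r.get("year")
    try:
        entry = metadata[fish_id]
    except KeyError:
        raise JoinError(f"no metadata for fish_id {fish_id!r}") from None
    if len(entry) == 2:
        return entry[0], entry[1], None
    return tuple(entry[:3])


def summarize_cohort(calls: list[LifeHistoryCall], metadata) -> CohortSummary:
    """Percentage table of calls per (species, location, year) cohort.

    ``metadata`` maps fish_id → (species, location[, year]), either as a
    dict or a DataFrame with those columns. A call whose fish_id has no
    metadata raises :class:`JoinError` naming the fish.
    """
    if not calls:
        raise EmptyInputError("no life-history calls to summarize")
    rows = []
    for call in calls:
        species, location, year = _lookup(metadata, call.fish_id)
        rows.append(
            {"species": species, "location": location, "year": year, "category": call.category}
        )
    frame = pd.DataFrame(rows)
    out = []
    for (species, location, year), group in frame.groupby(
        ["species", "location", "year"], dropna=False, sort=True
    ):
        n = len(group)
        counts = group["category"].value_counts()
        row = {"species": species, "location": location, "year": year, "N": n}
        for cat in CATEGORIES:
            row[cat] = round_half_up(100.0 * counts.get(cat, 0) / n, 1)
        out.append(row)
    return CohortSummary(table=pd.DataFrame(out))


def species_ratio_summary(profiles: list[ElementProfile], metadata) -> pd.DataFrame:
    """Pooled Sr:Ca distribution statistics per species.

    Pools every retained (ok) point of every transect of a species — the
    per-point distribution, not a distribution of per-fish means — and
    reports n, mean, sd, median and quartiles in mmol/mol.
    """
    if not profiles:
        raise EmptyInputError("no profiles to summarize")
    pooled: dict[str, list[np.ndarray]] = {}
    for profile in profiles:
        species = _lookup(metadata, profile.fish_id)[0]
        pooled.setdefault(species, []).append(profile.ok_ratios)
    rows = []
    for species in sorted(pooled):
        values = np.concatenate(pooled[species])
        rows.append(
            {
                "species": species,
                "n_points": values.size,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                "median": float(np.median(values)),
                "q1": float(np.quantile(values, 0.25)),
                "q3": float(np.quantile(values, 0.75)),
            }
        )
    return pd.DataFrame(rows)
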