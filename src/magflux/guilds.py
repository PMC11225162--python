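"""Guild-level activity comparison and community flux summaries.

Within a functional guild — the MAGs that encode a pathway (positive
presence call) — each member's pathway-level TPM is expressed as a
percentage share of the guild total per sample, aggregated to
mean ± sd over replicate samples of a condition, and ranked to pinpoint
the active populations. Community-level carbon flux is summarized as the
summed pathway expression over eligible MAGs per condition.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import PathwayCatalog
from .presence import PresenceCall, presence_frame

__all__ = [
    "GuildError",
    "METHANOGENESIS_ROUTES",
    "active_population_filter",
    "flux_table",
    "guild_shares",
    "methanogenesis_route_shares",
    "rank_active",
    "replicate_aggregate",
]

# Packaged catalog ids of the four methanogenesis routes.
METHANOGENESIS_ROUTES = (
    "METH_HYDRO",
    "METH_ACETO",
    "METH_METHANOL",
    "METH_METHYLAMINE",
)


class GuildError(ValueError):
    """Raised for unknown pathways, conditions or empty MAG sets."""


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return presence_frame(calls)


def _eligible_mags(calls: pd.DataFrame, pathway_id: str) -> list[str]:
    sub = calls[(calls["pathway_id"] == pathway_id) & calls["present"]]
    return sorted(sub["mag_id"].unique())


def guild_shares(
    pathway_id: str,
    activities: pd.DataFrame,
    calls: Iterable[PresenceCall] | pd.DataFrame,
    sample_id: str,
) -> pd.DataFrame:
    """Percent share of one pathway's expression per eligible MAG in one sample.

    Eligibility = a positive presence call, so stray expression from MAGs
    that do not encode the pathway is excluded. Shares sum to 100 when the
    guild has any expression; an all-zero guild is reported with shares 0
    and ``zero_guild=True``.
    """
    calls_df = _calls_frame(calls)
    if pathway_id not in set(calls_df["pathway_id"]):
        raise GuildError(f"unknown pathway {pathway_id!r}")
    mags = _eligible_mags(calls_df, pathway_id)
    sub = activities[
        (activities["pathway_id"] == pathway_id)
        & (activities["sample_id"] == sample_id)
        & activities["mag_id"].isin(mags)
    ]
    values = sub.set_index("mag_id")["value"].reindex(mags).fillna(0.0)
    total = float(values.sum())
    if total > 0:
        shares = values / total * 100.0
        zero = False
    else:
        shares = values * 0.0
        zero = True
    return pd.DataFrame(
        {
            "pathway_id": pathway_id,
            "sample_id": sample_id,
            "mag_id": mags,
            "share": shares.to_numpy(dtype=float),
            "zero_guild": zero,
        }
    )


def replicate_aggregate(
    shares: pd.DataFrame, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Mean ± sample sd (n-1) of shares across replicates of each condition.

    ``shares`` is long-format with at least ``pathway_id, sample_id,
    mag_id, share``; conditions come from the sample sheet. A condition
    with a single replicate gets sd = NaN.
    """
    mapping = sample_sheet.set_index("sample_id")["condition"]
    unknown = set(shares["sample_id"]) - set(mapping.index)
    if unknown:
        raise GuildError(f"samples missing from sample sheet: {sorted(unknown)}")
    df = shares.copy()
    df["condition"] = df["sample_id"].map(mapping)
    agg = (
        df.groupby(["pathway_id", "condition", "mag_id"], sort=True)["share"]
        .agg(mean_share="mean", sd_share=lambda s: s.std(ddof=1), n_replicates="size")
        .reset_index()
    )
    return agg


def rank_active(
    aggregated: pd.DataFrame, pathway_id: str, condition: str
) -> pd.DataFrame:
    """MAGs of one guild ordered by descending mean share; ties broken by
    ascending mag_id, so the ranking is deterministic under re-runs."""
    sub = aggregated[
        (aggregated["pathway_id"] == pathway_id)
        & (aggregated["condition"] == condition)
    ].copy()
    sub = sub.sort_values(
        ["mean_share", "mag_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    sub.insert(0, "rank", np.arange(1, len(sub) + 1))
    return sub


def methanogenesis_route_shares(
    activities: pd.DataFrame,
    calls: Iterable[PresenceCall] | pd.DataFrame,
    archaeal_mags: Sequence[str],
    sample_id: str,
    routes: Sequence[str] = METHANOGENESIS_ROUTES,
) -> pd.Series:
    """Percent of archaeal methanogenesis activity per route in one sample.

    Sums each route's pathway expression over eligible archaeal MAGs and
    normalizes across routes to 100%.
    """
    if not archaeal_mags:
        raise GuildError("no archaeal MAGs flagged")
    calls_df = _calls_frame(calls)
    totals = {}
    for route in routes:
        mags = [m for m in _eligible_mags(calls_df, route) if m in set(archaeal_mags)]
        sub = activities[
            (activities["pathway_id"] == route)
            & (activities["sample_id"] == sample_id)
            & activities["mag_id"].isin(mags)
        ]
        totals[route] = float(sub["value"].sum())
    grand = sum(totals.values())
    if grand > 0:
        return pd.Series({r: v / grand * 100.0 for r, v in totals.items()})
    return pd.Series({r: 0.0 for r in totals})


def flux_table(
    catalog: PathwayCatalog,
    activities: pd.DataFrame,
    calls: Iterable[PresenceCall] | pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Summed pathway expression over eligible MAGs per condition.

    Per pathway and condition: mean activity across replicates per MAG,
    summed over the MAGs with a positive presence call. Pathways or
    conditions without eligible expression appear with total 0.
    """
    calls_df = _calls_frame(calls)
    mapping = sample_sheet.set_index("sample_id")["condition"]
    conditions = list(dict.fromkeys(sample_sheet["condition"]))
    df = activities.copy()
    df["condition"] = df["sample_id"].map(mapping)
    rows = []
    for pw in catalog:
        mags = _eligible_mags(calls_df, pw.pathway_id)
        sub = df[(df["pathway_id"] == pw.pathway_id) & df["mag_id"].isin(mags)]
        per = (
            sub.groupby(["condition", "mag_id"])["value"].mean()
            if not sub.empty
            else pd.Series(dtype=float)
        )
        for cond in conditions:
            total = float(per.xs(cond).sum()) if (not per.empty and cond in per.index.get_level_values(0)) else 0.0
            rows.append((pw.pathway_id, pw.category, cond, total))
    return pd.DataFrame(
        rows, columns=["pathway_id", "category", "condition", "total_expression"]
    )


def active_population_filter(
    relative_expression: pd.DataFrame, threshold_percent: float = 1.0
) -> list[str]:
    """MAGs whose transcriptome fraction strictly exceeds the threshold in
    at least one sample (``relative_expression`` is MAG x sample, fractions)."""
    frac = threshold_percent / 100.0
    mask = (relative_expression > frac).any(axis=1)
    return sorted(relative_expression.index[mask])
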