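"""Pathway presence calling from genomic KO content.

A step is detected in a MAG when at least one of its enzyme variants has
every required subunit KO annotated somewhere in the MAG. Pathway
completeness is the fraction of *key* steps detected, kept as an exact
rational so threshold comparisons at boundaries such as 10/11 vs 0.9
never suffer floating-point artifacts. A pathway is present iff
completeness >= its presence threshold (default 1, i.e. every key step).

Presence is a genomic statement only; "transcriptionally expressed" is a
separate notion (presence AND positive pathway activity) handled in
:mod:`magflux.guilds`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Set

import pandas as pd

from .catalog import PathwayCatalog, PathwayDefinition, Step
from .genes import GeneTable

__all__ = [
    "PresenceCall",
    "PresenceError",
    "call_presence",
    "detect_step",
    "pathway_completeness",
    "presence_frame",
]


class PresenceError(ValueError):
    """Raised for pathways that cannot be scored (e.g. no key steps)."""


@dataclass(frozen=True)
class PresenceCall:
    mag_id: str
    pathway_id: str
    n_key_steps: int
    n_detected: int
    completeness: Fraction
    present: bool
    detected_step_ids: tuple[str, ...]


def detect_step(mag_kos: Set[str], step: Step) -> bool:
    """True iff some variant has ALL required subunits in ``mag_kos``.

    Optional subunits never influence detection.
    """
    return any(
        all(ko in mag_kos for ko in variant.required) for variant in step.variants
    )


def pathway_completeness(
    mag_kos: Set[str], pathway: PathwayDefinition, mag_id: str = ""
) -> PresenceCall:
    """Score one MAG against one pathway and apply its threshold.

    Completeness is ``n_detected / n_key_steps`` as an exact Fraction;
    ``present`` compares it against the pathway's threshold with >=.
    """
    key_steps = pathway.key_steps
    if not key_steps:
        raise PresenceError(
            f"pathway {pathway.pathway_id!r} has no key steps"
        )
    detected = tuple(s.step_id for s in key_steps if detect_step(mag_kos, s))
    completeness = Fraction(len(detected), len(key_steps))
    return PresenceCall(
        mag_id=mag_id,
        pathway_id=pathway.pathway_id,
        n_key_steps=len(key_steps),
        n_detected=len(detected),
        completeness=completeness,
        present=completeness >= pathway.presence_threshold,
        detected_step_ids=detected,
    )


def call_presence(table: GeneTable, catalog: PathwayCatalog) -> list[PresenceCall]:
    """One :class:`PresenceCall` per (MAG, pathway) pair."""
    calls = []
    for mag_id in table.mag_ids:
        mag_kos = table.mag_kos(mag_id)
        for pathway in catalog:
            calls.append(pathway_completeness(mag_kos, pathway, mag_id=mag_id))
    return calls


def presence_frame(calls: Iterable[PresenceCall]) -> pd.DataFrame:
    """Long-format presence table (completeness as float for output only)."""
    rows = [
        (
            c.mag_id,
            c.pathway_id,
            c.n_key_steps,
            c.n_detected,
            float(c.completeness),
            c.present,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mag_id",
            "pathway_id",
            "n_key_steps",
            "n_detected",
            "completeness",
            "present",
        ],
    )
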