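"""Pathway catalog: stepwise KO logic for anaerobic carbon-flux pathways.

A pathway is an ordered list of reaction steps. Each step can be satisfied
by one of several enzyme *variants* (isoenzymes or alternative complexes,
OR-semantics); a variant is a set of required subunit KOs (AND-semantics)
plus optional accessory subunits that never influence presence calls or
expression aggregation.

The step grammar is a flat OR-of-AND expression modelled on KEGG module
definition strings, without nesting:

    ``K01902+K01903,K22224``  — a two-subunit complex OR a single enzyme
    ``K00248+-K03522``        — required K00248 with optional K03522

The packaged default catalog (:func:`load_default_catalog`) covers 90
anaerobic pathways spanning polymer depolymerization, sugar and amino-acid
fermentation, LCFA beta-oxidation, syntrophic SCFA oxidation, central
carbon metabolism, the four methanogenesis routes, and anaerobic energy
conservation. Every pathway requires 100% of its key steps for a presence
call except the 11-step methylmalonyl-CoA pathway (``MMC``), which uses a
relaxed >=90% threshold to tolerate MAG incompleteness.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "CATEGORIES",
    "CatalogError",
    "ComplexVariant",
    "PathwayCatalog",
    "PathwayDefinition",
    "Step",
    "StepParseError",
    "ValidationReport",
    "dump_catalog",
    "load_catalog",
    "load_default_catalog",
    "parse_step_expression",
    "step_to_expression",
    "validate_catalog",
]

_KO_RE = re.compile(r"^K\d{5}$")

CATEGORIES = frozenset(
    {
        "depolymerization",
        "sugar",
        "amino_acid",
        "lcfa_beta_oxidation",
        "scfa_oxidation",
        "central_carbon",
        "methanogenesis",
        "energy_conservation",
    }
)

_DEFAULT_CATALOG_RESOURCE = "anaerobic_pathways.yaml"


class CatalogError(ValueError):
    """Raised for malformed catalog files or definitions."""


class StepParseError(CatalogError):
    """Raised when a step definition string violates the grammar."""


def _validate_ko(token: str, position: int) -> str:
    ko = token.strip().upper()
    if not _KO_RE.match(ko):
        raise StepParseError(
            f"malformed KO token {token!r} at position {position}: "
            "expected 'K' followed by 5 digits"
        )
    return ko


@dataclass(frozen=True)
class ComplexVariant:
    """One way of catalysing a step: an AND-set of required subunit KOs."""

    required: tuple[str, ...]
    optional: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.required:
            raise CatalogError("variant must have at least one required subunit")
        seen: set[str] = set()
        for ko in (*self.required, *self.optional):
            if ko in seen:
                raise CatalogError(f"duplicate subunit {ko} in variant")
            seen.add(ko)


@dataclass(frozen=True)
class Step:
    """A reaction step: OR over variants; ``is_key`` steps count toward completeness."""

    step_id: str
    variants: tuple[ComplexVariant, ...]
    is_key: bool = True

    def __post_init__(self) -> None:
        if not self.variants:
            raise CatalogError(f"step {self.step_id!r} has no variants")

    def required_kos(self) -> set[str]:
        """All KOs appearing as a required subunit of any variant."""
        return {ko for v in self.variants for ko in v.required}


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    category: str
    steps: tuple[Step, ...]
    presence_threshold: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        if not self.steps:
            raise CatalogError(f"pathway {self.pathway_id!r} has an empty step list")
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"pathway {self.pathway_id!r}: unknown category {self.category!r}"
            )
        if not (0 < self.presence_threshold <= 1):
            raise CatalogError(
                f"pathway {self.pathway_id!r}: presence_threshold "
                f"{self.presence_threshold} outside (0, 1]"
            )
        ids = [s.step_id for s in self.steps]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CatalogError(
                f"pathway {self.pathway_id!r}: duplicate step ids {dup}"
            )

    @property
    def key_steps(self) -> tuple[Step, ...]:
        return tuple(s for s in self.steps if s.is_key)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


class PathwayCatalog:
    """Ordered, id-keyed collection of :class:`PathwayDefinition`."""

    def __init__(self, pathways: Iterable[PathwayDefinition]):
        self._pathways: dict[str, PathwayDefinition] = {}
        for pw in pathways:
            if pw.pathway_id in self._pathways:
                raise CatalogError(f"duplicate pathway_id {pw.pathway_id!r}")
            self._pathways[pw.pathway_id] = pw

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[PathwayDefinition]:
        return iter(self._pathways.values())

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __getitem__(self, pathway_id: str) -> PathwayDefinition:
        try:
            return self._pathways[pathway_id]
        except KeyError:
            raise KeyError(f"unknown pathway_id {pathway_id!r}") from None

    def get(self, pathway_id: str) -> PathwayDefinition | None:
        return self._pathways.get(pathway_id)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self._pathways)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCatalog):
            return NotImplemented
        return self._pathways == other._pathways


def parse_step_expression(text: str, step_id: str = "step", is_key: bool = True) -> Step:
    """Parse a flat OR-of-AND step definition string into a :class:`Step`.

    ``,`` separates variants (OR); ``+`` joins subunits within a variant
    (AND); a ``-`` prefix marks a subunit as optional. Whitespace is
    ignored. Variant and subunit order is preserved.
    """
    if not text or not text.strip():
        raise StepParseError("empty step definition")
    compact = re.sub(r"\s+", "", text)
    variants: list[ComplexVariant] = []
    pos = 0
    for var_idx, chunk in enumerate(compact.split(",")):
        if not chunk:
            raise StepParseError(
                f"empty variant at position {pos} in {text!r}"
            )
        required: list[str] = []
        optional: list[str] = []
        for token in chunk.split("+"):
            if not token:
                raise StepParseError(
                    f"empty subunit token at position {pos} in {text!r}"
                )
            if token.startswith("-"):
                optional.append(_validate_ko(token[1:], pos))
            else:
                required.append(_validate_ko(token, pos))
            pos += len(token) + 1
        if not required:
            raise StepParseError(
                f"variant {var_idx} of {text!r} has only optional subunits"
            )
        dupes = {k for k in required + optional if (required + optional).count(k) > 1}
        if dupes:
            raise StepParseError(
                f"duplicate subunit {sorted(dupes)[0]} in variant {var_idx} of {text!r}"
            )
        variants.append(ComplexVariant(tuple(required), tuple(optional)))
    return Step(step_id=step_id, variants=tuple(variants), is_key=is_key)


def step_to_expression(step: Step) -> str:
    """Inverse of :func:`parse_step_expression` (order-preserving)."""
    parts = []
    for v in step.variants:
        tokens = list(v.required) + [f"-{ko}" for ko in v.optional]
        parts.append("+".join(tokens))
    return ",".join(parts)


def _threshold_from_raw(raw: object, pathway_id: str) -> Fraction:
    if raw is None:
        return Fraction(1)
    try:
        thr = Fraction(str(raw))
    except (ValueError, ZeroDivisionError) as exc:
        raise CatalogError(
            f"pathway {pathway_id!r}: unreadable threshold {raw!r}"
        ) from exc
    if not (0 < thr <= 1):
        raise CatalogError(
            f"pathway {pathway_id!r}: threshold {raw!r} outside (0, 1]"
        )
    return thr


def _pathway_from_mapping(entry: Mapping) -> PathwayDefinition:
    try:
        pathway_id = str(entry["id"])
    except KeyError:
        raise CatalogError(f"pathway entry missing 'id': {entry!r}") from None
    raw_steps = entry.get("steps")
    if not raw_steps:
        raise CatalogError(f"pathway {pathway_id!r} has an empty step list")
    steps = []
    for i, raw in enumerate(raw_steps, start=1):
        if isinstance(raw, str):
            raw = {"expr": raw}
        step_id = str(raw.get("step_id", f"s{i}"))
        try:
            steps.append(
                parse_step_expression(
                    str(raw["expr"]),
                    step_id=step_id,
                    is_key=bool(raw.get("key", True)),
                )
            )
        except KeyError:
            raise CatalogError(
                f"pathway {pathway_id!r} step {step_id!r} missing 'expr'"
            ) from None
        except StepParseError as exc:
            raise CatalogError(f"pathway {pathway_id!r}: {exc}") from exc
    return PathwayDefinition(
        pathway_id=pathway_id,
        name=str(entry.get("name", pathway_id)),
        category=str(entry.get("category", "central_carbon")),
        steps=tuple(steps),
        presence_threshold=_threshold_from_raw(entry.get("threshold"), pathway_id),
    )


def load_catalog(path: str | Path) -> PathwayCatalog:
    """Load a pathway catalog from a YAML file.

    The file holds a top-level ``pathways:`` list; each entry has ``id``,
    ``name``, ``category``, optional ``threshold`` (default 1.0) and a
    ``steps`` list of ``{step_id, key, expr}`` mappings (or bare expression
    strings).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "pathways" not in doc:
        raise CatalogError(f"{path}: expected a mapping with a 'pathways' list")
    return PathwayCatalog(_pathway_from_mapping(e) for e in doc["pathways"])


def load_default_catalog() -> PathwayCatalog:
    """Load the packaged 90-pathway anaerobic carbon-flux catalog."""
    ref = resources.files("magflux.data").joinpath(_DEFAULT_CATALOG_RESOURCE)
    with resources.as_file(ref) as path:
        return load_catalog(path)


def dump_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    """Serialize a catalog to YAML; re-loading yields an equal catalog."""
    doc = {
        "pathways": [
            {
                "id": pw.pathway_id,
                "name": pw.name,
                "category": pw.category,
                **(
                    {"threshold": str(pw.presence_threshold)}
                    if pw.presence_threshold != 1
                    else {}
                ),
                "steps": [
                    {
                        "step_id": s.step_id,
                        **({} if s.is_key else {"key": False}),
                        "expr": step_to_expression(s),
                    }
                    for s in pw.steps
                ],
            }
            for pw in catalog
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


@dataclass
class ValidationReport:
    """Report-only result of :func:`validate_catalog`; never mutates input."""

    shared_kos: list[tuple[str, str, list[str]]] = field(default_factory=list)
    no_key_steps: list[str] = field(default_factory=list)
    threshold_exceptions: list[tuple[str, Fraction]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.shared_kos or self.no_key_steps)


def validate_catalog(catalog: PathwayCatalog) -> ValidationReport:
    """Flag KOs reused across steps of one pathway, pathways without key
    steps, and deliberate non-default presence thresholds."""
    report = ValidationReport()
    for pw in catalog:
        ko_steps: dict[str, list[str]] = {}
        for step in pw.steps:
            for ko in sorted(step.required_kos()):
                ko_steps.setdefault(ko, []).append(step.step_id)
        for ko, step_ids in sorted(ko_steps.items()):
            if len(step_ids) > 1:
                report.shared_kos.append((pw.pathway_id, ko, step_ids))
        if not pw.key_steps:
            report.no_key_steps.append(pw.pathway_id)
        if pw.presence_threshold != 1:
            report.threshold_exceptions.append((pw.pathway_id, pw.presence_threshold))
    return report
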