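"""Synthetic methanogenic-community generator with known ground truth.

Emulates the inputs the pipeline consumes — a MAG-labeled ORF catalog,
GhostKOALA-style KO annotations, and per-sample transcript counts — for a
community whose pathway content and activity structure are known by
construction, so presence calling, TPM aggregation and guild ranking can
be validated end to end without sequencing data.

For every pathway a MAG truly encodes, each step receives at least one
gene per required subunit of one uniformly chosen variant, guaranteeing a
complete pathway before annotation dropout. Decoy genes (unannotated or
carrying off-catalog KOs) pad the catalog. Counts are drawn per gene and
sample from a negative binomial with mean proportional to gene length
(so TPM recovers the configured activity structure) scaled by a per-MAG,
per-pathway activity multiplier:

    mean = baseline_mean * length_nt/1000 * multiplier
    Var  = mean + mean^2 / nb_dispersion

All randomness flows from a single seed through hierarchical
``SeedSequence`` streams (community structure per MAG, counts per
sample), so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import PathwayCatalog, PathwayDefinition
from .genes import GeneRecord, GeneTable
from .presence import call_presence

__all__ = ["SimConfig", "SimResult", "SimTruth", "degrade_mag", "simulate_community"]

_PARTIAL_OTHER = ("01", "10", "11")


class SimulationError(ValueError):
    """Raised for infeasible simulation configs."""


@dataclass
class SimConfig:
    """Study-condition knobs for :func:`simulate_community`.

    Defaults mirror a desk-scale anaerobic-digester metatranscriptome:
    a handful of MAGs, three replicate samples per condition, ORF lengths
    of 300-3000 nt, ~86% full-length ORFs, moderately overdispersed
    counts (dispersion 10, i.e. CV^2 adds 0.1 at large means) with a
    baseline of 50 expected counts per kilobase-length gene.
    """

    catalog: PathwayCatalog
    n_mags: int = 8
    presence_profile: Mapping[str, frozenset[str]] | None = None
    pathway_prob: float = 0.3
    annotation_dropout: float = 0.0
    copies_per_ko: tuple[int, int] = (1, 2)
    gene_length_range: tuple[int, int] = (300, 3000)
    activity_multiplier: Mapping[tuple[str, str], float] = field(default_factory=dict)
    baseline_mean: float = 50.0
    nb_dispersion: float = 10.0
    n_samples: int = 2
    n_replicates: int = 3
    n_decoy_genes_per_mag: int = 15
    full_length_prob: float = 0.86
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.annotation_dropout <= 1):
            raise SimulationError("annotation_dropout outside [0, 1]")
        if not (0 <= self.pathway_prob <= 1):
            raise SimulationError("pathway_prob outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be positive")
        if self.n_mags < 1 or self.n_samples < 1 or self.n_replicates < 1:
            raise SimulationError("n_mags, n_samples, n_replicates must be >= 1")
        lo, hi = self.copies_per_ko
        if lo < 1 or hi < lo:
            raise SimulationError("copies_per_ko must be a range with min >= 1")
        lo, hi = self.gene_length_range
        if lo < 3 or hi < lo:
            raise SimulationError("gene_length_range must be a range with min >= 3")


@dataclass
class SimTruth:
    """Ground truth consistent with the emitted files.

    ``presence`` is the presence implied by the pre-dropout KO content
    (profile pathways are complete by construction; shared KOs may make
    further pathways genuinely complete). ``ranking`` orders each
    pathway's encoding MAGs by activity multiplier (descending, ties by
    mag_id). ``gene_means`` are the configured per-gene NB means.
    """

    profile: dict[str, frozenset[str]]
    presence: dict[tuple[str, str], bool]
    ranking: dict[str, list[str]]
    gene_means: pd.Series

    def to_json(self, path: str | Path) -> None:
        doc = {
            "profile": {m: sorted(p) for m, p in self.profile.items()},
            "presence": [
                {"mag_id": m, "pathway_id": p, "present": v}
                for (m, p), v in sorted(self.presence.items())
            ],
            "ranking": self.ranking,
            "gene_means": {g: float(v) for g, v in self.gene_means.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimResult:
    genes: GeneTable
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: SimTruth
    ko_assignments: list[tuple[str, str]]

    def observed_gene_table(self) -> GeneTable:
        """The gene table as the pipeline would see it: post-dropout KO
        labels attached (equivalent to writing and re-ingesting the files)."""
        by_gene: dict[str, list[str]] = {}
        for gene_id, ko in self.ko_assignments:
            by_gene.setdefault(gene_id, []).append(ko)
        return GeneTable(
            GeneRecord(
                r.gene_id,
                r.mag_id,
                r.length_nt,
                r.partial_flag,
                tuple(by_gene.get(r.gene_id, ())),
            )
            for r in self.genes
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit exactly the formats the ingestion modules read."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": out / "genes.tsv",
            "ko": out / "ko.tsv",
            "counts": out / "counts.tsv",
            "samples": out / "samples.tsv",
            "truth": out / "truth.json",
        }
        # Gene table emitted unannotated; KO labels arrive via ko.tsv,
        # mirroring the Prodigal-then-GhostKOALA ingestion route.
        gdf = self.genes.df[["gene_id", "mag_id", "length_nt", "partial"]].copy()
        gdf["ko"] = ""
        gdf.to_csv(paths["genes"], sep="\t", index=False)
        with open(paths["ko"], "w", encoding="utf-8") as fh:
            for gene_id, ko in self.ko_assignments:
                fh.write(f"{gene_id}\t{ko}\n")
        self.counts.to_csv(paths["counts"], sep="\t")
        self.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        return paths


def _draw_profile(config: SimConfig, rng: np.random.Generator) -> dict[str, frozenset[str]]:
    mags = [f"bin.{i + 1}" for i in range(config.n_mags)]
    pathway_ids = config.catalog.pathway_ids
    profile = {}
    for mag in mags:
        mask = rng.random(len(pathway_ids)) < config.pathway_prob
        profile[mag] = frozenset(p for p, m in zip(pathway_ids, mask) if m)
    return profile


def simulate_community(config: SimConfig) -> SimResult:
    """Generate a community with known presence, activity and count truth."""
    root = np.random.SeedSequence(config.seed)
    ss_profile, ss_structure, ss_counts = root.spawn(3)

    if config.presence_profile is not None:
        profile = {m: frozenset(p) for m, p in config.presence_profile.items()}
        unknown = {
            p for paths in profile.values() for p in paths if p not in config.catalog
        }
        if unknown:
            raise SimulationError(f"profile names unknown pathways: {sorted(unknown)}")
    else:
        profile = _draw_profile(config, np.random.default_rng(ss_profile))
    if not profile:
        raise SimulationError("empty presence profile: no MAGs to simulate")

    mags = list(profile)
    lo_c, hi_c = config.copies_per_ko
    lo_l, hi_l = config.gene_length_range
    catalog_kos = {
        ko
        for pw in config.catalog
        for s in pw.steps
        for v in s.variants
        for ko in (*v.required, *v.optional)
    }

    records: list[GeneRecord] = []
    ko_assignments: list[tuple[str, str]] = []
    gene_means: dict[str, float] = {}
    truth_records: list[GeneRecord] = []  # pre-dropout KO content

    mag_seeds = ss_structure.spawn(len(mags))
    for mag, mag_ss in zip(mags, mag_seeds):
        rng = np.random.default_rng(mag_ss)
        counter = 0

        def new_gene(ko: str | None, multiplier: float) -> None:
            nonlocal counter
            counter += 1
            gene_id = f"{mag}_{counter}"
            length = int(rng.integers(lo_l, hi_l + 1))
            if rng.random() < config.full_length_prob:
                partial = "00"
            else:
                partial = _PARTIAL_OTHER[int(rng.integers(0, 3))]
            truth_records.append(
                GeneRecord(gene_id, mag, length, partial, (ko,) if ko else ())
            )
            observed_ko = ko
            if ko is not None and rng.random() < config.annotation_dropout:
                observed_ko = None
            records.append(GeneRecord(gene_id, mag, length, partial, ()))
            if observed_ko is not None:
                ko_assignments.append((gene_id, observed_ko))
            gene_means[gene_id] = (
                config.baseline_mean * length / 1000.0 * multiplier
            )

        for pathway_id in sorted(profile[mag]):
            pw: PathwayDefinition = config.catalog[pathway_id]
            mult = float(config.activity_multiplier.get((mag, pathway_id), 1.0))
            if mult <= 0:
                raise SimulationError(
                    f"activity multiplier for ({mag}, {pathway_id}) must be positive"
                )
            for step in pw.steps:
                variant = step.variants[int(rng.integers(0, len(step.variants)))]
                for ko in variant.required:
                    for _ in range(int(rng.integers(lo_c, hi_c + 1))):
                        new_gene(ko, mult)
        # decoys: half unannotated, half carrying off-catalog KOs
        for d in range(config.n_decoy_genes_per_mag):
            if d % 2 == 0:
                new_gene(None, 1.0)
            else:
                while True:
                    fake = f"K{int(rng.integers(90000, 100000)):05d}"
                    if fake not in catalog_kos:
                        break
                new_gene(fake, 1.0)

    if not records:
        raise SimulationError("config produced zero genes")

    genes = GeneTable(records)
    truth_table = GeneTable(truth_records)

    sample_ids = [
        f"C{c + 1}_r{r + 1}"
        for c in range(config.n_samples)
        for r in range(config.n_replicates)
    ]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": [s.split("_")[0] for s in sample_ids],
            "replicate": [s.split("_r")[1] for s in sample_ids],
        }
    )

    gene_ids = genes.gene_ids
    means = np.array([gene_means[g] for g in gene_ids])
    r = config.nb_dispersion
    p = r / (r + means)
    sample_seeds = ss_counts.spawn(len(sample_ids))
    cols = {}
    for sample_id, s_ss in zip(sample_ids, sample_seeds):
        s_rng = np.random.default_rng(s_ss)
        cols[sample_id] = s_rng.negative_binomial(r, p).astype(float)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    implied = call_presence(truth_table, config.catalog)
    presence = {(c.mag_id, c.pathway_id): c.present for c in implied}

    ranking: dict[str, list[str]] = {}
    for pw in config.catalog:
        encoders = [m for m in mags if pw.pathway_id in profile[m]]
        encoders.sort(
            key=lambda m: (
                -float(config.activity_multiplier.get((m, pw.pathway_id), 1.0)),
                m,
            )
        )
        ranking[pw.pathway_id] = encoders

    truth = SimTruth(
        profile=profile,
        presence=presence,
        ranking=ranking,
        gene_means=pd.Series(gene_means).reindex(gene_ids),
    )
    return SimResult(
        genes=genes,
        counts=counts,
        sample_sheet=sheet,
        truth=truth,
        ko_assignments=ko_assignments,
    )


def degrade_mag(
    table: GeneTable,
    mag_id: str,
    pathway: PathwayDefinition,
    fraction_steps_removed: float,
    seed: int,
) -> GeneTable:
    """Emulate MAG incompleteness: drop all of a MAG's genes for a
    uniformly chosen fraction of one pathway's steps.

    The number of steps removed is ``round(fraction * n_steps)``; genes
    are removed when they carry a KO required by a removed step.
    """
    if not (0 <= fraction_steps_removed <= 1):
        raise SimulationError("fraction_steps_removed outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_remove = int(round(fraction_steps_removed * pathway.n_steps))
    if n_remove == 0:
        return table
    idx = rng.choice(pathway.n_steps, size=n_remove, replace=False)
    doomed_kos = set()
    for i in sorted(idx):
        doomed_kos |= pathway.steps[i].required_kos()
    kept = [
        r
        for r in table
        if not (r.mag_id == mag_id and any(ko in doomed_kos for ko in r.kos))
    ]
    return GeneTable(kept)
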