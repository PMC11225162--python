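"""TPM normalization and gene-to-pathway expression aggregation.

Transcript counts (RSEM-style expected counts) are normalized to
transcripts-per-million within each sample:

    rate_i = count_i / length_i
    TPM_i  = rate_i / sum_j rate_j * 1e6

so every sample column sums to 1e6. Gene-level TPM is then rolled up by
two rules:

1. a step catalyzed by a single enzyme complex takes the arithmetic mean
   of its required subunits' expression (an unexpressed subunit enters
   the mean as 0);
2. multiple enzymes (variants) or multiple gene copies of one enzyme
   are summed.

Pathway-level activity in a MAG is the arithmetic mean of its step
values over ALL steps (silent steps contribute 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import PathwayCatalog, PathwayDefinition, Step
from .genes import GeneTable

__all__ = [
    "ExpressionError",
    "PathwayActivityRecord",
    "compute_tpm",
    "ko_expression",
    "mag_ko_tpm",
    "mag_relative_expression",
    "mag_relative_expression_matrix",
    "pathway_activity_table",
    "pathway_expression",
    "read_counts_matrix",
    "read_rsem_counts",
    "step_expression",
    "step_expression_table",
]

MILLION = 1_000_000.0


class ExpressionError(ValueError):
    """Raised for inconsistent counts, lengths or sample references."""


@dataclass(frozen=True)
class PathwayActivityRecord:
    mag_id: str
    pathway_id: str
    sample_id: str
    value: float
    n_steps: int


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix TSV (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ExpressionError(f"{path}: duplicate gene ids in count matrix")
    if (df.to_numpy() < 0).any():
        raise ExpressionError(f"{path}: negative counts")
    return df.astype(float)


def read_rsem_counts(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Assemble a count matrix from per-sample RSEM-style TSVs.

    ``paths`` maps sample_id -> file with columns
    ``gene_id, length, expected_count``. Genes absent from a sample get 0.
    """
    columns = {}
    for sample_id, path in paths.items():
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        missing = {"gene_id", "expected_count"} - set(df.columns)
        if missing:
            raise ExpressionError(f"{path}: missing columns {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            raise ExpressionError(f"{path}: duplicate gene ids")
        columns[sample_id] = df.set_index("gene_id")["expected_count"].astype(float)
    out = pd.DataFrame(columns).fillna(0.0)
    out.index.name = "gene_id"
    return out


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Normalize a gene x sample count matrix to TPM.

    Every gene in ``counts`` must have a positive length; every sample must
    have at least one positive count (an all-zero column has no defined
    sequencing depth).
    """
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise ExpressionError(f"no length for gene {missing[0]!r}")
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ExpressionError("negative counts")
    lens = lengths.reindex(counts.index).to_numpy(dtype=float)
    if (lens <= 0).any():
        bad = counts.index[np.nonzero(lens <= 0)[0][0]]
        raise ExpressionError(f"non-positive length for gene {bad!r}")
    rates = values / lens[:, None]
    depth = rates.sum(axis=0)
    zero = np.nonzero(depth == 0)[0]
    if zero.size:
        raise ExpressionError(
            f"sample {counts.columns[zero[0]]!r} has all-zero counts"
        )
    tpm = rates / depth[None, :] * MILLION
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def mag_ko_tpm(expr: pd.DataFrame, genes: GeneTable) -> pd.DataFrame:
    """Summed TPM per (mag_id, KO) per sample.

    A gene carrying k KOs contributes its full TPM to each of them.
    Returns a frame indexed by a (mag_id, ko) MultiIndex.
    """
    gdf = genes.df[["gene_id", "mag_id", "kos"]]
    gdf = gdf[gdf["kos"].map(len) > 0]
    if gdf.empty:
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["mag_id", "ko"]),
            columns=expr.columns,
            dtype=float,
        )
    exploded = gdf.explode("kos").rename(columns={"kos": "ko"})
    joined = exploded.join(expr, on="gene_id", how="inner")
    return joined.groupby(["mag_id", "ko"], sort=True)[list(expr.columns)].sum()


def ko_expression(
    mag_id: str,
    ko: str,
    expr: pd.DataFrame,
    genes: GeneTable,
    sample_id: str,
) -> float:
    """Summed TPM over all gene copies of one KO in one MAG (0 if none)."""
    if sample_id not in expr.columns:
        raise ExpressionError(f"unknown sample {sample_id!r}")
    gene_ids = genes.genes_with_ko(mag_id, ko)
    present = [g for g in gene_ids if g in expr.index]
    if not present:
        return 0.0
    return float(expr.loc[present, sample_id].sum())


def _step_value(step: Step, ko_value) -> float:
    """Sum over variants of the mean over each variant's required subunits."""
    total = 0.0
    for variant in step.variants:
        total += sum(ko_value(ko) for ko in variant.required) / len(variant.required)
    return total


def step_expression(
    mag_id: str,
    step: Step,
    expr: pd.DataFrame,
    genes: GeneTable,
    sample_id: str,
) -> float:
    """Step-level TPM: per variant, mean over required subunits (missing
    subunits count 0); variants are summed. Optional subunits are ignored."""
    return _step_value(
        step, lambda ko: ko_expression(mag_id, ko, expr, genes, sample_id)
    )


def pathway_expression(
    mag_id: str,
    pathway: PathwayDefinition,
    expr: pd.DataFrame,
    genes: GeneTable,
    sample_id: str,
) -> PathwayActivityRecord:
    """Pathway activity: mean of step expression over ALL steps."""
    step_values = [
        step_expression(mag_id, s, expr, genes, sample_id) for s in pathway.steps
    ]
    return PathwayActivityRecord(
        mag_id=mag_id,
        pathway_id=pathway.pathway_id,
        sample_id=sample_id,
        value=float(np.mean(step_values)),
        n_steps=len(step_values),
    )


def step_expression_table(
    catalog: PathwayCatalog,
    expr: pd.DataFrame,
    genes: GeneTable,
    mag_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format step expression for every (MAG, pathway, step, sample).

    Vectorized across samples via the (mag, KO) TPM table; equivalent to
    calling :func:`step_expression` per cell.
    """
    ko_tpm = mag_ko_tpm(expr, genes)
    mags = list(mag_ids) if mag_ids is not None else genes.mag_ids
    samples = list(expr.columns)
    zeros = np.zeros(len(samples))

    def lookup(mag: str, ko: str) -> np.ndarray:
        try:
            return ko_tpm.loc[(mag, ko)].to_numpy(dtype=float)
        except KeyError:
            return zeros

    rows = []
    for mag in mags:
        for pw in catalog:
            for step in pw.steps:
                value = np.zeros(len(samples))
                for variant in step.variants:
                    acc = np.zeros(len(samples))
                    for ko in variant.required:
                        acc = acc + lookup(mag, ko)
                    value += acc / len(variant.required)
                for j, sample in enumerate(samples):
                    rows.append(
                        (mag, pw.pathway_id, step.step_id, sample, float(value[j]))
                    )
    return pd.DataFrame(
        rows, columns=["mag_id", "pathway_id", "step_id", "sample_id", "value"]
    )


def pathway_activity_table(
    catalog: PathwayCatalog,
    expr: pd.DataFrame,
    genes: GeneTable,
    mag_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format pathway activity for every (MAG, pathway, sample)."""
    steps = step_expression_table(catalog, expr, genes, mag_ids)
    n_steps = {pw.pathway_id: pw.n_steps for pw in catalog}
    agg = (
        steps.groupby(["mag_id", "pathway_id", "sample_id"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    agg["n_steps"] = agg["pathway_id"].map(n_steps)
    return agg


def mag_relative_expression(
    mag_id: str,
    expr: pd.DataFrame,
    genes: GeneTable,
    sample_id: str,
) -> float:
    """Fraction of a sample's transcriptome attributed to one MAG's genes."""
    if mag_id not in set(genes.mag_ids):
        raise ExpressionError(f"unknown mag_id {mag_id!r}")
    if sample_id not in expr.columns:
        raise ExpressionError(f"unknown sample {sample_id!r}")
    gene_ids = [r.gene_id for r in genes if r.mag_id == mag_id]
    present = [g for g in gene_ids if g in expr.index]
    if not present:
        return 0.0
    return float(expr.loc[present, sample_id].sum()) / MILLION


def mag_relative_expression_matrix(
    expr: pd.DataFrame, genes: GeneTable
) -> pd.DataFrame:
    """MAG x sample matrix of transcriptome fractions (columns sum to 1
    when every expressed gene belongs to some MAG)."""
    owner = genes.df.set_index("gene_id")["mag_id"]
    joined = expr.join(owner, how="inner")
    out = joined.groupby("mag_id", sort=True)[list(expr.columns)].sum() / MILLION
    return out
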