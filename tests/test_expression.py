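"""TPM normalization and the step/pathway aggregation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from magflux.catalog import parse_step_expression, PathwayCatalog, PathwayDefinition
from magflux.expression import (
    MILLION,
    ExpressionError,
    compute_tpm,
    ko_expression,
    mag_relative_expression,
    pathway_activity_table,
    pathway_expression,
    step_expression,
    step_expression_table,
)

from conftest import make_gene_table


def _expr(genes, tpm_by_gene, sample="s1"):
    return pd.DataFrame({sample: pd.Series(tpm_by_gene, dtype=float)})


# ---------------------------------------------------------------- TPM


def test_tpm_single_gene_is_one_million():
    counts = pd.DataFrame({"s1": [17.0]}, index=["g1"])
    tpm = compute_tpm(counts, pd.Series({"g1": 500}))
    assert tpm.loc["g1", "s1"] == pytest.approx(MILLION)


def test_tpm_equal_rates_split_evenly():
    counts = pd.DataFrame({"s1": [10.0, 20.0, 30.0]}, index=["a", "b", "c"])
    lengths = pd.Series({"a": 100, "b": 200, "c": 300})
    tpm = compute_tpm(counts, lengths)
    assert tpm["s1"].to_numpy() == pytest.approx([MILLION / 3] * 3)


def test_tpm_length_normalization():
    counts = pd.DataFrame({"s1": [1.0, 1.0]}, index=["a", "b"])
    tpm = compute_tpm(counts, pd.Series({"a": 100, "b": 300}))
    assert tpm["s1"].to_numpy() == pytest.approx([750_000.0, 250_000.0])


def test_tpm_all_zero_sample_errors():
    counts = pd.DataFrame({"ok": [1.0, 2.0], "dead": [0.0, 0.0]}, index=["a", "b"])
    with pytest.raises(ExpressionError, match="dead"):
        compute_tpm(counts, pd.Series({"a": 100, "b": 100}))


def test_tpm_missing_length_errors():
    counts = pd.DataFrame({"s1": [1.0]}, index=["a"])
    with pytest.raises(ExpressionError, match="'a'"):
        compute_tpm(counts, pd.Series(dtype=float))


@settings(derandomize=True, max_examples=300)
@given(
    st.integers(2, 20),
    st.integers(1, 4),
    st.integers(0, 2**31 - 1),
    st.floats(0.001, 1000.0),
)
def test_tpm_conservation_and_scale_equivariance(n_genes, n_samples, seed, scale):
    """Columns sum to 1e6; rescaling one sample's counts changes nothing."""
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.poisson(20.0, size=(n_genes, n_samples)).astype(float) + rng.random((n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    counts.iloc[0] += 1.0  # guarantee signal in every sample
    lengths = pd.Series(rng.integers(100, 5000, n_genes), index=counts.index)
    tpm = compute_tpm(counts, lengths)
    assert np.allclose(tpm.sum(axis=0), MILLION, rtol=1e-6)
    scaled = counts.copy()
    scaled["s0"] = scaled["s0"] * scale
    tpm2 = compute_tpm(scaled, lengths)
    assert np.allclose(tpm2["s0"], tpm["s0"], rtol=1e-9)


# ------------------------------------------------- KO / step / pathway


def test_ko_expression_sums_copies():
    genes = make_gene_table(
        [
            ("g1", "magA", 100, "00", ("K00001",)),
            ("g2", "magA", 100, "00", ("K00001",)),
            ("g3", "magB", 100, "00", ("K00001",)),
        ]
    )
    expr = _expr(genes, {"g1": 5.0, "g2": 5.0, "g3": 99.0})
    assert ko_expression("magA", "K00001", expr, genes, "s1") == pytest.approx(10.0)
    assert ko_expression("magA", "K99999", expr, genes, "s1") == 0.0
    assert ko_expression("magB", "K00001", expr, genes, "s1") == pytest.approx(99.0)


def test_step_expression_complex_mean():
    """Rule: a complex takes the mean over its required subunits."""
    genes = make_gene_table(
        [
            ("g1", "m", 100, "00", ("K00001",)),
            ("g2", "m", 100, "00", ("K00002",)),
        ]
    )
    expr = _expr(genes, {"g1": 10.0, "g2": 20.0})
    step = parse_step_expression("K00001+K00002")
    assert step_expression("m", step, expr, genes, "s1") == pytest.approx(15.0)


def test_step_expression_variants_sum():
    """Complex mean (10,20)->15 plus summed copies (5,5)->10 gives 25."""
    genes = make_gene_table(
        [
            ("g1", "m", 100, "00", ("K00001",)),
            ("g2", "m", 100, "00", ("K00002",)),
            ("g3", "m", 100, "00", ("K00003",)),
            ("g4", "m", 100, "00", ("K00003",)),
        ]
    )
    expr = _expr(genes, {"g1": 10.0, "g2": 20.0, "g3": 5.0, "g4": 5.0})
    step = parse_step_expression("K00001+K00002,K00003")
    assert step_expression("m", step, expr, genes, "s1") == pytest.approx(25.0)


def test_step_expression_zero_fills_missing_subunit():
    genes = make_gene_table([("g1", "m", 100, "00", ("K00001",))])
    expr = _expr(genes, {"g1": 30.0})
    step = parse_step_expression("K00001+K00002")
    assert step_expression("m", step, expr, genes, "s1") == pytest.approx(15.0)


def test_step_expression_ignores_optional_subunits():
    genes = make_gene_table(
        [
            ("g1", "m", 100, "00", ("K00001",)),
            ("g2", "m", 100, "00", ("K00002",)),
        ]
    )
    expr = _expr(genes, {"g1": 10.0, "g2": 100.0})
    step = parse_step_expression("K00001+-K00002")
    assert step_expression("m", step, expr, genes, "s1") == pytest.approx(10.0)


def _brute_force_step(mag_id, step, genes, tpm, sample):
    """Independent oracle: enumerate (variant, subunit, gene-copy) triples."""
    total = 0.0
    for variant in step.variants:
        subunit_sum = 0.0
        for ko in variant.required:
            for rec in genes:
                if rec.mag_id == mag_id and ko in rec.kos:
                    subunit_sum += tpm[rec.gene_id]
        total += subunit_sum / len(variant.required)
    return total


@settings(derandomize=True, max_examples=300)
@given(st.integers(0, 2**31 - 1))
def test_step_expression_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    ko_pool = [f"K{i:05d}" for i in range(1, 9)]
    n_genes = int(rng.integers(1, 15))
    rows = []
    for i in range(n_genes):
        n_kos = int(rng.integers(0, 3))
        kos = tuple(rng.choice(ko_pool, size=n_kos, replace=False))
        rows.append((f"g{i}", f"m{int(rng.integers(1, 3))}", 100, "00", kos))
    genes = make_gene_table(rows)
    tpm = {f"g{i}": float(rng.gamma(2.0, 50.0)) for i in range(n_genes)}
    expr = _expr(genes, tpm)
    n_variants = int(rng.integers(1, 4))
    variants = []
    for _ in range(n_variants):
        size = int(rng.integers(1, 4))
        variants.append("+".join(rng.choice(ko_pool, size=size, replace=False)))
    step = parse_step_expression(",".join(variants))
    for mag in ("m1", "m2"):
        fast = step_expression(mag, step, expr, genes, "s1")
        slow = _brute_force_step(mag, step, genes, tpm, "s1")
        assert fast == pytest.approx(slow, rel=1e-9, abs=1e-12)


def test_step_expression_monotone_in_new_copies():
    """Adding an expressed copy of a step KO never lowers the step value."""
    base_rows = [("g1", "m", 100, "00", ("K00001",))]
    genes = make_gene_table(base_rows)
    step = parse_step_expression("K00001+K00002,K00003")
    before = step_expression("m", step, _expr(genes, {"g1": 10.0}), genes, "s1")
    for new_ko in ("K00001", "K00002", "K00003"):
        more = make_gene_table(base_rows + [("g2", "m", 100, "00", (new_ko,))])
        after = step_expression(
            "m", step, _expr(more, {"g1": 10.0, "g2": 7.0}), more, "s1"
        )
        assert after >= before


@pytest.mark.parametrize(
    "step_values, expected",
    [((25.0, 15.0, 20.0), 20.0), ((0.0, 0.0, 0.0), 0.0), ((11.0,) + (0.0,) * 10, 1.0)],
)
def test_pathway_expression_is_mean_over_all_steps(step_values, expected):
    """Silent steps enter the pathway mean as zero."""
    rows, tpm = [], {}
    exprs = []
    for i, v in enumerate(step_values):
        ko = f"K{i + 1:05d}"
        exprs.append(ko)
        if v > 0:
            rows.append((f"g{i}", "m", 100, "00", (ko,)))
            tpm[f"g{i}"] = v
    if not rows:  # all-zero pathway still needs a gene universe for TPM
        rows = [("g0", "m", 100, "00", ())]
        tpm = {"g0": 1.0}
    genes = make_gene_table(rows)
    pathway = PathwayDefinition(
        pathway_id="P",
        name="toy",
        category="sugar",
        steps=tuple(
            parse_step_expression(e, step_id=f"s{i}") for i, e in enumerate(exprs)
        ),
    )
    rec = pathway_expression("m", pathway, _expr(genes, tpm), genes, "s1")
    assert rec.value == pytest.approx(expected)
    assert rec.n_steps == len(step_values)


def test_pathway_expression_step_order_invariant():
    genes = make_gene_table(
        [("g1", "m", 100, "00", ("K00001",)), ("g2", "m", 100, "00", ("K00002",))]
    )
    expr = _expr(genes, {"g1": 8.0, "g2": 4.0})
    steps = [
        parse_step_expression("K00001", step_id="a"),
        parse_step_expression("K00002", step_id="b"),
        parse_step_expression("K00003", step_id="c"),
    ]
    fwd = PathwayDefinition("P", "t", "sugar", tuple(steps))
    rev = PathwayDefinition("P", "t", "sugar", tuple(reversed(steps)))
    assert (
        pathway_expression("m", fwd, expr, genes, "s1").value
        == pathway_expression("m", rev, expr, genes, "s1").value
    )


def test_pathway_activity_table_matches_scalar_api(catalog):
    genes = make_gene_table(
        [
            ("g1", "m1", 100, "00", ("K01805",)),  # xylA
            ("g2", "m1", 100, "00", ("K00854",)),  # xylB
            ("g3", "m2", 100, "00", ("K01805",)),
        ]
    )
    expr = pd.DataFrame(
        {"s1": [10.0, 20.0, 5.0], "s2": [1.0, 2.0, 3.0]}, index=["g1", "g2", "g3"]
    )
    table = pathway_activity_table(catalog, expr, genes)
    for _, row in table[table["pathway_id"] == "XYL_ISOM"].iterrows():
        rec = pathway_expression(
            row["mag_id"], catalog["XYL_ISOM"], expr, genes, row["sample_id"]
        )
        assert row["value"] == pytest.approx(rec.value)


# ------------------------------------------------- MAG fractions


def test_mag_relative_expression():
    genes = make_gene_table(
        [
            ("g1", "magA", 100, "00", ()),
            ("g2", "magA", 100, "00", ()),
            ("g3", "magB", 100, "00", ()),
        ]
    )
    expr = _expr(genes, {"g1": 150_000.0, "g2": 50_000.0, "g3": 800_000.0})
    a = mag_relative_expression("magA", expr, genes, "s1")
    b = mag_relative_expression("magB", expr, genes, "s1")
    assert a == pytest.approx(0.2)
    assert a + b == pytest.approx(1.0)
    with pytest.raises(ExpressionError, match="unknown mag_id"):
        mag_relative_expression("nope", expr, genes, "s1")
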