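import pandas as pd
import pytest

from magflux.catalog import load_default_catalog
from magflux.genes import GeneRecord, GeneTable


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def mmc(catalog):
    return catalog["MMC"]


# One variant per MMC step chosen so that no KO is shared between steps
# (K01026 appears in both the activation and dethiolation steps of the
# packaged definition; these choices avoid it).
MMC_DISJOINT_VARIANTS = {
    "propionate_activation": ("K01908",),
    "propionyl_coa_carboxylation": ("K01965", "K01966"),
    "mmc_epimerase": ("K05606",),
    "mmc_mutase": ("K01847",),
    "succinyl_coa_synthetase": ("K01902", "K01903"),
    "succinate_oxidation": ("K00239", "K00240", "K00241"),
    "fumarase": ("K01676",),
    "malate_dh": ("K00024",),
    "oxaloacetate_decarboxylase": ("K01571", "K01572"),
    "pfor": ("K03737",),
    "acetyl_coa_dethiolation": ("K01895",),
}


@pytest.fixture(scope="session")
def mmc_step_kos(mmc):
    return [MMC_DISJOINT_VARIANTS[s.step_id] for s in mmc.steps]


def make_gene_table(rows):
    """Build a GeneTable from (gene_id, mag_id, length, partial, kos) tuples."""
    return GeneTable(GeneRecord(*row) for row in rows)


@pytest.fixture()
def toy_genes():
    return make_gene_table(
        [
            ("g1", "magA", 100, "00", ("K00001",)),
            ("g2", "magA", 200, "00", ("K00002",)),
            ("g3", "magB", 300, "01", ()),
        ]
    )


@pytest.fixture()
def toy_sample_sheet():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "condition": ["H7", "H7", "H7"],
            "replicate": ["1", "2", "3"],
        }
    )
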