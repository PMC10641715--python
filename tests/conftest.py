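import numpy as np
import pandas as pd
import pytest

from rgenescape.datamodel import ExpressionMatrix, GeneAnnotation, LibraryMetadata
from rgenescape.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A compact but structured simulation config used across tests."""
    return SimulationConfig(
        n_genes=400,
        n_r_genes=80,
        n_libraries=24,
        n_bioprojects=3,
        core_fraction=0.0625,   # 5 core genes
        off_fraction=0.20,      # 16 off genes
        n_de_r_genes=10,
        seed=12345,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def toy_matrix(values, gene_ids=None, library_ids=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i + 1}" for i in range(arr.shape[0])]
    libs = library_ids or [f"L{j + 1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=libs))


def toy_annotation(rows) -> GeneAnnotation:
    """rows: (gene_id, chrom, start, end, is_r, is_full)."""
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "is_r_gene", "is_full_length"]
    )
    df["chrom"] = df["chrom"].astype(object).where(df["chrom"].notna(), pd.NA)
    return GeneAnnotation(df)


def toy_metadata(rows) -> LibraryMetadata:
    """rows: dicts with any subset of metadata columns; the rest defaulted."""
    defaults = {
        "bioproject": "BP01",
        "tissue": "leaf",
        "treatment_class": "mock",
        "organism": "none",
        "organism_kingdom": "none",
        "organism_lifecycle": "none",
        "dpi": 0,
        "cultivar_status": "susceptible",
        "seq_layout": "paired",
        "depth_category": 3,
    }
    full = [{**defaults, **r} for r in rows]
    return LibraryMetadata(pd.DataFrame(full)[["library_id", *defaults.keys()]])
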