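import numpy as np
import pandas as pd
import pytest

from isoshift import SimulationConfig, simulate_event_counts, simulate_isoform_matrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_genes=40,
        frac_diu=0.25,
        n_events_per_category={"AFE": 20, "ALE": 20, "RI": 20, "SE": 30, "TandemUTR": 40},
    )


@pytest.fixture(scope="session")
def iso_bundle(small_config):
    quant, sheet, truth = simulate_isoform_matrix(small_config)
    return quant, sheet, truth


@pytest.fixture(scope="session")
def event_bundle(small_config):
    events, annotations, sheet, truth = simulate_event_counts(small_config)
    return events, annotations, sheet, truth


def toy_sheet(n: int) -> pd.DataFrame:
    rows = []
    for i in range(n):
        rows.append((f"ind{i:03d}_ctl", f"ind{i:03d}", "control"))
        rows.append((f"ind{i:03d}_inf", f"ind{i:03d}", "infected"))
    return pd.DataFrame(rows, columns=["sample_id", "individual_id", "condition"])


def toy_quant(tpms_by_gene: dict, sheet: pd.DataFrame) -> pd.DataFrame:
    """Build a TPM matrix where every sample has identical isoform TPMs."""
    rows, idx, genes = [], [], []
    for gene, tpms in tpms_by_gene.items():
        for k, v in enumerate(tpms):
            rows.append([v] * len(sheet))
            idx.append(f"{gene}.i{k}")
            genes.append(gene)
    quant = pd.DataFrame(rows, index=pd.Index(idx, name="isoform_id"),
                         columns=sheet["sample_id"].tolist())
    quant.insert(0, "gene_id", genes)
    return quant


def dirichlet_proportions(rng: np.random.Generator, alpha, n: int) -> np.ndarray:
    return rng.dirichlet(np.asarray(alpha, float), size=n)
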