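import numpy as np
import pytest

from dock1433.core_data import Dataset, LabeledSite, ObservationTable, ProteinRecord
from dock1433.model import ForestConfig
from dock1433.simulate import SimulationConfig, simulate_dataset

#: Letters used for filler sequence (no Ser/Thr, so candidate positions are
#: exactly where tests plant them).
FILLER = "ACDEFGHIKLMNPQRVWY"


def make_protein(pid: str, n_st: int, length: int, rng: np.random.Generator,
                 st_letter: str = "S") -> ProteinRecord:
    """A protein with exactly n_st candidate residues at random positions."""
    letters = rng.choice(list(FILLER), size=length)
    st_pos = rng.choice(length, size=n_st, replace=False)
    letters[st_pos] = st_letter
    return ProteinRecord(pid, "".join(letters))


def separable_dataset(n_proteins: int = 6, n_st: int = 10, seed: int = 0) -> Dataset:
    """Each protein's docking site is its only observed phosphosite, so the
    PTM score separates classes perfectly (1.0 vs 0.0)."""
    rng = np.random.default_rng(seed)
    proteins, labels = {}, []
    table = ObservationTable()
    for i in range(n_proteins):
        pid = f"P{i}"
        protein = make_protein(pid, n_st, 120, rng)
        proteins[pid] = protein
        st_positions = [j + 1 for j, a in enumerate(protein.sequence) if a in "ST"]
        true_pos = int(rng.choice(st_positions))
        table.add(pid, true_pos, protein.sequence[true_pos - 1], 10)
        labels.append(LabeledSite(pid, true_pos, 1))
    ds = Dataset(proteins, table, labels)
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def small_sim() -> Dataset:
    """A small default-structure simulated dataset shared across tests."""
    return simulate_dataset(SimulationConfig(seed=7, n_proteins=12))


@pytest.fixture(scope="session")
def separable() -> Dataset:
    return separable_dataset()


@pytest.fixture()
def fast_forest() -> ForestConfig:
    return ForestConfig(seed=3, n_trees=40, class_balance="downsample")
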