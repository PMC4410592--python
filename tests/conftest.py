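import numpy as np
import pandas as pd
import pytest

from epicase import ControlSummary, MethylationDataset, SimulationConfig, simulate


@pytest.fixture(scope="session")
def worked_example():
    """The textbook case: x*=0.4 against 10 controls with mean 0.5, SD 0.1."""
    return 0.4, ControlSummary(mean=0.5, sd=0.1, n=10)


@pytest.fixture(scope="session")
def sim_dataset():
    """Default synthetic dataset: two imprinted-like DMRs (effects 1.0, 0.5)."""
    return simulate(SimulationConfig(seed=11))


def make_dataset(beta: pd.DataFrame, manifest: pd.DataFrame | None = None,
                 detection_p: pd.DataFrame | None = None,
                 case: str | None = None) -> MethylationDataset:
    """Assemble a MethylationDataset around a beta matrix with simple defaults."""
    if manifest is None:
        manifest = pd.DataFrame(
            {
                "chrom": ["chr1"] * len(beta),
                "pos": np.arange(1, len(beta) + 1) * 100,
                "design_type": ["II"] * len(beta),
            },
            index=beta.index,
        )
    if detection_p is None:
        detection_p = pd.DataFrame(
            np.zeros(beta.shape), index=beta.index, columns=beta.columns
        )
    case = case or beta.columns[0]
    roles = {case: "case", **{s: "control" for s in beta.columns if s != case}}
    return MethylationDataset(manifest, beta, detection_p, roles)
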