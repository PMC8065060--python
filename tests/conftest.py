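import numpy as np
import pandas as pd
import pytest

from dqmotif.registry import ResiduePanel, load_default_registry
from dqmotif.simulate import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return ResiduePanel()


@pytest.fixture(scope="session")
def registry(panel):
    return load_default_registry(panel)


@pytest.fixture(scope="session")
def study_cohort(registry, panel):
    """One study-scale cohort (636 controls / 962 cases) under the default
    generative model, shared across tests."""
    return simulate_cohort(SynthConfig(seed=20240917), registry, panel)


@pytest.fixture(scope="session")
def study_cohort_motifs(study_cohort, registry, panel):
    from dqmotif.motifs import attach_motifs
    return attach_motifs(study_cohort, registry, panel)


def balanced_config(**overrides) -> SynthConfig:
    """A fast-sampling configuration (high baseline prevalence) for
    simulation-heavy tests; effects default to none."""
    defaults = dict(motif_effects={}, baseline_logit=0.0,
                    n_cases=1000, n_controls=1000, rare_motif_rate=0.0, seed=1)
    defaults.update(overrides)
    return SynthConfig(**defaults)


def genotype_frame(status, motif_1, motif_2, **extra) -> pd.DataFrame:
    """Minimal cohort-with-motifs frame for analyses that only need motif
    pairs and status."""
    df = pd.DataFrame({"status": status, "motif_1": motif_1, "motif_2": motif_2})
    for k, v in extra.items():
        df[k] = v
    return df
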