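import numpy as np
import pandas as pd
import pytest

import tracerbudget as tb

MERGE_KEYS = ["treatment", "composition", "replicate", "taxon", "kind", "element", "food"]


def recovered_vs_truth(experiment: tb.SyntheticExperiment) -> pd.DataFrame:
    """Join pipeline-recovered rates against the generator's truth table."""
    results = tb.analyze(
        experiment.measurements, experiment.chambers, experiment.foods, run_anova=False
    )
    merged = results.rates.merge(experiment.truth, on=MERGE_KEYS, how="inner", validate="1:1")
    assert len(merged) == len(experiment.truth)
    return merged


def mean_recovery_errors(
    n_runs: int, base_seed: int, noise_sd_permil: float = 0.2
) -> pd.DataFrame:
    """Per-run mean recovery error for each rate kind x element.

    Each run is an independent experiment (its own control specimens), so
    the spread across runs captures every error source — including the
    control-background offset shared by all replicates within one run.
    """
    rows = []
    for run in range(n_runs):
        cfg = tb.TruthConfig(noise_sd_permil=noise_sd_permil, seed=base_seed + run)
        merged = recovered_vs_truth(tb.generate_experiment(cfg))
        err = merged["value"] - merged["true_rate"]
        for (kind, element), grp in err.groupby([merged["kind"], merged["element"]]):
            rows.append(
                {"run": run, "kind": kind, "element": element, "mean_error": grp.mean()}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def zero_noise_experiment() -> tb.SyntheticExperiment:
    return tb.generate_experiment(tb.TruthConfig(noise_sd_permil=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_experiment() -> tb.SyntheticExperiment:
    """Realistic measurement noise (0.2 permil), the default design (n=3)."""
    return tb.generate_experiment(tb.TruthConfig(noise_sd_permil=0.2, seed=42))


@pytest.fixture(scope="session")
def noisy_analysis(noisy_experiment) -> tb.AnalysisResults:
    return tb.analyze(
        noisy_experiment.measurements,
        noisy_experiment.chambers,
        noisy_experiment.foods,
    )
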