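import numpy as np
import pytest
from hypothesis import settings

import multisyn as m
from multisyn.features import build_combination_matrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

REFERENCE_CONFIG = m.SimConfig(
    n_cell_lines=20, n_genes=100, n_targets=60, n_drugs=10, noise_sd=0.1, seed=1
)


@pytest.fixture(scope="session")
def reference_world():
    return m.generate_world(REFERENCE_CONFIG)


@pytest.fixture(scope="session")
def reference_training(reference_world):
    """Standardized monotherapy samples of the reference world."""
    w = reference_world
    mono, _ = m.generate_responses(w)
    samples, _ = m.assemble_samples(w.profiles(), w.target_map, mono, w.schema)
    std = m.FeatureStandardizer().fit(samples.X)
    return samples, std


@pytest.fixture(scope="session")
def reference_regressor(reference_training):
    """Small conic network fitted on the reference monotherapy samples."""
    samples, std = reference_training
    model = m.DNNRegressor(
        hidden_units=(32, 16), dropout_rate=0.0, optimizer="adam",
        learning_rate=1e-3, batch_size=32, epochs=600, seed=0,
    )
    model.fit(std.transform(samples.X), samples.y_regression)
    return model


@pytest.fixture(scope="session")
def combination_predictions(reference_world, reference_training, reference_regressor):
    """(predicted, true) log-IC50 over all 2-4 drug combinations x cell lines."""
    w = reference_world
    _, std = reference_training
    combos = m.enumerate_combinations(w.drugs, min_size=2, max_size=4)
    _, truth = m.generate_responses(w, combos)
    ids = [c.canonical_id for c in combos]
    preds, trues = [], []
    for cell in w.cell_lines:
        X = build_combination_matrix(w.profiles()[cell], combos, w.target_map, w.schema)
        preds.append(reference_regressor.predict(std.transform(X)))
        cell_truth = truth[truth.cell_line_id == cell].set_index("combination_id")
        trues.append(cell_truth.loc[ids, "true_log_ic50"].to_numpy())
    return np.concatenate(preds), np.concatenate(trues)


@pytest.fixture()
def tiny_world():
    return m.generate_world(m.SimConfig(n_cell_lines=6, n_genes=24, n_targets=12, n_drugs=5,
                                        n_pathways=4, seed=7))
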