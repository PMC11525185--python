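"""Shared fixtures: the reference synthetic grammar, a trained surrogate
activity model (session-scoped; used by design and interpretation tests),
and a closed-form linear scorer for gradient/attribution oracles."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import credesign as cd


class LinearScorer:
    """f(x) = <W, onehot> per cell; exposes the same prediction surface as
    the convolutional model, with exactly known gradients."""

    def __init__(self, weights: np.ndarray):
        self.W = np.asarray(weights, dtype=np.float64)  # (L, 4, C)
        length, _, n_out = self.W.shape
        self.config = SimpleNamespace(
            insert_length=length, n_outputs=n_out,
            cell_names=tuple(f"cell{i}" for i in range(n_out)),
            flank_length=0)

    def predict(self, batch, clamp=None, batch_size=None):
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 2:
            batch = batch[None]
        out = np.einsum("nlb,lbc->nc", batch, self.W)
        if clamp is not None:
            out = np.clip(out, clamp[0], clamp[1])
        return out

    def predict_with_grad(self, batch, d_out_fn):
        out = self.predict(batch)
        d = np.asarray(d_out_fn(out))
        return out, np.einsum("nc,lbc->nlb", d, self.W)


@pytest.fixture(scope="session")
def grammar():
    return cd.default_grammar(seed=7)


@pytest.fixture(scope="session")
def sim_data(grammar):
    """A mid-sized simulated MPRA table with ground-truth annotations."""
    table, anns = cd.simulate_mpra(grammar, 6000, seed=11)
    return table, anns


@pytest.fixture(scope="session")
def surrogate_model(grammar, sim_data):
    """Desk-scale activity model trained on the simulated MPRA."""
    table, _ = sim_data
    split = cd.augment_training(cd.make_split(table))
    cfg = cd.PredictorConfig.desk_scale(tuple(grammar.cell_types), epochs=5)
    model = cd.build_model(cfg, seed=1)
    model, metrics = cd.train(model, split, seed=2)
    model.metadata["val_metrics"] = metrics[-1]
    return model


@pytest.fixture(scope="session")
def linear_scorer_factory():
    return LinearScorer
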