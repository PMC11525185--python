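"""Convolutional sequence-to-activity model.

The architecture has three functional segments: (1) three convolution /
batch-norm / ReLU / max-pool blocks; (2) a fully connected layer applied to
the flattened feature map; (3) independent per-cell-type branches, each a
stack of four linear transforms, producing one log2FC estimate per cell
type.  Inserts (200 nt by default) are padded on both sides with constant
reporter-backbone flanks to the model input length, and predictions for the
padded forward and reverse-complement sequences are averaged.

The default configuration is Basset-family sized (300/200/200 channels,
kernels 19/11/7, pools 3/4/4 at 600 nt input); any consistent configuration
is accepted, and the test suite uses a much smaller one.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .mpra_data import TrainingSplit, cell_types_of
from .seqcore import (OneHotSequence, default_flanks, encode_onehot,
                      random_sequences, reverse_complement)

logger = logging.getLogger(__name__)

DEFAULT_CLAMP = (-2.0, 6.0)


@dataclass
class PredictorConfig:
    input_length: int = 600
    insert_length: int = 200
    n_outputs: int = 3
    cell_names: tuple[str, ...] = ("K562", "HepG2", "SKNSH")
    conv_channels: tuple[int, ...] = (300, 200, 200)
    kernel_sizes: tuple[int, ...] = (19, 11, 7)
    pool_sizes: tuple[int, ...] = (3, 4, 4)
    hidden: int = 300
    branch_hidden: int = 64
    branch_depth: int = 4
    dropout: float = 0.1
    batch_size: int = 128
    epochs: int = 10
    learning_rate: float = 3e-3
    loss: str = "mse"

    def __post_init__(self) -> None:
        if len(self.cell_names) != self.n_outputs:
            self.cell_names = tuple(f"cell{i}" for i in range(self.n_outputs))
        if not (len(self.conv_channels) == len(self.kernel_sizes) == len(self.pool_sizes)):
            raise ValueError("conv stack specs must have equal lengths")
        if self.flatten_size() < 1:
            raise ValueError("conv/pool arithmetic collapses the sequence to length 0; "
                             "reduce kernel or pool sizes or increase input_length")

    @property
    def flank_length(self) -> int:
        pad = self.input_length - self.insert_length
        if pad < 0 or pad % 2:
            raise ValueError("input_length - insert_length must be a non-negative even number")
        return pad // 2

    def conv_out_length(self) -> int:
        l = self.input_length
        for k, p in zip(self.kernel_sizes, self.pool_sizes):
            l = l - k + 1
            if l < 1:
                raise ValueError(f"conv kernel {k} does not fit remaining length")
            l //= p
        return l

    def flatten_size(self) -> int:
        return self.conv_out_length() * self.conv_channels[-1]

    @classmethod
    def desk_scale(cls, cell_names: tuple[str, ...] = ("cellA", "cellB", "cellC"),
                   **overrides) -> "PredictorConfig":
        """A small configuration sized for single-CPU work: same three-segment
        architecture, short flanks and modest channel counts."""
        base = dict(input_length=230, insert_length=200,
                    n_outputs=len(cell_names), cell_names=tuple(cell_names),
                    conv_channels=(32, 32, 64), kernel_sizes=(11, 7, 5),
                    pool_sizes=(3, 4, 2), hidden=96, branch_hidden=32,
                    branch_depth=4, dropout=0.1, batch_size=256, epochs=6,
                    learning_rate=5e-3, loss="weighted_mse")
        base.update(overrides)
        return cls(**base)


def build_network(config: PredictorConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in = 4
    for c_out, k, p in zip(config.conv_channels, config.kernel_sizes, config.pool_sizes):
        layers += [nn.Conv1d(c_in, c_out, k, rng), nn.BatchNorm1d(c_out),
                   nn.ReLU(), nn.MaxPool1d(p)]
        c_in = c_out
    layers += [nn.Flatten(), nn.Linear(config.flatten_size(), config.hidden, rng),
               nn.ReLU(), nn.Dropout(config.dropout, rng)]
    branches = []
    for _ in range(config.n_outputs):
        stack: list[nn.Layer] = []
        d = config.hidden
        for depth in range(config.branch_depth - 1):
            # leaky activation: narrow branches die under plain ReLU
            stack += [nn.Linear(d, config.branch_hidden, rng), nn.LeakyReLU(),
                      nn.Dropout(config.dropout, rng)]
            d = config.branch_hidden
        stack.append(nn.Linear(d, 1, rng))
        branches.append(nn.Sequential(stack))
    layers.append(nn.BranchedHeads(branches))
    return nn.Sequential(layers)


class PredictorModel:
    """A built (possibly trained) activity predictor.

    In eval mode the model is a deterministic function of its input batch.
    ``predict`` accepts insert-length sequences and handles flank padding,
    strand averaging and optional clamping; ``forward_padded`` /
    ``input_grad`` expose the raw differentiable interface used by the
    sequence designers and by attribution.
    """

    def __init__(self, config: PredictorConfig, seed: int = 0,
                 flanks: tuple[str, str] | None = None):
        self.config = config
        self.seed = seed
        self.net = build_network(config, np.random.default_rng(seed))
        fl = config.flank_length
        if flanks is None:
            if fl > 0:
                f5, f3 = default_flanks(fl)
                flanks = (f5.decode(), f3.decode())
            else:
                flanks = ("", "")
        if len(flanks[0]) != fl or len(flanks[1]) != fl:
            raise ValueError(f"flanks must each have length {fl}")
        self.flanks = flanks
        self._flank5 = (encode_onehot(flanks[0]).matrix if fl else
                        np.zeros((0, 4), dtype=np.float32))
        self._flank3 = (encode_onehot(flanks[1]).matrix if fl else
                        np.zeros((0, 4), dtype=np.float32))
        self.metadata: dict = {"seed": seed}

    # -- input plumbing ----------------------------------------------------

    def _to_array(self, inserts) -> np.ndarray:
        if isinstance(inserts, np.ndarray):
            arr = inserts.astype(np.float32, copy=False)
            if arr.ndim == 2:
                arr = arr[None]
        else:
            mats = []
            for s in inserts:
                if isinstance(s, str):
                    s = encode_onehot(s)
                mats.append(s.matrix)
            arr = np.stack(mats)
        if arr.shape[1] != self.config.insert_length:
            raise ValueError(f"insert length {arr.shape[1]} does not match the model "
                             f"contract ({self.config.insert_length})")
        return arr

    def pad_batch(self, inserts: np.ndarray) -> np.ndarray:
        """(N, insert, 4) -> (N, input_length, 4) with constant flanks."""
        n = inserts.shape[0]
        f5 = np.broadcast_to(self._flank5, (n,) + self._flank5.shape)
        f3 = np.broadcast_to(self._flank3, (n,) + self._flank3.shape)
        return np.concatenate([f5, inserts, f3], axis=1)

    # -- forward / backward ------------------------------------------------

    def forward_padded(self, padded: np.ndarray, train: bool = False) -> np.ndarray:
        """Single-orientation forward pass on (N, L, 4) padded batches."""
        return self.net.forward(np.ascontiguousarray(padded.transpose(0, 2, 1)), train=train)

    def backward_to_input(self, d_out: np.ndarray) -> np.ndarray:
        """Backprop d_out (N, n_outputs) through the last forward pass;
        returns gradients on the padded one-hot input, (N, L, 4)."""
        dx = self.net.backward(d_out.astype(np.float32, copy=False))
        return dx.transpose(0, 2, 1)

    def predict(self, inserts, clamp: tuple[float, float] | None = None,
                batch_size: int = 512) -> np.ndarray:
        """rc-averaged activity predictions, (N, n_outputs).

        Each insert is flank-padded; the model is applied to the padded
        sequence and its reverse complement and the two outputs averaged.
        """
        arr = self._to_array(inserts)
        outs = []
        for i in range(0, len(arr), batch_size):
            chunk = arr[i:i + batch_size]
            fwd = self.forward_padded(self.pad_batch(chunk))
            rev = self.forward_padded(self.pad_batch(reverse_complement(chunk)))
            outs.append(0.5 * (fwd + rev))
        out = np.concatenate(outs) if outs else np.zeros((0, self.config.n_outputs))
        if clamp is not None:
            out = np.clip(out, clamp[0], clamp[1])
        return out

    def predict_with_grad(self, inserts: np.ndarray, d_out_fn) -> tuple[np.ndarray, np.ndarray]:
        """Forward + backward in one call for design/attribution.

        ``d_out_fn(outputs) -> d_out`` supplies the gradient of the scalar
        objective with respect to the rc-averaged outputs.  Returns
        (outputs, gradient w.r.t. the *insert* one-hot, shape (N, insert, 4)).
        """
        arr = self._to_array(inserts)
        fl = self.config.insert_length
        f0 = self.config.flank_length
        padded = self.pad_batch(arr)
        fwd = self.forward_padded(padded)
        rev_padded = self.pad_batch(reverse_complement(arr))
        rev = self.forward_padded(rev_padded)
        out = 0.5 * (fwd + rev)
        d_out = np.asarray(d_out_fn(out), dtype=np.float32)
        # rc pass gradient (last forward was the rc orientation); map the
        # insert-region gradient back to forward coordinates
        g_rev = self.backward_to_input(0.5 * d_out)[:, f0:f0 + fl, :]
        g_rev = reverse_complement(g_rev)
        # fwd pass gradient: re-run forward to restore caches, then backward
        self.forward_padded(padded)
        g_fwd = self.backward_to_input(0.5 * d_out)[:, f0:f0 + fl, :]
        return out, g_fwd + g_rev

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        state = {f"param_{i}": p.value for i, p in enumerate(self.net.params())}
        bn_state = {}
        i = 0
        for layer in _iter_layers(self.net):
            if isinstance(layer, nn.BatchNorm1d):
                bn_state[f"bn_mean_{i}"] = layer.running_mean
                bn_state[f"bn_var_{i}"] = layer.running_var
                i += 1
        meta = json.dumps({"config": asdict(self.config), "seed": self.seed,
                           "flanks": self.flanks, "metadata": self.metadata})
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state, **bn_state)

    @classmethod
    def load(cls, path: str | Path) -> "PredictorModel":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        cfg = meta["config"]
        for key in ("cell_names", "conv_channels", "kernel_sizes", "pool_sizes"):
            cfg[key] = tuple(cfg[key])
        model = cls(PredictorConfig(**cfg), seed=meta["seed"], flanks=tuple(meta["flanks"]))
        for i, p in enumerate(model.net.params()):
            p.value[...] = data[f"param_{i}"]
        i = 0
        for layer in _iter_layers(model.net):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = data[f"bn_mean_{i}"]
                layer.running_var[...] = data[f"bn_var_{i}"]
                i += 1
        model.metadata = meta.get("metadata", {})
        return model


def _iter_layers(layer: nn.Layer):
    yield layer
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    if isinstance(layer, nn.BranchedHeads):
        for b in layer.branches:
            yield from _iter_layers(b)


def build_model(config: PredictorConfig, seed: int = 0,
                flanks: tuple[str, str] | None = None) -> PredictorModel:
    """Deterministic model construction under a fixed seed."""
    return PredictorModel(config, seed=seed, flanks=flanks)


# ---------------------------------------------------------------------------
# training


def _encode_table(table: pd.DataFrame, cells: list[str]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([encode_onehot(s).matrix for s in table["sequence"]])
    y = table[[f"log2fc_{c}" for c in cells]].to_numpy(dtype=np.float32)
    return x, y


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def train(model: PredictorModel, split: TrainingSplit,
          epochs: int | None = None, batch_size: int | None = None,
          learning_rate: float | None = None, seed: int = 0,
          verbose: bool = False) -> tuple[PredictorModel, list[dict]]:
    """Fit the model by minimizing MSE on the (augmented) training split.

    The parameter state with the best validation loss across epochs is
    restored at the end (early model selection).  Returns the model and a
    per-epoch metrics log including per-cell-type validation Pearson r.
    """
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    batch_size = cfg.batch_size if batch_size is None else batch_size
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    cells = list(cfg.cell_names)
    present = cell_types_of(split.train)
    if set(cells) != set(present):
        if len(present) == cfg.n_outputs:
            cells = present
        else:
            raise ValueError(f"split has cell types {present}, model expects {cells}")

    metrics: list[dict] = []
    if epochs == 0:
        return model, metrics

    x_train, y_train = _encode_table(split.train, cells)
    x_val, y_val = (None, None)
    if len(split.val):
        x_val, y_val = _encode_table(split.val, cells)

    # per-cell loss weights: inverse label variance (normalized), so low
    # dynamic-range cell types are not drowned out in the multi-task loss
    if cfg.loss == "weighted_mse":
        v = y_train.var(axis=0)
        wts = (1.0 / np.maximum(v, 1e-6)).astype(np.float32)
        wts *= len(wts) / wts.sum()
    else:
        wts = np.ones(y_train.shape[1], dtype=np.float32)

    opt = nn.Adam(model.net.params(), lr=lr)
    rng = np.random.default_rng(seed)
    best_val = np.inf
    best_state = None
    n = len(x_train)
    total_steps = max(1, epochs * ((n + batch_size - 1) // batch_size))
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            xb = model.pad_batch(x_train[idx])
            yb = y_train[idx]
            opt.zero_grad()
            out = model.forward_padded(xb, train=True)
            diff = out - yb
            loss = float((wts * diff ** 2).mean())
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}, step {step}; "
                                   f"output range [{np.nanmin(out)}, {np.nanmax(out)}]")
            model.net.backward((2.0 / diff.size) * (wts * diff))
            opt.step(nn.cosine_lr(step, total_steps, lr, lr * 1e-2, flat_frac=0.4))
            ep_loss += loss * len(idx)
            step += 1
        entry = {"epoch": epoch, "train_loss": ep_loss / n}
        if x_val is not None:
            pred = model.predict(x_val)
            val_loss = float(((pred - y_val) ** 2).mean())
            entry["val_loss"] = val_loss
            for j, c in enumerate(cells):
                r = _pearson(pred[:, j], y_val[:, j])
                if np.isnan(r):
                    warnings.warn(f"validation Pearson r undefined for {c} "
                                  "(constant predictions or targets)")
                entry[f"val_r_{c}"] = r
            if val_loss < best_val:
                best_val = val_loss
                best_state = nn.get_state(model.net)
        if verbose:
            logger.info("epoch %s: %s", epoch, entry)
        metrics.append(entry)
    if best_state is not None:
        nn.set_state(model.net, best_state)
    model.metadata["trained_epochs"] = epochs
    model.metadata["n_train"] = int(n)
    return model, metrics


# ---------------------------------------------------------------------------
# genome scanning


def genome_scan(model: PredictorModel, fasta: str | Path, window: int = 200,
                stride: int = 50, objective=None, target_cell: int = 0,
                clamp: tuple[float, float] = DEFAULT_CLAMP,
                skip_n: bool = False, top_k: int | None = None,
                batch_size: int = 512) -> pd.DataFrame:
    """Tile every contig of a FASTA into windows and rank them by objective.

    The default objective is the bent-MinGap for ``target_cell`` computed on
    clamped rc-averaged predictions.  Windows containing N score with those
    rows as zeros unless ``skip_n``.  Contigs shorter than the window are
    skipped with a log entry.
    """
    from pyfaidx import Fasta

    from .objectives import bent_min_gap_batch

    if objective is None:
        def objective(acts):
            return bent_min_gap_batch(acts, target_cell, clamp=clamp)

    fa = Fasta(str(fasta))
    rows = []
    for name in fa.keys():
        contig = str(fa[name][:].seq).upper()
        if len(contig) < window:
            logger.info("contig %s shorter than window (%d < %d); skipped",
                        name, len(contig), window)
            continue
        starts = list(range(0, len(contig) - window + 1, stride))
        for i in range(0, len(starts), batch_size):
            chunk = starts[i:i + batch_size]
            seqs, kept = [], []
            for s in chunk:
                sub = contig[s:s + window]
                if skip_n and "N" in sub:
                    continue
                seqs.append(encode_onehot(sub).matrix)
                kept.append(s)
            if not seqs:
                continue
            acts = model.predict(np.stack(seqs), clamp=clamp)
            scores = objective(acts)
            for s, act, sc in zip(kept, acts, scores):
                row = {"chrom": name, "start": s, "end": s + window, "score": float(sc)}
                for j, c in enumerate(model.config.cell_names):
                    row[f"pred_{c}"] = float(act[j])
                rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
        if top_k is not None:
            table = table.head(top_k)
    return table
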