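"""Attribution and motif semantics.

Contribution scores come from sampled integrated gradients (SIG): expected
gradients along the straight path in log-probability (logit) space from the
uniform background (the zero matrix) to a scaled one-hot endpoint.  At each
path point the logits are softmaxed into a position probability matrix,
one-hot sequences are sampled from it, and gradients are backpropagated
through the sampling with the straight-through estimator.  Averaging the
gradients over samples and path points and scaling by the path displacement
yields *hypothetical* scores for all four bases at every position; masking
with the observed one-hot gives the per-base contribution track.

On top of the maps: contribution-block calling and ablation,
pattern-to-PWM conversion, a contribution-space motif scanner (Pearson
correlation of map windows against a motif's contribution weight matrix),
motif-level effect summaries, co-occurrence, NMF motif programs, and
saturation-mutagenesis effect maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import nn
from .seqcore import MotifModel, OneHotSequence, reverse_complement
from .designers import _sample_categorical

logger = logging.getLogger(__name__)


@dataclass
class ContributionMap:
    """Per-cell hypothetical and masked contribution scores for one sequence."""

    hypothetical: np.ndarray   # (n_cells, L, 4)
    masked: np.ndarray         # (n_cells, L, 4); hypothetical * one-hot
    seq_id: str = ""
    cell_names: tuple[str, ...] = ()

    @property
    def per_position(self) -> np.ndarray:
        """Masked scores summed over the base axis, (n_cells, L)."""
        return self.masked.sum(axis=2)


def sampled_integrated_gradients(
    model,
    seq,
    n_path_points: int = 16,
    samples_per_point: int = 8,
    scale: float = 8.0,
    seed: int = 0,
) -> ContributionMap:
    """SIG contribution map of one insert-length sequence, per cell type.

    ``scale`` sets the one-hot endpoint of the logit-space path (softmax of
    scale * one-hot concentrates ~99.9% of mass on the observed base).
    Path points use the midpoint rule; a batch of categorical samples is
    drawn at each point.  Deterministic under a fixed seed.
    """
    if isinstance(seq, OneHotSequence):
        onehot, name = seq.matrix, seq.name
    elif isinstance(seq, str):
        from .seqcore import encode_onehot

        onehot, name = encode_onehot(seq).matrix, ""
    else:
        onehot, name = np.asarray(seq, dtype=np.float32), ""
    length = onehot.shape[0]
    n_cells = model.config.n_outputs
    rng = np.random.default_rng(seed)

    alphas = (np.arange(n_path_points) + 0.5) / n_path_points
    # sample the whole path once; reuse the same batch for every cell type
    probs = nn.softmax(alphas[:, None, None] * scale * onehot[None], axis=-1)
    reps = np.repeat(probs, samples_per_point, axis=0)          # (K*S, L, 4)
    samples = _sample_categorical(reps, rng)

    hyp = np.zeros((n_cells, length, 4), dtype=np.float64)
    for c in range(n_cells):
        sel = np.zeros((len(samples), n_cells), dtype=np.float32)
        sel[:, c] = 1.0
        _, g = model.predict_with_grad(samples, lambda out: sel)
        if not np.all(np.isfinite(g)):
            bad = int(np.argwhere(~np.isfinite(g))[0][0])
            raise FloatingPointError(f"non-finite gradient at path sample {bad}")
        # straight-through to the probabilities, then through the softmax
        g_z = nn.softmax_backward(reps, g.astype(np.float64), axis=-1)
        hyp[c] = scale * g_z.mean(axis=0)
    masked = hyp * onehot[None]
    return ContributionMap(hypothetical=hyp, masked=masked, seq_id=name,
                           cell_names=tuple(model.config.cell_names))


# ---------------------------------------------------------------------------
# contribution blocks


@dataclass
class ContributionBlock:
    start: int
    end: int            # half-open
    sign: str           # '+' or '-'
    mean_score: float   # mean smoothed score inside the block
    cell: str = ""


def call_blocks(scores: np.ndarray, sigma: float = 1.15, thresh: float = 0.015,
                min_run: int = 4, cell: str = "") -> list[ContributionBlock]:
    """Gaussian-smooth a per-position score track and call contiguous
    blocks: positive where the smoothed signal exceeds ``thresh`` for at
    least ``min_run`` positions, negative where it falls below ``-thresh``
    likewise."""
    scores = np.asarray(scores, dtype=float)
    smooth = gaussian_filter1d(scores, sigma=sigma, mode="reflect")
    blocks: list[ContributionBlock] = []
    for sign, mask in (("+", smooth > thresh), ("-", smooth < -thresh)):
        start = None
        for i, m in enumerate(np.append(mask, False)):
            if m and start is None:
                start = i
            elif not m and start is not None:
                if i - start >= min_run:
                    blocks.append(ContributionBlock(
                        start=start, end=i, sign=sign,
                        mean_score=float(smooth[start:i].mean()), cell=cell))
                start = None
    blocks.sort(key=lambda b: (b.start, b.sign))
    return blocks


def _randomize_positions(onehot: np.ndarray, positions: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    out = onehot.copy()
    out[positions] = 0.0
    out[positions, rng.integers(0, 4, len(positions))] = 1.0
    return out


def ablate_blocks(
    model,
    seq,
    blocks: list[ContributionBlock],
    mode: str = "positive",
    n_random: int = 1,
    seed: int = 0,
    min_outside: int = 5,
) -> pd.DataFrame:
    """Replace block (or matched outside) positions with uniform-random
    bases and report the prediction change, averaged over ``n_random``
    independent randomizations.

    Modes: ``positive`` / ``negative`` disrupt the blocks of that sign;
    ``outside`` samples positions not covered by any block, with coverage
    matched to the upper half of the block-coverage distribution (at least
    ``min_outside`` positions; recorded as skipped when infeasible).
    """
    if isinstance(seq, OneHotSequence):
        onehot = seq.matrix
    else:
        onehot = np.asarray(seq, dtype=np.float32)
    length = onehot.shape[0]
    rng = np.random.default_rng(seed)
    cells = list(model.config.cell_names)
    base = model.predict(onehot[None])[0]
    rows = []
    if mode in ("positive", "negative"):
        sign = "+" if mode == "positive" else "-"
        chosen = [b for b in blocks if b.sign == sign]
        for b in chosen:
            positions = np.arange(b.start, b.end)
            deltas = np.zeros(len(cells))
            for _ in range(n_random):
                disrupted = _randomize_positions(onehot, positions, rng)
                deltas += model.predict(disrupted[None])[0] - base
            row = {"mode": mode, "start": b.start, "end": b.end,
                   "n_positions": len(positions)}
            for j, c in enumerate(cells):
                row[f"delta_{c}"] = deltas[j] / n_random
            rows.append(row)
    elif mode == "outside":
        covered = np.zeros(length, dtype=bool)
        sizes = []
        for b in blocks:
            covered[b.start:b.end] = True
            sizes.append(b.end - b.start)
        free = np.flatnonzero(~covered)
        if sizes:
            upper = [s for s in sorted(sizes) if s >= np.median(sizes)]
            target = int(np.mean(upper))
        else:
            target = min_outside
        target = max(target, min_outside)
        if len(free) < target:
            logger.info("outside ablation skipped: %d free positions < %d",
                        len(free), target)
            return pd.DataFrame(rows)
        positions = rng.choice(free, size=target, replace=False)
        deltas = np.zeros(len(cells))
        for _ in range(n_random):
            disrupted = _randomize_positions(onehot, positions, rng)
            deltas += model.predict(disrupted[None])[0] - base
        row = {"mode": mode, "start": -1, "end": -1, "n_positions": target}
        for j, c in enumerate(cells):
            row[f"delta_{c}"] = deltas[j] / n_random
        rows.append(row)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pattern -> PWM


def pattern_to_pwm(pattern: np.ndarray, polarity: str = "positive",
                   motif_id: str = "pattern") -> MotifModel:
    """Convert a contribution-space pattern into a motif model.

    Positive patterns: scores are divided by the maximum position score sum
    and multiplied by 10; the PPM is the row-wise softmax.  Negative
    patterns first flip the sign of their negative-contribution portions,
    compensating the (typically smaller) magnitude by a factor 1.2.  The
    original pattern is retained as the motif's CWM.
    """
    pattern = np.asarray(pattern, dtype=float)
    if not np.any(pattern):
        raise ValueError("all-zero pattern")
    work = pattern.copy()
    if polarity == "negative":
        row_sums = work.sum(axis=1)
        work[row_sums < 0] *= -1.2
    elif polarity != "positive":
        raise ValueError("polarity must be 'positive' or 'negative'")
    denom = np.abs(work.sum(axis=1)).max()
    scaled = 10.0 * work / denom
    ppm = nn.softmax(scaled, axis=-1)
    return MotifModel(ppm, id=motif_id, cwm=pattern, source="discovered")


# ---------------------------------------------------------------------------
# contribution-score motif scan


def _window_pearson(maps: np.ndarray, cwm: np.ndarray) -> np.ndarray:
    """Pearson r between every length-w window of (n, L, 4) maps and the
    (w, 4) cwm; zero-variance windows yield NaN."""
    w = cwm.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(maps, w, axis=1)
    # windows: (n, P, 4, w) -> flatten feature axis in (w, 4) order
    x = windows.transpose(0, 1, 3, 2).reshape(windows.shape[0], windows.shape[1], w * 4)
    y = cwm.reshape(-1)
    d = w * 4
    mx = x.mean(axis=2)
    my = y.mean()
    cov = x @ y / d - mx * my
    vx = (x ** 2).mean(axis=2) - mx ** 2
    vy = float(y.var())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    r[vx <= 0] = np.nan
    return r


def contribution_motif_scan(
    motifs: list[MotifModel],
    maps: list[ContributionMap],
    pad: int = 5,
    r_cap: float = 0.75,
    sd_mult: float = 4.0,
    sample_n: int = 500_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Scan hypothetical contribution maps for motif instances.

    Each map is zero-padded by ``pad`` on both sides; every window is
    correlated (Pearson) with each motif's CWM in both orientations.  Per
    (cell, motif), up to ``sample_n`` coefficients are sampled to set the
    hit threshold min(r_cap, mu + sd_mult * sigma).  Returns a DataFrame
    with columns seq_id, cell, motif_id, start, end, strand, r (coordinates
    clipped to the unpadded sequence).
    """
    if not maps:
        return pd.DataFrame(columns=["seq_id", "cell", "motif_id", "start",
                                     "end", "strand", "r"])
    n_cells, length, _ = maps[0].hypothetical.shape
    cells = maps[0].cell_names or tuple(str(i) for i in range(n_cells))
    rng = np.random.default_rng(seed)
    padded = np.zeros((len(maps), n_cells, length + 2 * pad, 4))
    for i, m in enumerate(maps):
        padded[i, :, pad:pad + length, :] = m.hypothetical
    seq_ids = [m.seq_id or str(i) for i, m in enumerate(maps)]
    rows = []
    for motif in motifs:
        if motif.cwm is None:
            raise ValueError(f"motif {motif.id} has no cwm")
        w = motif.cwm.shape[0]
        if w > length + 2 * pad:
            raise ValueError(f"motif {motif.id} longer than padded maps")
        rc_cwm = reverse_complement(motif.cwm)
        for ci in range(n_cells):
            cellmaps = padded[:, ci]
            r_fwd = _window_pearson(cellmaps, motif.cwm)
            r_rev = _window_pearson(cellmaps, rc_cwm)
            allr = np.concatenate([r_fwd.ravel(), r_rev.ravel()])
            allr = allr[np.isfinite(allr)]
            if len(allr) == 0:
                continue
            if len(allr) > sample_n:
                allr = rng.choice(allr, size=sample_n, replace=False)
            thr = min(r_cap, float(allr.mean() + sd_mult * allr.std()))
            for strand, rmat in (("+", r_fwd), ("-", r_rev)):
                hit_i, hit_p = np.nonzero(np.nan_to_num(rmat, nan=-np.inf) >= thr)
                for si, p in zip(hit_i, hit_p):
                    rows.append({"seq_id": seq_ids[si], "cell": cells[ci],
                                 "motif_id": motif.id,
                                 "start": max(0, int(p) - pad),
                                 "end": min(length, int(p) - pad + w),
                                 "strand": strand,
                                 "r": float(rmat[si, p])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# motif-level model probes


def motif_embed_background(model, motif: MotifModel, n: int = 5000,
                           seed: int = 0, length: int | None = None) -> dict:
    """Predicted standalone effect of a motif embedded in random background.

    Builds a length x 4 PPM that is uniform except for the motif PPM
    centered, samples ``n`` sequences from it and from the all-uniform
    baseline, and reports per-cell-type means and their difference.
    """
    from .seqcore import sample_onehot

    length = length or model.config.insert_length
    if motif.width > length:
        raise ValueError("motif wider than the sequence length")
    rng = np.random.default_rng(seed)
    ppm = np.full((length, 4), 0.25)
    start = (length - motif.width) // 2
    ppm[start:start + motif.width] = motif.ppm
    with_motif = model.predict(sample_onehot(ppm, n, rng))
    baseline = model.predict(sample_onehot(np.full((length, 4), 0.25), n, rng))
    return {
        "cells": list(model.config.cell_names),
        "mean_with_motif": with_motif.mean(axis=0),
        "mean_baseline": baseline.mean(axis=0),
        "delta": with_motif.mean(axis=0) - baseline.mean(axis=0),
        "se": np.sqrt(with_motif.var(axis=0) / n + baseline.var(axis=0) / n),
    }


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def motif_ablation(model, sequences: dict[str, np.ndarray],
                   hits: pd.DataFrame, n_random: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """Predicted effect of replacing all instances of a motif with random
    segments; overlapping hits are merged before replacement.

    ``sequences`` maps seq_id to (L, 4) one-hot; ``hits`` is a scan table
    for a single motif (or pre-filtered).  Each sequence with at least one
    hit is disrupted ``n_random`` times with independent random segments;
    the averaged prediction minus the original gives the effect.
    """
    rng = np.random.default_rng(seed)
    cells = list(model.config.cell_names)
    rows = []
    for seq_id, group in hits.groupby("seq_id", sort=True):
        if seq_id not in sequences:
            continue
        onehot = np.asarray(sequences[seq_id], dtype=np.float32)
        spans = _merge_spans([(int(r.start), int(r.end)) for r in group.itertuples()])
        positions = np.concatenate([np.arange(s, e) for s, e in spans])
        base = model.predict(onehot[None])[0]
        acc = np.zeros(len(cells))
        for _ in range(n_random):
            acc += model.predict(_randomize_positions(onehot, positions, rng)[None])[0]
        row = {"seq_id": seq_id, "n_positions": len(positions)}
        for j, c in enumerate(cells):
            row[f"delta_{c}"] = acc[j] / n_random - base[j]
        rows.append(row)
    return pd.DataFrame(rows)


def motif_contribution_summary(hits: pd.DataFrame,
                               maps: dict[str, ContributionMap]) -> pd.DataFrame:
    """Per-motif, per-cell weighted mean contribution and directionality.

    For every hit, the masked contribution scores inside its span (for the
    hit's cell) are summed; per (motif, cell) the instance sums are averaged
    with the hit correlation coefficients as weights.  Directionality is
    the sign of the mean of the weighted averages across cells.
    """
    rows = []
    if len(hits) == 0:
        return pd.DataFrame(rows)
    all_cells = list(dict.fromkeys(hits["cell"]))
    for motif_id, mgroup in hits.groupby("motif_id", sort=True):
        entry: dict = {"motif_id": motif_id}
        cell_means = []
        for cell in all_cells:
            sub = mgroup[mgroup["cell"] == cell]
            if len(sub) == 0:
                entry[f"contribution_{cell}"] = np.nan
                continue
            sums, weights = [], []
            for h in sub.itertuples():
                cmap = maps.get(h.seq_id)
                if cmap is None:
                    continue
                ci = cmap.cell_names.index(cell) if cmap.cell_names else int(cell)
                sums.append(cmap.masked[ci, h.start:h.end].sum())
                weights.append(h.r)
            if not sums:
                entry[f"contribution_{cell}"] = np.nan
                continue
            wmean = float(np.average(sums, weights=weights))
            entry[f"contribution_{cell}"] = wmean
            cell_means.append(wmean)
        mean_all = np.nanmean([entry[f"contribution_{c}"] for c in all_cells])
        entry["directionality"] = "activator" if mean_all > 0 else "repressor"
        rows.append(entry)
    return pd.DataFrame(rows)


def cooccurrence(hits: pd.DataFrame,
                 groups: dict[str, list[str]]) -> dict[str, pd.DataFrame]:
    """Per-group motif-pair co-occurrence percentages.

    A pair co-occurs in a sequence when the sequence has at least one hit of
    each motif (any cell, any strand).  Returns per group a symmetric
    percentage matrix; empty groups give NaN rows with a warning.
    """
    import warnings

    motif_ids = sorted(set(hits["motif_id"])) if len(hits) else []
    presence: dict[str, set[str]] = {}
    for h in hits.itertuples():
        presence.setdefault(h.seq_id, set()).add(h.motif_id)
    out = {}
    for gname, seq_ids in groups.items():
        mat = pd.DataFrame(np.nan, index=motif_ids, columns=motif_ids)
        if len(seq_ids) == 0:
            warnings.warn(f"empty group {gname!r}: co-occurrence undefined")
            out[gname] = mat
            continue
        sets = [presence.get(s, set()) for s in seq_ids]
        for i, mi in enumerate(motif_ids):
            for j, mj in enumerate(motif_ids[i:], start=i):
                pct = 100.0 * sum((mi in s) and (mj in s) for s in sets) / len(sets)
                mat.iloc[i, j] = mat.iloc[j, i] = pct
        out[gname] = mat
    return out


# ---------------------------------------------------------------------------
# NMF motif programs


@dataclass
class ProgramDecomposition:
    """Non-negative factorization of a motif-count matrix X ~ W H."""

    X: np.ndarray
    W: np.ndarray               # (n, k) coefficients
    H: np.ndarray               # (k, f) features
    k: int
    reconstruction_error: float
    program_function: np.ndarray | None = None   # (k, n_cells)

    @property
    def W_normalized(self) -> np.ndarray:
        sums = self.W.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            out = np.where(sums > 0, self.W / np.where(sums == 0, 1, sums), 0.0)
        return out


def nmf_programs(X: np.ndarray, k: int = 12, seed: int = 0,
                 motif_contributions: np.ndarray | None = None,
                 contribution_clip: float = 3.0,
                 max_iter: int = 2000, tol: float = 1e-6) -> ProgramDecomposition:
    """Decompose a non-negative motif-count matrix into k programs.

    Frobenius-loss NMF with deterministic SVD-based initialization and
    multiplicative updates (scikit-learn).  If per-motif, per-cell
    contributions are supplied, each program's activity signature is the
    H-weighted average of the contributions, clipped at an upper bound to
    mitigate extreme outliers.
    """
    from sklearn.decomposition import NMF

    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n, f)={min(X.shape)}")
    model = NMF(n_components=k, init="nndsvda", solver="mu",
                beta_loss="frobenius", max_iter=max_iter, tol=tol,
                random_state=seed)
    W = model.fit_transform(X)
    H = model.components_
    err = float(np.linalg.norm(X - W @ H, "fro"))
    program_function = None
    if motif_contributions is not None:
        contrib = np.clip(np.asarray(motif_contributions, dtype=float),
                          None, contribution_clip)
        weights = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-12)
        program_function = weights @ np.nan_to_num(contrib)
    return ProgramDecomposition(X=X, W=W, H=H, k=k, reconstruction_error=err,
                                program_function=program_function)


def motif_count_matrix(hits: pd.DataFrame, seq_ids: list[str],
                       motif_ids: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Sequences x motifs matrix of hit counts (unique loci, any cell)."""
    if motif_ids is None:
        motif_ids = sorted(set(hits["motif_id"])) if len(hits) else []
    index = {s: i for i, s in enumerate(seq_ids)}
    midx = {m: j for j, m in enumerate(motif_ids)}
    X = np.zeros((len(seq_ids), len(motif_ids)))
    if len(hits):
        uniq = hits.drop_duplicates(["seq_id", "motif_id", "start", "strand"])
        for h in uniq.itertuples():
            if h.seq_id in index and h.motif_id in midx:
                X[index[h.seq_id], midx[h.motif_id]] += 1
    return X, motif_ids


# ---------------------------------------------------------------------------
# saturation mutagenesis


def saturation_effects(ref_activity: float, variants: pd.DataFrame,
                       length: int = 200) -> tuple[pd.DataFrame, np.ndarray]:
    """Variant effects and the per-position logo summary.

    ``variants`` needs columns position (0-based), alt (base) and activity;
    exactly 3 alternate bases per position are expected.  The effect is
    variant activity minus the reference activity; the per-position summary
    is the negative mean effect (so destructive positions plot upward).
    Missing variants are reported with their positions.
    """
    expected = 3 * length
    counts = variants.groupby("position").size()
    missing = [p for p in range(length) if counts.get(p, 0) < 3]
    if len(variants) != expected or missing:
        raise ValueError(f"incomplete saturation table: expected {expected} variants "
                         f"(3 x {length}); positions missing alts: {missing[:20]}")
    effects = variants.copy()
    effects["effect"] = effects["activity"] - ref_activity
    per_position = -effects.groupby("position")["effect"].mean().to_numpy()
    return effects, per_position


# ---------------------------------------------------------------------------
# k-mer diversity


def kmer_diversity(sequences: list[str], k: int = 4, n_neighbors: int = 4) -> np.ndarray:
    """Mean Manhattan distance from each sequence's k-mer count vector to
    its ``n_neighbors`` nearest neighbours (self excluded)."""
    from sklearn.neighbors import NearestNeighbors

    if len(sequences) < n_neighbors + 1:
        raise ValueError("need more sequences than neighbours")
    base_idx = {b: i for i, b in enumerate("ACGT")}
    X = np.zeros((len(sequences), 4 ** k), dtype=np.float32)
    mask = 4 ** k
    for row, s in enumerate(sequences):
        code = 0
        valid = 0
        for ch in s:
            b = base_idx.get(ch)
            if b is None:
                code, valid = 0, 0
                continue
            code = (code * 4 + b) % mask
            valid += 1
            if valid >= k:
                X[row, code] += 1
    nbrs = NearestNeighbors(n_neighbors=n_neighbors + 1, metric="manhattan").fit(X)
    dist, _ = nbrs.kneighbors(X)
    return dist[:, 1:].mean(axis=1)
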