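"""Specificity objectives and specificity geometry.

MinGap is the activity in the target cell type minus the maximum off-target
activity.  The bending function g(x) = x - exp(-x) + 1 penalizes high
off-target expression: it is approximately linear for large x but drops
super-linearly for negative x, so bent-MinGap = g(y+) - g(y-) rewards
designs that actively repress the off-target cell types.  Predictions are
clamped into a limited interval (default [-2, 6]) before bending to keep
pathological out-of-distribution predictions from dominating the objective.

The propeller coordinate system maps a 3-cell activity vector to a radial
point: radius = MaxGap (max minus min) and angular deviation from the
argmax axis = (1 - MinGap/MaxGap) * 60 degrees, i.e. 60 * (median - min) /
(max - min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqcore import MotifModel, OneHotSequence, reverse_complement

DEFAULT_CLAMP = (-2.0, 6.0)


# ---------------------------------------------------------------------------
# MinGap / bending


def min_gap(a: np.ndarray, target: int) -> float:
    """Target-cell activity minus the maximum off-target activity."""
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("min_gap requires at least 2 cell types")
    off = np.delete(a, target)
    return float(a[target] - off.max())


def bend(x):
    """g(x) = x - exp(-x) + 1."""
    x = np.asarray(x, dtype=float)
    out = x - np.exp(-x) + 1.0
    return float(out) if out.ndim == 0 else out


def bend_grad(x):
    """g'(x) = 1 + exp(-x)."""
    x = np.asarray(x, dtype=float)
    return 1.0 + np.exp(-x)


def bent_min_gap(a: np.ndarray, target: int,
                 clamp: tuple[float, float] | None = DEFAULT_CLAMP) -> float:
    """g(y+) - g(y-) on clamped activities."""
    a = np.asarray(a, dtype=float)
    if clamp is not None:
        a = np.clip(a, clamp[0], clamp[1])
    off = np.delete(a, target)
    return float(bend(a[target]) - bend(off.max()))


def bent_min_gap_batch(acts: np.ndarray, target: int,
                       clamp: tuple[float, float] | None = DEFAULT_CLAMP) -> np.ndarray:
    """Vectorized bent-MinGap over an (N, C) activity batch."""
    acts = np.asarray(acts, dtype=float)
    if clamp is not None:
        acts = np.clip(acts, clamp[0], clamp[1])
    off = np.delete(acts, target, axis=1)
    return bend(acts[:, target]) - bend(off.max(axis=1))


def min_gap_batch(acts: np.ndarray, target: int,
                  clamp: tuple[float, float] | None = None) -> np.ndarray:
    acts = np.asarray(acts, dtype=float)
    if clamp is not None:
        acts = np.clip(acts, clamp[0], clamp[1])
    off = np.delete(acts, target, axis=1)
    return acts[:, target] - off.max(axis=1)


def bent_min_gap_grad(acts: np.ndarray, target: int,
                      clamp: tuple[float, float] | None = DEFAULT_CLAMP) -> np.ndarray:
    """d bent-MinGap / d activities for an (N, C) batch.

    The clamp contributes zero gradient outside the interval; the off-target
    max routes gradient to the arg-max off-target cell only.
    """
    acts = np.asarray(acts, dtype=float)
    n, c = acts.shape
    clamped = np.clip(acts, clamp[0], clamp[1]) if clamp is not None else acts
    inside = np.ones_like(acts, dtype=bool)
    if clamp is not None:
        inside = (acts > clamp[0]) & (acts < clamp[1])
    grad = np.zeros_like(acts)
    yp = clamped[:, target]
    grad[:, target] = bend_grad(yp) * inside[:, target]
    off_idx = [j for j in range(c) if j != target]
    off = clamped[:, off_idx]
    amax = off.argmax(axis=1)
    for row in range(n):
        j = off_idx[amax[row]]
        grad[row, j] = -bend_grad(clamped[row, j]) * inside[row, j]
    return grad


@dataclass
class ObjectiveSpec:
    """A specificity objective: which cell to target, whether to bend, the
    clamp interval, and an optional motif penalty pool."""

    target_cell: int
    kind: str = "bent_min_gap"          # or "min_gap"
    clamp: tuple[float, float] | None = DEFAULT_CLAMP
    penalty: "PenaltyPool | None" = None

    def value(self, acts: np.ndarray) -> np.ndarray:
        if self.kind == "bent_min_gap":
            return bent_min_gap_batch(acts, self.target_cell, clamp=self.clamp)
        if self.kind == "min_gap":
            return min_gap_batch(acts, self.target_cell, clamp=self.clamp)
        raise ValueError(f"unknown objective kind {self.kind!r}")

    def grad(self, acts: np.ndarray) -> np.ndarray:
        if self.kind != "bent_min_gap":
            raise NotImplementedError("gradients implemented for bent_min_gap only")
        return bent_min_gap_grad(acts, self.target_cell, clamp=self.clamp)


# ---------------------------------------------------------------------------
# motif penalty


@dataclass
class PenaltyPool:
    """An ordered motif pool with per-motif score thresholds.

    Order is the order of inclusion: earlier motifs receive larger
    penalty weights (m - i + 1)^(1/3) for 1-based index i.
    """

    motifs: list[MotifModel] = field(default_factory=list)
    thresholds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.motifs) != len(self.thresholds):
            raise ValueError("one threshold per motif required")
        if not all(np.isfinite(self.thresholds)):
            raise ValueError("thresholds must be finite")

    def __len__(self) -> int:
        return len(self.motifs)

    def add(self, motif: MotifModel, threshold: float) -> None:
        self.motifs.append(motif)
        self.thresholds.append(float(threshold))


def _as_batch(batch) -> np.ndarray:
    if isinstance(batch, np.ndarray):
        arr = batch
    else:
        arr = np.stack([b.matrix if isinstance(b, OneHotSequence) else np.asarray(b)
                        for b in batch])
    return arr.astype(np.float64, copy=False)


def _strand_scores(arr: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    w = pwm.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(arr, w, axis=1)
    return np.einsum("npbw,wb->np", windows, pwm, optimize=True)


def motif_penalty(batch, pool: PenaltyPool,
                  grad: bool = False) -> float | tuple[float, np.ndarray]:
    """Weighted sum of above-threshold PWM match scores, batch-averaged.

    penalty = (1 / (m n)) * sum_i (m - i + 1)^(1/3) * sum_{j: s_j >= t_i} s_j
    where j runs over every window of every batch sequence on both strands,
    n is the batch size and i is the 1-based inclusion index.  With
    ``grad=True`` also returns d penalty / d one-hot (same shape as batch),
    which is exact because the match scores are linear in the one-hot.
    """
    if len(pool) == 0:
        raise ValueError("penalty pool is empty")
    arr = _as_batch(batch)
    n, seq_len, _ = arr.shape
    m = len(pool)
    total = 0.0
    g = np.zeros_like(arr) if grad else None
    for i, (motif, thr) in enumerate(zip(pool.motifs, pool.thresholds)):
        w = motif.width
        if w > seq_len:
            import warnings

            warnings.warn(f"motif {motif.id} wider than sequences; contributes 0")
            continue
        weight = (m - i) ** (1.0 / 3.0)  # (m - i + 1)^(1/3) for 1-based i
        for pwm in (motif.pwm, motif.reverse_complement().pwm):
            scores = _strand_scores(arr, pwm)
            mask = scores >= thr
            total += weight * scores[mask].sum()
            if grad and mask.any():
                factor = weight / (m * n)
                masked = mask.astype(np.float64)
                for t in range(w):
                    g[:, t:t + scores.shape[1], :] += (
                        masked[:, :, None] * (factor * pwm[t])[None, None, :])
    value = total / (m * n)
    if grad:
        return value, g
    return value


def motif_presence_score(seq: OneHotSequence | np.ndarray, motif: MotifModel,
                         threshold: float | None = None) -> float:
    """Sum of above-threshold match scores on both strands, normalized by
    the consensus (maximum attainable) score.  Threshold defaults to the
    motif's Patser score threshold."""
    if threshold is None:
        threshold = motif.patser_threshold()
    arr = seq.matrix if isinstance(seq, OneHotSequence) else np.asarray(seq)
    arr = arr[None].astype(np.float64)
    if motif.width > arr.shape[1]:
        return 0.0
    total = 0.0
    for pwm in (motif.pwm, motif.reverse_complement().pwm):
        scores = _strand_scores(arr, pwm)[0]
        total += scores[scores >= threshold].sum()
    return float(total / motif.consensus_score)


# ---------------------------------------------------------------------------
# propeller geometry


@dataclass
class PropellerPoint:
    axis: int              # argmax cell type (ties -> lowest index)
    radius: float          # MaxGap = max - min
    angle_deg: float       # deviation from the argmax axis, in [0, 60]
    min_activity: float
    tied: bool = False     # argmax tie encountered
    toward_axis: int = -1  # the median cell's axis (deviation direction)


def propeller(a: np.ndarray) -> PropellerPoint:
    """Propeller coordinates of a 3-cell activity vector.

    radius = max - min; angle = 60 * (median - min) / (max - min), deviating
    from the argmax axis toward the median cell's axis.  A zero radius
    yields angle 0 by convention.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (3,):
        raise ValueError("propeller requires exactly 3 cell types")
    order = np.argsort(-a, kind="stable")  # ties -> lowest index first
    hi, mid, lo = (int(i) for i in order)
    radius = float(a[hi] - a[lo])
    tied = bool(np.sum(a == a[hi]) > 1)
    angle = 0.0 if radius == 0 else 60.0 * float(a[mid] - a[lo]) / radius
    return PropellerPoint(axis=hi, radius=radius, angle_deg=angle,
                          min_activity=float(a[lo]), tied=tied,
                          toward_axis=mid if radius > 0 else -1)


@dataclass
class SpecificityCall:
    specific: bool
    effective_target: int
    reassigned: bool
    max_gap: float
    min_gap: float
    ratio: float


def classify_specific(a: np.ndarray, maxgap_min: float = 1.0,
                      designed_target: int | None = None) -> SpecificityCall:
    """Cell-type-specificity call for a 3-cell activity vector.

    Specific iff MaxGap > maxgap_min and MinGap/MaxGap > 0.5 (both strict),
    taking the argmax cell as the effective target — so the maximum
    off-target is closer to the minimum off-target than to the target.
    The stringent variant uses maxgap_min = 4.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (3,):
        raise ValueError("classify_specific requires exactly 3 cell types")
    effective = int(np.argmax(a))
    srt = np.sort(a)
    max_gap = float(srt[2] - srt[0])
    mg = float(srt[2] - srt[1])  # target minus max off-target, target = argmax
    ratio = mg / max_gap if max_gap > 0 else 0.0
    specific = (max_gap > maxgap_min) and (ratio > 0.5)
    reassigned = designed_target is not None and effective != designed_target
    return SpecificityCall(specific=specific, effective_target=effective,
                           reassigned=bool(reassigned), max_gap=max_gap,
                           min_gap=mg, ratio=ratio)


STRINGENT_MAXGAP = 4.0


def specificity_summary(table: pd.DataFrame, cells: list[str] | None = None,
                        group_col: str = "group", target_col: str = "target",
                        se_filter_max: float | None = 1.0) -> dict:
    """Library-wide specificity percentages and reassignment counts.

    ``table`` needs per-cell ``log2fc_<cell>`` columns, a group label column
    and a designed-target column holding cell names.  Oligos whose
    ``log2fc_se_<cell>`` exceeds ``se_filter_max`` in any cell type are
    dropped first (set to None to skip).  Returns per-group percent specific
    under the lenient (MaxGap > 1) and stringent (MaxGap > 4) rules, plus
    the number of sequences that pass only via target reassignment.
    """
    from .mpra_data import cell_types_of, se_filter

    if cells is None:
        cells = cell_types_of(table)
    if len(cells) != 3:
        raise ValueError("specificity_summary requires exactly 3 cell types")
    if se_filter_max is not None and any(f"log2fc_se_{c}" in table.columns for c in cells):
        table = se_filter(table, max_se=se_filter_max)
    acts = table[[f"log2fc_{c}" for c in cells]].to_numpy(dtype=float)
    cell_index = {c: i for i, c in enumerate(cells)}
    designed = table[target_col].map(cell_index).to_numpy()
    out: dict = {"groups": {}, "reassigned_lenient": 0, "reassigned_stringent": 0}
    calls = {}
    for label, gap in (("lenient", 1.0), ("stringent", STRINGENT_MAXGAP)):
        calls[label] = [classify_specific(a, maxgap_min=gap, designed_target=d)
                        for a, d in zip(acts, designed)]
        out[f"reassigned_{label}"] = int(sum(c.specific and c.reassigned
                                             for c in calls[label]))
    groups = table[group_col].to_numpy()
    for g in pd.unique(groups):
        mask = groups == g
        entry = {}
        for label in ("lenient", "stringent"):
            sub = [c for c, m in zip(calls[label], mask) if m]
            entry[f"percent_specific_{label}"] = round(
                100.0 * sum(c.specific for c in sub) / len(sub), 1) if sub else float("nan")
        out["groups"][str(g)] = entry
    return out


# ---------------------------------------------------------------------------
# plotting

_AXIS_ANGLES = np.array([90.0, -30.0, -150.0])  # cell 0 up, then clockwise


def propeller_xy(a: np.ndarray) -> tuple[float, float]:
    """Cartesian position of one activity triple in the propeller plane."""
    p = propeller(a)
    if p.radius == 0:
        return 0.0, 0.0
    base = _AXIS_ANGLES[p.axis]
    # rotate toward the median cell's axis by the deviation angle
    delta = (_AXIS_ANGLES[p.toward_axis] - base + 540.0) % 360.0 - 180.0
    theta = np.deg2rad(base + np.sign(delta) * p.angle_deg)
    return float(p.radius * np.cos(theta)), float(p.radius * np.sin(theta))


def plot_propeller(acts: np.ndarray, path, cell_names=("cell0", "cell1", "cell2"),
                   title: str = "") -> None:
    """Render a propeller dot plot (matplotlib, saved to ``path``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    acts = np.asarray(acts, dtype=float)
    xy = np.array([propeller_xy(a) for a in acts])
    mins = acts.min(axis=1)
    fig, ax = plt.subplots(figsize=(5, 5))
    rmax = max(1.0, float(np.abs(xy).max()) * 1.1)
    for ang, name in zip(_AXIS_ANGLES, cell_names):
        t = np.deg2rad(ang)
        ax.plot([0, rmax * np.cos(t)], [0, rmax * np.sin(t)], color="0.8", lw=1)
        ax.text(1.05 * rmax * np.cos(t), 1.05 * rmax * np.sin(t), name,
                ha="center", va="center")
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=mins, s=6, cmap="viridis")
    fig.colorbar(sc, ax=ax, label="min activity")
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
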