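"""MPRA activity tables: filtering, aggregation, splits, augmentation, and a
synthetic-MPRA generator.

Tables are pandas DataFrames with one row per oligo and columns::

    oligo_id  sequence  chrom  source_library  plasmid_count
    log2fc_<cell>  log2fc_se_<cell>  rna_count_<cell>     (one set per cell type)

The synthetic generator plants activator/repressor motif instances from a
cell-type grammar into random 200-mers and emits activities under an
additive (optionally saturating) effect model plus Gaussian noise, together
with ground-truth annotations of every planted instance.  It exists so that
model training, sequence design and interpretation can all be exercised and
validated without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqcore import BASES, MotifModel, decode_onehot, sample_onehot

PLASMID_COUNT_MIN = 20          # oligos below this plasmid count are dropped
LOW_TAIL_SD = 6.0               # activity outlier filter: mean - 6 s.d.
SE_MAX_DEFAULT = 1.0            # replicate-SE filter bound
DUPLICATE_LOG2FC = 0.5          # high-activity duplication threshold
VAL_CHROMS = frozenset({"19", "21", "X"})
TEST_CHROMS = frozenset({"7", "13"})


def cell_types_of(table: pd.DataFrame) -> list[str]:
    return [c[len("log2fc_"):] for c in table.columns
            if c.startswith("log2fc_") and not c.startswith("log2fc_se_")]


# ---------------------------------------------------------------------------
# filtering / aggregation


def filter_and_aggregate(tables: list[pd.DataFrame], precedence: list[str]) -> pd.DataFrame:
    """Apply count filters, resolve duplicate oligos by library precedence,
    and drop extreme low-activity outliers.

    Order: count filter -> precedence aggregation -> low-tail filter.
    Duplicates within the highest-precedence tier present are averaged;
    records of the same oligo in lower tiers are dropped.
    """
    table = pd.concat(tables, ignore_index=True)
    if len(table) == 0:
        return table
    known = set(precedence)
    libs = set(table["source_library"].unique())
    if not libs <= known:
        raise ValueError(f"unknown library name(s) not in precedence list: {sorted(libs - known)}")
    cells = cell_types_of(table)

    keep = table["plasmid_count"] >= PLASMID_COUNT_MIN
    for c in cells:
        keep &= table[f"rna_count_{c}"] > 0
    table = table[keep]
    if len(table) == 0:
        return table.reset_index(drop=True)

    rank = {lib: i for i, lib in enumerate(precedence)}
    table = table.assign(_rank=table["source_library"].map(rank))
    top = table.groupby("oligo_id")["_rank"].transform("min")
    table = table[table["_rank"] == top]
    numeric = ([f"log2fc_{c}" for c in cells] + [f"log2fc_se_{c}" for c in cells]
               + [f"rna_count_{c}" for c in cells] + ["plasmid_count"])
    agg = {col: "mean" for col in numeric}
    for col in ("sequence", "chrom", "source_library"):
        agg[col] = "first"
    table = table.groupby("oligo_id", as_index=False, sort=False).agg(agg)
    table = table.sort_values("oligo_id", kind="stable").reset_index(drop=True)

    keep = pd.Series(True, index=table.index)
    for c in cells:
        col = table[f"log2fc_{c}"]
        keep &= col >= col.mean() - LOW_TAIL_SD * col.std(ddof=0)
    return table[keep].reset_index(drop=True)


def se_filter(table: pd.DataFrame, max_se: float = SE_MAX_DEFAULT) -> pd.DataFrame:
    """Drop records whose replicate log2FC standard error exceeds ``max_se``
    in any cell type (strict inequality: SE == max_se is retained)."""
    keep = pd.Series(True, index=table.index)
    for c in cell_types_of(table):
        keep &= ~(table[f"log2fc_se_{c}"] > max_se)
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# splits / augmentation


@dataclass
class TrainingSplit:
    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame
    augmented: bool = False


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def make_split(table: pd.DataFrame,
               val_chroms: frozenset = VAL_CHROMS,
               test_chroms: frozenset = TEST_CHROMS) -> TrainingSplit:
    """Partition by chromosome: held-out validation and test chromosomes,
    everything else trains.  Assignment is a pure function of chrom."""
    if set(val_chroms) & set(test_chroms):
        raise ValueError("validation and test chromosome sets overlap")
    chrom = table["chrom"].map(_norm_chrom)
    val = table[chrom.isin(val_chroms)].reset_index(drop=True)
    test = table[chrom.isin(test_chroms)].reset_index(drop=True)
    train = table[~chrom.isin(val_chroms | test_chroms)].reset_index(drop=True)
    return TrainingSplit(train=train, val=val, test=test)


_RC = str.maketrans("ACGTN", "TGCAN")


def rc_string(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def augment_training(split: TrainingSplit,
                     duplicate_threshold: float = DUPLICATE_LOG2FC,
                     duplicate_rc: bool = False) -> TrainingSplit:
    """Add reverse-complement copies of every training record, plus one
    duplicate (forward orientation by default) of each record whose log2FC
    exceeds the threshold in any cell type.  Validation/test are untouched.
    """
    train = split.train
    cells = cell_types_of(train)
    rc = train.copy()
    rc["sequence"] = rc["sequence"].map(rc_string)
    rc["oligo_id"] = rc["oligo_id"].astype(str) + "_rc"
    high = train[[f"log2fc_{c}" for c in cells]].max(axis=1) > duplicate_threshold
    dup = train[high].copy()
    dup["oligo_id"] = dup["oligo_id"].astype(str) + "_dup"
    parts = [train, rc, dup]
    if duplicate_rc:
        dup_rc = dup.copy()
        dup_rc["sequence"] = dup_rc["sequence"].map(rc_string)
        dup_rc["oligo_id"] = dup_rc["oligo_id"].astype(str) + "_rc"
        parts.append(dup_rc)
    out = pd.concat(parts, ignore_index=True)
    return TrainingSplit(train=out, val=split.val, test=split.test, augmented=True)


# ---------------------------------------------------------------------------
# synthetic MPRA


@dataclass
class SynthGrammar:
    """A planted activator/repressor motif grammar for simulated cell types.

    Each motif carries the cell type it acts in and a signed effect in
    log2FC units.  Activities are baseline + sum of planted effects
    (optionally clipped into [-cap, cap]) + Gaussian(0, noise_sd).
    """

    cell_types: list[str]
    activators: dict[str, list[tuple[MotifModel, float]]]
    repressors: dict[str, list[tuple[MotifModel, float]]]
    baseline: float = 0.0
    noise_sd: float = 0.25
    interaction: str = "additive-saturating"   # or "additive"
    cap: float = 6.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for d in (self.activators, self.repressors):
            for motifs in d.values():
                for _, eff in motifs:
                    if not np.isfinite(eff):
                        raise ValueError("effect sizes must be finite")

    def all_motifs(self) -> list[tuple[MotifModel, str, float]]:
        out = []
        for cell in self.cell_types:
            for m, eff in self.activators.get(cell, []):
                out.append((m, cell, eff))
            for m, eff in self.repressors.get(cell, []):
                out.append((m, cell, eff))
        return out


def _random_sharp_ppm(width: int, rng: np.random.Generator, dominance: float = 0.95) -> np.ndarray:
    ppm = np.full((width, 4), (1 - dominance) / 3)
    ppm[np.arange(width), rng.integers(0, 4, width)] = dominance
    return ppm


def default_grammar(seed: int = 7, noise_sd: float = 0.25) -> SynthGrammar:
    """The package's reference simulation: 3 cell types, 2 activators and
    1 repressor each, activator effects in [1.5, 3.5] and repressor effects
    in [-2.5, -1] log2FC units."""
    rng = np.random.default_rng(seed)
    cells = ["cellA", "cellB", "cellC"]
    activators: dict[str, list[tuple[MotifModel, float]]] = {}
    repressors: dict[str, list[tuple[MotifModel, float]]] = {}
    k = 0
    for cell in cells:
        activators[cell] = []
        repressors[cell] = []
        for j in range(2):
            w = int(rng.integers(8, 11))
            m = MotifModel(_random_sharp_ppm(w, rng), id=f"act_{cell}_{j}", source="supplied")
            activators[cell].append((m, float(rng.uniform(1.5, 3.5))))
            k += 1
        w = int(rng.integers(8, 11))
        m = MotifModel(_random_sharp_ppm(w, rng), id=f"rep_{cell}", source="supplied")
        repressors[cell].append((m, float(rng.uniform(-2.5, -1.0))))
    return SynthGrammar(cell_types=cells, activators=activators, repressors=repressors,
                        noise_sd=noise_sd)


_CHROMS = [str(i) for i in range(1, 23)] + ["X"]


MATCH_THRESHOLD_FRACTION = 0.9  # of consensus score; counts a motif occurrence


def count_motif_matches(onehots: np.ndarray, motif: MotifModel,
                        threshold_fraction: float = MATCH_THRESHOLD_FRACTION) -> np.ndarray:
    """Number of strong PWM matches (both strands) per sequence in an
    (n, L, 4) one-hot batch."""
    thr = threshold_fraction * motif.consensus_score
    counts = np.zeros(len(onehots), dtype=np.int64)
    for pwm in (motif.pwm, motif.reverse_complement().pwm):
        windows = np.lib.stride_tricks.sliding_window_view(onehots, motif.width, axis=1)
        scores = np.einsum("npbw,wb->np", windows, pwm, optimize=True)
        counts += (scores >= thr).sum(axis=1)
    return counts


def simulate_mpra(
    grammar: SynthGrammar,
    n: int,
    seed: int,
    seq_length: int = 200,
    max_motifs: int = 4,
    max_place_tries: int = 50,
) -> tuple[pd.DataFrame, list[list[dict]]]:
    """Simulate an MPRA table of ``n`` random ``seq_length``-mers with 0-4
    planted motif instances each, plus ground-truth annotations.

    Planted instances are consensus sites (strand chosen at random) at
    non-overlapping positions.  Activities are computed from the *final*
    sequence by counting strong PWM matches of every grammar motif — so a
    motif occurrence contributes whether it was planted or arose in the
    random background, and the label is an exact function of the sequence
    (plus Gaussian noise).  Returns (table, annotations) where
    annotations[i] lists dicts with keys motif_id, cell, effect, start,
    end, strand for row i.  Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = grammar.all_motifs()
    for m, _, _ in pool:
        if m.width > seq_length:
            raise ValueError(f"motif {m.id} wider than sequence length {seq_length}")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    annotations: list[list[dict]] = []
    from .seqcore import encode_onehot

    for i in range(n):
        seq = list(decode_onehot(sample_onehot(np.full((seq_length, 4), 0.25), 1, rng)[0]))
        k = int(rng.integers(0, max_motifs + 1)) if pool else 0
        placed: list[tuple[int, int]] = []
        anns: list[dict] = []
        for _ in range(k):
            m, cell, eff = pool[int(rng.integers(0, len(pool)))]
            for _try in range(max_place_tries):
                start = int(rng.integers(0, seq_length - m.width + 1))
                end = start + m.width
                if all(end <= s or start >= e for s, e in placed):
                    break
            else:
                raise RuntimeError("could not place motif without overlap "
                                   f"after {max_place_tries} tries")
            inst = m.consensus
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                inst = rc_string(inst)
            seq[start:end] = list(inst)
            placed.append((start, end))
            anns.append({"motif_id": m.id, "cell": cell, "effect": eff,
                         "start": start, "end": end, "strand": strand})
        seqs.append("".join(seq))
        annotations.append(anns)

    # activities from sequence content: strong-match counts x effect sizes
    onehots = np.stack([encode_onehot(s).matrix for s in seqs])
    effects = np.zeros((n, len(grammar.cell_types)))
    cell_idx = {c: j for j, c in enumerate(grammar.cell_types)}
    for m, cell, eff in pool:
        effects[:, cell_idx[cell]] += eff * count_motif_matches(onehots, m)

    rows = []
    for i in range(n):
        row = {
            "oligo_id": f"synth_{i:06d}",
            "sequence": seqs[i],
            "chrom": _CHROMS[int(rng.integers(0, len(_CHROMS)))],
            "source_library": "synthetic",
            "plasmid_count": int(rng.poisson(120) + PLASMID_COUNT_MIN),
        }
        for j, c in enumerate(grammar.cell_types):
            total = grammar.baseline + effects[i, j]
            if grammar.interaction == "additive-saturating":
                total = float(np.clip(total, -grammar.cap, grammar.cap))
            total += float(rng.normal(0.0, grammar.noise_sd)) if grammar.noise_sd else 0.0
            row[f"log2fc_{c}"] = total
            row[f"log2fc_se_{c}"] = float(rng.uniform(0.05, 0.3))
            row[f"rna_count_{c}"] = int(rng.poisson(100) + 1)
        rows.append(row)
    return pd.DataFrame(rows), annotations


# ---------------------------------------------------------------------------
# I/O helpers


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_annotations(path: str | Path, annotations: list[list[dict]]) -> None:
    Path(path).write_text(json.dumps(annotations, indent=1))


def read_annotations(path: str | Path) -> list[list[dict]]:
    return json.loads(Path(path).read_text())
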