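"""Sequence-generation algorithms: gradient-based (Fast SeqProp),
evolutionary (AdaLead) and probabilistic (simulated annealing), plus the
iterative motif-penalization track and a built-in motif-enrichment routine.

All three designers maximize a cell-type-specificity objective evaluated on
clamped model predictions.  Fast SeqProp and AdaLead use bent-MinGap;
simulated annealing minimizes the energy -MinGap (no bending).  Fast
SeqProp optimizes a learnable 200 x 4 logit matrix: per step the logits are
instance-normalized (no learnable affine), softmaxed into a position
probability matrix, a batch of one-hot sequences is sampled, and gradients
flow back through the sampling with the straight-through estimator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .objectives import (ObjectiveSpec, PenaltyPool, min_gap_batch,
                         motif_penalty)
from .seqcore import BASES, MotifModel, decode_onehot, random_sequences, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class DesignResult:
    sequences: list[str]
    activities: np.ndarray            # (n_accepted, n_cells)
    objective_values: np.ndarray      # (n_accepted,)
    trace: list[float]                # per-step mean objective
    rejected_count: int
    provenance: dict = field(default_factory=dict)


def anneal_temperature(s: int) -> float:
    """tau(s) = 1 / (1 + s^0.501); strictly decreasing with tau(0) = 1 and
    a diverging temperature sum."""
    return 1.0 / (1.0 + s ** 0.501)


# ---------------------------------------------------------------------------
# Fast SeqProp


def _instance_norm(theta: np.ndarray, eps: float = 1e-5):
    """Normalize per (run, base) over the length axis; no learnable affine."""
    mu = theta.mean(axis=1, keepdims=True)
    var = theta.var(axis=1, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    z = (theta - mu) * invstd
    return z, invstd


def _instance_norm_backward(z: np.ndarray, invstd: np.ndarray, dz: np.ndarray) -> np.ndarray:
    dmean = dz.mean(axis=1, keepdims=True)
    dproj = (dz * z).mean(axis=1, keepdims=True)
    return invstd * (dz - dmean - z * dproj)


def _sample_categorical(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One-hot samples from (..., L, 4) probabilities."""
    cdf = np.cumsum(p, axis=-1)
    u = rng.random(p.shape[:-1] + (1,))
    idx = (u > cdf).sum(axis=-1)
    out = np.zeros(p.shape, dtype=np.float32)
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return out


def fast_seqprop(
    model,
    objective: ObjectiveSpec,
    n_runs: int = 1,
    seed: int = 0,
    steps: int = 300,
    samples_per_step: int = 20,
    lr: float = 0.5,
    lr_min: float = 1e-6,
    collect_min: float | None = 3.6,
    seq_length: int | None = None,
) -> DesignResult:
    """Gradient-based sequence design over reparameterized nucleotide logits.

    Logits start from a standard normal draw and are optimized with Adam
    under a cosine-annealed learning rate.  The per-step loss is the
    negative mean objective of ``samples_per_step`` one-hot samples per run
    (plus the motif penalty if the objective carries a pool).  After the
    final step, 20 sequences are sampled per run and the best one by
    objective is collected unless it falls below ``collect_min``.
    """
    if not hasattr(model, "predict_with_grad"):
        raise TypeError("fast_seqprop requires a differentiable model "
                        "(predict_with_grad)")
    length = seq_length or model.config.insert_length
    rng = np.random.default_rng(seed)
    theta = nn.Param(rng.normal(0.0, 1.0, (n_runs, length, 4)))
    opt = nn.Adam([theta], lr=lr)
    trace: list[float] = []
    s = samples_per_step
    for step in range(steps):
        z, invstd = _instance_norm(theta.value)
        p = nn.softmax(z, axis=-1)
        onehot = _sample_categorical(np.broadcast_to(p[:, None], (n_runs, s) + p.shape[1:]), rng)
        flat = onehot.reshape(n_runs * s, length, 4)

        def d_out_fn(acts):
            # loss = -mean objective (+ penalty); d loss / d acts
            return -objective.grad(acts) / flat.shape[0]

        acts, g = model.predict_with_grad(flat, d_out_fn)
        obj = objective.value(acts)
        if objective.penalty is not None and len(objective.penalty):
            pen, pgrad = motif_penalty(flat, objective.penalty, grad=True)
            g = g + pgrad
        else:
            pen = 0.0
        trace.append(float(obj.mean() - pen))
        # straight-through: sample gradient passes to the probabilities
        dp = g.reshape(n_runs, s, length, 4).sum(axis=1)
        dz = nn.softmax_backward(p, dp, axis=-1)
        opt.zero_grad()
        theta.grad[...] = _instance_norm_backward(z, invstd, dz)
        opt.step(nn.cosine_lr(step, steps, lr, lr_min))

    # finalize: sample 20 per run, keep each run's best
    z, _ = _instance_norm(theta.value)
    p = nn.softmax(z, axis=-1)
    final = _sample_categorical(np.broadcast_to(p[:, None], (n_runs, 20) + p.shape[1:]), rng)
    flat = final.reshape(n_runs * 20, length, 4)
    acts = model.predict(flat, clamp=objective.clamp)
    obj = objective.value(acts).reshape(n_runs, 20)
    best = obj.argmax(axis=1)
    seqs, accepted_acts, accepted_obj, rejected = [], [], [], 0
    for r in range(n_runs):
        val = float(obj[r, best[r]])
        if collect_min is not None and val < collect_min:
            rejected += 1
            continue
        seqs.append(decode_onehot(final[r, best[r]]))
        accepted_acts.append(acts.reshape(n_runs, 20, -1)[r, best[r]])
        accepted_obj.append(val)
    return DesignResult(
        sequences=seqs,
        activities=np.array(accepted_acts) if accepted_acts else np.zeros((0, acts.shape[1])),
        objective_values=np.array(accepted_obj),
        trace=trace,
        rejected_count=rejected,
        provenance={"algorithm": "fast_seqprop", "seed": seed, "steps": steps,
                    "samples_per_step": s, "lr": lr, "n_runs": n_runs,
                    "collect_min": collect_min,
                    "penalty_pool": [m.id for m in objective.penalty.motifs]
                    if objective.penalty else []},
    )


# ---------------------------------------------------------------------------
# AdaLead


def _mutate(seqs: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Expected ``mu`` substitutions per sequence (to a different base)."""
    n, length, _ = seqs.shape
    out = seqs.copy()
    hit = rng.random((n, length)) < mu / length
    rows, cols = np.nonzero(hit)
    if len(rows):
        cur = seqs[rows, cols].argmax(axis=1)
        shift = rng.integers(1, 4, len(rows))
        new = (cur + shift) % 4
        out[rows, cols] = 0.0
        out[rows, cols, new] = 1.0
    return out


def adalead(
    model,
    objective: ObjectiveSpec,
    n_runs: int = 1,
    seed: int = 0,
    population: int = 20,
    generations: int = 30,
    mu: float = 1.0,
    recomb_rate: float = 0.1,
    threshold: float = 0.25,
    rho: int = 2,
    collect_min_mingap: float | None = 2.0,
    seq_length: int | None = None,
) -> DesignResult:
    """Adaptive greedy evolutionary search.

    Per run: ``population`` random sequences evolve for ``generations``
    rounds.  Parents are those within ``threshold`` (relative) of the
    generation's best fitness; children are produced by per-site
    recombination at ``recomb_rate`` and Poisson-like mutation with
    expectation ``mu``, then refined by a greedy rollout of depth ``rho``.
    Only the single best sequence of a run is collected, and only if its
    (unbent) MinGap is at least ``collect_min_mingap``.
    """
    length = seq_length or model.config.insert_length
    rng = np.random.default_rng(seed)
    target = objective.target_cell

    def fitness(batch: np.ndarray) -> np.ndarray:
        return objective.value(model.predict(batch, clamp=objective.clamp))

    seqs_out, acts_out, obj_out, rejected = [], [], [], 0
    trace: list[float] = []
    for run in range(n_runs):
        pop = random_sequences(population, length, rng)
        fit = fitness(pop)
        for gen in range(generations):
            fmax = fit.max()
            cut = fmax - threshold * abs(fmax)
            parents = pop[fit >= cut]
            if len(parents) == 0:
                parents = pop[[int(fit.argmax())]]
            # children: per-site crossover between two random parents at
            # recomb_rate (clone of the first parent when rate is 0)
            p1 = parents[rng.integers(0, len(parents), population)]
            p2 = parents[rng.integers(0, len(parents), population)]
            if recomb_rate <= 0:
                children = p1.copy()
            else:
                cross = (rng.random((population, length)) < recomb_rate)[..., None]
                children = np.where(cross, p2, p1)
            if mu > 0:
                children = _mutate(children, mu, rng)
            child_fit = fitness(children)
            # greedy rollout: keep mutating improvers up to depth rho - 1
            for _ in range(max(0, rho - 1)):
                if mu <= 0:
                    break
                trial = _mutate(children, mu, rng)
                trial_fit = fitness(trial)
                better = trial_fit > child_fit
                children[better] = trial[better]
                child_fit[better] = trial_fit[better]
            allpop = np.concatenate([pop, children])
            allfit = np.concatenate([fit, child_fit])
            order = np.argsort(-allfit, kind="stable")[:population]
            pop, fit = allpop[order], allfit[order]
            trace.append(float(fit.mean()))
            if all(np.array_equal(pop[0], q) for q in pop[1:]):
                logger.info("adalead run %d: population collapsed at generation %d",
                            run, gen)
                break
        best = int(fit.argmax())
        acts = model.predict(pop[[best]], clamp=objective.clamp)
        mg = float(min_gap_batch(acts, target)[0])
        if collect_min_mingap is not None and mg < collect_min_mingap:
            rejected += 1
            continue
        seqs_out.append(decode_onehot(pop[best]))
        acts_out.append(acts[0])
        obj_out.append(float(fit[best]))
    return DesignResult(
        sequences=seqs_out,
        activities=np.array(acts_out) if acts_out else np.zeros((0, model.config.n_outputs)),
        objective_values=np.array(obj_out),
        trace=trace,
        rejected_count=rejected,
        provenance={"algorithm": "adalead", "seed": seed, "mu": mu,
                    "recomb_rate": recomb_rate, "threshold": threshold,
                    "rho": rho, "population": population,
                    "generations": generations, "n_runs": n_runs},
    )


# ---------------------------------------------------------------------------
# simulated annealing


def simulated_annealing(
    model,
    objective: ObjectiveSpec | None = None,
    target_cell: int = 0,
    n_runs: int = 1,
    seed: int = 0,
    steps: int = 3000,
    n_mutations: int = 3,
    collect_min: float | None = None,
    return_best: bool = True,
    seq_length: int | None = None,
    energy_fn=None,
    record_acceptance: bool = False,
) -> DesignResult:
    """Metropolis-Hastings chain on sequence space.

    Energy is the negative (unbent) MinGap on clamped predictions; proposals
    mutate three uniformly chosen positions to uniformly chosen different
    bases (symmetric).  A worsening proposal (dE > 0) is accepted with
    probability exp(-dE / tau(s)) under the annealing schedule
    tau(s) = 1/(1 + s^0.501).  ``energy_fn`` (batch of one-hot -> energies)
    overrides the model-based energy, which lets the acceptance rule be
    validated on closed-form landscapes.
    """
    if objective is not None:
        target_cell = objective.target_cell
        clamp = objective.clamp
    else:
        clamp = (-2.0, 6.0)
    rng = np.random.default_rng(seed)
    if energy_fn is None:
        length = seq_length or model.config.insert_length

        def energy_fn(batch):
            return -min_gap_batch(model.predict(batch, clamp=clamp), target_cell)
    else:
        length = seq_length or 200

    state = random_sequences(n_runs, length, rng)
    energy = np.asarray(energy_fn(state), dtype=float)
    best_state, best_energy = state.copy(), energy.copy()
    trace = []
    acceptance_log: list[tuple[float, float, bool]] = []
    for s in range(steps):
        tau = anneal_temperature(s)
        prop = state.copy()
        for r in range(n_runs):
            pos = rng.choice(length, size=min(n_mutations, length), replace=False)
            cur = prop[r, pos].argmax(axis=1)
            new = (cur + rng.integers(1, 4, len(pos))) % 4
            prop[r, pos] = 0.0
            prop[r, pos, new] = 1.0
        e_prop = np.asarray(energy_fn(prop), dtype=float)
        de = e_prop - energy
        accept = (de <= 0) | (rng.random(n_runs) < np.exp(-np.maximum(de, 0) / tau))
        if record_acceptance:
            for r in range(n_runs):
                if de[r] > 0:
                    acceptance_log.append((tau, float(de[r]), bool(accept[r])))
        state[accept] = prop[accept]
        energy[accept] = e_prop[accept]
        improved = energy < best_energy
        best_state[improved] = state[improved]
        best_energy[improved] = energy[improved]
        trace.append(float(-energy.mean()))
    final_state = best_state if return_best else state
    final_obj = -(best_energy if return_best else energy)
    seqs, acts_out, obj_out, rejected = [], [], [], 0
    acts = (model.predict(final_state, clamp=clamp)
            if model is not None else np.zeros((n_runs, 1)))
    for r in range(n_runs):
        if collect_min is not None and final_obj[r] < collect_min:
            rejected += 1
            continue
        seqs.append(decode_onehot(final_state[r]))
        acts_out.append(acts[r])
        obj_out.append(float(final_obj[r]))
    return DesignResult(
        sequences=seqs,
        activities=np.array(acts_out) if acts_out else np.zeros((0, acts.shape[1])),
        objective_values=np.array(obj_out),
        trace=trace,
        rejected_count=rejected,
        provenance={"algorithm": "simulated_annealing", "seed": seed,
                    "steps": steps, "n_mutations": n_mutations,
                    "n_runs": n_runs, "return_best": return_best,
                    "acceptance_log": acceptance_log},
    )


# ---------------------------------------------------------------------------
# motif enrichment (built-in surrogate for external discovery tools)


_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def _shuffle_seqs(seqs: list[str], rng: np.random.Generator) -> list[str]:
    return ["".join(rng.permutation(list(s))) for s in seqs]


def _kmer_counts(seqs: list[str], w: int) -> dict[str, int]:
    from .mpra_data import rc_string

    counts: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - w + 1):
            kmer = s[i:i + w]
            if "N" in kmer:
                continue
            canon = min(kmer, rc_string(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def _ppm_from_windows(windows: list[str], width: int, pseudo: float = 0.5) -> np.ndarray:
    counts = np.full((width, 4), pseudo)
    for win in windows:
        for i, ch in enumerate(win):
            if ch in _BASE_IDX:
                counts[i, _BASE_IDX[ch]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def enrich_motifs(
    foreground: list[str],
    background: list[str] | None = None,
    n_motifs: int = 10,
    widths: range = range(8, 16),
    seed: int = 0,
    min_ratio: float = 1.5,
    em_iters: int = 2,
) -> list[MotifModel]:
    """Seed-and-extend motif enrichment of foreground vs background.

    The most over-represented w-mer (strand-canonical, smoothed fg/bg count
    ratio) seeds each motif; its foreground occurrences (up to one mismatch)
    are aligned into a PPM which is polished by a couple of EM-style rescan
    passes.  Found occurrences are masked before the next round.  Output is
    ranked by enrichment and may be shorter than ``n_motifs`` (empty if
    nothing exceeds ``min_ratio``).  Results from an external discovery tool
    in MEME format can be used interchangeably downstream.
    """
    from .mpra_data import rc_string

    if not foreground:
        raise ValueError("foreground is empty")
    if min(len(s) for s in foreground) < min(widths):
        raise ValueError("foreground sequences shorter than the minimum motif width")
    rng = np.random.default_rng(seed)
    fg = list(foreground)
    bg = background if background is not None else _shuffle_seqs(fg, rng)
    bg_counts = {w: _kmer_counts(bg, w) for w in widths}
    bg_totals = {w: max(1, sum(bg_counts[w].values())) for w in widths}
    found: list[MotifModel] = []
    for round_i in range(n_motifs):
        best = None  # (ratio, kmer, w)
        for w in widths:
            fgc = _kmer_counts(fg, w)
            total_fg = max(1, sum(fgc.values()))
            for kmer, c in fgc.items():
                if c < 3:
                    continue
                b = bg_counts[w].get(kmer, 0)
                ratio = (c / total_fg) / ((b + 1) / bg_totals[w])
                score = ratio * math.log1p(c)
                if best is None or score > best[0]:
                    best = (score, ratio, kmer, w)
        if best is None or best[1] < min_ratio:
            break
        _, _, seed_kmer, w = best
        wins = []
        pats = (seed_kmer, rc_string(seed_kmer))
        for s in fg:
            for i in range(len(s) - w + 1):
                sub = s[i:i + w]
                if "N" in sub:
                    continue
                if sum(a != b for a, b in zip(sub, pats[0])) <= 1:
                    wins.append(sub)
                elif sum(a != b for a, b in zip(sub, pats[1])) <= 1:
                    wins.append(rc_string(sub))
        if not wins:
            break
        ppm = _ppm_from_windows(wins, w)
        # EM polish: rescan with the PWM, rebuild from best-scoring windows
        for _ in range(em_iters):
            motif = MotifModel(ppm, id="tmp")
            thr = 0.6 * motif.consensus_score
            wins = []
            rc_pwm = motif.reverse_complement().pwm
            for s in fg:
                best_sc, best_win = -np.inf, None
                for i in range(len(s) - w + 1):
                    sub = s[i:i + w]
                    if "N" in sub:
                        continue
                    idx = [_BASE_IDX[ch] for ch in sub]
                    sc = sum(motif.pwm[j, b] for j, b in enumerate(idx))
                    sc_rc = sum(rc_pwm[j, b] for j, b in enumerate(idx))
                    if sc_rc > sc:
                        sc, sub = sc_rc, rc_string(sub)
                    if sc > best_sc:
                        best_sc, best_win = sc, sub
                if best_win is not None and best_sc >= thr:
                    wins.append(best_win)
            if len(wins) < 3:
                break
            ppm = _ppm_from_windows(wins, w)
        motif = MotifModel(ppm, id=f"enriched_{round_i + 1}", source="discovered")
        found.append(motif)
        # mask occurrences before the next round
        thr = 0.7 * motif.consensus_score
        rc_pwm = motif.reverse_complement().pwm
        masked_fg = []
        for s in fg:
            chars = list(s)
            for i in range(len(s) - w + 1):
                sub = s[i:i + w]
                if "N" in sub:
                    continue
                idx = [_BASE_IDX[ch] for ch in sub]
                sc = max(sum(motif.pwm[j, b] for j, b in enumerate(idx)),
                         sum(rc_pwm[j, b] for j, b in enumerate(idx)))
                if sc >= thr:
                    chars[i:i + w] = ["N"] * w
            masked_fg.append("".join(chars))
        fg = masked_fg
    return found


# ---------------------------------------------------------------------------
# penalization track


def penalization_track(
    model,
    target_cell: int,
    seed: int = 0,
    rounds: int = 5,
    batch_round0: int = 500,
    batch_penalized: int = 250,
    threshold_fraction: float = 0.25,
    n_motifs: int = 10,
    widths: range = range(8, 16),
    fsp_kwargs: dict | None = None,
) -> tuple[list[DesignResult], PenaltyPool]:
    """Iterative design with a growing motif-penalty pool.

    Round 0 designs a non-penalized batch; its top enriched motif seeds the
    pool.  Each later round designs a smaller batch penalizing the current
    pool, then appends that round's top enriched motif.  Per-motif score
    thresholds are ``threshold_fraction`` x consensus score (0 makes the
    penalty maximally stringent).  Halts early with partial results if
    enrichment finds no motif.
    """
    fsp_kwargs = dict(fsp_kwargs or {})
    fsp_kwargs.setdefault("collect_min", None)  # keep batch sizes fixed
    pool = PenaltyPool()
    results: list[DesignResult] = []
    for round_i in range(rounds + 1):
        n = batch_round0 if round_i == 0 else batch_penalized
        objective = ObjectiveSpec(target_cell=target_cell,
                                  penalty=pool if round_i > 0 else None)
        res = fast_seqprop(model, objective, n_runs=n,
                           seed=seed + 1000 * round_i, **fsp_kwargs)
        res.provenance["round"] = round_i
        res.provenance["pool_size"] = len(pool)
        results.append(res)
        if round_i == rounds:
            break
        motifs = enrich_motifs(res.sequences, n_motifs=n_motifs, widths=widths,
                               seed=seed + 1000 * round_i + 500)
        if not motifs:
            logger.warning("penalization track: no enriched motif at round %d; "
                           "halting with partial results", round_i)
            break
        top = motifs[0]
        pool.add(top, threshold_fraction * top.consensus_score)
    return results, pool
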