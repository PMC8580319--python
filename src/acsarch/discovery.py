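"""Greedy sequential motif discovery by expectation-maximization.

The occurrence model is ZOOPS (zero or one occurrence per sequence): each
sequence carries at most one copy of the motif, with prior probability
gamma that it carries one at all.  Discovery proceeds greedily: run EM from
several seeded starting points per candidate width, keep the motif with the
best penalized log-likelihood ratio, probabilistically erase its
occurrences, and repeat until the motif budget is exhausted or no candidate
clears the significance floor.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from acsarch.motifs import (
    BackgroundModel,
    MotifModel,
    MotifError,
    DEFAULT_PSEUDOCOUNT,
    build_motif_model,
    encode,
    estimate_background,
)


@dataclass(frozen=True)
class MotifOccurrence:
    sequence_id: str
    start: int           # 0-based
    instance: str
    posterior: float


@dataclass(frozen=True)
class DiscoveredMotif:
    """A discovered motif with its supporting occurrences and EM diagnostics."""

    model: MotifModel
    occurrences: list[MotifOccurrence]
    llr: float
    criterion: float     # llr penalized by log(#possible alignments)

    @property
    def consensus(self) -> str:
        return self.model.consensus

    @property
    def nsites(self) -> int:
        return len(self.occurrences)


def _em_zoops(enc_seqs, erasure_logs, width, background, rng, n_restarts,
              max_iter, tol, pseudocount, mode):
    """Best-of-restarts EM for one width.  Returns (llr, theta, gamma, z_list)."""
    n = len(background.alphabet)
    log_bg = np.log(background.frequencies)
    windows = [len(e) - width + 1 for e in enc_seqs]
    usable = [i for i, w in enumerate(windows) if w >= 1]
    if not usable:
        return None

    # deterministic restart seeds: distinct subsequence windows
    starts = []
    for _ in range(n_restarts):
        s = usable[rng.integers(len(usable))]
        j = int(rng.integers(windows[s]))
        starts.append((s, j))

    # per-sequence per-window erasure log-weight, window products via cumsum
    erasure_win = []
    for s, e in enumerate(enc_seqs):
        if windows[s] < 1:
            erasure_win.append(np.zeros(0))
            continue
        c = np.concatenate([[0.0], np.cumsum(erasure_logs[s])])
        erasure_win.append(c[width:] - c[:-width])

    best = None
    for (s0, j0) in starts:
        theta = np.tile(background.frequencies, (width, 1)) * 0.4
        seed_window = enc_seqs[s0][j0:j0 + width]
        for i, a in enumerate(seed_window):
            if a < n:
                theta[i, a] += 0.6
        theta /= theta.sum(axis=1, keepdims=True)
        gamma = 0.5 if mode == "zoops" else 1.0

        llr_prev = -np.inf
        llr = 0.0
        z_list = None
        for _ in range(max_iter):
            log_theta = np.log(theta)
            # log ratio per window, per sequence; ambiguous letters neutral
            log_ratio_cols = np.vstack([log_theta.T - log_bg[:, None]]).T  # (w, n)
            log_ratio_cols = np.hstack(
                [log_ratio_cols, np.zeros((width, 1))])
            llr = 0.0
            z_list = []
            exp_counts = np.zeros((width, n))
            z_total = 0.0
            for s, e in enumerate(enc_seqs):
                W = windows[s]
                if W < 1:
                    z_list.append(np.zeros(0))
                    continue
                lr = np.zeros(W)
                for i in range(width):
                    lr += log_ratio_cols[i][e[i:i + W]]
                lw = lr + erasure_win[s]
                if mode == "zoops":
                    lw = lw + np.log(gamma / W)
                    terms = np.concatenate([[np.log1p(-gamma)], lw])
                else:  # oops
                    lw = lw - np.log(W)
                    terms = lw
                Z = logsumexp(terms)
                llr += Z
                z = np.exp(lw - Z)
                z_list.append(z)
                z_total += z.sum()
                for i in range(width):
                    idx = e[i:i + W]
                    std = idx < n
                    np.add.at(exp_counts[i], idx[std], z[std])
            # M-step
            theta = (exp_counts + pseudocount * background.frequencies) \
                / (exp_counts.sum(axis=1, keepdims=True) + pseudocount)
            if mode == "zoops":
                gamma = min(max(z_total / len(usable), 1.0 / (2 * len(usable))),
                            0.999)
            if abs(llr - llr_prev) < tol:
                break
            llr_prev = llr
        if best is None or llr > best[0]:
            best = (llr, theta, gamma, z_list)
    return best


def _instance_log_odds(instances, background, pseudocount) -> float:
    """Total log-odds of instances under the PWM they themselves define."""
    model = build_motif_model(instances, background, pseudocount,
                              allow_any_width=True)
    n = len(background.alphabet)
    total = 0.0
    for inst in instances:
        enc = encode(inst, background.alphabet)
        for i, a in enumerate(enc):
            if a < n:
                total += model.log_odds[i, a]
    return total


def _refine_phase(seqs, occ_idx, width, background, pseudocount):
    """Pick the rigid register shift maximizing the alignment's log-odds.

    ``occ_idx`` holds (sequence ordinal, start, posterior) triples.  Only
    shifts keeping every occurrence inside its sequence are considered.
    """
    best_shift, best_score = 0, None
    for shift in range(-(width // 2), width // 2 + 1):
        if all(0 <= j + shift <= len(seqs[s]) - width
               for s, j, _ in occ_idx):
            instances = [seqs[s][j + shift:j + shift + width]
                         for s, j, _ in occ_idx]
            score = _instance_log_odds(instances, background, pseudocount)
            if best_score is None or score > best_score + 1e-9 or \
                    (abs(score - best_score) <= 1e-9 and
                     abs(shift) < abs(best_shift)):
                best_shift, best_score = shift, score
    return [(s, j + best_shift, z) for s, j, z in occ_idx], best_shift


def discover_motifs(sequences, min_width: int = 6, max_width: int = 50,
                    max_motifs: int = 25, mode: str = "zoops",
                    n_restarts: int = 20, max_iter: int = 200,
                    tol: float = 1e-6, seed: int = 0,
                    background: BackgroundModel | None = None,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    sequence_ids=None) -> list[DiscoveredMotif]:
    """Greedy sequential ZOOPS/OOPS motif discovery.

    Parameters mirror the conventional discovery setup: motif widths 6-50,
    up to 25 motifs.  A motif is retained only if its log-likelihood ratio
    exceeds log of the number of possible alignments (an E-value-like
    significance floor), so degenerate inputs yield zero motifs rather than
    a spurious one.

    Returns :class:`DiscoveredMotif` records in discovery order.
    """
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise MotifError("discovery needs at least two sequences")
    if min(len(s) for s in seqs) <= min_width:
        raise MotifError("every sequence must be longer than min_width")
    if mode not in ("zoops", "oops"):
        raise MotifError(f"unknown occurrence mode {mode!r}")
    if background is None:
        background = estimate_background(seqs)
    if sequence_ids is None:
        sequence_ids = [f"seq{i}" for i in range(len(seqs))]
    n = len(background.alphabet)
    enc_seqs = [encode(s, background.alphabet) for s in seqs]
    rng = np.random.default_rng(seed)
    erasure_logs = [np.zeros(len(e)) for e in enc_seqs]

    found: list[DiscoveredMotif] = []
    for _round in range(max_motifs):
        best_width = None
        for width in range(min_width, max_width + 1):
            if max(len(e) for e in enc_seqs) < width:
                continue
            res = _em_zoops(enc_seqs, erasure_logs, width, background, rng,
                            n_restarts, max_iter, tol, pseudocount, mode)
            if res is None:
                continue
            llr, theta, gamma, z_list = res
            total_windows = sum(max(len(e) - width + 1, 0) for e in enc_seqs)
            crit = llr - np.log(max(total_windows, 1))
            if best_width is None or crit > best_width[0]:
                best_width = (crit, llr, width, theta, gamma, z_list)
        if best_width is None:
            break
        crit, llr, width, theta, gamma, z_list = best_width
        if crit <= 0:
            break
        # hard occurrences: best window per sequence with posterior > 0.5
        occ_idx: list[tuple[int, int, float]] = []
        for s, z in enumerate(z_list):
            if len(z) == 0:
                continue
            j = int(np.argmax(z))
            if z[j] > 0.5:
                occ_idx.append((s, j, float(z[j])))
        if len(occ_idx) < 2:
            break
        # EM can converge to a shifted register of the true alignment; try
        # rigid shifts of every occurrence and keep the best register
        for _ in range(6):   # iterate: large registers converge in steps
            occ_idx, shift = _refine_phase(seqs, occ_idx, width, background,
                                           pseudocount)
            if shift == 0:
                break
        occurrences = [MotifOccurrence(sequence_ids[s], j,
                                       seqs[s][j:j + width], z)
                       for s, j, z in occ_idx]
        instances = [o.instance for o in occurrences]
        model = build_motif_model(instances, background, pseudocount,
                                  motif_id=f"motif{len(found) + 1}",
                                  allow_any_width=True)
        found.append(DiscoveredMotif(model=model, occurrences=occurrences,
                                     llr=float(llr), criterion=float(crit)))
        # probabilistic erasure of the claimed occurrences
        for s, j, z in occ_idx:
            keep = max(1.0 - z, 1e-10)
            erasure_logs[s][j:j + width] += np.log(keep)
    return found
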