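"""De novo motif discovery and PWM scanning.

The searcher is a zero-or-one-occurrence-per-sequence (ZOOPS) Gibbs
sampler over both strands: for each width in the requested range and each
restart it iterates site resampling to convergence, the best model per
motif slot is kept (smallest Fisher-combined best-hit p over sequences),
and the chosen sites are masked before the next motif slot is searched.

Scanning uses log-odds scores against a background base composition with
exact per-hit p-values: the null distribution of the integerized score is
computed by dynamic-programming convolution over the PWM columns
(discretization step 0.01 bits by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from mscm.model import Motif, MotifHit

BASE_ORDER = "ACGT"
_ENC = {b: i for i, b in enumerate(BASE_ORDER)}
_ENC["N"] = 4
UNIFORM_BG = np.full(4, 0.25)
#: probability floor applied to PWM entries before taking log-odds
PWM_FLOOR = 1e-10
#: sentinel column score for masked (N) bases: any window touching an N
#: scores far below every achievable PWM score
_N_SCORE = -(10 ** 7)


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[c] for c in seq), dtype=np.int64, count=len(seq))


def reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    return np.asarray(pwm)[::-1, ::-1]


@dataclass
class ScanResult:
    best: Optional[MotifHit]
    hits: List[MotifHit] = field(default_factory=list)


class PwmScanner:
    """Log-odds scanner for one PWM with an exact integer-score null.

    The null distribution is over a single aligned position drawn from the
    background; both strands use their own score table and null (these
    coincide under a strand-symmetric background).
    """

    def __init__(self, pwm: np.ndarray, background: Optional[np.ndarray] = None,
                 step_bits: float = 0.01):
        self.pwm = np.asarray(pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must have shape (width, 4)")
        self.width = self.pwm.shape[0]
        self.background = UNIFORM_BG if background is None else np.asarray(background, float)
        self.background = self.background / self.background.sum()
        self.step_bits = float(step_bits)
        self._fwd = self._int_table(self.pwm)
        self._rev = self._int_table(reverse_complement_pwm(self.pwm))
        self._fwd_null = _score_null(self._fwd[:, :4], self.background)
        self._rev_null = _score_null(self._rev[:, :4], self.background)

    def _int_table(self, pwm: np.ndarray) -> np.ndarray:
        logodds = np.log2(np.clip(pwm, PWM_FLOOR, None) / self.background[None, :])
        ints = np.rint(logodds / self.step_bits).astype(np.int64)
        table = np.empty((self.width, 5), dtype=np.int64)
        table[:, :4] = ints
        table[:, 4] = _N_SCORE
        return table

    def window_scores(self, enc: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Integer scores at every offset, forward and reverse strand."""
        if enc.size < self.width:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        win = sliding_window_view(enc, self.width)
        cols = np.arange(self.width)
        fwd = self._fwd[cols[None, :], win].sum(axis=1)
        rev = self._rev[cols[None, :], win].sum(axis=1)
        return fwd, rev

    def logp(self, int_score: int, strand: str = "+") -> float:
        """Natural-log p-value of an integer score: P(S >= score) under
        the background null for that strand's score table."""
        scores, tail = self._fwd_null if strand == "+" else self._rev_null
        idx = int(np.searchsorted(scores, int_score, side="left"))
        p = tail[idx] if idx < tail.size else 0.0
        return math.log(max(float(p), 1e-300))

    def scan(self, sequence: str, threshold_p: float = 0.01) -> ScanResult:
        """Best hit (reported regardless of threshold) plus all hits with
        p below ``threshold_p``.  Reverse-strand hits are reported by the
        start of the match on the stored sequence."""
        enc = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
        fwd, rev = self.window_scores(enc)
        if fwd.size == 0:
            return ScanResult(best=None, hits=[])
        log_thresh = math.log(threshold_p)
        hits: List[MotifHit] = []
        best: Optional[MotifHit] = None
        best_score = None
        for strand, scores in (("+", fwd), ("-", rev)):
            top = int(scores.argmax())
            top_logp = self.logp(int(scores[top]), strand)
            # "+" is scanned first, so it wins exact ties
            if best is None or scores[top] > best_score:
                best = MotifHit(start=top, strand=strand, logp=min(top_logp, 0.0))
                best_score = scores[top]
            for pos in np.nonzero(scores >= _hit_floor(self, strand, log_thresh))[0]:
                lp = self.logp(int(scores[pos]), strand)
                if lp <= log_thresh:
                    hits.append(MotifHit(start=int(pos), strand=strand, logp=min(lp, 0.0)))
        hits.sort(key=lambda h: (h.start, h.strand))
        return ScanResult(best=best, hits=hits)


def _hit_floor(scanner: PwmScanner, strand: str, log_thresh: float) -> int:
    """Smallest integer score whose p-value is below the threshold."""
    scores, tail = scanner._fwd_null if strand == "+" else scanner._rev_null
    ok = np.nonzero(np.log(np.maximum(tail, 1e-300)) <= log_thresh)[0]
    return int(scores[ok[0]]) if ok.size else int(scores[-1]) + 1


def _score_null(int_table: np.ndarray, background: np.ndarray):
    """Exact distribution of the integer score of one background-drawn
    window: DP convolution over PWM columns.

    Returns (ascending unique scores, survival probabilities P(S >= s)).
    """
    cur = np.ones(1)
    cur_lo = 0
    for j in range(int_table.shape[0]):
        col = int_table[j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + cur.size - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(col[b]) - new_lo
            new[off:off + cur.size] += background[b] * cur
        cur, cur_lo = new, new_lo
    scores = np.arange(cur_lo, cur_lo + cur.size)
    nz = cur > 0
    scores = scores[nz]
    probs = cur[nz]
    tail = np.cumsum(probs[::-1])[::-1]
    return scores, tail


def scan_promoter(pwm: np.ndarray, sequence: str,
                  background: Optional[np.ndarray] = None,
                  threshold_p: float = 0.01, step_bits: float = 0.01) -> ScanResult:
    """Scan one promoter with a PWM; see :class:`PwmScanner`.

    A sequence shorter than the PWM width yields a no-hit result.
    """
    return PwmScanner(pwm, background=background, step_bits=step_bits).scan(
        sequence, threshold_p=threshold_p
    )


# ---------------------------------------------------------------------------
# ZOOPS Gibbs sampler
# ---------------------------------------------------------------------------

def _site_counts(windows, sites, width):
    counts = np.zeros((width, 4))
    for gene, site in sites.items():
        if site is None:
            continue
        pos, strand = site
        win = windows[gene][pos]
        if strand == "-":
            win = 3 - win[::-1]
        for j in range(width):
            counts[j, win[j]] += 1
    return counts


def _pwm_from_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    num = counts + pseudocount
    return num / num.sum(axis=1, keepdims=True)


def find_motifs(
    promoters: Dict[str, str],
    n_motifs: int = 3,
    width_range: Tuple[int, int] = (6, 24),
    n_restarts: int = 5,
    seed: Optional[int] = None,
    max_sweeps: int = 500,
    tol: float = 1e-6,
    background: Optional[np.ndarray] = None,
    zoops_prior: float = 0.8,
    pseudocount: float = 0.25,
    step_bits: float = 0.01,
) -> List[Motif]:
    """Search member promoters for up to ``n_motifs`` ungapped motifs.

    Returns motifs ordered by discovery; each carries a per-gene best hit
    (log p-value) from scanning the final PWM over every input promoter,
    and an E-value surrogate: the Fisher combination of per-sequence
    best-hit p-values times the number of width/restart hypotheses.
    Deterministic given ``seed``.  With fewer than 3 usable promoters a
    warning is issued and the empty list returned.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    genes = sorted(promoters)
    w_lo, w_hi = int(width_range[0]), int(width_range[1])
    usable = [g for g in genes if len(promoters[g]) >= w_hi]
    if len(usable) < 3:
        usable = [g for g in genes if len(promoters[g]) >= w_lo]
    if len(usable) < 3:
        warnings.warn("fewer than 3 usable promoters; motif search skipped")
        return []
    rng = np.random.default_rng(seed)
    # working copies that get masked as motifs are fixed
    work = {g: encode(promoters[g]) for g in genes}

    n_hypotheses = (w_hi - w_lo + 1) * n_restarts
    motifs: List[Motif] = []
    for slot in range(1, n_motifs + 1):
        best = None  # (p_comb, pwm, sites, width)
        for width in range(w_lo, w_hi + 1):
            windows = {}
            valid = {}
            for g in usable:
                enc = work[g]
                if enc.size < width:
                    continue
                win = sliding_window_view(enc, width)
                ok = ~(win == 4).any(axis=1)
                if ok.any():
                    windows[g] = win
                    valid[g] = ok
            if len(windows) < 3:
                continue
            for _ in range(n_restarts):
                sites, _ll = _gibbs_run(windows, valid, width, rng, zoops_prior,
                                        pseudocount, bg, max_sweeps, tol)
                counts = _site_counts(windows, sites, width)
                if counts.sum() < 2:
                    continue
                pwm = _pwm_from_counts(counts, pseudocount)
                p_comb = _fisher_best_hit_p(pwm, work, list(windows), bg, step_bits)
                if best is None or p_comb < best[0]:
                    best = (p_comb, pwm, dict(sites), width)
        if best is None:
            break
        p_comb, pwm, sites, width = best
        scanner = PwmScanner(pwm, background=bg, step_bits=step_bits)
        hits: Dict[str, MotifHit] = {}
        for g in genes:
            res = scanner.scan(work[g])
            if res.best is not None:
                hits[g] = res.best
        motifs.append(
            Motif(motif_id=slot, pwm=pwm, hits=hits,
                  evalue=float(p_comb * n_hypotheses))
        )
        # mask the chosen sites before the next motif slot
        for g, site in sites.items():
            if site is None:
                continue
            pos, _strand = site
            work[g] = work[g].copy()
            work[g][pos:pos + width] = 4
    return motifs


def _gibbs_run(windows, valid, width, rng, zoops_prior, pseudocount, bg,
               max_sweeps, tol):
    genes = sorted(windows)
    sites: Dict[str, Optional[Tuple[int, str]]] = {}
    for g in genes:
        ok = np.nonzero(valid[g])[0]
        pos = int(ok[rng.integers(ok.size)])
        strand = "+" if rng.random() < 0.5 else "-"
        sites[g] = (pos, strand)
    counts = _site_counts(windows, sites, width)
    prev_ll = -np.inf
    for _sweep in range(max_sweeps):
        for g in genes:
            site = sites[g]
            if site is not None:
                _remove_site(counts, windows, g, site, width)
            pwm = _pwm_from_counts(counts, pseudocount)
            logodds = np.log2(np.clip(pwm, PWM_FLOOR, None) / bg[None, :])
            cols = np.arange(width)
            win = windows[g]
            fwd = np.where(valid[g], logodds[cols[None, :], np.minimum(win, 3)].sum(axis=1),
                           -np.inf)
            rc_lo = logodds[::-1, ::-1]
            rev = np.where(valid[g], rc_lo[cols[None, :], np.minimum(win, 3)].sum(axis=1),
                           -np.inf)
            n_pos = int(valid[g].sum())
            log_site_prior = math.log(zoops_prior / (2 * n_pos))
            log_w = np.concatenate([
                fwd * math.log(2) + log_site_prior,
                rev * math.log(2) + log_site_prior,
                [math.log(1 - zoops_prior)],
            ])
            mx = log_w.max()
            w = np.exp(log_w - mx)
            w /= w.sum()
            choice = int(rng.choice(w.size, p=w))
            if choice == w.size - 1:
                sites[g] = None
            else:
                strand = "+" if choice < fwd.size else "-"
                pos = choice if choice < fwd.size else choice - fwd.size
                sites[g] = (int(pos), strand)
                _add_site(counts, windows, g, sites[g], width)
        ll = _complete_ll(counts, sites, windows, valid, width, pseudocount, bg, zoops_prior)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return sites, prev_ll


def _remove_site(counts, windows, gene, site, width):
    pos, strand = site
    win = windows[gene][pos]
    if strand == "-":
        win = 3 - win[::-1]
    for j in range(width):
        counts[j, win[j]] -= 1


def _add_site(counts, windows, gene, site, width):
    pos, strand = site
    win = windows[gene][pos]
    if strand == "-":
        win = 3 - win[::-1]
    for j in range(width):
        counts[j, win[j]] += 1


def _complete_ll(counts, sites, windows, valid, width, pseudocount, bg, zoops_prior):
    pwm = _pwm_from_counts(counts, pseudocount)
    logodds = np.log2(np.clip(pwm, PWM_FLOOR, None) / bg[None, :])
    cols = np.arange(width)
    ll = 0.0
    for g, site in sites.items():
        n_pos = int(valid[g].sum())
        if site is None:
            ll += math.log(1 - zoops_prior)
            continue
        pos, strand = site
        win = windows[g][pos]
        if strand == "-":
            win = 3 - win[::-1]
        ll += logodds[cols, np.minimum(win, 3)].sum() * math.log(2)
        ll += math.log(zoops_prior / (2 * n_pos))
    return ll


def _fisher_best_hit_p(pwm, work, genes, bg, step_bits) -> float:
    scanner = PwmScanner(pwm, background=bg, step_bits=step_bits)
    logps = []
    for g in genes:
        res = scanner.scan(work[g])
        if res.best is not None:
            logps.append(res.best.logp)
    if not logps:
        return 1.0
    chi2 = -2.0 * sum(logps)
    return float(stats.chi2.sf(chi2, 2 * len(logps)))


# ---------------------------------------------------------------------------
# motif comparison
# ---------------------------------------------------------------------------

def _column_r(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def motif_similarity(pwm1: np.ndarray, pwm2: np.ndarray, min_overlap: int = 5) -> float:
    """Similarity in [0, 1] of two PWMs of possibly different widths.

    Maximum over all ungapped offsets and both orientations of the mean
    per-column Pearson correlation of the probability vectors, mapped to
    [0, 1] via (r + 1) / 2.  Overlaps shorter than ``min_overlap`` columns
    contribute nothing; if no offset reaches the minimum overlap the
    similarity is 0.
    """
    p1 = np.asarray(pwm1, float)
    best = 0.0
    for p2 in (np.asarray(pwm2, float), reverse_complement_pwm(pwm2)):
        w1, w2 = p1.shape[0], p2.shape[0]
        for off in range(-(w2 - 1), w1):
            lo1, hi1 = max(0, off), min(w1, off + w2)
            if hi1 - lo1 < min_overlap:
                continue
            rs = [
                _column_r(p1[i], p2[i - off])
                for i in range(lo1, hi1)
            ]
            sim = (float(np.mean(rs)) + 1.0) / 2.0
            best = max(best, sim)
    return best
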