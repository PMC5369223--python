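"""Dirichlet-multinomial change-point segmentation-classification model.

The encoded symbol sequence is modelled as a concatenation of homogeneous
segments.  Change-point indicators at every between-symbol boundary are
a-priori independent Bernoulli(phi) — '#' boundaries are fixed change-points
with probability 1 — so the number of change-points varies.  Each segment
draws a class label from Categorical(pi) and its own composition theta from
the class Dirichlet(alpha_c); theta is collapsed analytically, so a segment
of class c with symbol counts n contributes the ordered Dirichlet-
multinomial marginal

    log M(n | alpha_c) = log Gamma(A) - log Gamma(A + N)
                         + sum_j [log Gamma(alpha_cj + n_j) - log Gamma(alpha_cj)]

with A = sum_j alpha_cj, N = sum_j n_j (no multinomial coefficient:
segments are ordered strings, and the coefficient cancels in every ratio).

Sampling is by partially-collapsed Gibbs: a left-to-right sweep resamples
every free boundary indicator jointly with the labels of the affected
segments (labels summed out in the toggle odds, then redrawn), followed by
conjugate updates of pi and, optionally, phi, and random-walk Metropolis on
log alpha_c.  The sweep kernel is JIT-compiled with numba and uses
incremental updates of segment marginals, so one sweep costs O(n) plus
O(32 T) per segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln, logsumexp

from cpseg.encoding import ALPHABET, EncodedSequence

N_SYMBOLS = 32

# symbols whose reference-strand base is G or C (strand-invariant)
_REF_GC_SYMBOLS = np.array([i % 4 in (1, 2) for i in range(N_SYMBOLS)])


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Sampler configuration.

    Parameters
    ----------
    T:
        Number of segment classes (>= 1).
    alpha0:
        Initial per-class Dirichlet parameters, shape (T, 32).  Default:
        all-ones with a small seeded jitter to break class symmetry.
    cp_prior_phi:
        Prior change-point probability per free boundary, or ``"sample"``
        to place a flat Beta(1, 1) hyperprior on it.
    pi_prior:
        Dirichlet parameter (scalar or length-T) for the class mixture.
    n_iter, thin:
        Number of sweeps and thinning interval.
    sample_pi, sample_alpha:
        Disable to hold pi (at its normalized prior) / alpha (at alpha0)
        fixed — used by the exact-enumeration oracle, which requires fixed
        parameters.
    alpha_mh_steps, alpha_step_size:
        Metropolis steps per class per sweep on log alpha, and the
        random-walk scale.
    """

    T: int = 2
    alpha0: np.ndarray | None = None
    cp_prior_phi: float | str = 0.01
    pi_prior: float | np.ndarray = 1.0
    seed: int = 0
    n_iter: int = 1000
    thin: int = 1
    sample_pi: bool = True
    sample_alpha: bool = True
    alpha_mh_steps: int = 2
    alpha_step_size: float = 0.2
    alpha_prior_rate: float = 1e-3
    alpha_jitter: float = 0.05
    warm_start: bool = True
    warm_window: int = 200
    warm_restarts: int = 5
    warm_kappa: float = 100.0

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (isinstance(self.cp_prior_phi, str) and self.cp_prior_phi == "sample"):
            phi = float(self.cp_prior_phi)
            if not (0.0 < phi < 1.0):
                raise ValueError("cp_prior_phi must be in (0, 1) or 'sample'")
        if self.alpha0 is not None:
            a = np.asarray(self.alpha0, dtype=float)
            if a.shape != (self.T, N_SYMBOLS):
                raise ValueError(f"alpha0 must have shape ({self.T}, {N_SYMBOLS})")
            if np.any(a <= 0):
                raise ValueError("all Dirichlet parameters must be > 0")

    def pi_prior_vector(self) -> np.ndarray:
        p = np.asarray(self.pi_prior, dtype=float)
        if p.ndim == 0:
            p = np.full(self.T, float(p))
        if p.shape != (self.T,) or np.any(p <= 0):
            raise ValueError("pi_prior must be positive, scalar or length-T")
        return p


@dataclass
class SampleTrace:
    """Thinned per-sweep records of the sampler state.

    ``seg_starts[r]`` are the segment start positions of record ``r`` (the
    change-point set is ``starts[1:] - 1`` as boundary indices) and
    ``seg_labels[r]`` the matching class labels.  ``theta`` holds, per
    record and class, the posterior-predictive mean composition given the
    sweep's class-aggregated counts and alpha.
    """

    config: ModelConfig
    n: int
    fixed_boundaries: np.ndarray
    loglik: np.ndarray  # (R,)
    n_changepoints: np.ndarray  # (R,)
    pi: np.ndarray  # (R, T)
    theta: np.ndarray  # (R, T, 32)
    alpha: np.ndarray  # (T, 32) final state
    phi: np.ndarray  # (R,)
    seg_starts: list = field(default_factory=list)
    seg_labels: list = field(default_factory=list)
    seg_label_probs: list = field(default_factory=list)
    alpha_accept_rate: float = 0.0

    @property
    def n_records(self) -> int:
        return len(self.loglik)

    def boundary_marginals(self, burnin: int = 0) -> np.ndarray:
        """Posterior frequency of a change-point at each boundary."""
        out = np.zeros(self.n - 1)
        recs = range(burnin, self.n_records)
        count = 0
        for r in recs:
            b = self.seg_starts[r][1:] - 1
            out[b] += 1
            count += 1
        if count == 0:
            raise ValueError("no post-burn-in records")
        return out / count

    def save(self, directory) -> None:
        """Serialize the trace as a directory of plain-text tables."""
        import os

        import yaml

        os.makedirs(directory, exist_ok=True)
        cfg = {
            "T": self.config.T,
            "cp_prior_phi": self.config.cp_prior_phi,
            "n_iter": self.config.n_iter,
            "thin": self.config.thin,
            "seed": self.config.seed,
            "n": int(self.n),
        }
        with open(os.path.join(directory, "config.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh)
        np.savetxt(
            os.path.join(directory, "loglik.tsv"),
            np.column_stack([np.arange(self.n_records), self.loglik, self.n_changepoints]),
            fmt=["%d", "%.6f", "%d"],
            header="record\tloglik\tn_changepoints",
            delimiter="\t",
            comments="",
        )
        T = self.config.T
        theta2 = self.theta.reshape(self.n_records, T * N_SYMBOLS)
        np.savetxt(
            os.path.join(directory, "theta.tsv"), theta2, fmt="%.6g", delimiter="\t"
        )
        np.savetxt(os.path.join(directory, "pi.tsv"), self.pi, fmt="%.6g", delimiter="\t")
        with open(os.path.join(directory, "segments.tsv"), "w") as fh:
            fh.write("record\tstarts\tlabels\n")
            for r in range(self.n_records):
                starts = ",".join(map(str, self.seg_starts[r]))
                labs = ",".join(map(str, self.seg_labels[r]))
                fh.write(f"{r}\t{starts}\t{labs}\n")


# ---------------------------------------------------------------------------
# collapsed segment marginal


def segment_log_marginal(counts: Sequence[float], alpha: Sequence[float]) -> float:
    """Log ordered Dirichlet-multinomial marginal of one segment.

    ``log ∫ prod_i theta_{x_i} Dirichlet(theta | alpha) dtheta`` for a
    segment whose symbol counts are ``counts``.  Zero for an empty segment.
    """
    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("all Dirichlet parameters must be > 0")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    A = alpha.sum()
    N = counts.sum()
    return float(
        gammaln(A)
        - gammaln(A + N)
        + np.sum(gammaln(alpha + counts) - gammaln(alpha))
    )


def _class_log_marginals(counts_matrix: np.ndarray, alpha_c: np.ndarray) -> float:
    """Sum of segment log marginals for all segments of one class (vectorized)."""
    if counts_matrix.shape[0] == 0:
        return 0.0
    A = alpha_c.sum()
    N = counts_matrix.sum(axis=1)
    per_seg = (
        gammaln(A)
        - gammaln(A + N)
        + np.sum(gammaln(alpha_c[None, :] + counts_matrix) - gammaln(alpha_c)[None, :], axis=1)
    )
    return float(per_seg.sum())


# ---------------------------------------------------------------------------
# numba sweep kernel


@njit(cache=True, fastmath=False)
def _seg_lm(prefix, s, e, alpha, sumA, lgalpha, out):
    T = alpha.shape[0]
    N = e - s
    for c in range(T):
        acc = 0.0
        for j in range(32):
            nj = prefix[e, j] - prefix[s, j]
            if nj > 0:
                a = alpha[c, j]
                acc += math.lgamma(a + nj) - math.lgamma(a)
        A = sumA[c]
        out[c] = acc + math.lgamma(A) - math.lgamma(A + N)


@njit(cache=True)
def _lse(x):
    m = x[0]
    for i in range(1, x.size):
        if x[i] > m:
            m = x[i]
    s = 0.0
    for i in range(x.size):
        s += np.exp(x[i] - m)
    return m + np.log(s)


@njit(cache=True)
def _sample_cat(logw):
    m = logw[0]
    for i in range(1, logw.size):
        if logw[i] > m:
            m = logw[i]
    tot = 0.0
    for i in range(logw.size):
        tot += np.exp(logw[i] - m)
    u = np.random.random() * tot
    acc = 0.0
    for i in range(logw.size):
        acc += np.exp(logw[i] - m)
        if u <= acc:
            return i
    return logw.size - 1


@njit(cache=True)
def _next_end(cp, from_b, n):
    """End position (exclusive) of the segment whose first possible
    terminating boundary is ``from_b``."""
    nb = cp.size
    for b in range(from_b, nb):
        if cp[b]:
            return b + 1
    return n


@njit(cache=True)
def _sweep_kernel(sym, prefix, fixed, cp, lab_at, alpha, sumA, logpi, logphi, log1mphi, seed):
    """One Gibbs sweep over all boundaries (and the affected labels)."""
    np.random.seed(seed)
    n = sym.size
    T = alpha.shape[0]
    lgalpha = np.zeros((T, 32))  # unused placeholder kept for signature stability
    lm_seg = np.empty(T)
    lm_left = np.zeros(T)
    lm_right = np.empty(T)
    lm_next = np.empty(T)
    lm_merged = np.empty(T)
    logw = np.empty(T)
    cnt_left = np.zeros(32, dtype=np.int64)
    n_left = 0

    if n == 1:
        _seg_lm(prefix, 0, 1, alpha, sumA, lgalpha, lm_seg)
        for c in range(T):
            logw[c] = logpi[c] + lm_seg[c]
        lab_at[0] = _sample_cat(logw)
        return

    s = 0
    e = _next_end(cp, 0, n)
    _seg_lm(prefix, s, e, alpha, sumA, lgalpha, lm_seg)
    # left covers [s, s+1)
    for c in range(T):
        lm_left[c] = np.log(alpha[c, sym[s]]) - np.log(sumA[c])
    cnt_left[:] = 0
    cnt_left[sym[s]] = 1
    n_left = 1
    # right covers [s+1, e)
    _seg_lm(prefix, s + 1, e, alpha, sumA, lgalpha, lm_right)
    cnt_right = np.zeros(32, dtype=np.int64)
    for j in range(32):
        cnt_right[j] = prefix[e, j] - prefix[s + 1, j]
    n_right = e - s - 1

    b = 0
    while b <= n - 2:
        if b < e - 1:
            # interior boundary, cp[b] is False
            for c in range(T):
                logw[c] = logpi[c] + lm_left[c]
            lwL = _lse(logw)
            for c in range(T):
                logw[c] = logpi[c] + lm_right[c]
            lwR = _lse(logw)
            for c in range(T):
                logw[c] = logpi[c] + lm_seg[c]
            lwM = _lse(logw)
            lon = logphi + lwL + lwR
            loff = log1mphi + lwM
            mx = lon if lon > loff else loff
            pon = np.exp(lon - mx)
            poff = np.exp(loff - mx)
            if np.random.random() * (pon + poff) < pon:
                cp[b] = True
                for c in range(T):
                    logw[c] = logpi[c] + lm_left[c]
                lab_at[s] = _sample_cat(logw)
                for c in range(T):
                    logw[c] = logpi[c] + lm_right[c]
                lab_at[b + 1] = _sample_cat(logw)
                s = b + 1
                for c in range(T):
                    lm_seg[c] = lm_right[c]
                for c in range(T):
                    lm_left[c] = 0.0
                cnt_left[:] = 0
                n_left = 0
            else:
                for c in range(T):
                    logw[c] = logpi[c] + lm_seg[c]
                lab_at[s] = _sample_cat(logw)
            # advance to boundary b+1: left gains sym[b+1], right loses it
            x = sym[b + 1]
            for c in range(T):
                lm_left[c] += np.log(alpha[c, x] + cnt_left[x]) - np.log(sumA[c] + n_left)
            cnt_left[x] += 1
            n_left += 1
            cnt_right[x] -= 1
            n_right -= 1
            for c in range(T):
                lm_right[c] -= np.log(alpha[c, x] + cnt_right[x]) - np.log(sumA[c] + n_right)
            b += 1
        else:
            # b == e-1: a current change-point terminates the segment here
            if fixed[b]:
                for c in range(T):
                    logw[c] = logpi[c] + lm_left[c]
                lab_at[s] = _sample_cat(logw)
                s = e
                e = _next_end(cp, b + 1, n)
                _seg_lm(prefix, s, e, alpha, sumA, lgalpha, lm_seg)
                for c in range(T):
                    lm_left[c] = np.log(alpha[c, sym[s]]) - np.log(sumA[c])
                cnt_left[:] = 0
                cnt_left[sym[s]] = 1
                n_left = 1
                _seg_lm(prefix, s + 1, e, alpha, sumA, lgalpha, lm_right)
                for j in range(32):
                    cnt_right[j] = prefix[e, j] - prefix[s + 1, j]
                n_right = e - s - 1
                b += 1
            else:
                e2 = _next_end(cp, b + 1, n)
                _seg_lm(prefix, e, e2, alpha, sumA, lgalpha, lm_next)
                _seg_lm(prefix, s, e2, alpha, sumA, lgalpha, lm_merged)
                for c in range(T):
                    logw[c] = logpi[c] + lm_left[c]
                lwL = _lse(logw)
                for c in range(T):
                    logw[c] = logpi[c] + lm_next[c]
                lwN = _lse(logw)
                for c in range(T):
                    logw[c] = logpi[c] + lm_merged[c]
                lwM = _lse(logw)
                lkeep = logphi + lwL + lwN
                lrem = log1mphi + lwM
                mx = lkeep if lkeep > lrem else lrem
                pk = np.exp(lkeep - mx)
                pr = np.exp(lrem - mx)
                if np.random.random() * (pk + pr) < pk:
                    for c in range(T):
                        logw[c] = logpi[c] + lm_left[c]
                    lab_at[s] = _sample_cat(logw)
                    s = e
                    e = e2
                    for c in range(T):
                        lm_seg[c] = lm_next[c]
                    for c in range(T):
                        lm_left[c] = np.log(alpha[c, sym[s]]) - np.log(sumA[c])
                    cnt_left[:] = 0
                    cnt_left[sym[s]] = 1
                    n_left = 1
                    _seg_lm(prefix, s + 1, e, alpha, sumA, lgalpha, lm_right)
                    for j in range(32):
                        cnt_right[j] = prefix[e, j] - prefix[s + 1, j]
                    n_right = e - s - 1
                    b += 1
                else:
                    cp[b] = False
                    for c in range(T):
                        logw[c] = logpi[c] + lm_merged[c]
                    lab_at[s] = _sample_cat(logw)
                    for c in range(T):
                        lm_seg[c] = lm_merged[c]
                    e = e2
                    # advance: left was [s, b+1); extend with sym[b+1]
                    x = sym[b + 1]
                    for c in range(T):
                        lm_left[c] += np.log(alpha[c, x] + cnt_left[x]) - np.log(
                            sumA[c] + n_left
                        )
                    cnt_left[x] += 1
                    n_left += 1
                    _seg_lm(prefix, b + 2, e, alpha, sumA, lgalpha, lm_right)
                    for j in range(32):
                        cnt_right[j] = prefix[e, j] - prefix[b + 2, j]
                    n_right = e - b - 2
                    b += 1
    # final segment label
    if s < n:
        for c in range(T):
            logw[c] = logpi[c] + lm_seg[c]
        lab_at[s] = _sample_cat(logw)


# ---------------------------------------------------------------------------
# driver


def _prepare_input(seq):
    if isinstance(seq, EncodedSequence):
        sym, fixed, _ = seq.model_input()
        return sym.astype(np.int64), fixed
    if isinstance(seq, str):
        bad = set(seq) - set(ALPHABET) - {"#"}
        if bad:
            raise ValueError(f"symbols outside alphabet: {sorted(bad)}")
        sym = np.array([ALPHABET.index(c) for c in seq if c != "#"], dtype=np.int64)
        n = len(sym)
        fixed = np.zeros(max(n - 1, 0), dtype=np.bool_)
        j = -1
        for c in seq:
            if c == "#":
                if 0 <= j < n - 1:
                    fixed[j] = True
            else:
                j += 1
        return sym, fixed
    sym = np.asarray(seq, dtype=np.int64)
    if sym.size and (sym.min() < 0 or sym.max() >= N_SYMBOLS):
        raise ValueError("symbol indices must be in 0..31")
    return sym, np.zeros(max(sym.size - 1, 0), dtype=np.bool_)


def _init_alpha(config: ModelConfig, rng: np.random.Generator) -> np.ndarray:
    if config.alpha0 is not None:
        return np.asarray(config.alpha0, dtype=float).copy()
    a = np.ones((config.T, N_SYMBOLS))
    if config.T > 1 and config.alpha_jitter > 0:
        a *= np.exp(config.alpha_jitter * rng.standard_normal(a.shape))
    return a


def gibbs_sample(seq, config: ModelConfig) -> SampleTrace:
    """Run the sampler on an encoded sequence (or raw symbol string/indices).

    Deterministic for a fixed ``config.seed``.  Returns a :class:`SampleTrace`
    with one record per ``thin`` sweeps.
    """
    sym, fixed = _prepare_input(seq)
    n = sym.size
    if n == 0:
        raise ValueError("sequence is empty")
    T = config.T
    rng = np.random.default_rng(config.seed)

    prefix = np.zeros((n + 1, N_SYMBOLS), dtype=np.int64)
    onehot = np.zeros((n, N_SYMBOLS), dtype=np.int64)
    onehot[np.arange(n), sym] = 1
    np.cumsum(onehot, axis=0, out=prefix[1:])

    cp = fixed.copy()
    lab_at = np.zeros(n, dtype=np.int64)
    starts0 = np.concatenate([[0], np.flatnonzero(cp) + 1])
    lab_at[starts0] = rng.integers(0, T, size=starts0.size)

    # separate stream so the oracle sees the identical initial alpha
    alpha = _init_alpha(config, np.random.default_rng(config.seed))
    pi_prior = config.pi_prior_vector()
    if config.sample_pi:
        pi = rng.dirichlet(pi_prior)
    else:
        pi = pi_prior / pi_prior.sum()

    sample_phi = isinstance(config.cp_prior_phi, str)
    phi = 0.01 if sample_phi else float(config.cp_prior_phi)
    n_free = int((~fixed).sum())

    # Warm start: tile the sequence into fixed windows, cluster the windows
    # by (conservation, GC) with k-means, and seed labels, change-points
    # and moment-matched alpha from the clustering.  All-ones alpha with
    # jitter leaves the classes statistically exchangeable and the chain
    # can take very long to break that symmetry on its own; the warm start
    # only picks the starting state and does not change the target.
    win = config.warm_window
    if (
        config.warm_start
        and config.sample_alpha
        and config.alpha0 is None
        and T > 1
        and n >= 2 * T * win
    ):
        bounds = np.arange(0, n + win - 1, win)
        bounds[-1] = n
        if n - bounds[-2] < win // 2 and len(bounds) > 2:
            bounds = np.delete(bounds, -2)
        wcnt = (prefix[bounds[1:]] - prefix[bounds[:-1]]).astype(float)
        wlen = wcnt.sum(axis=1)
        comp = wcnt / wlen[:, None]
        feat = np.column_stack(
            [comp[:, 0] + comp[:, 21], comp[:, _REF_GC_SYMBOLS].sum(axis=1)]
        )
        W = feat.shape[0]
        best_assign, best_cost = None, np.inf
        for _ in range(config.warm_restarts):
            centers = feat[rng.choice(W, size=T, replace=False)]
            assign = np.zeros(W, dtype=np.int64)
            for _ in range(30):
                d = ((feat[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
                assign = d.argmin(axis=1)
                for c in range(T):
                    m = assign == c
                    if m.any():
                        centers[c] = feat[m].mean(axis=0)
            d = ((feat[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            cost = d[np.arange(W), assign].sum()
            if cost < best_cost:
                best_cost, best_assign = cost, assign.copy()
        assign = best_assign
        centers32 = np.empty((T, N_SYMBOLS))
        for c in range(T):
            m = assign == c
            if m.any():
                centers32[c] = wcnt[m].sum(axis=0) / wlen[m].sum()
            else:
                centers32[c] = np.full(N_SYMBOLS, 1.0 / N_SYMBOLS)
        alpha = config.warm_kappa * (centers32 + 1e-3)
        cp = fixed.copy()
        cp[bounds[1:-1] - 1] = True
        lab_at = np.zeros(n, dtype=np.int64)
        lab_at[bounds[:-1]] = assign

    n_rec = config.n_iter // config.thin
    rec_loglik = np.empty(n_rec)
    rec_ncp = np.empty(n_rec, dtype=np.int64)
    rec_pi = np.empty((n_rec, T))
    rec_theta = np.empty((n_rec, T, N_SYMBOLS))
    rec_phi = np.empty(n_rec)
    seg_starts_list: list[np.ndarray] = []
    seg_labels_list: list[np.ndarray] = []
    seg_probs_list: list[np.ndarray] = []

    mh_prop = 0
    mh_acc = 0
    r = 0
    for sweep in range(config.n_iter):
        kseed = int(rng.integers(0, 2**31 - 1))
        logpi = np.log(pi)
        _sweep_kernel(
            sym,
            prefix,
            fixed,
            cp,
            lab_at,
            alpha,
            alpha.sum(axis=1),
            logpi,
            np.log(phi),
            np.log1p(-phi),
            kseed,
        )
        starts = np.concatenate([[0], np.flatnonzero(cp) + 1])
        ends = np.concatenate([starts[1:], [n]])
        labels = lab_at[starts]
        counts = prefix[ends] - prefix[starts]  # (S, 32)
        class_sizes = np.bincount(labels, minlength=T)

        # conjugate mixture update
        if config.sample_pi:
            pi = rng.dirichlet(pi_prior + class_sizes)
        # change-point rate update
        if sample_phi:
            k_on = int(cp.sum() - fixed.sum())
            phi = float(rng.beta(1 + k_on, 1 + n_free - k_on))
            phi = min(max(phi, 1e-12), 1 - 1e-12)

        # per-class aggregated counts, per-class current log marginal, and
        # each segment's label posterior given (pi, alpha) — the latter is
        # the Rao-Blackwellized quantity the membership profiles average
        agg = np.zeros((T, N_SYMBOLS))
        cur_lm = np.zeros(T)
        S = counts.shape[0]
        seg_lm_all = np.empty((S, T))
        N_seg = counts.sum(axis=1)
        for c in range(T):
            A = alpha[c].sum()
            seg_lm_all[:, c] = (
                gammaln(A)
                - gammaln(A + N_seg)
                + np.sum(
                    gammaln(alpha[c][None, :] + counts) - gammaln(alpha[c])[None, :],
                    axis=1,
                )
            )
            mask = labels == c
            if mask.any():
                agg[c] = counts[mask].sum(axis=0)
                cur_lm[c] = float(seg_lm_all[mask, c].sum())
        logw = seg_lm_all + np.log(pi)[None, :]
        logw -= logw.max(axis=1, keepdims=True)
        lab_probs = np.exp(logw)
        lab_probs /= lab_probs.sum(axis=1, keepdims=True)

        # Metropolis on log alpha_c (elementwise jitter or concentration scale)
        if config.sample_alpha:
            lam = config.alpha_prior_rate
            for c in range(T):
                mask = labels == c
                cm = counts[mask]
                cur = cur_lm[c]
                for _ in range(config.alpha_mh_steps):
                    la = np.log(alpha[c])
                    if rng.random() < 0.5:
                        la_new = la + config.alpha_step_size * rng.standard_normal(
                            N_SYMBOLS
                        )
                    else:
                        la_new = la + config.alpha_step_size * rng.standard_normal()
                    a_new = np.exp(la_new)
                    new = _class_log_marginals(cm, a_new) if cm.shape[0] else 0.0
                    # Exp(lam) prior on each alpha_j; log-scale Jacobian
                    logr = (
                        new
                        - cur
                        - lam * (a_new.sum() - alpha[c].sum())
                        + (la_new.sum() - la.sum())
                    )
                    mh_prop += 1
                    if np.log(rng.random()) < logr:
                        alpha[c] = a_new
                        cur = new
                        mh_acc += 1
                cur_lm[c] = cur

        if (sweep + 1) % config.thin == 0:
            theta = (agg + alpha) / (agg.sum(axis=1) + alpha.sum(axis=1))[:, None]
            # plug-in multinomial log-likelihood at the sweep's theta
            with np.errstate(divide="ignore"):
                ll = float(np.sum(agg * np.log(theta)))
            rec_loglik[r] = ll
            rec_ncp[r] = starts.size - 1
            rec_pi[r] = pi
            rec_theta[r] = theta
            rec_phi[r] = phi
            seg_starts_list.append(starts.astype(np.int32))
            seg_labels_list.append(labels.astype(np.int32))
            seg_probs_list.append(lab_probs.astype(np.float32))
            r += 1

    return SampleTrace(
        config=config,
        n=n,
        fixed_boundaries=fixed,
        loglik=rec_loglik,
        n_changepoints=rec_ncp,
        pi=rec_pi,
        theta=rec_theta,
        alpha=alpha,
        phi=rec_phi,
        seg_starts=seg_starts_list,
        seg_labels=seg_labels_list,
        seg_label_probs=seg_probs_list,
        alpha_accept_rate=(mh_acc / mh_prop) if mh_prop else 0.0,
    )


# ---------------------------------------------------------------------------
# exact enumeration oracle


def enumerate_posterior(seq, config: ModelConfig):
    """Exact posterior marginals by enumeration (small instances only).

    Sums the collapsed joint over all ``2^(n-1)`` segmentations (fixed
    boundaries forced on), with segment labels summed independently per
    segment — valid because pi and alpha are held fixed, which the
    configuration must request (``sample_pi=False, sample_alpha=False``).

    Returns ``(boundary_marginal, class_marginal)`` with shapes
    ``(n-1,)`` and ``(n, T)``.
    """
    sym, fixed = _prepare_input(seq)
    n = sym.size
    T = config.T
    if n - 1 > 14 or T > 3:
        raise ValueError(
            f"enumeration limited to n-1 <= 14 boundaries and T <= 3 classes "
            f"(got n={n}, T={T})"
        )
    if config.sample_pi or config.sample_alpha:
        raise ValueError(
            "the enumeration oracle requires fixed parameters: "
            "set sample_pi=False and sample_alpha=False"
        )
    if isinstance(config.cp_prior_phi, str):
        raise ValueError("the enumeration oracle requires a fixed cp_prior_phi")
    alpha = _init_alpha(config, np.random.default_rng(config.seed))
    pi_prior = config.pi_prior_vector()
    pi = pi_prior / pi_prior.sum()
    logpi = np.log(pi)
    phi = float(config.cp_prior_phi)
    lphi, l1mphi = np.log(phi), np.log1p(-phi)

    onehot = np.zeros((n, N_SYMBOLS), dtype=np.int64)
    onehot[np.arange(n), sym] = 1
    prefix = np.zeros((n + 1, N_SYMBOLS), dtype=np.int64)
    np.cumsum(onehot, axis=0, out=prefix[1:])

    # segment weights for every (s, e): lw[s][e] = lse_c(logpi + lm), and
    # class posteriors post[s][e][c]
    lw = np.full((n, n + 1), -np.inf)
    post = np.zeros((n, n + 1, T))
    for s in range(n):
        for e in range(s + 1, n + 1):
            cnt = prefix[e] - prefix[s]
            lm = np.array([segment_log_marginal(cnt, alpha[c]) for c in range(T)])
            w = logpi + lm
            lw[s, e] = logsumexp(w)
            post[s, e] = np.exp(w - lw[s, e])

    free = np.flatnonzero(~fixed)
    nfree = free.size
    log_weights = []
    configs = []
    for mask in range(1 << nfree):
        cp = fixed.copy()
        for i in range(nfree):
            if mask >> i & 1:
                cp[free[i]] = True
        starts = np.concatenate([[0], np.flatnonzero(cp) + 1])
        ends = np.concatenate([starts[1:], [n]])
        k_on = int(bin(mask).count("1"))
        lp = k_on * lphi + (nfree - k_on) * l1mphi
        lp += sum(lw[s, e] for s, e in zip(starts, ends))
        log_weights.append(lp)
        configs.append((cp, starts, ends))

    log_weights = np.array(log_weights)
    w = np.exp(log_weights - logsumexp(log_weights))
    boundary = np.zeros(n - 1)
    class_marg = np.zeros((n, T))
    for wt, (cp, starts, ends) in zip(w, configs):
        boundary += wt * cp
        for s, e in zip(starts, ends):
            class_marg[s:e] += wt * post[s, e]
    return boundary, class_marg
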