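"""Burn-in detection, information criteria and choice of the class count T.

Runs with increasing T are compared on post-burn-in samples via AIC, BIC
and a DIC variant, then screened for over-fitting: classes with negligible
mixture proportion, or whose conservation level varies widely across
sweeps ("unstable" classes), disqualify a model.  The selection rule is
explicit and logged so a human can override it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from cpseg.model import ModelConfig, SampleTrace, gibbs_sample

N_SYMBOLS = 32


@dataclass
class ModelScore:
    """Scores and screening verdicts for one value of T."""

    T: int
    AIC: float
    BIC: float
    DICV: float
    mean_loglik: float
    max_loglik: float
    mean_n_changepoints: float
    mixture_means: np.ndarray
    stability_flags: np.ndarray  # True = stable
    burnin_index: int
    conservation_means: np.ndarray = field(default=None)

    def __post_init__(self):
        for v in (self.AIC, self.BIC, self.DICV):
            if not np.isfinite(v):
                raise ValueError("information criteria must be finite")


def detect_burnin(
    loglik_series, window: int = 100, alpha: float = 0.05, two_sided: bool = False
) -> int:
    """Index at which the rising log-likelihood trend has flattened.

    Scans from the start for the smallest index whose trailing ``window``
    sweeps show a least-squares slope that is not significantly positive
    (one-sided t-test at level ``alpha``); capped at half the series.
    With ``two_sided`` the test rejects trends of either sign — used on
    per-class conservation series, which can drift downward as well as up.
    """
    y = np.asarray(loglik_series, dtype=float)
    n = y.size
    if n < window:
        raise ValueError(f"series length {n} is shorter than the window ({window})")
    cap = n // 2
    x = np.arange(window, dtype=float)
    for i in range(0, cap + 1):
        seg = y[i : i + window]
        if np.allclose(seg, seg[0]):
            return i
        res = stats.linregress(x, seg)
        if two_sided:
            p = res.pvalue
        else:
            # one-sided p-value for slope > 0
            p = res.pvalue / 2 if res.slope > 0 else 1 - res.pvalue / 2
        if p > alpha:
            return i
    return cap


def aic(k: float, max_loglik: float) -> float:
    """Akaike information criterion: ``2 k - 2 max log-likelihood``."""
    return 2 * k - 2 * max_loglik


def bic(k: float, n: int, max_loglik: float) -> float:
    """Bayesian information criterion with sample size ``n``."""
    return k * np.log(n) - 2 * max_loglik


def _conservation(theta: np.ndarray) -> np.ndarray:
    """E(theta) = (theta_a + theta_v) / sum(theta) along the last axis."""
    num = theta[..., 0] + theta[..., 21]
    return num / theta.sum(axis=-1)


def _modal_segmentation(trace: SampleTrace, burnin: int):
    """Boundaries with posterior marginal >= 0.5, as segment starts/ends."""
    bm = trace.boundary_marginals(burnin)
    cp = bm >= 0.5
    cp |= trace.fixed_boundaries
    starts = np.concatenate([[0], np.flatnonzero(cp) + 1])
    ends = np.concatenate([starts[1:], [trace.n]])
    return starts, ends


def information_criteria(
    trace: SampleTrace, burnin: int, seq=None
) -> tuple[float, float, float]:
    """(AIC, BIC, DICV) from the post-burn-in trace.

    The parameter count is ``k = 31 T + (T - 1) + mean change-point count``
    (class compositions, mixture, and the segmentation's effective cost).
    ``BIC`` uses the encoded sequence length as the sample size.  ``DICV``
    is ``2 * mean(deviance) - deviance at the posterior-mean compositions
    and modal segmentation`` — an approximation, flagged as such.
    """
    R = trace.n_records
    if burnin >= R:
        raise ValueError("empty post-burn-in window")
    T = trace.config.T
    ll = trace.loglik[burnin:]
    k = 31 * T + (T - 1) + float(trace.n_changepoints[burnin:].mean())
    max_ll = float(ll.max())
    aic_val = aic(k, max_ll)
    bic_val = bic(k, trace.n, max_ll)

    # deviance at posterior-mean parameters, modal segmentation
    theta_bar = trace.theta[burnin:].mean(axis=0)  # (T, 32)
    pi_bar = trace.pi[burnin:].mean(axis=0)
    starts, ends = _modal_segmentation(trace, burnin)
    if seq is not None:
        from cpseg.model import _prepare_input

        sym, _ = _prepare_input(seq)
        onehot = np.zeros((trace.n, N_SYMBOLS))
        onehot[np.arange(trace.n), sym] = 1
        prefix = np.zeros((trace.n + 1, N_SYMBOLS))
        np.cumsum(onehot, axis=0, out=prefix[1:])
        log_theta = np.log(theta_bar)
        ll_hat = 0.0
        for s, e in zip(starts, ends):
            cnt = prefix[e] - prefix[s]
            ll_hat += float((cnt @ log_theta.T + np.log(pi_bar)).max())
        d_hat = -2 * ll_hat
    else:
        # without the sequence, fall back to the best recorded likelihood
        d_hat = -2 * max_ll
    mean_dev = float((-2 * ll).mean())
    dicv = 2 * mean_dev - d_hat
    return float(aic_val), float(bic_val), float(dicv)


def class_stability(trace: SampleTrace, burnin: int, threshold: float = 0.05):
    """Flag classes whose conservation level varies widely across sweeps.

    Returns ``(flags, series)``: ``flags[c]`` is True when the post-burn-in
    standard deviation of class c's conservation is <= threshold (stable);
    ``series`` is the full per-sweep conservation matrix for plotting.
    """
    series = _conservation(trace.theta)  # (R, T)
    sd = series[burnin:].std(axis=0)
    return sd <= threshold, series


def score_trace(trace: SampleTrace, seq=None, stability_threshold: float = 0.05) -> ModelScore:
    """Summarize one run into a :class:`ModelScore`.

    Burn-in combines the log-likelihood trend with the per-class
    conservation trends (the latter catch slow drift of the class
    compositions that the likelihood plateau can mask).
    """
    window = min(100, max(10, trace.n_records // 4))
    burnin = detect_burnin(trace.loglik, window=window)
    for c in range(trace.config.T):
        cons_c = _conservation(trace.theta[:, c, :])
        burnin = max(burnin, detect_burnin(cons_c, window=window, two_sided=True))
    aic, bic, dicv = information_criteria(trace, burnin, seq=seq)
    flags, series = class_stability(trace, burnin, stability_threshold)
    return ModelScore(
        T=trace.config.T,
        AIC=aic,
        BIC=bic,
        DICV=dicv,
        mean_loglik=float(trace.loglik[burnin:].mean()),
        max_loglik=float(trace.loglik[burnin:].max()),
        mean_n_changepoints=float(trace.n_changepoints[burnin:].mean()),
        mixture_means=trace.pi[burnin:].mean(axis=0),
        stability_flags=flags,
        burnin_index=burnin,
        conservation_means=series[burnin:].mean(axis=0),
    )


def score_models(seq, T_values, base_config: ModelConfig | None = None, **overrides):
    """Run the sampler for each T and score every run.

    Returns ``(scores, traces)`` keyed by position in ``T_values``.
    """
    scores = []
    traces = []
    for T in T_values:
        kwargs = dict(
            cp_prior_phi=0.01,
            seed=0,
            n_iter=1000,
        )
        if base_config is not None:
            kwargs.update(
                cp_prior_phi=base_config.cp_prior_phi,
                pi_prior=base_config.pi_prior,
                seed=base_config.seed,
                n_iter=base_config.n_iter,
                thin=base_config.thin,
                sample_pi=base_config.sample_pi,
                sample_alpha=base_config.sample_alpha,
                alpha_mh_steps=base_config.alpha_mh_steps,
                alpha_step_size=base_config.alpha_step_size,
            )
        kwargs.update(overrides)
        trace = gibbs_sample(seq, ModelConfig(T=T, **kwargs))
        traces.append(trace)
        scores.append(score_trace(trace, seq=seq))
    return scores, traces


def select_model(
    scores: list[ModelScore],
    min_mixture: float = 0.01,
    criterion: str = "vote",
    log: list | None = None,
) -> int:
    """Choose the number of classes T from per-T scores.

    For a single criterion ("AIC", "BIC", "DICV"): the smallest admissible
    T at a local minimum of that criterion, falling back to the global
    minimum among admissible models.  A model is admissible when every
    class is stable and every mixture mean is at least ``min_mixture``
    (an over-fitting screen).  The default ``"vote"`` lets each criterion
    nominate a T that way and takes the median, breaking ties toward
    smaller T: BIC's parameter cost (31 per class) is very conservative on
    sequences of a few tens of kb, so no single criterion is trusted alone.
    Every verdict is appended to ``log`` when given.
    """
    if len(scores) < 2:
        raise ValueError("need scores for at least two values of T")
    if criterion == "vote":
        votes = []
        for crit in ("AIC", "BIC", "DICV"):
            votes.append(select_model(scores, min_mixture, crit, log=log))
        votes.sort()
        chosen = votes[len(votes) // 2]
        if log is not None:
            log.append(f"votes (AIC, BIC, DICV): {votes} -> chosen T={chosen}")
        return chosen
    scores = sorted(scores, key=lambda s: s.T)
    values = {s.T: getattr(s, criterion) for s in scores}
    admissible = {}
    for s in scores:
        reasons = []
        if not bool(np.all(s.stability_flags)):
            bad = np.flatnonzero(~s.stability_flags).tolist()
            reasons.append(f"unstable classes {bad}")
        low = np.flatnonzero(s.mixture_means < min_mixture).tolist()
        if low:
            reasons.append(f"mixture means below {min_mixture} for classes {low}")
        admissible[s.T] = not reasons
        if log is not None:
            verdict = "admissible" if not reasons else "; ".join(reasons)
            log.append(f"T={s.T}: {criterion}={values[s.T]:.2f} [{verdict}]")
    Ts = [s.T for s in scores]
    ok = [t for t in Ts if admissible[t]]
    if not ok:
        failures = "; ".join(
            f"T={s.T} inadmissible" for s in scores if not admissible[s.T]
        )
        raise ValueError(f"no admissible model: {failures}")

    def is_local_min(i):
        t = Ts[i]
        v = values[t]
        left = values[Ts[i - 1]] if i > 0 else np.inf
        right = values[Ts[i + 1]] if i < len(Ts) - 1 else np.inf
        return v <= left and v <= right

    for i, t in enumerate(Ts):
        if admissible[t] and is_local_min(i):
            if log is not None:
                log.append(f"chosen T={t} (first admissible local {criterion} minimum)")
            return t
    best = min(ok, key=lambda t: (values[t], t))
    if log is not None:
        log.append(f"chosen T={best} (global {criterion} minimum among admissible)")
    return best
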