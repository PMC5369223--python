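"""Per-class conservation and per-position class-membership profiles.

The conservation level of a composition theta is
``E(theta) = (theta_a + theta_v) / sum_j theta_j`` — 'a' and 'v' encode the
two fully conserved column types (all-A/T and all-C/G).  Class membership
profiles are Monte-Carlo estimates over post-burn-in sweeps of the
probability that each encoded position lies in a segment of each class;
at every position the class probabilities sum to one.  Profiles are
projected to reference coordinates through the encoded sequence's
coordinate map and exported as WIG (1-based) or BED (0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from cpseg.encoding import EncodedSequence
from cpseg.model import SampleTrace

A_IDX, V_IDX = 0, 21  # 'a' and 'v' in the 32-symbol alphabet


def conservation_of(theta: np.ndarray) -> np.ndarray:
    """E(theta) along the last axis of a composition array."""
    theta = np.asarray(theta, dtype=float)
    return (theta[..., A_IDX] + theta[..., V_IDX]) / theta.sum(axis=-1)


@dataclass
class ConservationSeries:
    """Per-sweep, per-class conservation values with post-burn-in means."""

    values: np.ndarray  # (R, T)
    burnin_index: int

    @property
    def means(self) -> np.ndarray:
        return self.values[self.burnin_index :].mean(axis=0)

    def class_order(self) -> np.ndarray:
        """Class indices sorted by decreasing post-burn-in conservation."""
        return np.argsort(-self.means, kind="stable")


def conservation_series(trace: SampleTrace, burnin: int = 0) -> ConservationSeries:
    """Compute E(theta) for every class at every recorded sweep."""
    values = conservation_of(trace.theta)
    return ConservationSeries(values=values, burnin_index=burnin)


@dataclass
class ClassProfile:
    """Posterior class-membership probabilities per encoded position.

    ``probs[i, c]`` is the probability that encoded position ``i`` belongs
    to class ``c`` (labels aligned across sweeps); rows sum to 1.  The
    coordinate arrays mirror the encoded sequence (reference chromosome and
    0-based position per encoded symbol).
    """

    probs: np.ndarray  # (n, T)
    chrom_names: list
    chrom_idx: np.ndarray
    pos: np.ndarray
    gap_before: np.ndarray
    conservation_means: np.ndarray  # (T,)

    def __post_init__(self):
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("class probabilities must sum to 1 at every position")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def __len__(self) -> int:
        return self.probs.shape[0]


def _align_labels(trace: SampleTrace, burnin: int):
    """Resolve label switching by greedy matching to running centroids.

    Each post-burn-in sweep's classes are relabeled to minimize the total
    L1 distance between the sweep's class compositions and running centroid
    compositions (Hungarian assignment), which gives classes a consistent
    identity across sweeps.
    """
    T = trace.config.T
    R = trace.n_records
    perms = np.tile(np.arange(T), (R, 1))
    centroids = None
    weight = 0.0
    for r in range(burnin, R):
        theta = trace.theta[r]  # (T, 32)
        if centroids is None:
            centroids = theta.copy()
            perms[r] = np.arange(T)
            weight = 1.0
            continue
        cost = np.abs(theta[:, None, :] - centroids[None, :, :]).sum(axis=2)
        row, col = linear_sum_assignment(cost)
        perm = np.empty(T, dtype=np.int64)
        perm[row] = col
        perms[r] = perm
        reordered = np.empty_like(theta)
        reordered[perm] = theta
        centroids = (centroids * weight + reordered) / (weight + 1.0)
        weight += 1.0
    return perms


def class_profiles(
    trace: SampleTrace, seq: EncodedSequence | None, burnin: int
) -> ClassProfile:
    """Monte-Carlo class-membership profile from post-burn-in samples.

    The probability of class c at position i is the fraction of sweeps in
    which the segment containing i carries (aligned) label c.
    """
    R = trace.n_records
    if burnin >= R:
        raise ValueError("empty post-burn-in window")
    n = trace.n
    if seq is not None and seq.n_symbols != n:
        raise ValueError(
            f"trace length {n} does not match encoded sequence ({seq.n_symbols} symbols)"
        )
    T = trace.config.T
    perms = _align_labels(trace, burnin)
    acc = np.zeros((n, T))
    soft = len(trace.seg_label_probs) == trace.n_records
    for r in range(burnin, R):
        starts = trace.seg_starts[r]
        ends = np.concatenate([starts[1:], [n]])
        if soft:
            # Rao-Blackwellized: average each segment's label posterior
            # given that sweep's (pi, alpha) instead of the sampled label
            probs = np.zeros_like(trace.seg_label_probs[r])
            probs[:, perms[r]] = trace.seg_label_probs[r]
            acc += np.repeat(probs, ends - starts, axis=0)
        else:
            labels = perms[r][trace.seg_labels[r]]
            lab_per_pos = np.repeat(labels, ends - starts)
            acc[np.arange(n), lab_per_pos] += 1.0
    acc /= R - burnin
    acc /= acc.sum(axis=1, keepdims=True)

    theta_mean = np.empty((T, trace.theta.shape[2]))
    # per-class posterior-mean composition under the aligned labels
    for c in range(T):
        vals = [trace.theta[r][np.flatnonzero(perms[r] == c)[0]] for r in range(burnin, R)]
        theta_mean[c] = np.mean(vals, axis=0)
    cons = conservation_of(theta_mean)

    if seq is not None:
        _, _, keep = seq.model_input()
        chrom_idx = seq.chrom_idx[keep]
        pos = seq.pos[keep]
        gap_before = (seq.gap_before + seq.ambig_before)[keep].astype(np.int64)
        chrom_names = list(seq.chrom_names)
    else:
        chrom_idx = np.zeros(n, dtype=np.int32)
        pos = np.arange(n, dtype=np.int64)
        gap_before = np.zeros(n, dtype=np.int64)
        chrom_names = ["seq"]
    return ClassProfile(
        probs=acc,
        chrom_names=chrom_names,
        chrom_idx=chrom_idx,
        pos=pos,
        gap_before=gap_before,
        conservation_means=cons,
    )


# ---------------------------------------------------------------------------
# track writers


def write_wig(profile: ClassProfile, class_id: int, path, track_name=None) -> None:
    """variableStep WIG (1-based) of one class's membership probability."""
    name = track_name or f"class{class_id}"
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        cur_chrom = None
        for i in range(len(profile)):
            ci = profile.chrom_idx[i]
            if ci < 0:
                continue
            chrom = profile.chrom_names[ci]
            if chrom != cur_chrom:
                fh.write(f"variableStep chrom={chrom}\n")
                cur_chrom = chrom
            fh.write(f"{profile.pos[i] + 1}\t{profile.probs[i, class_id]:.4f}\n")


def thresholded_bed(profile: ClassProfile, class_id: int, threshold: float = 0.9):
    """Maximal runs with class probability >= threshold, as BED intervals.

    Runs are broken at chromosome changes and at non-adjacent reference
    coordinates (alignment discontinuities).  Returns a list of
    ``(chrom, start, end)`` 0-based half-open tuples.
    """
    out = []
    n = len(profile)
    i = 0
    while i < n:
        if profile.probs[i, class_id] < threshold or profile.chrom_idx[i] < 0:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and profile.probs[j + 1, class_id] >= threshold
            and profile.chrom_idx[j + 1] == profile.chrom_idx[i]
            and profile.pos[j + 1] > profile.pos[j]
        ):
            j += 1
        out.append(
            (
                profile.chrom_names[profile.chrom_idx[i]],
                int(profile.pos[i]),
                int(profile.pos[j]) + 1,
            )
        )
        i = j + 1
    return out


def save_profile(profile: ClassProfile, directory) -> None:
    """Persist a profile as a directory of plain-text tables."""
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(
            {
                "chrom_names": profile.chrom_names,
                "conservation_means": profile.conservation_means.tolist(),
            },
            fh,
        )
    T = profile.n_classes
    header = "chrom_idx\tpos\tgap_before\t" + "\t".join(
        f"class{c}" for c in range(T)
    )
    body = np.column_stack(
        [profile.chrom_idx, profile.pos, profile.gap_before, profile.probs]
    )
    np.savetxt(
        os.path.join(directory, "profile.tsv"),
        body,
        fmt=["%d", "%d", "%d"] + ["%.6f"] * T,
        delimiter="\t",
        header=header,
        comments="",
    )


def load_profile(directory) -> ClassProfile:
    """Load a profile saved by :func:`save_profile`."""
    import json
    import os

    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    body = np.loadtxt(os.path.join(directory, "profile.tsv"), skiprows=1, ndmin=2)
    probs = body[:, 3:]
    probs = probs / probs.sum(axis=1, keepdims=True)  # undo rounding drift
    return ClassProfile(
        probs=probs,
        chrom_names=meta["chrom_names"],
        chrom_idx=body[:, 0].astype(np.int32),
        pos=body[:, 1].astype(np.int64),
        gap_before=body[:, 2].astype(np.int64),
        conservation_means=np.array(meta["conservation_means"]),
    )


def write_bed(intervals, path, name_prefix="seg") -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            chrom, start, end = iv[:3]
            rest = "\t".join(str(x) for x in iv[3:])
            line = f"{chrom}\t{start}\t{end}\t{name_prefix}{k}"
            if rest:
                line += "\t" + rest
            fh.write(line + "\n")
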