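"""Calling Putative Functional Elements (PFEs) from class profiles.

A PFE is a run of reference positions, at least 100 nt long, whose every
position has >= 0.9 posterior probability of belonging to one of the
conserved classes anchoring the gene in question — the classes whose
thresholded segments overlap the gene's annotated exons, plus any class
conserved at a higher level than those.  Runs are broken at alignment gaps
of >= 20 columns, discarded when gaps make up >= 10% of their length, and
only classes conserved above 50% are reported.  Runs inside a gene body but
outside exons are intronic PFEs; runs of the single most conserved class
outside all gene bodies are intergenic PFEs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from cpseg.intervals import distance, overlap_bp, subtract
from cpseg.profiles import ClassProfile, thresholded_bed


@dataclass
class PfeCriteria:
    """Filtering thresholds for PFE calling (defaults as used genome-wide)."""

    min_length_nt: int = 100
    min_profile: float = 0.9
    max_gap_run_cols: int = 20
    max_gap_fraction: float = 0.10
    min_class_conservation: float = 0.50

    def __post_init__(self):
        if self.min_length_nt < 1:
            raise ValueError("min_length_nt must be positive")
        if not (0 < self.min_profile <= 1):
            raise ValueError("min_profile must be in (0, 1]")
        if self.max_gap_run_cols < 1:
            raise ValueError("max_gap_run_cols must be positive")
        if not (0 < self.max_gap_fraction <= 1):
            raise ValueError("max_gap_fraction must be in (0, 1]")
        if not (0 <= self.min_class_conservation < 1):
            raise ValueError("min_class_conservation must be in [0, 1)")


@dataclass
class Pfe:
    """One called element (reference coordinates, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    class_id: int
    class_conservation: float
    gene: str = "intergenic"
    min_profile_value: float = 1.0
    gap_cols: int = 0
    n_positions: int = 0
    support: dict = field(default_factory=dict)

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def as_bed(self):
        return (
            self.chrom,
            self.start,
            self.end,
            f"{self.gene}|class{self.class_id}",
            int(round(1000 * self.min_profile_value)),
        )


def candidate_segments(
    profile: ClassProfile,
    class_id: int,
    criteria: PfeCriteria,
    allowed=None,
) -> list[dict]:
    """Maximal qualifying runs of high-probability membership in one class.

    ``allowed`` optionally restricts the encoded positions considered (a
    boolean mask over encoded positions) — used to clip candidates to
    intronic or intergenic space, re-applying every threshold to the
    clipped pieces.  Runs are split at alignment-gap runs of
    ``max_gap_run_cols`` or more skipped columns, rejected when skipped
    columns make up ``max_gap_fraction`` of their aligned length, and kept
    only at ``min_length_nt`` aligned positions or more.
    """
    if not (0 <= class_id < profile.n_classes):
        raise ValueError(f"unknown class {class_id} (model has {profile.n_classes})")
    n = len(profile)
    probs = profile.probs[:, class_id]
    ok = probs >= criteria.min_profile
    if allowed is not None:
        ok = ok & np.asarray(allowed, dtype=bool)
    ok &= profile.chrom_idx >= 0

    runs = []
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        run = [i]
        j = i + 1
        while j < n and ok[j]:
            contiguous = (
                profile.chrom_idx[j] == profile.chrom_idx[j - 1]
                and profile.pos[j] > profile.pos[j - 1]
                and profile.gap_before[j] < criteria.max_gap_run_cols
            )
            if not contiguous:
                break
            run.append(j)
            j += 1
        runs.append(run)
        i = j
    out = []
    for run in runs:
        n_pos = len(run)
        gap_cols = int(profile.gap_before[run[1:]].sum()) if n_pos > 1 else 0
        if gap_cols / n_pos >= criteria.max_gap_fraction:
            continue
        if n_pos < criteria.min_length_nt:
            continue
        out.append(
            {
                "chrom": profile.chrom_names[profile.chrom_idx[run[0]]],
                "start": int(profile.pos[run[0]]),
                "end": int(profile.pos[run[-1]]) + 1,
                "n_positions": n_pos,
                "gap_cols": gap_cols,
                "min_profile_value": float(probs[run].min()),
            }
        )
    return out


def exon_anchored_classes(
    class_beds: dict,
    exons,
    conservation_means,
    min_class_conservation: float = 0.50,
) -> set[int]:
    """Classes anchoring a gene: exon-overlapping ones plus any class more
    conserved than the best of those; classes at or below the conservation
    floor are excluded."""
    cons = np.asarray(conservation_means, dtype=float)
    overlapping = set()
    for c, segs in class_beds.items():
        for seg in segs:
            if any(overlap_bp(seg, ex) > 0 for ex in exons):
                overlapping.add(c)
                break
    eligible = {c for c in class_beds if cons[c] > min_class_conservation}
    anchored = overlapping & eligible
    if anchored:
        top = max(cons[c] for c in anchored)
        anchored |= {c for c in eligible if cons[c] > top}
    return anchored


def call_pfes(
    profile: ClassProfile,
    genes,
    exons,
    criteria: PfeCriteria | None = None,
    exclusion_list=None,
    log: list | None = None,
) -> list[Pfe]:
    """Call intronic and intergenic PFEs from a class profile.

    ``genes`` and ``exons`` are BED-like (chrom, start, end, name) tuples;
    exon names must match their gene's name.  Per gene, candidates from its
    exon-anchored classes are restricted to intronic space (inside the gene
    body, outside every exon); candidates of the single most conserved
    class lying wholly outside all gene bodies become intergenic PFEs.
    ``exclusion_list`` intervals (curated non-homologous alignments) are
    removed from consideration entirely.
    """
    criteria = criteria or PfeCriteria()
    genes = [g if len(g) > 3 else (*g[:3], f"gene{k}") for k, g in enumerate(genes)]
    profile_chroms = set(profile.chrom_names)
    for g in genes:
        if g[0] not in profile_chroms:
            raise ValueError(
                f"annotation chromosome {g[0]!r} absent from profile "
                f"(has {sorted(profile_chroms)})"
            )
    cons = profile.conservation_means
    n = len(profile)

    def position_mask(intervals):
        mask = np.zeros(n, dtype=bool)
        for chrom, start, end, *_ in intervals:
            try:
                ci = profile.chrom_names.index(chrom)
            except ValueError:
                continue
            mask |= (
                (profile.chrom_idx == ci)
                & (profile.pos >= start)
                & (profile.pos < end)
            )
        return mask

    excl_mask = np.zeros(n, dtype=bool)
    if exclusion_list:
        excl_mask = position_mask(exclusion_list)

    # per-class thresholded segments for exon anchoring
    class_beds = {
        c: thresholded_bed(profile, c, criteria.min_profile)
        for c in range(profile.n_classes)
    }

    pfes: list[Pfe] = []

    for chrom, gstart, gend, gid in genes:
        gene_exons = [e for e in exons if (len(e) < 4 or e[3] == gid) and e[0] == chrom]
        anchored = exon_anchored_classes(
            class_beds, gene_exons, cons, criteria.min_class_conservation
        )
        if not anchored:
            if log is not None:
                log.append(f"{gid}: no exon-anchored class above conservation floor")
            continue
        introns = subtract((chrom, gstart, gend), gene_exons)
        intron_mask = position_mask(introns) & ~excl_mask
        for c in sorted(anchored):
            for cand in candidate_segments(profile, c, criteria, allowed=intron_mask):
                pfes.append(
                    Pfe(
                        chrom=cand["chrom"],
                        start=cand["start"],
                        end=cand["end"],
                        class_id=c,
                        class_conservation=float(cons[c]),
                        gene=gid,
                        min_profile_value=cand["min_profile_value"],
                        gap_cols=cand["gap_cols"],
                        n_positions=cand["n_positions"],
                    )
                )

    # intergenic: single most conserved class, outside all gene bodies
    eligible = [c for c in range(profile.n_classes) if cons[c] > criteria.min_class_conservation]
    if eligible:
        top = max(cons[c] for c in eligible)
        tied = [c for c in eligible if cons[c] == top]
        top_class = tied[0]
        if len(tied) > 1 and log is not None:
            log.append(f"intergenic class tie among {tied}; using class {top_class}")
        outside = ~position_mask(genes) & ~excl_mask
        for cand in candidate_segments(profile, top_class, criteria, allowed=outside):
            pfes.append(
                Pfe(
                    chrom=cand["chrom"],
                    start=cand["start"],
                    end=cand["end"],
                    class_id=top_class,
                    class_conservation=float(cons[top_class]),
                    gene="intergenic",
                    min_profile_value=cand["min_profile_value"],
                    gap_cols=cand["gap_cols"],
                    n_positions=cand["n_positions"],
                )
            )

    # deduplicate identical intervals from multiple classes: keep the more
    # conserved class (per gene attribution)
    best: dict = {}
    for p in pfes:
        key = (p.chrom, p.start, p.end, p.gene)
        if key not in best or p.class_conservation > best[key].class_conservation:
            best[key] = p
    out = sorted(best.values(), key=lambda p: (p.chrom, p.start, p.end, p.gene))
    return out


def overlap_report(pfes: list[Pfe], tracks: dict, proximity_nt: int = 30):
    """Per-PFE, per-track support flags plus summary counts.

    For each named track (a list of BED intervals) and each PFE, reports
    whether they overlap, how many bases, whether a track feature is fully
    contained in the PFE, and whether a feature lies within ``proximity_nt``
    without overlapping (a near miss).  Also returns per-track totals and
    per-track-combination counts (input for a Venn diagram).
    """
    import pandas as pd

    rows = []
    for p in pfes:
        iv = (p.chrom, p.start, p.end)
        row = {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "gene": p.gene,
            "class_id": p.class_id,
        }
        flags = {}
        for name, feats in tracks.items():
            ov_bp = 0
            contained = False
            near = False
            for f in feats:
                bp = overlap_bp(iv, f)
                ov_bp += bp
                if bp > 0 and f[1] >= p.start and f[2] <= p.end:
                    contained = True
                if bp == 0 and distance(iv, f) <= proximity_nt:
                    near = True
            row[f"{name}_overlap"] = ov_bp > 0
            row[f"{name}_bp"] = ov_bp
            row[f"{name}_contained"] = contained
            row[f"{name}_near"] = near and ov_bp == 0
            flags[name] = ov_bp > 0
            p.support[name] = ov_bp > 0
        rows.append(row)
    table = pd.DataFrame(rows)
    names = list(tracks)
    summary = {name: int(table[f"{name}_overlap"].sum()) if rows else 0 for name in names}
    venn = {}
    for r in range(1, len(names) + 1):
        for comb in itertools.combinations(names, r):
            if rows:
                m = np.ones(len(table), dtype=bool)
                for name in names:
                    col = table[f"{name}_overlap"].to_numpy()
                    m &= col if name in comb else ~col
                venn[comb] = int(m.sum())
            else:
                venn[comb] = 0
    return table, summary, venn


def proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    ``z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2))`` with
    ``p = (k1 + k2) / (n1 + n2)``; the p-value is two-sided normal.
    Used to test enrichment of transcription factors among PFE-bearing
    genes against the genome-wide aligned-gene background.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    p = (k1 + k2) / (n1 + n2)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    pval = 2 * norm.sf(abs(z))
    return float(z), float(pval)
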