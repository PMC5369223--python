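"""Synthetic 3-way alignments with known segmental class structure.

The generator emulates the statistical structure the segmentation model
assumes: the reference is tiled by segments, each carrying a class with a
characteristic column composition (conservation level and GC content),
and columns are drawn i.i.d. within a segment.  Each drawn symbol is
rendered as one of its two strand-equivalent base triples with equal
probability, exercising strand symmetry end to end.  Indel columns are
inserted in short runs and alignment blocks can be broken, except inside
exons and planted elements (deeply conserved regions align contiguously).
A gene body with exons hosted in high-conservation segments, and planted
intronic elements of the same host class, provide ground truth for
end-to-end recovery scoring.  No phylogenetic substitution process is
simulated: tests must match the model's own assumptions, not evolutionary
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cpseg.encoding import ALPHABET, AlignmentBlock, ThreeWayAlignment
from cpseg.intervals import overlap_bp

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# reference (row 1) base of each symbol's canonical column; G/C flag is
# strand-invariant, so every symbol has a definite reference GC class
_REF_IS_GC = np.array([(_BASES[i % 4] in "GC") for i in range(32)])
_CONSERVED = np.zeros(32, dtype=bool)
_CONSERVED[[0, 21]] = True  # 'a' (A/A/A) and 'v' (C/C/C)


def composition_from_targets(conservation: float, gc: float) -> np.ndarray:
    """A 32-symbol composition with the requested conservation and GC.

    Puts ``conservation * gc`` on 'v' and ``conservation * (1 - gc)`` on
    'a', and spreads the remaining mass uniformly within each reference-GC
    class of the 30 non-conserved symbols, so that
    ``E(theta) = conservation`` and the reference GC content equals ``gc``
    exactly.
    """
    if not (0 < conservation <= 1) or not (0 < gc < 1):
        raise ValueError("conservation must be in (0, 1] and gc in (0, 1)")
    theta = np.zeros(32)
    theta[21] = conservation * gc  # 'v'
    theta[0] = conservation * (1 - gc)  # 'a'
    rest = 1.0 - conservation
    gc_syms = _REF_IS_GC & ~_CONSERVED
    at_syms = ~_REF_IS_GC & ~_CONSERVED
    theta[gc_syms] = rest * gc / gc_syms.sum()
    theta[at_syms] = rest * (1 - gc) / at_syms.sum()
    return theta


@dataclass
class TruthConfig:
    """Specification of a synthetic benchmark alignment.

    Class compositions are derived from per-class conservation and GC
    targets (or given directly via ``compositions``).  The last class (the
    most conserved by default) hosts exons and planted intronic elements;
    background segments draw their classes from the remaining ones.
    """

    T_true: int = 3
    conservation: tuple = (0.45, 0.50, 0.65)
    gc: tuple = (0.35, 0.55, 0.45)
    compositions: np.ndarray | None = None
    total_length: int = 20_000
    mean_segment_length: float = 500.0
    background_mixture: tuple | None = None
    gap_run_rate: float = 0.002
    mean_gap_run: float = 4.0
    block_break_rate: float = 1e-4
    n_exons: int = 6
    exon_length: int = 150
    exon_flank: int = 25
    n_elements: int = 6
    element_length: int = 300
    host_class: int | None = None
    gene_margin: int = 1_000
    chrom: str = "chrSim"
    seed: int = 0

    def class_compositions(self) -> np.ndarray:
        if self.compositions is not None:
            comp = np.asarray(self.compositions, dtype=float)
            if comp.shape != (self.T_true, 32):
                raise ValueError("compositions must have shape (T_true, 32)")
            if not np.allclose(comp.sum(axis=1), 1.0):
                raise ValueError("compositions must sum to 1")
            return comp
        if len(self.conservation) != self.T_true or len(self.gc) != self.T_true:
            raise ValueError("need one conservation and gc target per class")
        return np.array(
            [composition_from_targets(c, g) for c, g in zip(self.conservation, self.gc)]
        )


@dataclass
class TruthSet:
    """A generated alignment plus its planted ground truth."""

    alignment: ThreeWayAlignment
    segments: list  # (chrom, start, end, class_id)
    gene_bodies: list  # (chrom, start, end, gene_id)
    exons: list  # (chrom, start, end, gene_id)
    elements: list  # (chrom, start, end, element_id)
    realized_compositions: np.ndarray  # (T_true, 32) empirical
    config: TruthConfig

    def truth_masks(self):
        return {
            "segments": self.segments,
            "exons": self.exons,
            "genes": self.gene_bodies,
            "elements": self.elements,
        }


def _expand_symbol(sym_idx: int, flip: bool) -> tuple[str, str, str]:
    col = (
        _BASES[sym_idx % 4],
        _BASES[(sym_idx // 4) % 4],
        _BASES[sym_idx // 16],
    )
    if flip:
        col = tuple(_COMP[b] for b in col)
    return col


def generate_alignment(config: TruthConfig) -> TruthSet:
    """Generate a 3-way alignment with planted segmental structure.

    Deterministic given ``config.seed``.  Raises when the exon/element plan
    cannot fit inside the gene body.
    """
    rng = np.random.default_rng(config.seed)
    comp = config.class_compositions()
    T = config.T_true
    host = config.host_class if config.host_class is not None else T - 1
    L = config.total_length
    chrom = config.chrom

    bg_classes = [c for c in range(T) if c != host] or [host]
    if config.background_mixture is not None:
        bg_mix = np.asarray(config.background_mixture, dtype=float)
        if bg_mix.size != len(bg_classes):
            raise ValueError("background_mixture must cover the non-host classes")
        bg_mix = bg_mix / bg_mix.sum()
    else:
        bg_mix = np.full(len(bg_classes), 1.0 / len(bg_classes))

    # ------- plan features (exon host segments and planted elements) -------
    gene_start, gene_end = config.gene_margin, L - config.gene_margin
    if gene_end <= gene_start:
        raise ValueError("total_length too small for the gene margins")
    features = []  # (start, end, kind, truth interval)
    n_feat = config.n_exons + config.n_elements
    if n_feat:
        span = gene_end - gene_start
        exon_seg = config.exon_length + 2 * config.exon_flank
        need = config.n_exons * exon_seg + config.n_elements * config.element_length
        if need >= span:
            raise ValueError(
                f"feature plan needs {need} nt but the gene body has only {span}"
            )
        step = span / (n_feat + 1)
        kinds = []
        n_ex, n_el = config.n_exons, config.n_elements
        while len(kinds) < n_feat:
            if n_ex and (len(kinds) % 2 == 0 or not n_el):
                kinds.append("exon")
                n_ex -= 1
            else:
                kinds.append("element")
                n_el -= 1
        pos = gene_start
        for k, kind in enumerate(kinds):
            center = int(gene_start + (k + 1) * step)
            seg_len = exon_seg if kind == "exon" else config.element_length
            start = max(pos + 1, center - seg_len // 2)
            end = start + seg_len
            if end > gene_end:
                raise ValueError("feature plan does not fit inside the gene body")
            features.append((start, end, kind))
            pos = end

    # ------- tile the reference with segments -------
    segments = []  # (start, end, class_id, protected)
    cursor = 0
    fi = 0
    while cursor < L:
        next_feat = features[fi] if fi < len(features) else None
        if next_feat and cursor == next_feat[0]:
            segments.append((next_feat[0], next_feat[1], host, True))
            cursor = next_feat[1]
            fi += 1
            continue
        limit = next_feat[0] if next_feat else L
        length = int(rng.geometric(1.0 / config.mean_segment_length))
        end = min(cursor + length, limit)
        cls = int(rng.choice(bg_classes, p=bg_mix))
        segments.append((cursor, end, cls, False))
        cursor = end

    # ------- render columns -------
    rows = [[], [], []]
    blocks: list[AlignmentBlock] = []
    block_ref_start = 0
    sym_by_class = [[] for _ in range(T)]
    refpos = 0

    def close_block():
        nonlocal rows, block_ref_start
        if rows[0]:
            blocks.append(
                AlignmentBlock(
                    ref_chrom=chrom,
                    ref_start=block_ref_start,
                    rows=tuple("".join(r) for r in rows),
                )
            )
        rows = [[], [], []]
        block_ref_start = refpos

    del_remaining = 0
    del_row = 1
    for start, end, cls, protected in segments:
        probs = comp[cls]
        length = end - start
        syms = rng.choice(32, size=length, p=probs)
        flips = rng.random(length) < 0.5
        for i in range(length):
            if not protected:
                if rng.random() < config.block_break_rate and rows[0]:
                    close_block()
                if del_remaining == 0 and rng.random() < config.gap_run_rate:
                    run = int(rng.geometric(1.0 / config.mean_gap_run))
                    if rng.random() < 0.5:
                        # insertion in a non-reference species: extra columns
                        # with a reference gap, occupying no reference
                        # coordinate
                        for _ in range(run):
                            col = [_BASES[rng.integers(4)] for _ in range(3)]
                            col[0] = "-"
                            for r in range(3):
                                rows[r].append(col[r])
                    else:
                        # deletion in species 2 or 3: the next `run`
                        # reference positions carry no symbol
                        del_remaining = run
                        del_row = int(rng.integers(1, 3))
            if del_remaining > 0 and not protected:
                del_remaining -= 1
                col = [_BASES[rng.integers(4)] for _ in range(3)]
                col[del_row] = "-"
                for r in range(3):
                    rows[r].append(col[r])
                refpos += 1
                continue
            s = int(syms[i])
            sym_by_class[cls].append(s)
            col = _expand_symbol(s, bool(flips[i]))
            for r in range(3):
                rows[r].append(col[r])
            refpos += 1
    close_block()

    aln = ThreeWayAlignment(blocks=blocks)

    realized = np.zeros((T, 32))
    for c in range(T):
        if sym_by_class[c]:
            cnt = np.bincount(np.array(sym_by_class[c]), minlength=32)
            realized[c] = cnt / cnt.sum()

    exons = []
    elements = []
    k_ex = k_el = 0
    for start, end, kind in features:
        if kind == "exon":
            exons.append((chrom, start + config.exon_flank, end - config.exon_flank, "gene0"))
            k_ex += 1
        else:
            elements.append((chrom, start, end, f"element{k_el}"))
            k_el += 1
    return TruthSet(
        alignment=aln,
        segments=[(chrom, s, e, c) for s, e, c, _ in segments],
        gene_bodies=[(chrom, gene_start, gene_end, "gene0")],
        exons=exons,
        elements=elements,
        realized_compositions=realized,
        config=config,
    )


def score_recovery(called, truth_elements, min_reciprocal_overlap: float = 0.5):
    """Precision/recall/F1 of called elements against planted truth.

    A call matches a truth interval when their overlap is at least
    ``min_reciprocal_overlap`` of both lengths; each truth interval matches
    at most one call.  Also reports the mean absolute boundary error over
    matched pairs.
    """
    call_ivs = []
    for c in called:
        if hasattr(c, "chrom"):
            call_ivs.append((c.chrom, c.start, c.end))
        else:
            call_ivs.append((c[0], c[1], c[2]))
    truth_ivs = [(t[0], t[1], t[2]) for t in truth_elements]

    matched_calls = set()
    matched_truth = set()
    boundary_errors = []
    for ti, t in enumerate(truth_ivs):
        best_ci, best_bp = None, 0
        for ci, cv in enumerate(call_ivs):
            if ci in matched_calls:
                continue
            bp = overlap_bp(t, cv)
            if (
                bp > best_bp
                and bp >= min_reciprocal_overlap * (t[2] - t[1])
                and bp >= min_reciprocal_overlap * (cv[2] - cv[1])
            ):
                best_ci, best_bp = ci, bp
        if best_ci is not None:
            matched_calls.add(best_ci)
            matched_truth.add(ti)
            cv = call_ivs[best_ci]
            boundary_errors.append((abs(cv[1] - t[1]) + abs(cv[2] - t[2])) / 2)
    precision = len(matched_calls) / len(call_ivs) if call_ivs else 0.0
    recall = len(matched_truth) / len(truth_ivs) if truth_ivs else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_called": len(call_ivs),
        "n_truth": len(truth_ivs),
        "mean_boundary_error": float(np.mean(boundary_errors)) if boundary_errors else 0.0,
    }
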