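"""Minimal genomic-interval helpers (BED 0-based half-open throughout)."""

from __future__ import annotations


def read_bed(path):
    """Read a BED file into a list of (chrom, start, end, name) tuples.

    Missing name columns become empty strings; extra columns are ignored.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            out.append((f[0], int(f[1]), int(f[2]), name))
    return out


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, [name, [score, ...]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def overlap_bp(a, b) -> int:
    """Overlapped bases between two (chrom, start, end, ...) intervals."""
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def distance(a, b) -> int:
    """Gap between two intervals on the same chromosome (0 if they touch
    or overlap); a large sentinel across chromosomes."""
    if a[0] != b[0]:
        return 1 << 60
    if overlap_bp(a, b) > 0:
        return 0
    return max(a[1], b[1]) - min(a[2], b[2])


def subtract(interval, others):
    """Pieces of ``interval`` not covered by any interval in ``others``."""
    chrom, start, end = interval[:3]
    cuts = sorted(
        (max(start, o[1]), min(end, o[2]))
        for o in others
        if o[0] == chrom and o[1] < end and o[2] > start
    )
    pieces = []
    cur = start
    for s, e in cuts:
        if s > cur:
            pieces.append((chrom, cur, s))
        cur = max(cur, e)
    if cur < end:
        pieces.append((chrom, cur, end))
    return pieces


def merge(intervals):
    """Union of intervals as a sorted, disjoint list."""
    ivs = sorted((i[0], i[1], i[2]) for i in intervals)
    out = []
    for chrom, s, e in ivs:
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out
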