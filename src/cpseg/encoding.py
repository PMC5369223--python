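"""Strand-symmetric 32-symbol encoding of 3-way genomic alignments.

Every ungapped alignment column over three species is one of 4^3 = 64 base
triples.  A triple and its base-wise complement carry the same information
irrespective of which strand is read, so the 64 triples collapse into 32
strand-equivalence pairs, each assigned one symbol from ``a``–``z``,
``U``–``Z``.  Columns containing an indel are excluded from the encoded
sequence but tallied in a gap ledger; discontinuities between alignment
blocks are marked with ``#``, which the segmentation model treats as a fixed
change-point.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

ALPHABET = "abcdefghijklmnopqrstuvwxyzUVWXYZ"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}
_IUPAC_AMBIG = set("NRYSWKMBDHV")


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str):
        self._name = name

    def __repr__(self):  # pragma: no cover
        return self._name


#: returned by :func:`encode_column` for columns containing an indel
GAP = _Sentinel("GAP")
#: returned by :func:`encode_column` for columns containing an ambiguity code
AMBIG = _Sentinel("AMBIG")


@dataclass(frozen=True)
class EncodingScheme:
    """The 32-symbol column encoding.

    ``row_order`` names the species role of each alignment row; row 1 varies
    fastest in the symbol table, row 3 slowest.  The symbol index of an
    ungapped column is ``i1 + 4*i2 + 16*i3`` (base indices A,C,G,T = 0..3)
    computed for whichever of the column / its complement gives the smaller
    index — exactly one of the pair has a row-3 base in {A, C} and therefore
    an index below 32.  This reproduces the conventional printed table in
    which row 3 only takes values A and C.
    """

    alphabet: str = ALPHABET
    row_order: tuple[str, str, str] = ("zebrafish", "mouse", "human")
    complement_map: dict = field(default_factory=lambda: dict(_COMPLEMENT))

    def __post_init__(self):
        if len(set(self.alphabet)) != 32:
            raise ValueError("alphabet must contain exactly 32 distinct symbols")

    def symbol_index(self, bases: Sequence[str]) -> int:
        """Index 0..31 of an ungapped, unambiguous column (A/C/G/T only)."""
        b = [x.upper() for x in bases]
        i = _BASE_INDEX[b[0]] + 4 * _BASE_INDEX[b[1]] + 16 * _BASE_INDEX[b[2]]
        # complement flips each base index x -> 3 - x
        ic = (3 - _BASE_INDEX[b[0]]) + 4 * (3 - _BASE_INDEX[b[1]]) + 16 * (3 - _BASE_INDEX[b[2]])
        return min(i, ic)

    def symbol(self, bases: Sequence[str]) -> str:
        return self.alphabet[self.symbol_index(bases)]

    def columns_for_symbol(self, symbol: str) -> list[tuple[str, str, str]]:
        """The two strand-equivalent base triples encoded by ``symbol``."""
        idx = self.alphabet.index(symbol)
        bases = "ACGT"
        col = (bases[idx % 4], bases[(idx // 4) % 4], bases[idx // 16])
        comp = tuple(_COMPLEMENT[b] for b in col)
        return [col, comp]


DEFAULT_SCHEME = EncodingScheme()


def encode_column(bases: Sequence[str], scheme: EncodingScheme = DEFAULT_SCHEME):
    """Encode one alignment column (three bases in row order).

    Returns the symbol for a fully resolved column, :data:`GAP` if any base
    is ``-``, or :data:`AMBIG` if any base is an IUPAC ambiguity code.
    Case-insensitive.  Raises ``ValueError`` for characters outside the
    alignment alphabet.
    """
    if len(bases) != 3:
        raise ValueError(f"expected 3 bases, got {len(bases)}")
    up = [str(b).upper() for b in bases]
    for j, b in enumerate(up):
        if b == "-":
            return GAP
    for b in up:
        if b in _IUPAC_AMBIG:
            return AMBIG
    for j, b in enumerate(up):
        if b not in _BASE_INDEX:
            raise ValueError(f"invalid base {b!r} in column position {j}")
    return scheme.symbol(up)


def complement_column(bases: Sequence[str]) -> tuple[str, ...]:
    return tuple(_COMPLEMENT[b.upper()] for b in bases)


@dataclass
class AlignmentBlock:
    """One gap-containing aligned block of three equal-length rows.

    ``ref_start`` is the 0-based reference coordinate of the first
    reference (row 1) base; reference-gap columns occupy no coordinate.
    """

    ref_chrom: str
    ref_start: int
    rows: tuple[str, str, str]
    ref_strand: str = "+"

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(lens) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def ref_ungapped_length(self) -> int:
        return len(self.rows[0]) - self.rows[0].count("-")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_ungapped_length


@dataclass
class ThreeWayAlignment:
    """An ordered, reference-sorted set of 3-way alignment blocks."""

    blocks: list[AlignmentBlock]
    species_order: tuple[str, str, str] = ("zebrafish", "mouse", "human")

    def __post_init__(self):
        prev_end = {}
        for b in self.blocks:
            if b.ref_start < prev_end.get(b.ref_chrom, -1):
                raise ValueError("blocks must be sorted and non-overlapping on the reference")
            prev_end[b.ref_chrom] = b.ref_end

    @property
    def n_columns(self) -> int:
        return sum(b.n_columns for b in self.blocks)


@dataclass
class EncodedSequence:
    """A 32-symbol sequence with '#' fixed change-points and coordinate maps.

    Arrays are parallel to ``symbols``.  ``pos[i]`` is the 0-based reference
    coordinate of symbol ``i`` (-1 at ``#``); ``gap_before[i]`` /
    ``ambig_before[i]`` count indel / ambiguous alignment columns skipped
    between the previous emitted symbol and this one ('#' rows carry the
    trailing skipped columns of the preceding block).
    """

    symbols: str
    chrom_names: list[str]
    chrom_idx: np.ndarray  # int32, -1 at '#'
    pos: np.ndarray  # int64, -1 at '#'
    gap_before: np.ndarray  # int32
    ambig_before: np.ndarray  # int32
    tail_gap: int = 0
    tail_ambig: int = 0
    n_allgap_cols: int = 0
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.symbols)
        for arr in (self.chrom_idx, self.pos, self.gap_before, self.ambig_before):
            if len(arr) != n:
                raise ValueError("coordinate arrays must parallel the symbol string")
        s = self.symbols
        if s.startswith("#") or s.endswith("#") or "##" in s:
            raise ValueError("'#' may not start/end the sequence or repeat")
        if np.any(self.gap_before < 0) or np.any(self.ambig_before < 0):
            raise ValueError("gap ledger entries must be non-negative")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_symbols(self) -> int:
        return len(self.symbols) - self.symbols.count("#")

    @property
    def n_columns_accounted(self) -> int:
        """Total alignment columns this sequence accounts for."""
        return int(
            self.n_symbols
            + self.gap_before.sum()
            + self.ambig_before.sum()
            + self.tail_gap
            + self.tail_ambig
            + self.n_allgap_cols
        )

    def model_input(self):
        """(symbol indices without '#', fixed-boundary mask, original positions).

        The fixed-boundary mask has one entry per boundary between adjacent
        retained symbols; boundaries where a '#' stood are mandatory
        change-points.
        """
        keep = np.array([c != "#" for c in self.symbols])
        sym_idx = np.array(
            [ALPHABET.index(c) for c in self.symbols if c != "#"], dtype=np.int32
        )
        n = len(sym_idx)
        fixed = np.zeros(max(n - 1, 0), dtype=np.bool_)
        j = -1
        for c in self.symbols:
            if c == "#":
                if 0 <= j < n - 1:
                    fixed[j] = True
            else:
                j += 1
        return sym_idx, fixed, np.flatnonzero(keep)

    def to_tsv(self, path) -> None:
        """Sidecar coordinate table: symbol_index, chrom, ref_pos_0based, gap_cols_before."""
        with open(path, "w") as fh:
            fh.write("symbol_index\tsymbol\tchrom\tref_pos_0based\tgap_cols_before\n")
            for i, c in enumerate(self.symbols):
                chrom = self.chrom_names[self.chrom_idx[i]] if self.chrom_idx[i] >= 0 else "."
                fh.write(
                    f"{i}\t{c}\t{chrom}\t{self.pos[i]}\t"
                    f"{self.gap_before[i] + self.ambig_before[i]}\n"
                )


def encode_alignment(
    aln: ThreeWayAlignment,
    scheme: EncodingScheme = DEFAULT_SCHEME,
    exclude_soft_masked: bool = False,
) -> EncodedSequence:
    """Encode a 3-way alignment into a single symbol sequence.

    Indel and ambiguous columns are omitted from the symbol string but
    tallied in the gap ledger; block discontinuities become single ``#``
    fixed change-points.  Soft-masked (lowercase) bases are encoded normally
    unless ``exclude_soft_masked``, in which case their columns are tallied
    as ambiguous.
    """
    symbols: list[str] = []
    chrom_names: list[str] = []
    chrom_lookup: dict[str, int] = {}
    chrom_idx: list[int] = []
    pos: list[int] = []
    gap_before: list[int] = []
    ambig_before: list[int] = []
    n_allgap = 0
    pending_gap = 0
    pending_ambig = 0

    for bi, block in enumerate(aln.blocks):
        if block.ref_chrom not in chrom_lookup:
            chrom_lookup[block.ref_chrom] = len(chrom_names)
            chrom_names.append(block.ref_chrom)
        ci = chrom_lookup[block.ref_chrom]
        if bi > 0 and symbols:
            # '#' row carries the trailing skipped columns of the previous block
            symbols.append("#")
            chrom_idx.append(-1)
            pos.append(-1)
            gap_before.append(pending_gap)
            ambig_before.append(pending_ambig)
            pending_gap = pending_ambig = 0
        refpos = block.ref_start
        r1, r2, r3 = block.rows
        for k in range(block.n_columns):
            col = (r1[k], r2[k], r3[k])
            if all(c == "-" for c in col):
                n_allgap += 1
                continue
            masked = exclude_soft_masked and any(c.islower() for c in col if c != "-")
            try:
                enc = encode_column(col, scheme)
            except ValueError as exc:
                raise ValueError(f"block {bi}, column {k}: {exc}") from exc
            advances = col[0] != "-"
            if enc is GAP:
                pending_gap += 1
            elif enc is AMBIG or masked:
                pending_ambig += 1
            else:
                symbols.append(enc)
                chrom_idx.append(ci)
                pos.append(refpos)
                gap_before.append(pending_gap)
                ambig_before.append(pending_ambig)
                pending_gap = pending_ambig = 0
            if advances:
                refpos += 1

    return EncodedSequence(
        symbols="".join(symbols),
        chrom_names=chrom_names,
        chrom_idx=np.array(chrom_idx, dtype=np.int32),
        pos=np.array(pos, dtype=np.int64),
        gap_before=np.array(gap_before, dtype=np.int32),
        ambig_before=np.array(ambig_before, dtype=np.int32),
        tail_gap=pending_gap,
        tail_ambig=pending_ambig,
        n_allgap_cols=n_allgap,
        source_meta={"species_order": list(aln.species_order)},
    )


def concatenate(seqs: Sequence[EncodedSequence]) -> EncodedSequence:
    """Join encoded sequences with '#' fixed change-points at the seams.

    Each constituent keeps its own chromosome names and coordinates; short
    genes are concatenated this way to give the segmentation model a larger
    sample.
    """
    if not seqs:
        raise ValueError("cannot concatenate an empty list of sequences")
    if len(seqs) == 1:
        return seqs[0]
    symbols: list[str] = []
    chrom_names: list[str] = []
    chrom_idx: list[np.ndarray] = []
    pos: list[np.ndarray] = []
    gap_before: list[np.ndarray] = []
    ambig_before: list[np.ndarray] = []
    allgap = 0
    for si, s in enumerate(seqs):
        offset = len(chrom_names)
        remap = np.where(s.chrom_idx >= 0, s.chrom_idx + offset, -1).astype(np.int32)
        chrom_names.extend(s.chrom_names)
        if si > 0:
            symbols.append("#")
            chrom_idx.append(np.array([-1], dtype=np.int32))
            pos.append(np.array([-1], dtype=np.int64))
            prev = seqs[si - 1]
            gap_before.append(np.array([prev.tail_gap], dtype=np.int32))
            ambig_before.append(np.array([prev.tail_ambig], dtype=np.int32))
        symbols.append(s.symbols)
        chrom_idx.append(remap)
        pos.append(s.pos)
        gap_before.append(s.gap_before)
        ambig_before.append(s.ambig_before)
        allgap += s.n_allgap_cols
    last = seqs[-1]
    return EncodedSequence(
        symbols="".join(symbols),
        chrom_names=chrom_names,
        chrom_idx=np.concatenate(chrom_idx),
        pos=np.concatenate(pos),
        gap_before=np.concatenate(gap_before),
        ambig_before=np.concatenate(ambig_before),
        tail_gap=last.tail_gap,
        tail_ambig=last.tail_ambig,
        n_allgap_cols=allgap,
        source_meta={"concatenated": len(seqs)},
    )


# ---------------------------------------------------------------------------
# readers


def read_maf(path_or_handle):
    """Parse a multiz-style MAF file into Biopython alignment blocks."""
    if isinstance(path_or_handle, (str,)):
        with open(path_or_handle) as fh:
            return list(AlignIO.parse(fh, "maf"))
    return list(AlignIO.parse(path_or_handle, "maf"))


def _species_of(src: str) -> str:
    # multiz src is "assembly.chrom..."; the assembly identifies the species
    return src.split(".", 1)[0]


def _chrom_of(src: str) -> str:
    parts = src.split(".", 1)
    return parts[1] if len(parts) > 1 else parts[0]


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT.get(c.upper(), "N") for c in reversed(s))


def extract_threeway(
    maf_blocks: Iterable,
    species_triple: tuple[str, str, str],
    reference_species: str | None = None,
) -> ThreeWayAlignment:
    """Project MAF blocks onto three species, reference-referenced.

    Blocks missing any of the three species are dropped; columns where all
    three retained rows are gapped are removed.  If the reference row is on
    the '-' strand, all three rows are reverse-complemented and the start is
    converted to forward-strand coordinates.
    """
    if reference_species is None:
        reference_species = species_triple[0]
    if reference_species not in species_triple:
        raise ValueError(
            f"reference species {reference_species!r} not in triple {species_triple}"
        )
    seen: set[str] = set()
    out_blocks: list[AlignmentBlock] = []
    for msa in maf_blocks:
        rows = {}
        for rec in msa:
            sp = _species_of(rec.id)
            seen.add(sp)
            if sp in species_triple and sp not in rows:
                rows[sp] = rec
        if len(rows) < 3:
            continue
        ref = rows[reference_species]
        order = [reference_species] + [s for s in species_triple if s != reference_species]
        strings = [str(rows[s].seq) for s in order]
        start = ref.annotations["start"]
        size = ref.annotations["size"]
        strand = ref.annotations.get("strand", 1)
        if strand in (-1, "-"):
            src_size = ref.annotations["srcSize"]
            start = src_size - start - size
            strings = [_revcomp(s) for s in strings]
        # drop all-gap columns
        cols = [
            tuple(s[k] for s in strings)
            for k in range(len(strings[0]))
            if not all(s[k] == "-" for s in strings)
        ]
        if not cols:
            continue
        new_rows = tuple("".join(c[i] for c in cols) for i in range(3))
        out_blocks.append(
            AlignmentBlock(
                ref_chrom=_chrom_of(ref.id),
                ref_start=int(start),
                rows=new_rows,
            )
        )
    missing = [s for s in species_triple if s not in seen]
    if missing and not out_blocks:
        if seen:
            raise ValueError(
                f"species {missing} not found in MAF; available: {sorted(seen)}"
            )
    out_blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    return ThreeWayAlignment(blocks=out_blocks, species_order=tuple(species_triple))


def read_fasta_alignment(
    path_or_handle,
    species_order: tuple[str, str, str] = ("zebrafish", "mouse", "human"),
    ref_chrom: str | None = None,
    ref_start: int = 0,
) -> ThreeWayAlignment:
    """Read three aligned gap-containing FASTA records as a single block.

    The first record is the reference.  ``ref_chrom`` defaults to the first
    record's id.
    """
    handle = open(path_or_handle) if isinstance(path_or_handle, str) else path_or_handle
    try:
        aln = AlignIO.read(handle, "fasta")
    finally:
        if isinstance(path_or_handle, str):
            handle.close()
    if len(aln) != 3:
        raise ValueError(f"expected exactly 3 aligned records, got {len(aln)}")
    rows = tuple(str(rec.seq) for rec in aln)
    chrom = ref_chrom if ref_chrom is not None else aln[0].id
    block = AlignmentBlock(ref_chrom=chrom, ref_start=ref_start, rows=rows)
    return ThreeWayAlignment(blocks=[block], species_order=species_order)


def write_fasta_alignment(aln: ThreeWayAlignment, path, names=None) -> None:
    """Write a single-block 3-way alignment as aligned multi-FASTA."""
    if len(aln.blocks) != 1:
        raise ValueError("FASTA export supports single-block alignments only")
    names = names or list(aln.species_order)
    block = aln.blocks[0]
    with open(path, "w") as fh:
        for name, row in zip(names, block.rows):
            fh.write(f">{name} {block.ref_chrom}:{block.ref_start}\n")
            for i in range(0, len(row), 80):
                fh.write(row[i : i + 80] + "\n")


def write_maf(aln: ThreeWayAlignment, path, assemblies=None, src_sizes=None) -> None:
    """Write a 3-way alignment as MAF (one 'a' paragraph per block)."""
    assemblies = assemblies or list(aln.species_order)
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in aln.blocks:
            fh.write("a score=0.0\n")
            for i, (asm, row) in enumerate(zip(assemblies, block.rows)):
                ungapped = len(row) - row.count("-")
                if i == 0:
                    src = f"{asm}.{block.ref_chrom}"
                    start = block.ref_start
                    size_total = src_sizes.get(asm) if src_sizes else block.ref_end
                else:
                    src = f"{asm}.aln"
                    start = 0
                    size_total = src_sizes.get(asm) if src_sizes else ungapped
                fh.write(
                    f"s {src} {start} {ungapped} + {size_total or ungapped} {row}\n"
                )
            fh.write("\n")
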