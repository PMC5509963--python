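"""Alignment chains and the statistics the retrocopy filters consume.

An :class:`AlignmentChain` is a gapped local alignment of a query (a
protein or an EST) against a target (a genomic sequence or another
protein), stored as ordered gapless blocks.  Query coordinates are in
query units (amino acids for proteins, nucleotides otherwise); target
coordinates are always plus-strand nucleotides (or residues for
protein-protein chains).  Blocks are kept in query order, so for a
minus-strand chain target coordinates decrease along the block list.

PSL is read and written in the BLAT convention: 21 columns, blocks
ascending in target coordinates, and minus-strand query coordinates
counted from the reverse-complemented query.  LAST tabular (``-f TAB``)
input is also accepted; it carries no per-alignment match count, so
identity from that source is an upper bound unless recomputed from
sequence (see :func:`read_last_tab`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

from retrofinder.genome_model import GenomicInterval


class PslParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentBlock:
    q_start: int  # query units, plus-strand query coordinates
    t_start: int  # target units, plus-strand target coordinates (leftmost)
    length: int   # in query units


@dataclass
class AlignmentChain:
    query_id: str
    query_len: int
    target_id: str
    target_len: int
    strand: str                      # relative orientation of query vs target
    blocks: list[AlignmentBlock]     # in query order
    matches: int
    score: float
    protein_query: bool = False      # query in aa, target in nt (factor 3)

    @property
    def t_unit(self) -> int:
        return 3 if self.protein_query else 1

    @property
    def aligned_query(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def q_span(self) -> tuple[int, int]:
        return self.blocks[0].q_start, self.blocks[-1].q_start + self.blocks[-1].length

    @property
    def t_min(self) -> int:
        return min(b.t_start for b in self.blocks)

    @property
    def t_max(self) -> int:
        return max(b.t_start + b.length * self.t_unit for b in self.blocks)

    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.target_id, self.t_min, self.t_max, self.strand)

    def validate(self) -> None:
        if self.query_len <= 0:
            raise ValueError("query_len must be positive")
        prev = None
        for b in self.blocks:
            if b.length <= 0:
                raise ValueError("empty alignment block")
            if prev is not None:
                if b.q_start < prev.q_start + prev.length:
                    raise ValueError("blocks overlap or are unordered in query")
                if self.strand == "+" and b.t_start < prev.t_start + prev.length * self.t_unit:
                    raise ValueError("blocks overlap or are unordered in target")
                if self.strand == "-" and b.t_start + b.length * self.t_unit > prev.t_start:
                    raise ValueError("blocks overlap or are unordered in target")
            prev = b
        if self.matches > self.aligned_query:
            raise ValueError("matches exceed aligned length")


@dataclass(frozen=True)
class AlignmentStats:
    """Filter-facing summary: aligned length on target (bp), identity, coverage.

    identity = matches / aligned query positions (gap-excluded);
    coverage = aligned query positions / query length.
    """

    aln_len_bp: int
    identity: float
    coverage: float


def compute_stats(chain: AlignmentChain, protein_query: bool | None = None) -> AlignmentStats:
    """Alignment length, identity and coverage of a chain.

    A protein query occupies three target bases per aligned residue, so
    its aligned length in bp is three times the aligned residue count.
    """
    if protein_query is None:
        protein_query = chain.protein_query
    aligned = chain.aligned_query
    if aligned == 0:
        raise ValueError("chain has zero aligned length")
    if chain.query_len <= 0:
        raise ValueError("chain has non-positive query length")
    return AlignmentStats(
        aln_len_bp=aligned * (3 if protein_query else 1),
        identity=chain.matches / aligned,
        coverage=aligned / chain.query_len,
    )


# ---------------------------------------------------------------------------
# PSL

def read_psl(stream, protein_query: bool = False) -> list[AlignmentChain]:
    """Parse 21-column PSL (with or without the BLAT header) into chains.

    Minus-strand query coordinates are normalized to plus-strand
    convention; a two-character strand field (translated BLAT) is
    accepted, with the second character giving the target strand.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_psl(fh, protein_query)
    unit = 3 if protein_query else 1
    chains = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("psLayout", "match", "-", " ")):
            continue
        fields = line.split("\t")
        if len(fields) != 21:
            raise PslParseError(
                f"line {lineno}: expected 21 PSL columns, got {len(fields)}"
            )
        (matches, mis, rep, _n, _qni, _qbi, _tni, _tbi, strand, qname, qsize,
         _qs, _qe, tname, tsize, _ts, _te, bcount, bsizes, qstarts, tstarts) = fields
        qstrand = strand[0]
        tstrand = strand[1] if len(strand) > 1 else "+"
        sizes = [int(x) for x in bsizes.rstrip(",").split(",")]
        qss = [int(x) for x in qstarts.rstrip(",").split(",")]
        tss = [int(x) for x in tstarts.rstrip(",").split(",")]
        if not (len(sizes) == len(qss) == len(tss) == int(bcount)):
            raise PslParseError(f"line {lineno}: inconsistent block lists")
        qsize, tsize = int(qsize), int(tsize)
        blocks = []
        for bs, qs, ts in zip(sizes, qss, tss):
            q = qsize - (qs + bs) if qstrand == "-" else qs
            t = tsize - (ts + bs * unit) if tstrand == "-" else ts
            blocks.append(AlignmentBlock(q, t, bs))
        blocks.sort(key=lambda b: b.q_start)
        chain = AlignmentChain(
            query_id=qname,
            query_len=qsize,
            target_id=tname,
            target_len=tsize,
            strand="+" if qstrand == tstrand else "-",
            blocks=blocks,
            matches=int(matches),
            score=float(matches) * 1.0 + float(rep) - float(mis),
            protein_query=protein_query,
        )
        chain.validate()
        chains.append(chain)
    return chains


def write_psl(chains: Iterable[AlignmentChain], stream) -> None:
    """Write chains as 21-column PSL, blocks ascending in target."""
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_psl(chains, fh)
            return
    for c in chains:
        unit = c.t_unit
        blocks = sorted(c.blocks, key=lambda b: b.t_start)
        sizes = [b.length for b in blocks]
        if c.strand == "-":
            qss = [c.query_len - (b.q_start + b.length) for b in blocks]
        else:
            qss = [b.q_start for b in blocks]
        tss = [b.t_start for b in blocks]
        aligned = sum(sizes)
        qlo, qhi = c.q_span
        q_gaps = [
            blocks_q[1] - blocks_q[0]
            for blocks_q in zip(
                sorted(b.q_start + b.length for b in c.blocks)[:-1],
                sorted(b.q_start for b in c.blocks)[1:],
            )
        ]
        t_gaps = [
            nxt - prv
            for prv, nxt in zip(
                [b.t_start + b.length * unit for b in blocks][:-1],
                [b.t_start for b in blocks][1:],
            )
        ]
        row = [
            c.matches, aligned - c.matches, 0, 0,
            sum(1 for g in q_gaps if g > 0), sum(g for g in q_gaps if g > 0),
            sum(1 for g in t_gaps if g > 0), sum(g for g in t_gaps if g > 0),
            c.strand, c.query_id, c.query_len, qlo, qhi,
            c.target_id, c.target_len, blocks[0].t_start,
            blocks[-1].t_start + blocks[-1].length * unit,
            len(blocks),
            ",".join(map(str, sizes)) + ",",
            ",".join(map(str, qss)) + ",",
            ",".join(map(str, tss)) + ",",
        ]
        stream.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# LAST tabular

def read_last_tab(stream, protein_query: bool = False) -> list[AlignmentChain]:
    """Parse LAST ``-f TAB`` lines into chains.

    Column order is score, then (name, start, alnSize, strand, seqSize)
    for the target and then for the query, then the block string.  The
    format carries no match count, so ``matches`` is set to the aligned
    length (an upper bound); recount from sequence where identity
    filtering matters.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_last_tab(fh, protein_query)
    unit = 3 if protein_query else 1
    chains = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise PslParseError(f"line {lineno}: too few TAB columns")
        score = float(f[0])
        tname, tstart, _talen, tstrand, tsize = f[1], int(f[2]), int(f[3]), f[4], int(f[5])
        qname, qstart, _qalen, qstrand, qsize = f[6], int(f[7]), int(f[8]), f[9], int(f[10])
        blockstr = f[11]
        blocks = []
        t, q = tstart, qstart
        for tok in blockstr.rstrip(",").split(","):
            if not tok:
                continue
            if ":" in tok:
                tskip, qskip = tok.split(":")
                t += int(tskip)
                q += int(qskip)
            else:
                n = int(tok)
                if n <= 0:
                    raise PslParseError(f"line {lineno}: malformed block string")
                # TAB blocks are in target letters; query advances n/unit
                if n % unit != 0:
                    raise PslParseError(
                        f"line {lineno}: block size {n} not a codon multiple"
                    )
                blocks.append((q, t, n // unit))
                t += n
                q += n // unit
        norm = []
        for qb, tb, ln in blocks:
            qq = qsize - (qb + ln) if qstrand == "-" else qb
            tt = tsize - (tb + ln * unit) if tstrand == "-" else tb
            norm.append(AlignmentBlock(qq, tt, ln))
        norm.sort(key=lambda b: b.q_start)
        aligned = sum(b.length for b in norm)
        chain = AlignmentChain(
            query_id=qname,
            query_len=qsize,
            target_id=tname,
            target_len=tsize,
            strand="+" if qstrand == tstrand else "-",
            blocks=norm,
            matches=aligned,
            score=score,
            protein_query=protein_query,
        )
        chain.validate()
        chains.append(chain)
    return chains


# ---------------------------------------------------------------------------
# Chaining of fragmented local hits

def chain_colinear(chains: list[AlignmentChain], max_gap_bp: int = 1000) -> list[AlignmentChain]:
    """Merge co-linear local alignments of one query to one target region.

    Hard-masked genomes fragment a single retrocopy into several local
    hits; hits of the same query on the same target and strand are merged
    when the genomic gap between them is at most ``max_gap_bp`` and query
    order is preserved.  Matches and scores are summed.
    """
    by_key: dict[tuple, list[AlignmentChain]] = {}
    for c in chains:
        by_key.setdefault((c.query_id, c.target_id, c.strand, c.protein_query), []).append(c)
    merged: list[AlignmentChain] = []
    for key, group in sorted(by_key.items()):
        group.sort(key=lambda c: c.t_min)
        current = group[0]
        for nxt in group[1:]:
            gap = nxt.t_min - current.t_max
            if current.strand == "+":
                q_ok = nxt.q_span[0] >= current.q_span[1]
            else:
                q_ok = nxt.q_span[1] <= current.q_span[0]
            if 0 <= gap <= max_gap_bp and q_ok:
                blocks = current.blocks + nxt.blocks
                blocks.sort(key=lambda b: b.q_start)
                current = replace(
                    current,
                    blocks=blocks,
                    matches=current.matches + nxt.matches,
                    score=current.score + nxt.score,
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    return merged
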