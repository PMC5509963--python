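"""Cross-species retrocopy orthology from whole-genome-alignment blocks.

Retroposition of the same parental gene recurs independently in
different lineages, so sequence similarity alone cannot distinguish an
orthologous retrocopy (one insertion, inherited) from parallel
insertions.  Position does: two retrocopies are orthologous when they
occupy the same location in a whole-genome alignment.  Each retrocopy is
projected onto the alignment columns of the blocks it overlaps; two
retrocopies from different species are linked when their column sets
show at least 50% reciprocal overlap, and ortholog groups are the
connected components of the resulting graph.

Overlap is measured in alignment-column space by default (gap-aware); a
genomic-bp mode is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from retrofinder.genome_model import GenomicInterval


@dataclass
class WgaRow:
    """One species' row of an alignment block: segment plus gapped text."""

    species: str
    seq_id: str
    start: int          # 0-based plus-strand start of the segment
    size: int           # ungapped length
    strand: str
    src_size: int
    text: str           # gapped row, one character per column

    def plus_interval(self) -> GenomicInterval:
        if self.strand == "+":
            return GenomicInterval(self.seq_id, self.start, self.start + self.size, "+")
        start = self.src_size - (self.start + self.size)
        return GenomicInterval(self.seq_id, start, start + self.size, "-")


@dataclass
class WgaBlock:
    block_id: str
    rows: dict[str, WgaRow]  # keyed by species

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())).text)

    def validate(self) -> None:
        widths = {len(r.text) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError(f"block {self.block_id}: unequal row widths {widths}")
        for r in self.rows.values():
            if sum(1 for ch in r.text if ch != "-") != r.size:
                raise ValueError(
                    f"block {self.block_id}: row {r.species} size/text mismatch"
                )


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    members: frozenset  # of (species, retrocopy_id)


def read_maf(source) -> list[WgaBlock]:
    """Read MAF alignment blocks; row names are ``species.chrom``."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_maf(fh)
    blocks: list[WgaBlock] = []
    rows: dict[str, WgaRow] = {}

    def flush():
        nonlocal rows
        if rows:
            blk = WgaBlock(f"block{len(blocks)}", rows)
            blk.validate()
            blocks.append(blk)
        rows = {}

    for line in source:
        line = line.rstrip("\n")
        if line.startswith("a"):
            flush()
        elif line.startswith("s"):
            _, src, start, size, strand, src_size, text = line.split()
            species, _, chrom = src.partition(".")
            rows[species] = WgaRow(
                species, chrom, int(start), int(size), strand, int(src_size), text
            )
        elif not line.strip():
            flush()
    flush()
    return blocks


def write_maf(blocks: Sequence[WgaBlock], stream) -> None:
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_maf(blocks, fh)
            return
    stream.write("##maf version=1\n")
    for blk in blocks:
        stream.write("a score=0\n")
        for sp in sorted(blk.rows):
            r = blk.rows[sp]
            stream.write(
                f"s {r.species}.{r.seq_id} {r.start} {r.size} {r.strand} "
                f"{r.src_size} {r.text}\n"
            )
        stream.write("\n")


def project_to_columns(
    retro_locus: GenomicInterval, block: WgaBlock, species: str
) -> set[int]:
    """Map a retrocopy's genomic bases inside a block to column indices.

    Gap columns of the species' row are skipped; an empty set means the
    locus does not overlap the block's segment for that species.
    """
    row = block.rows.get(species)
    if row is None or retro_locus.seq_id != row.seq_id:
        return set()
    cols: set[int] = set()
    pos = row.start  # position along the row's own strand
    for col, ch in enumerate(row.text):
        if ch == "-":
            continue
        if row.strand == "+":
            plus = pos
        else:
            plus = row.src_size - pos - 1
        if retro_locus.start <= plus < retro_locus.end:
            cols.add(col)
        pos += 1
    return cols


def reciprocal_overlap(cols_a: set, cols_b: set) -> tuple[float, float]:
    """Fractions of each column set covered by the intersection."""
    if not cols_a or not cols_b:
        raise ValueError("empty column set")
    inter = len(cols_a & cols_b)
    return inter / len(cols_a), inter / len(cols_b)


def is_reciprocal_edge(cols_a: set, cols_b: set, min_fraction: float = 0.50) -> bool:
    fa, fb = reciprocal_overlap(cols_a, cols_b)
    return min(fa, fb) >= min_fraction


def build_groups(edges: Iterable[tuple]) -> list[OrthologGroup]:
    """Connected components of the orthology edge graph.

    Vertices are ``(species, retrocopy_id)`` pairs; singletons never
    appear (an edge implies two members).  Group ids are assigned from
    the lexicographically smallest member so output is deterministic.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(edges)
    groups = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = frozenset(comp)
        groups.append((min(members), members))
    groups.sort()
    return [
        OrthologGroup(f"OG_{i:05d}", members)
        for i, (_, members) in enumerate(groups, 1)
    ]


def group_retrocopies(
    blocks: Sequence[WgaBlock],
    calls_by_species: dict[str, Sequence],
    min_fraction: float = 0.50,
    mode: str = "columns",
) -> list[OrthologGroup]:
    """End-to-end orthology: project calls into blocks, link, and group.

    ``calls_by_species`` maps species name to that species' retrocopy
    calls.  A retrocopy spanning several blocks accumulates columns
    across blocks (keyed by block) before the reciprocal test.  In
    ``columns`` mode each retrocopy's overlap denominator is its own
    column count; in ``bp`` mode the shared (both-ungapped) columns are
    instead divided by each retrocopy's genomic length in bp.
    """
    if mode not in ("columns", "bp"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    footprint: dict[tuple[str, str], set] = {}
    locus_len: dict[tuple[str, str], int] = {}
    for bi, blk in enumerate(blocks):
        for species, calls in calls_by_species.items():
            if species not in blk.rows:
                continue
            for call in calls:
                locus = call.locus if hasattr(call, "locus") else call
                cols = project_to_columns(locus, blk, species)
                if not cols:
                    continue
                key = (species, _call_id(call))
                footprint.setdefault(key, set()).update((bi, c) for c in cols)
                locus_len[key] = len(locus)
    edges = []
    for (ka, cols_a), (kb, cols_b) in combinations(sorted(footprint.items()), 2):
        if ka[0] == kb[0]:  # same species never pairs
            continue
        inter = len(cols_a & cols_b)
        if inter == 0:
            continue
        if mode == "columns":
            fa, fb = inter / len(cols_a), inter / len(cols_b)
        else:
            fa, fb = inter / locus_len[ka], inter / locus_len[kb]
        if min(fa, fb) >= min_fraction:
            edges.append((ka, kb))
    return build_groups(edges)


def _call_id(call) -> str:
    return call.retrocopy_id if hasattr(call, "retrocopy_id") else str(call)


def groups_to_table(groups: Sequence[OrthologGroup]):
    import pandas as pd

    rows = []
    for g in groups:
        for species, rid in sorted(g.members):
            rows.append({"group_id": g.group_id, "species": species, "retrocopy_id": rid})
    return pd.DataFrame(rows, columns=["group_id", "species", "retrocopy_id"])
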