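"""ORF conservation of a retrocopy relative to its parental protein.

A retrocopy that still codes for the parental protein must keep the
parental reading frame intact: no insertion or deletion whose length is
not a multiple of three (a frameshift) and no in-frame stop codon.  The
assessment walks the protein-to-genome alignment chain: each inter-block
gap on the retrocopy side whose length is not a codon multiple counts as
one frameshift event, and each aligned codon that translates to a stop
counts as one premature stop.  The frame is re-anchored at every block,
so compensating frameshifts are counted as separate events and stops are
always read in the parental frame as propagated through the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from retrofinder.alignment_io import AlignmentChain


@dataclass(frozen=True)
class OrfReport:
    frameshift_count: int
    premature_stops: int

    @property
    def orf_conserved(self) -> bool:
        return self.frameshift_count == 0 and self.premature_stops == 0


def assess_orf(
    retro_sequence: str,
    chain: AlignmentChain,
    genetic_code: int | str = 1,
) -> OrfReport:
    """Count frameshifts and premature stops in an aligned retrocopy.

    ``retro_sequence`` is the strand-corrected sequence of the chain's
    genomic footprint: the genome slice ``[t_min, t_max)``,
    reverse-complemented when the chain is on the minus strand, so that
    it reads 5'→3' in protein order.  ``genetic_code`` is an NCBI
    translation table id or name.
    """
    if not chain.protein_query:
        raise ValueError("ORF assessment requires a protein-to-genome chain")
    t_min, t_max = chain.t_min, chain.t_max
    if len(retro_sequence) < t_max - t_min:
        raise ValueError(
            f"sequence length {len(retro_sequence)} shorter than chain span "
            f"{t_max - t_min}"
        )

    def seq_offset(t_start: int, length_aa: int) -> int:
        if chain.strand == "+":
            return t_start - t_min
        return t_max - (t_start + 3 * length_aa)

    frameshifts = 0
    stops = 0
    for prev, nxt in zip(chain.blocks[:-1], chain.blocks[1:]):
        if chain.strand == "+":
            gap = nxt.t_start - (prev.t_start + 3 * prev.length)
        else:
            gap = prev.t_start - (nxt.t_start + 3 * nxt.length)
        if gap < 0:
            raise ValueError("chain blocks overlap on target")
        if gap % 3 != 0:
            frameshifts += 1
    for b in chain.blocks:
        off = seq_offset(b.t_start, b.length)
        codons = retro_sequence[off : off + 3 * b.length]
        aa = str(Seq(codons).translate(table=genetic_code))
        stops += aa.count("*")
    return OrfReport(frameshift_count=frameshifts, premature_stops=stops)


def assess_call_orf(call, genome: dict[str, str], genetic_code: int | str = 1) -> OrfReport:
    """Assess a retrocopy call directly against the genome it was called on."""
    chain = call.chain
    if chain is None:
        raise ValueError(f"call {call.retrocopy_id} carries no alignment chain")
    seq = genome[call.locus.seq_id][chain.t_min : chain.t_max]
    if chain.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return assess_orf(seq, chain, genetic_code)
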