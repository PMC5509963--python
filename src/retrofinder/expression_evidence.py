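"""Expression evidence for retrocopy calls.

Retrocopies are nearly identical to their parental genes, so expression
evidence must be specific: RNA-Seq counts use uniquely mapped reads only,
and an EST supports a retrocopy only when its alignment there beats every
other alignment of that EST genome-wide, including the parental gene.
Two indirect signals — RNA-Pol-II ChIP peaks and CAGE transcription start
sites — are associated with a retrocopy when they fall in a strand-aware
window from a fixed distance upstream of the 5' end down to 30% of the
retrocopy body.

Evidence flags are tri-state: True (green), False (red), and None (grey,
"not assessed") for sources that were not provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from retrofinder.alignment_io import AlignmentChain, compute_stats
from retrofinder.genome_model import GenomicInterval

RPM_EXPRESSED_MIN = 1.0
EST_MIN_LENGTH_NT = 100
EST_MIN_IDENTITY = 0.90
DEFAULT_UNIQUE_MAPQ = 30


@dataclass
class EvidenceWindows:
    """Upstream search distances and body fraction for signal association."""

    polII_upstream: int = 1000
    tss_upstream: int = 500
    body_fraction: float = 0.30


@dataclass
class EvidenceBundle:
    rpm_by_library: dict[str, float] = field(default_factory=dict)
    rnaseq_expressed: bool | None = None
    est_ids: list[str] = field(default_factory=list)
    est_expressed: bool | None = None
    polII: bool | None = None
    tss: bool | None = None


def count_unique_reads(bam_source, locus: GenomicInterval,
                       min_mapq: int = DEFAULT_UNIQUE_MAPQ) -> int:
    """Count uniquely mapped reads overlapping a locus by ≥1 aligned base.

    A read is unique when its NH tag equals 1; when the aligner emits no
    NH tag, mapping quality ≥ ``min_mapq`` stands in.  Secondary and
    supplementary records are excluded.  ``bam_source`` is a path to a
    coordinate-sorted, indexed BAM or an open :class:`pysam.AlignmentFile`.
    """
    import pysam

    own = isinstance(bam_source, str)
    bam = pysam.AlignmentFile(bam_source) if own else bam_source
    try:
        try:
            it = bam.fetch(locus.seq_id, locus.start, locus.end)
        except ValueError as exc:
            raise ValueError(f"cannot fetch {locus.seq_id}: {exc}") from exc
        n = 0
        for read in it:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("NH"):
                if read.get_tag("NH") != 1:
                    continue
            elif read.mapping_quality < min_mapq:
                continue
            if read.get_overlap(locus.start, locus.end) >= 1:
                n += 1
        return n
    finally:
        if own:
            bam.close()


def compute_rpm(unique_count: int, total_mapped_reads: int) -> float:
    """Reads per million mapped reads; the 1 RPM expression cut is inclusive."""
    if total_mapped_reads <= 0:
        raise ValueError("library has zero mapped reads")
    return unique_count / total_mapped_reads * 1e6


def is_expressed_rpm(rpm: float) -> bool:
    return rpm >= RPM_EXPRESSED_MIN


@dataclass(frozen=True)
class EstValidation:
    accepted: bool
    reason: str
    est_id: str = ""


def validate_est(
    est_hits: Sequence[AlignmentChain],
    retro_locus: GenomicInterval,
    min_length_nt: int = EST_MIN_LENGTH_NT,
    min_identity: float = EST_MIN_IDENTITY,
) -> EstValidation:
    """Decide whether one EST's genome-wide hits support a retrocopy.

    ``est_hits`` are *all* alignments of a single EST.  The hit
    overlapping the retrocopy must be at least 100 nt long with at least
    90% identity, and must beat every other hit of the EST — strictly
    higher score *and* strictly higher identity — including the hit to
    the parental gene.  Ties reject.
    """
    on_locus = [h for h in est_hits if h.target_interval().overlaps(retro_locus)]
    if not on_locus:
        return EstValidation(False, "no alignment to the retrocopy locus")
    hit = max(on_locus, key=lambda h: (h.score, compute_stats(h).identity))
    st = compute_stats(hit)
    if st.aln_len_bp < min_length_nt:
        return EstValidation(False, f"alignment {st.aln_len_bp} nt < {min_length_nt} nt", hit.query_id)
    if st.identity < min_identity:
        return EstValidation(False, f"identity {st.identity:.3f} < {min_identity:.2f}", hit.query_id)
    for other in est_hits:
        if other is hit or other.target_interval().overlaps(retro_locus):
            continue
        ost = compute_stats(other)
        if not (hit.score > other.score and st.identity > ost.identity):
            return EstValidation(
                False,
                "a better or equal alignment exists elsewhere "
                f"({other.target_id}:{other.t_min})",
                hit.query_id,
            )
    return EstValidation(True, "best genome-wide hit", hit.query_id)


def association_window(
    locus: GenomicInterval,
    upstream_bp: int,
    body_fraction: float,
    contig_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter-proximal window of a retrocopy.

    Runs from ``upstream_bp`` upstream of the 5' end into the first
    ``body_fraction`` of the retrocopy body; clipped at contig bounds.
    """
    body = int(len(locus) * body_fraction)
    if locus.strand == "+":
        start = locus.start - upstream_bp
        end = locus.start + body
    else:
        start = locus.end - body
        end = locus.end + upstream_bp
    start = max(0, start)
    if contig_length is not None:
        end = min(end, contig_length)
    return GenomicInterval(locus.seq_id, start, max(end, start + 1), locus.strand)


def associate_signal(
    locus: GenomicInterval,
    features: Iterable[GenomicInterval],
    upstream_bp: int,
    body_fraction: float,
    contig_length: int | None = None,
) -> tuple[bool, list[GenomicInterval]]:
    """Is any feature within the retrocopy's promoter-proximal window?

    Returns the flag and the overlapping features (strand of the feature
    is ignored; peaks and TSS clusters are unstranded inputs here).
    """
    window = association_window(locus, upstream_bp, body_fraction, contig_length)
    matched = [
        f for f in features
        if f.seq_id == window.seq_id and f.start < window.end and f.end > window.start
    ]
    return bool(matched), matched


def merge_evidence(
    rpm_by_library: dict[str, float] | None = None,
    est_validations: Sequence[EstValidation] | None = None,
    polII: bool | None = None,
    tss: bool | None = None,
) -> EvidenceBundle:
    """Combine per-source results into one evidence bundle.

    A source that was not assessed stays ``None`` (grey badge), which is
    distinct from a negative result (red).  RNA-Seq is an OR over
    libraries: expressed when any library reaches 1 RPM.
    """
    bundle = EvidenceBundle(polII=polII, tss=tss)
    if rpm_by_library is not None:
        bundle.rpm_by_library = dict(rpm_by_library)
        bundle.rnaseq_expressed = any(
            is_expressed_rpm(v) for v in rpm_by_library.values()
        )
    if est_validations is not None:
        bundle.est_ids = sorted(
            {v.est_id for v in est_validations if v.accepted and v.est_id}
        )
        bundle.est_expressed = bool(bundle.est_ids)
    return bundle


def read_counts_table(path: str):
    """Read a (retrocopy_id, library, unique_count, library_total) TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"retrocopy_id", "library", "unique_count", "library_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df
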