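"""Exon-level transcript annotation: inclusion/skipping isoforms, reading
frame, strict-skipping selection and mutually-exclusive-exon substitution.

Given a GTF and the genomic coordinates of an exon targeted for deletion,
this module finds the gene's transcripts that include the exon (an exon
record with identical coordinates) or skip it (an intron spanning it),
decides whether skipping preserves the reading frame (deleted coding length
divisible by 3; fully-UTR exons trivially preserve frame), selects strict
skipping transcripts — isoforms whose coding region equals an inclusion
isoform's with exactly the targeted exon removed, or with the
mutually-exclusive partner exon substituted — and reports the longest
skipping mRNA regardless of other differences.

All coordinates are GTF convention: 1-based, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

Interval = tuple[int, int]


@dataclass(frozen=True)
class TargetedExon:
    chrom: str
    start: int           # 1-based inclusive
    end: int
    strand: str
    gene_id: str
    mxe_partner: Interval | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SkippingCall:
    exon: TargetedExon
    frame_preserving: bool | None        # None when no CDS is annotated
    deleted_coding_length: int | None
    inclusion_transcripts: list[str] = field(default_factory=list)
    skipping_transcripts: list[str] = field(default_factory=list)
    strict_skipping_transcripts: list[str] = field(default_factory=list)
    longest_skipping_transcript: str | None = None


def load_annotation(gtf_path: str | Path) -> gffutils.FeatureDB:
    """Parse a GTF into an in-memory gffutils database."""
    return gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True)


def _transcript_exons(db: gffutils.FeatureDB, tx_id: str) -> list[Interval]:
    return sorted((f.start, f.end)
                  for f in db.children(tx_id, featuretype="exon"))


def _transcript_cds(db: gffutils.FeatureDB, tx_id: str) -> list[Interval]:
    return sorted((f.start, f.end)
                  for f in db.children(tx_id, featuretype="CDS"))


def transcript_exon_coordinates(db: gffutils.FeatureDB
                                ) -> dict[str, list[Interval]]:
    """All transcripts' exon coordinate lists (1-based inclusive), for
    round-trip checks and re-emission."""
    return {t.id: _transcript_exons(db, t.id)
            for t in db.features_of_type("transcript")}


def map_transcripts(db: gffutils.FeatureDB, exon: TargetedExon
                    ) -> tuple[list[str], list[str]]:
    """Inclusion and skipping transcript ids for a targeted exon.

    Inclusion: the transcript carries an exon with identical start/end
    (exact match — alternative 5'/3' splice-site variants do not count).
    Skipping: one of the transcript's introns fully spans the exon.
    Raises if the exon matches no transcript of its gene on its strand.
    """
    try:
        gene = db[exon.gene_id]
    except gffutils.FeatureNotFoundError as e:
        raise ValueError(f"gene {exon.gene_id} not in annotation") from e
    if gene.strand != exon.strand or gene.seqid != exon.chrom:
        raise ValueError(
            f"exon {exon.chrom}:{exon.start}-{exon.end}({exon.strand}) does "
            f"not match gene {exon.gene_id} on "
            f"{gene.seqid}({gene.strand})")
    inclusion, skipping = [], []
    for tx in db.children(gene.id, featuretype="transcript"):
        exons = _transcript_exons(db, tx.id)
        if (exon.start, exon.end) in exons:
            inclusion.append(tx.id)
            continue
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if e1 < exon.start and exon.end < s2:
                skipping.append(tx.id)
                break
    if not inclusion and not skipping:
        raise ValueError(
            f"exon {exon.chrom}:{exon.start}-{exon.end} matches no "
            f"transcript of {exon.gene_id}")
    return inclusion, skipping


def _overlap_len(iv: Interval, intervals: list[Interval]) -> int:
    s, e = iv
    return sum(max(0, min(e, ce) - max(s, cs) + 1) for cs, ce in intervals)


def frame_preservation(db: gffutils.FeatureDB, exon: TargetedExon,
                       inclusion_tx: str) -> tuple[bool | None, int | None]:
    """(frame_preserving, deleted_coding_length) for skipping the exon from
    an inclusion transcript.

    Deleted coding length = overlap of the exon with the transcript's CDS;
    preserved iff divisible by 3. A fully-UTR exon deletes 0 coding
    nucleotides and preserves frame. Transcripts without CDS records are
    unassessable: returns (None, None).
    """
    cds = _transcript_cds(db, inclusion_tx)
    if not cds:
        return None, None
    deleted = _overlap_len((exon.start, exon.end), cds)
    return deleted % 3 == 0, deleted


def _subtract(intervals: list[Interval], cut: Interval) -> list[Interval]:
    """Remove ``cut`` from a sorted interval list (splitting as needed)."""
    cs, ce = cut
    out: list[Interval] = []
    for s, e in intervals:
        if e < cs or s > ce:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs - 1))
        if e > ce:
            out.append((ce + 1, e))
    return out


def strict_and_longest_skipping(db: gffutils.FeatureDB, exon: TargetedExon,
                                inclusion: list[str] | None = None,
                                skipping: list[str] | None = None
                                ) -> SkippingCall:
    """Classify skipping transcripts of a targeted exon.

    Strict: a skipping transcript whose CDS equals some inclusion
    transcript's CDS with exactly the targeted exon's coding overlap removed
    — or, when an MXE partner is declared, with the partner exon's interval
    substituted in its place. Comparison is at genomic-coordinate level
    (equal coordinate sets on one genome imply equal coding sequence).
    Longest: the skipping transcript with maximal summed exon (mRNA) length,
    regardless of other differences. No skipping transcript yields empty
    sets, not an error.
    """
    if inclusion is None or skipping is None:
        inclusion, skipping = map_transcripts(db, exon)

    frame, deleted = None, None
    for tx in inclusion:
        frame, deleted = frame_preservation(db, exon, tx)
        if frame is not None:
            break

    expected_sets: list[tuple[Interval, ...]] = []
    cut = (exon.start, exon.end)
    for tx in inclusion:
        cds = _transcript_cds(db, tx)
        if not cds:
            continue
        reduced = _subtract(cds, cut)
        expected_sets.append(tuple(reduced))
        if exon.mxe_partner is not None:
            with_partner = sorted(reduced + [exon.mxe_partner])
            expected_sets.append(tuple(with_partner))

    strict: list[str] = []
    for tx in skipping:
        cds = tuple(_transcript_cds(db, tx))
        if cds and cds in expected_sets:
            strict.append(tx)

    longest = None
    if skipping:
        longest = max(
            skipping,
            key=lambda t: sum(e - s + 1 for s, e in _transcript_exons(db, t)))
    return SkippingCall(
        exon=exon, frame_preserving=frame, deleted_coding_length=deleted,
        inclusion_transcripts=list(inclusion),
        skipping_transcripts=list(skipping),
        strict_skipping_transcripts=strict,
        longest_skipping_transcript=longest)


def annotate_exons(db: gffutils.FeatureDB, exons: list[TargetedExon]
                   ) -> "pd.DataFrame":
    """Per-exon annotation table for a list of targeted exons."""
    import pandas as pd

    rows = []
    for ex in exons:
        call = strict_and_longest_skipping(db, ex)
        rows.append({
            "chrom": ex.chrom, "start": ex.start, "end": ex.end,
            "strand": ex.strand, "gene_id": ex.gene_id,
            "exon_length": ex.length,
            "frame_preserving": call.frame_preserving,
            "deleted_coding_length": call.deleted_coding_length,
            "inclusion_transcripts": ",".join(call.inclusion_transcripts),
            "skipping_transcripts": ",".join(call.skipping_transcripts),
            "strict_skipping_transcripts":
                ",".join(call.strict_skipping_transcripts),
            "longest_skipping_transcript":
                call.longest_skipping_transcript or "",
        })
    return pd.DataFrame(rows)
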