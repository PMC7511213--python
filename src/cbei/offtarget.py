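"""Anchor-based off-target search of spacers against genome FASTA.

The spacer is split into ``mismatch + 1`` contiguous, near-equal exact
fragments ("anchors").  By the pigeonhole principle, any genomic window
within the mismatch budget of the spacer must contain at least one anchor
verbatim, so exact anchor hits are the only candidate loci that need full
verification (PAM adjacency and total Hamming distance).  Genomes of any
size are handled by slicing each contig into fixed-size segments plus
short junction segments spanning every internal boundary, so sites that
straddle a slice boundary are not lost.

Mismatches are substitutions only (Hamming distance); a genomic N counts
as a mismatch and never satisfies a PAM letter; the PAM itself must match
the editor's IUPAC pattern exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import pandas as pd

from cbei.cbe_model import CbeModel
from cbei.seqcore import NucSequence, read_fasta, reverse_complement

__all__ = [
    "AnchorSet", "OffTargetHit", "GenomeSegment",
    "build_anchors", "segment_genome", "scan_segment", "offtarget_search",
    "hits_to_frame", "DEFAULT_SEGMENT_SIZE", "DEFAULT_FLANK",
]

DEFAULT_SEGMENT_SIZE = 50_000_000
DEFAULT_FLANK = 100


@dataclass(frozen=True)
class AnchorSet:
    """A spacer split into ``max_mismatch + 1`` contiguous exact fragments."""

    spacer: str
    max_mismatch: int
    anchors: tuple[tuple[int, str], ...]  # (offset within spacer, fragment)


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic locus within the mismatch budget of a spacer, PAM-adjacent.

    ``start`` is the 1-based plus-strand position of the leftmost
    protospacer base on the contig; ``site_seq`` and ``pam_seq`` are
    written 5'->3' on the protospacer strand.
    """

    spacer: str
    contig: str
    start: int
    strand: str
    mismatches: int
    site_seq: str
    pam_seq: str
    is_on_target: bool


@dataclass(frozen=True)
class GenomeSegment:
    """A slice of one contig; ``seg_start`` is its 0-based contig offset."""

    contig: str
    seg_start: int
    seq: str
    is_junction: bool = False


def build_anchors(spacer: str, m: int) -> AnchorSet:
    """Split a spacer into m+1 contiguous fragments with lengths differing by <= 1."""
    if m < 0:
        raise ValueError("mismatch budget must be >= 0")
    if len(spacer) < m + 1:
        raise ValueError(
            f"spacer of length {len(spacer)} cannot be split into {m + 1} anchors"
        )
    k = m + 1
    base, rem = divmod(len(spacer), k)
    anchors = []
    off = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        anchors.append((off, spacer[off : off + size]))
        off += size
    return AnchorSet(spacer=spacer, max_mismatch=m, anchors=tuple(anchors))


def segment_genome(
    source: Union[str, Path, Iterable[NucSequence]],
    segment_size: int = DEFAULT_SEGMENT_SIZE,
    flank: int = DEFAULT_FLANK,
) -> Iterator[GenomeSegment]:
    """Stream a genome as tiling segments plus boundary-spanning junction segments.

    Each contig is tiled with non-overlapping segments of at most
    ``segment_size`` bases; for every internal tile boundary an extra
    junction segment of ``2 * flank`` bases centred on the boundary is
    emitted so boundary-straddling sites can be recovered.  Soft-masked
    (lowercase) sequence is treated as normal sequence.
    """
    if segment_size <= 2 * flank:
        raise ValueError("segment_size must exceed twice the junction flank")
    contigs = read_fasta(source) if isinstance(source, (str, Path)) else source
    for rec in contigs:
        s = rec.seq
        n = len(s)
        for lo in range(0, n, segment_size):
            yield GenomeSegment(contig=rec.id, seg_start=lo, seq=s[lo : lo + segment_size])
        for b in range(segment_size, n, segment_size):
            lo = max(0, b - flank)
            yield GenomeSegment(
                contig=rec.id, seg_start=lo, seq=s[lo : b + flank], is_junction=True
            )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_all(hay: str, needle: str) -> Iterator[int]:
    i = hay.find(needle)
    while i != -1:
        yield i
        i = hay.find(needle, i + 1)


def scan_segment(
    segment: GenomeSegment,
    anchors: AnchorSet,
    model: CbeModel,
) -> list[OffTargetHit]:
    """Verify every exact anchor occurrence in one segment, both strands.

    Windows (protospacer or PAM) running past the segment edge are
    skipped; junction segments recover sites near tile boundaries.
    Hits found by several anchors are reported once.
    """
    spacer = anchors.spacer
    m = anchors.max_mismatch
    L = len(spacer)
    P = model.pam_len
    matcher = model.pam_matcher
    seg = segment.seq.upper()
    hits: dict[tuple[int, str], OffTargetHit] = {}
    for strand in "+-":
        oriented = spacer if strand == "+" else reverse_complement(spacer)
        strand_anchors = (
            anchors.anchors if strand == "+" else build_anchors(oriented, m).anchors
        )
        # PAM on the plus strand sits right of the window when the
        # protospacer strand and PAM side "agree" (e.g. + strand, 3' PAM).
        pam_right = (strand == "+") == (model.pam_side == "3prime")
        for off, frag in strand_anchors:
            for i in _find_all(seg, frag):
                lo = i - off
                if lo < 0 or lo + L > len(seg):
                    continue
                key = (lo, strand)
                if key in hits:
                    continue
                window = seg[lo : lo + L]
                mism = _hamming(window, oriented)
                if mism > m:
                    continue
                pam_lo, pam_hi = (lo + L, lo + L + P) if pam_right else (lo - P, lo)
                if pam_lo < 0 or pam_hi > len(seg):
                    continue
                pam_plus = seg[pam_lo:pam_hi]
                site_seq = window if strand == "+" else reverse_complement(window)
                pam_seq = pam_plus if strand == "+" else reverse_complement(pam_plus)
                if not matcher.matches(pam_seq):
                    continue
                hits[key] = OffTargetHit(
                    spacer=spacer,
                    contig=segment.contig,
                    start=segment.seg_start + lo + 1,
                    strand=strand,
                    mismatches=mism,
                    site_seq=site_seq,
                    pam_seq=pam_seq,
                    is_on_target=(mism == 0),
                )
    return list(hits.values())


def offtarget_search(
    spacers: Sequence,
    genome: Union[str, Path, Iterable[NucSequence]],
    model: CbeModel,
    m: int,
    segment_size: int = DEFAULT_SEGMENT_SIZE,
    flank: int = DEFAULT_FLANK,
) -> list[OffTargetHit]:
    """Search spacers against a genome, sharing one pass over the segments.

    ``spacers`` may be raw strings or objects with a ``spacer_seq``
    attribute (design output rows).  Hits are deduplicated on
    (spacer, contig, start, strand) — a site found in both a tile and a
    junction segment, or by several anchors, appears once — and sorted
    by (spacer, contig, start).
    """
    seqs = [getattr(sp, "spacer_seq", sp).upper() for sp in spacers]
    if not seqs:
        raise ValueError("empty spacer list")
    if m > 3:
        import warnings

        warnings.warn(f"mismatch budget {m} is above the typical 0-3 range; search may be slow")
    anchor_sets = [build_anchors(sp, m) for sp in dict.fromkeys(seqs)]
    seen: set[tuple[str, str, int, str]] = set()
    out: list[OffTargetHit] = []
    for segment in segment_genome(genome, segment_size=segment_size, flank=flank):
        for aset in anchor_sets:
            for hit in scan_segment(segment, aset, model):
                key = (hit.spacer, hit.contig, hit.start, hit.strand)
                if key not in seen:
                    seen.add(key)
                    out.append(hit)
    out.sort(key=lambda h: (h.spacer, h.contig, h.start, h.strand))
    return out


def hits_to_frame(hits: Sequence[OffTargetHit]) -> pd.DataFrame:
    """Tabulate hits with the standard output columns."""
    cols = ["spacer", "contig", "start", "strand", "mismatches",
            "site_seq", "pam_seq", "is_on_target"]
    return pd.DataFrame([[getattr(h, c) for c in cols] for h in hits], columns=cols)
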