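"""Six-frame ORF detection.

An ORF is a maximal start->stop run on one of the six reading frames:
it begins at the 5'-most qualifying start codon for its terminating stop,
contains no internal stop, and its reported length includes the stop
codon.  ORFs that run off the end of the sequence without a stop are not
reported: downstream spacer design needs a bounded coding sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from cbei.seqcore import GeneticCode, NucSequence, reverse_complement

__all__ = ["OrfHit", "detect_orfs", "validate_cds", "DEFAULT_MIN_LEN", "MIN_LEN_RANGE"]

DEFAULT_MIN_LEN = 75
MIN_LEN_RANGE = (24, 150)


@dataclass(frozen=True)
class OrfHit:
    """One ORF on the input sequence.

    ``start``/``end`` are 1-based inclusive positions on the input plus
    strand (``start`` <= ``end`` on both strands); ``frame`` is +1/+2/+3
    or -1/-2/-3 counted from the 5' end of the respective strand;
    ``cds_seq`` is the ORF 5'->3' on its own strand, start codon first.
    """

    frame: int
    strand: str
    start: int
    end: int
    length_nt: int
    cds_seq: str

    def to_nucsequence(self, parent_id: str) -> NucSequence:
        return NucSequence(
            id=f"{parent_id}|ORF:{self.strand}{self.start}-{self.end}",
            seq=self.cds_seq,
        )


def _scan_strand(s: str, code: GeneticCode, min_len: int):
    """Yield (start0, end0, frame1) of maximal ORFs on one oriented string."""
    n = len(s)
    for off in range(3):
        current_start = None
        for i in range(off, n - 2, 3):
            codon = s[i : i + 3]
            if code.is_stop(codon):
                if current_start is not None and i + 3 - current_start >= min_len:
                    yield current_start, i + 3, off + 1
                current_start = None
            elif current_start is None and code.is_start(codon):
                current_start = i


def detect_orfs(
    seq: NucSequence,
    code: GeneticCode,
    min_len: int = DEFAULT_MIN_LEN,
    strict: bool = True,
) -> list[OrfHit]:
    """Detect all maximal ORFs of length >= ``min_len`` on all six frames.

    With ``strict`` (the default, matching interactive use), ``min_len``
    must lie in [24, 150]; batch callers may pass ``strict=False`` to use
    any positive threshold.
    """
    if strict and not (MIN_LEN_RANGE[0] <= min_len <= MIN_LEN_RANGE[1]):
        raise ValueError(
            f"min_len {min_len} outside permitted range {MIN_LEN_RANGE[0]}-{MIN_LEN_RANGE[1]}"
        )
    n = len(seq.seq)
    hits: list[OrfHit] = []
    for start0, end0, frame in _scan_strand(seq.seq, code, min_len):
        hits.append(
            OrfHit(
                frame=frame,
                strand="+",
                start=start0 + 1,
                end=end0,
                length_nt=end0 - start0,
                cds_seq=seq.seq[start0:end0],
            )
        )
    rc = reverse_complement(seq.seq)
    for start0, end0, frame in _scan_strand(rc, code, min_len):
        hits.append(
            OrfHit(
                frame=-frame,
                strand="-",
                start=n - end0 + 1,
                end=n - start0,
                length_nt=end0 - start0,
                cds_seq=rc[start0:end0],
            )
        )
    hits.sort(key=lambda h: (h.strand != "+", h.start, h.end))
    return hits


def validate_cds(seq: NucSequence, code: GeneticCode) -> list[str]:
    """Check that a sequence is a complete CDS on frame +1.

    Returns a list of human-readable problems (empty when the record is a
    valid CDS: length divisible by 3, starts with a start codon, ends with
    a stop codon, no internal stop).  Batch pipelines warn on problems
    instead of failing, so one malformed record cannot abort a run.
    """
    problems: list[str] = []
    s = seq.seq
    if len(s) % 3 != 0:
        problems.append(f"length {len(s)} not divisible by 3")
    if len(s) < 6:
        problems.append("shorter than two codons")
        return problems
    if not code.is_start(s[:3]):
        problems.append(f"does not begin with a start codon (saw {s[:3]})")
    n_codons = len(s) // 3
    if not code.is_stop(s[3 * (n_codons - 1) : 3 * n_codons]):
        problems.append("does not end with a stop codon")
    for j in range(n_codons - 1):
        if code.is_stop(s[3 * j : 3 * j + 3]):
            problems.append(f"internal stop codon at codon {j + 1}")
            break
    return problems
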