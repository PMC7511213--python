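"""Spacer search for premature stop-codon introduction.

For a chosen CDS and editor, every placement of the protospacer + PAM on
either strand is examined.  A placement qualifies when at least one C in
the editing window belongs to a codon that a C->T conversion (on the
protospacer strand) turns into a premature stop.  On the sense strand
C->T edits act directly on the codon; on the antisense strand a C->T
edit reads as G->A on the sense codon.  Under the standard genetic code
this makes CAA->TAA, CAG->TAG, CGA->TGA (sense) and TGG->TAG/TGA/TAA
(antisense) the editable codons — but the search simulates edits and
re-translates rather than pattern-matching those four, so non-standard
genetic codes are handled for free.

One site is emitted per (protospacer placement, edited codon) pair; a
placement whose window can disrupt two codons yields two rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from itertools import combinations

from cbei.cbe_model import CbeModel
from cbei.seqcore import GeneticCode, NucSequence, reverse_complement

__all__ = [
    "CbeiSite", "DesignReport",
    "stop_creating_edits", "stop_creating_codons",
    "find_cbei_sites", "annotate_context", "region_filter",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class CbeiSite:
    """One qualifying spacer whose in-window edit creates a premature stop.

    ``proto_start`` is the 1-based position on the CDS plus strand of the
    leftmost protospacer base (regardless of strand); ``edit_positions``
    are window positions (1-based from the protospacer 5' end) of the
    minimal set of C->T conversions that creates the stop.
    """

    cbe_name: str
    cds_id: str
    spacer_seq: str
    pam_seq: str
    strand: str
    proto_start: int
    edited_codon_index: int  # 1-based codon number in the CDS
    codon_before: str
    codon_after: str
    edit_positions: tuple[int, ...]
    context: str  # TC/CC/AC/GC, or "NC" at the CDS boundary
    context_rank: int | None
    cds_fraction: float
    annotation: str


@dataclass
class DesignReport:
    """Result of one CDS x CBE search, with whole-CDS and in-region counts."""

    cds_id: str
    cbe_name: str
    region_fraction: float
    sites: list[CbeiSite]
    n_sites_whole_cds: int
    n_sites_in_region: int
    n_plus: int
    n_minus: int
    histogram: list[int]  # site counts in ten equal cds_fraction bins
    warning: str | None = None

    @property
    def sites_in_region(self) -> list[CbeiSite]:
        return [s for s in self.sites if s.cds_fraction <= self.region_fraction / 100.0]


@lru_cache(maxsize=None)
def _stop_edits_cached(codon: str, stops: frozenset) -> tuple:
    out = []
    if codon in stops:
        return ()
    for strand, base, new in (("+", "C", "T"), ("-", "G", "A")):
        positions = [i for i in range(3) if codon[i] == base]
        for r in range(1, len(positions) + 1):
            for subset in combinations(positions, r):
                edited = "".join(
                    new if i in subset else codon[i] for i in range(3)
                )
                if edited in stops:
                    out.append((strand, frozenset(subset), edited))
    return tuple(out)


def stop_creating_edits(
    codon: str, code: GeneticCode
) -> set[tuple[str, frozenset[int], str]]:
    """All single-strand C->T edit subsets turning ``codon`` into a stop.

    Returns ``(strand, offsets, stop)`` triples where ``offsets`` are
    0-based positions within the codon; strand ``+`` means sense C->T,
    ``-`` means antisense C->T (sense G->A).  A codon that is already a
    stop yields the empty set.
    """
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        return set()
    return set(_stop_edits_cached(codon, code.stop_codons))


def stop_creating_codons(code: GeneticCode) -> set[str]:
    """Codons convertible to a stop, by exhaustive scan of all 64."""
    bases = "ACGT"
    return {
        a + b + c
        for a in bases for b in bases for c in bases
        if stop_creating_edits(a + b + c, code)
    }


def find_cbei_sites(
    cds: NucSequence,
    model: CbeModel,
    code: GeneticCode,
    region_fraction: float = 50.0,
) -> DesignReport:
    """Search both strands of a CDS for spacers that can create a premature stop.

    A placement requires protospacer and adjacent PAM fully inside the
    CDS and a PAM match; it is reported once per codon whose in-window
    edit yields a premature stop.  Sites whose protospacer or PAM
    contains N are skipped.  A CDS whose length is not divisible by 3
    triggers a warning and trailing bases are ignored for codon math.
    """
    if not (0 < region_fraction <= 100):
        raise ValueError(f"region_fraction must be in (0, 100], got {region_fraction}")
    s = cds.seq
    L = model.spacer_len
    P = model.pam_len
    warning = None
    if len(s) % 3 != 0:
        warning = f"{cds.id}: length {len(s)} not divisible by 3; trailing bases ignored"
        warnings.warn(warning)
    n_codons = len(s) // 3
    if len(s) < L + P:
        return DesignReport(
            cds_id=cds.id, cbe_name=model.name, region_fraction=region_fraction,
            sites=[], n_sites_whole_cds=0, n_sites_in_region=0,
            n_plus=0, n_minus=0, histogram=[0] * 10,
            warning=f"{cds.id}: shorter than spacer + PAM ({L + P} nt)",
        )

    matcher = model.pam_matcher
    sites: list[CbeiSite] = []
    # placements: p = leftmost protospacer base on the plus strand (0-based)
    for p in range(0, len(s) - L + 1):
        for strand in "+-":
            # locate the PAM on the plus strand given strand and pam side
            pam_right = (strand == "+") == (model.pam_side == "3prime")
            if pam_right:
                pam_lo, pam_hi = p + L, p + L + P
            else:
                pam_lo, pam_hi = p - P, p
            if pam_lo < 0 or pam_hi > len(s):
                continue
            proto_plus = s[p : p + L]
            pam_plus = s[pam_lo:pam_hi]
            if "N" in proto_plus or "N" in pam_plus:
                continue
            if strand == "+":
                spacer, pam = proto_plus, pam_plus
            else:
                spacer, pam = reverse_complement(proto_plus), reverse_complement(pam_plus)
            if not matcher.matches(pam):
                continue
            sites.extend(
                _sites_for_placement(
                    cds, s, model, code, n_codons, p, strand, spacer, pam,
                )
            )
    sites.sort(key=lambda x: (x.proto_start, x.strand, x.edited_codon_index))
    return _make_report(cds.id, model.name, region_fraction, sites, warning)


def _sites_for_placement(cds, s, model, code, n_codons, p, strand, spacer, pam):
    """Sites created by one (placement, strand); one per edited codon."""
    L = model.spacer_len
    # window position w (1-based from protospacer 5') -> plus-strand 0-based pos
    if strand == "+":
        pos_of = lambda w: p + w - 1
    else:
        pos_of = lambda w: p + L - w
    # eligible: in-window plus-strand positions carrying an editable C
    # (C on the protospacer strand: sense C for +, sense G for -)
    target = "C" if strand == "+" else "G"
    eligible: dict[int, set[int]] = {}  # codon index -> plus-strand offsets in codon
    winpos: dict[int, int] = {}  # plus-strand pos -> window position
    for w in model.window_positions():
        q = pos_of(w)
        if 0 <= q < 3 * n_codons and s[q] == target:
            eligible.setdefault(q // 3, set()).add(q % 3)
            winpos[q] = w
    out = []
    for j, offsets in sorted(eligible.items()):
        if j >= n_codons - 1:
            continue  # the natural terminator is not premature
        codon = s[3 * j : 3 * j + 3]
        candidates = [
            (st, subset, stop)
            for (st, subset, stop) in stop_creating_edits(codon, code)
            if st == strand and subset <= offsets
        ]
        if not candidates:
            continue
        # minimal edit: fewest bases, then 5'-most on the protospacer strand
        def key(c):
            wps = sorted(winpos[3 * j + o] for o in c[1])
            return (len(c[1]), wps)
        st, subset, stop = min(candidates, key=key)
        edit_positions = tuple(sorted(winpos[3 * j + o] for o in subset))
        context, rank = _context(s, model, strand, 3 * j, subset)
        site = CbeiSite(
            cbe_name=model.name,
            cds_id=cds.id,
            spacer_seq=spacer,
            pam_seq=pam,
            strand=strand,
            proto_start=p + 1,
            edited_codon_index=j + 1,
            codon_before=codon,
            codon_after=stop,
            edit_positions=edit_positions,
            context=context,
            context_rank=rank,
            cds_fraction=(3 * j + 1) / len(s),
            annotation="",
        )
        out.append(replace(site, annotation=_render_annotation(site, model)))
    return out


def _context(s, model, strand, codon_start, subset):
    """Dinucleotide context of the 5'-most stop-creating C on the edited strand."""
    if strand == "+":
        q = codon_start + min(subset)  # 5'-most on sense = leftmost
        if q == 0:
            return "NC", None
        prev = s[q - 1]
    else:
        q = codon_start + max(subset)  # 5'-most on antisense = rightmost
        if q + 1 >= len(s):
            return "NC", None
        prev = _COMP[s[q + 1]]
    ctx = prev + "C"
    try:
        rank = model.context_order.index(ctx) + 1
    except ValueError:
        return ctx, None
    return ctx, rank


def annotate_context(site: CbeiSite, cds: NucSequence, model: CbeModel) -> CbeiSite:
    """Recompute the 5'-dinucleotide context annotation of a site."""
    p = site.proto_start - 1
    L = model.spacer_len
    if site.strand == "+":
        offsets = {p + w - 1 - 3 * (site.edited_codon_index - 1) for w in site.edit_positions}
    else:
        offsets = {p + L - w - 3 * (site.edited_codon_index - 1) for w in site.edit_positions}
    ctx, rank = _context(
        cds.seq, model, site.strand, 3 * (site.edited_codon_index - 1), offsets
    )
    return replace(site, context=ctx, context_rank=rank)


def _render_annotation(site: CbeiSite, model: CbeModel) -> str:
    """Plain-text rendering: {spacer} braces, [window] brackets, (c>T) edits, PAM after a pipe."""
    chars = []
    edit = set(site.edit_positions)
    for w, base in enumerate(site.spacer_seq, start=1):
        chars.append(f"({base.lower()}>T)" if w in edit else base)
    w0, w1 = model.window_start - 1, model.window_end  # list indices
    body = "".join(chars[:w0]) + "[" + "".join(chars[w0:w1]) + "]" + "".join(chars[w1:])
    core = "{" + body + "}|" + site.pam_seq
    if model.pam_side == "5prime":
        core = site.pam_seq + "|{" + body + "}"
    return f"{core} {site.codon_before}>{site.codon_after}@{site.edited_codon_index}"


def _make_report(cds_id, cbe_name, region_fraction, sites, warning=None) -> DesignReport:
    limit = region_fraction / 100.0
    hist = [0] * 10
    for st in sites:
        hist[min(int(st.cds_fraction * 10), 9)] += 1
    return DesignReport(
        cds_id=cds_id,
        cbe_name=cbe_name,
        region_fraction=region_fraction,
        sites=sites,
        n_sites_whole_cds=len(sites),
        n_sites_in_region=sum(1 for st in sites if st.cds_fraction <= limit),
        n_plus=sum(1 for st in sites if st.strand == "+"),
        n_minus=sum(1 for st in sites if st.strand == "-"),
        histogram=hist,
        warning=warning,
    )


def region_filter(report: DesignReport, region_fraction: float) -> DesignReport:
    """Restrict a report to sites whose edited codon starts within the top N% of the CDS."""
    if not (0 < region_fraction <= 100):
        raise ValueError(f"region_fraction must be in (0, 100], got {region_fraction}")
    limit = region_fraction / 100.0
    kept = [s for s in report.sites if s.cds_fraction <= limit]
    out = _make_report(report.cds_id, report.cbe_name, region_fraction, kept, report.warning)
    out.n_sites_whole_cds = report.n_sites_whole_cds
    return out
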