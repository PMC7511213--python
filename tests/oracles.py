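"""Independent brute-force oracles used to verify the package's algorithms.

Everything here is written from the problem definition with the simplest
possible logic (enumerate, simulate, re-translate) and shares no search
code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def pam_ok(pam: str, pattern: str) -> bool:
    """Per-position IUPAC membership check; N in the sequence never matches."""
    return len(pam) == len(pattern) and all(
        b in ORACLE_IUPAC[p] for b, p in zip(pam, pattern)
    )


# ---------------------------------------------------------------- ORFs

def brute_orfs(seq: str, code, min_len: int) -> set[tuple]:
    """All maximal start->stop ORFs >= min_len, six frames.

    Enumerates every start codon, walks to the next in-frame stop, keeps
    the 5'-most start per (strand, stop).  Returns canonical tuples
    (strand, start_1based, end_1based, cds_seq) in input plus-strand
    coordinates.
    """
    out = {}
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for i in range(n - 2):
            if s[i : i + 3] not in code.start_codons:
                continue
            j = i + 3
            while j + 3 <= n:
                if s[j : j + 3] in code.stop_codons:
                    break
                j += 3
            else:
                continue
            if s[j : j + 3] not in code.stop_codons:
                continue
            end0 = j + 3
            key = (strand, end0)
            if key not in out or i < out[key]:
                out[key] = i
    hits = set()
    for (strand, end0), start0 in out.items():
        if end0 - start0 < min_len:
            continue
        s = seq if strand == "+" else rc(seq)
        cds = s[start0:end0]
        if strand == "+":
            hits.add((strand, start0 + 1, end0, cds))
        else:
            hits.add((strand, n - end0 + 1, n - start0, cds))
    return hits


# ------------------------------------------------------- design search

def brute_design_sites(cds: str, model, code) -> set[tuple]:
    """Every (placement, edited codon) able to create a premature stop.

    Tries every protospacer placement on both strands, every nonempty
    subset of in-window editable-C positions inside each codon, applies
    the edit and re-translates.  Returns canonical tuples
    (strand, proto_start_1based, codon_index_1based).
    """
    L = model.spacer_len
    P = len(model.pam_pattern)
    n_codons = len(cds) // 3
    found = set()
    for p in range(len(cds) - L + 1):
        for strand in "+-":
            pam_right = (strand == "+") == (model.pam_side == "3prime")
            pam_lo, pam_hi = (p + L, p + L + P) if pam_right else (p - P, p)
            if pam_lo < 0 or pam_hi > len(cds):
                continue
            proto_plus = cds[p : p + L]
            pam_plus = cds[pam_lo:pam_hi]
            if "N" in proto_plus or "N" in pam_plus:
                continue
            pam = pam_plus if strand == "+" else rc(pam_plus)
            if not pam_ok(pam, model.pam_pattern):
                continue
            editable = "C" if strand == "+" else "G"
            new = "T" if strand == "+" else "A"
            window_pos = []
            for w in range(model.window_start, model.window_end + 1):
                q = p + w - 1 if strand == "+" else p + L - w
                if 0 <= q < 3 * n_codons and cds[q] == editable:
                    window_pos.append(q)
            by_codon: dict[int, list[int]] = {}
            for q in window_pos:
                by_codon.setdefault(q // 3, []).append(q)
            for j, qs in by_codon.items():
                if j >= n_codons - 1:
                    continue
                codon = cds[3 * j : 3 * j + 3]
                if codon in code.stop_codons:
                    continue
                hit = False
                for r in range(1, len(qs) + 1):
                    for subset in combinations(qs, r):
                        edited = list(codon)
                        for q in subset:
                            edited[q - 3 * j] = new
                        if "".join(edited) in code.stop_codons:
                            hit = True
                if hit:
                    found.add((strand, p + 1, j + 1))
    return found


# ---------------------------------------------------- off-target scan

def brute_offtarget(genome: str, spacer: str, model, m: int) -> set[tuple]:
    """Full sliding-window Hamming + PAM scan of one contig, both strands.

    Returns canonical tuples (start_1based, strand, mismatches) for every
    window within Hamming distance m of the spacer with a valid adjacent
    PAM.  Vectorized with numpy but otherwise the textbook definition.
    """
    g = np.frombuffer(genome.upper().encode(), dtype=np.uint8)
    L = len(spacer)
    P = len(model.pam_pattern)
    hits = set()
    if len(g) < L:
        return hits
    windows = np.lib.stride_tricks.sliding_window_view(g, L)
    for strand in "+-":
        oriented = spacer if strand == "+" else rc(spacer)
        sp = np.frombuffer(oriented.encode(), dtype=np.uint8)
        mism = (windows != sp).sum(axis=1)
        pam_right = (strand == "+") == (model.pam_side == "3prime")
        for lo in np.nonzero(mism <= m)[0]:
            lo = int(lo)
            pam_lo, pam_hi = (lo + L, lo + L + P) if pam_right else (lo - P, lo)
            if pam_lo < 0 or pam_hi > len(g):
                continue
            pam_plus = genome[pam_lo:pam_hi].upper()
            pam = pam_plus if strand == "+" else rc(pam_plus)
            if pam_ok(pam, model.pam_pattern):
                hits.add((lo + 1, strand, int(mism[lo])))
    return hits
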