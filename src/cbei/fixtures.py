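"""Synthetic CDSs and genomes with planted, ledgered ground truth.

Every generator is fully determined by its spec's seed, and every planted
feature is recorded in a *ground-truth ledger* — a list of plain dicts
stating what a correct analysis must find (or must not find).  Background
sequence is i.i.d. at a target GC; after planting, genomes are self-scanned
with a naive full-window Hamming oracle and regenerated if the background
happens to contain an unplanned near-match, so expected hit counts are
exact rather than probabilistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from cbei.cbe_model import CbeModel, IUPAC_CODES, load_preset
from cbei.seqcore import GeneticCode, NucSequence, load_genetic_code, reverse_complement

__all__ = [
    "FixtureSpec", "PlantedSite", "GenomeFixtureSpec", "GenomePlant",
    "make_cds", "make_genome", "random_cds", "naive_offtarget_scan",
    "write_fixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedSite:
    """A stop-creating site to engineer into one CDS.

    ``codon`` is the editable codon to plant (CAA/CAG/CGA go on the sense
    strand; TGG is edited from the antisense strand); ``max_fraction``
    bounds where along the CDS the codon may sit.
    """

    cds_index: int
    model: str = "BE3"
    codon: str = "CAA"
    max_fraction: float = 0.5


@dataclass
class FixtureSpec:
    """Spec for a synthetic CDS set."""

    seed: int
    n_cds: int = 10
    length_range: tuple[int, int] = (300, 1500)
    gc: float = 0.5
    table_id: int = 1
    plants: tuple[PlantedSite, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length_range must be >= 30 nt and ordered")


@dataclass(frozen=True)
class GenomePlant:
    """A spacer copy to embed in a synthetic genome.

    ``distance`` substitutions are applied to the spacer; ``pam_valid``
    controls whether the adjacent PAM matches the editor; ``position`` is
    the 0-based plus-strand locus of the leftmost protospacer base
    (``None`` = random non-overlapping placement).
    """

    spacer: str
    distance: int = 0
    pam_valid: bool = True
    strand: str = "+"
    position: int | None = None


@dataclass
class GenomeFixtureSpec:
    """Spec for a synthetic genome with planted off-target loci."""

    seed: int
    length: int = 100_000
    gc: float = 0.5
    model: str = "BE3"
    name: str = "chr1"
    plants: tuple[GenomePlant, ...] = ()
    max_scan_m: int = 3


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _random_codon(rng: np.random.Generator, gc: float, code: GeneticCode) -> str:
    for _ in range(100):
        c = "".join(_random_bases(rng, 3, gc))
        if not code.is_stop(c):
            return c
    return "AAA"


def random_cds(
    rng: np.random.Generator, length: int, gc: float, code: GeneticCode
) -> str:
    """A valid CDS: start codon, stop-free body at ~target GC, one terminal stop."""
    if length % 3 != 0:
        length -= length % 3
    n_codons = max(length // 3, 3)
    start = sorted(code.start_codons)[0] if "ATG" not in code.start_codons else "ATG"
    stop = sorted(code.stop_codons)[rng.integers(len(code.stop_codons))]
    body = [_random_codon(rng, gc, code) for _ in range(n_codons - 2)]
    return start + "".join(body) + stop


def _concrete_pam(rng: np.random.Generator, pattern: str, valid: bool) -> str:
    """A concrete PAM that matches (valid) or provably fails (invalid) the pattern."""
    if valid:
        return "".join(IUPAC_CODES[ch][rng.integers(len(IUPAC_CODES[ch]))] for ch in pattern)
    # break every constrained position; if the pattern is all-N no invalid PAM exists
    out = []
    broken = False
    for ch in pattern:
        allowed = IUPAC_CODES[ch]
        disallowed = [b for b in _BASES if b not in allowed]
        if disallowed:
            out.append(disallowed[rng.integers(len(disallowed))])
            broken = True
        else:
            out.append(_BASES[rng.integers(4)])
    if not broken:
        raise ValueError(f"pattern {pattern!r} matches every sequence; no invalid PAM exists")
    return "".join(out)


def make_cds(spec: FixtureSpec) -> tuple[list[NucSequence], list[dict]]:
    """Generate a CDS set with planted stop-creating sites and its ledger.

    Each planted feature yields a ledger entry recording the CDS id, the
    editor, the 1-based codon index of the planted codon, the stop codon
    an in-window edit must create, and the region fraction bound.
    """
    rng = np.random.default_rng(spec.seed)
    code = load_genetic_code(spec.table_id)
    lo, hi = spec.length_range
    seqs: list[str] = []
    for _ in range(spec.n_cds):
        length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        seqs.append(random_cds(rng, length, spec.gc, code))
    ledger: list[dict] = []
    for plant in spec.plants:
        if not 0 <= plant.cds_index < spec.n_cds:
            raise ValueError(f"plant cds_index {plant.cds_index} out of range")
        model = load_preset(plant.model)
        seqs[plant.cds_index], entry = _plant_site(
            rng, seqs[plant.cds_index], model, code, plant
        )
        entry["cds_id"] = f"cds{plant.cds_index + 1}"
        ledger.append(entry)
    records = [NucSequence(id=f"cds{i + 1}", seq=s) for i, s in enumerate(seqs)]
    return records, ledger


def _plant_site(
    rng: np.random.Generator,
    cds: str,
    model: CbeModel,
    code: GeneticCode,
    plant: PlantedSite,
) -> tuple[str, dict]:
    """Engineer one editable codon + compatible PAM into a CDS."""
    L, P = model.spacer_len, model.pam_len
    strand = "-" if plant.codon == "TGG" else "+"
    edits = [
        (st, subset, stop)
        for (st, subset, stop) in _codon_edits(plant.codon, code)
        if st == strand and len(subset) == 1
    ]
    if not edits:
        raise ValueError(
            f"codon {plant.codon} has no single-base stop-creating edit on strand {strand}"
        )
    _, subset, stop = edits[rng.integers(len(edits))]
    offset = next(iter(subset))  # offset of the edited base within the codon
    n_codons = len(cds) // 3
    max_j = int(plant.max_fraction * n_codons) - 1
    candidates = []
    for j in range(1, min(max_j, n_codons - 2) + 1):
        q = 3 * j + offset  # plus-strand position of the edited base
        for w in model.window_positions():
            p = q - (w - 1) if strand == "+" else q - L + w
            pam_right = (strand == "+") == (model.pam_side == "3prime")
            pam_lo, pam_hi = (p + L, p + L + P) if pam_right else (p - P, p)
            lo_all = min(p, pam_lo)
            hi_all = max(p + L, pam_hi)
            # keep the start codon and the natural terminator untouched,
            # and never let the PAM overwrite the planted codon
            pam_clear = pam_hi <= 3 * j or pam_lo >= 3 * j + 3
            if lo_all >= 3 and hi_all <= len(cds) - 3 and pam_clear:
                candidates.append((j, w, p, pam_lo, pam_hi))
    if not candidates:
        raise ValueError(
            f"cannot place a {plant.codon} site for {model.name} within "
            f"fraction {plant.max_fraction} of a {len(cds)} nt CDS"
        )
    j, w, p, pam_lo, pam_hi = candidates[rng.integers(len(candidates))]
    s = list(cds)
    s[3 * j : 3 * j + 3] = plant.codon
    for attempt in range(200):
        pam_plus = _concrete_pam(rng, model.pam_pattern, valid=True)
        if (strand == "+") != (model.pam_side == "3prime"):
            pam_plus = reverse_complement(pam_plus)
        trial = list(s)
        trial[pam_lo:pam_hi] = pam_plus
        if _no_new_stop(trial, code, exclude={j}):
            s = trial
            break
    else:
        raise ValueError(f"could not write a stop-free PAM for {model.name}")
    return "".join(s), {
        "kind": "cbei_site",
        "model": model.name,
        "codon_index": j + 1,
        "codon_before": plant.codon,
        "codon_after": stop,
        "strand": strand,
        "window_position": w,
        "max_fraction": plant.max_fraction,
    }


def _codon_edits(codon: str, code: GeneticCode):
    from cbei.cbei_design import stop_creating_edits

    return stop_creating_edits(codon, code)


def _no_new_stop(seq_list: list[str], code: GeneticCode, exclude: set[int]) -> bool:
    n_codons = len(seq_list) // 3
    for j in range(1, n_codons - 1):
        if j in exclude:
            continue
        if code.is_stop("".join(seq_list[3 * j : 3 * j + 3])):
            return False
    return True


def make_genome(spec: GenomeFixtureSpec) -> tuple[NucSequence, list[dict]]:
    """Generate a genome with planted spacer copies at exact Hamming distances.

    The ledger records, per plant, the contig position (1-based), strand,
    distance, and whether the PAM is valid — i.e. whether the locus must
    appear in a search with mismatch budget >= distance.  The assembled
    genome is self-scanned with the naive oracle; backgrounds that contain
    an unplanned PAM-valid near-match within ``max_scan_m`` are redrawn.
    """
    model = load_preset(spec.model)
    L, P = model.spacer_len, model.pam_len
    for plant in spec.plants:
        if plant.distance > len(plant.spacer):
            raise ValueError("planted distance exceeds spacer length")
        if len(plant.spacer) != L:
            raise ValueError(
                f"plant spacer length {len(plant.spacer)} != model spacer_len {L}"
            )
    for attempt in range(20):
        rng = np.random.default_rng([spec.seed, attempt])
        genome = _random_bases(rng, spec.length, spec.gc)
        ledger: list[dict] = []
        occupied: list[tuple[int, int]] = []
        ok = True
        for plant in spec.plants:
            placed = _place_plant(rng, genome, model, plant, occupied)
            if placed is None:
                ok = False
                break
            ledger.append(placed)
        if not ok:
            continue
        seq = "".join(genome)
        if _self_scan_clean(seq, model, spec, ledger):
            rec = NucSequence(id=spec.name, seq=seq)
            for entry in ledger:
                entry["contig"] = spec.name
            return rec, ledger
    raise RuntimeError("could not build a collision-free genome in 20 attempts")


def _place_plant(rng, genome, model, plant, occupied):
    L, P = model.spacer_len, model.pam_len
    site = list(plant.spacer)
    positions = rng.choice(L, size=plant.distance, replace=False)
    for q in positions:
        site[q] = rng.choice([b for b in _BASES if b != site[q]])
    site_seq = "".join(site)
    pam_seq = _concrete_pam(rng, model.pam_pattern, valid=plant.pam_valid)
    pam_right_on_proto = model.pam_side == "3prime"
    if plant.strand == "+":
        cassette = site_seq + pam_seq if pam_right_on_proto else pam_seq + site_seq
        site_off = 0 if pam_right_on_proto else P
    else:
        rc_site, rc_pam = reverse_complement(site_seq), reverse_complement(pam_seq)
        cassette = rc_pam + rc_site if pam_right_on_proto else rc_site + rc_pam
        site_off = P if pam_right_on_proto else 0
    clen = len(cassette)
    for attempt in range(200):
        if plant.position is not None:
            lo = plant.position - site_off
            if attempt > 0:
                return None
        else:
            lo = int(rng.integers(0, len(genome) - clen))
        if lo < 0 or lo + clen > len(genome):
            return None
        if all(hi2 <= lo or lo2 >= lo + clen for lo2, hi2 in occupied):
            break
    else:
        return None
    genome[lo : lo + clen] = cassette
    occupied.append((lo, lo + clen))
    return {
        "kind": "offtarget_site",
        "spacer": plant.spacer,
        "start": lo + site_off + 1,  # 1-based leftmost protospacer base
        "strand": plant.strand,
        "distance": plant.distance,
        "pam_valid": plant.pam_valid,
        "site_seq": site_seq,
        "pam_seq": pam_seq,
    }


def _self_scan_clean(seq, model, spec, ledger) -> bool:
    expected = {
        (e["spacer"], e["start"], e["strand"])
        for e in ledger
        if e["pam_valid"] and e["distance"] <= spec.max_scan_m
    }
    for spacer in {p.spacer for p in spec.plants}:
        for start0, strand, mism, _, _ in naive_offtarget_scan(
            seq, spacer, model, spec.max_scan_m
        ):
            if (spacer, start0 + 1, strand) not in expected:
                return False
    return True


def naive_offtarget_scan(
    genome_seq: str, spacer: str, model: CbeModel, m: int
) -> list[tuple[int, str, int, str, str]]:
    """Naive full-window Hamming + PAM scan (vectorized); the generator's oracle.

    Returns ``(start0, strand, mismatches, site_seq, pam_seq)`` tuples with
    0-based plus-strand starts, sorted by position then strand.
    """
    g = np.frombuffer(genome_seq.upper().encode(), dtype=np.uint8)
    L, P = len(spacer), model.pam_len
    matcher = model.pam_matcher
    hits = []
    if len(g) < L:
        return hits
    windows = np.lib.stride_tricks.sliding_window_view(g, L)
    for strand in "+-":
        oriented = spacer if strand == "+" else reverse_complement(spacer)
        sp = np.frombuffer(oriented.encode(), dtype=np.uint8)
        mism = (windows != sp).sum(axis=1)
        pam_right = (strand == "+") == (model.pam_side == "3prime")
        for lo in np.nonzero(mism <= m)[0]:
            lo = int(lo)
            pam_lo, pam_hi = (lo + L, lo + L + P) if pam_right else (lo - P, lo)
            if pam_lo < 0 or pam_hi > len(g):
                continue
            pam_plus = genome_seq[pam_lo:pam_hi].upper()
            window = genome_seq[lo : lo + L].upper()
            if strand == "+":
                site_seq, pam_seq = window, pam_plus
            else:
                site_seq, pam_seq = reverse_complement(window), reverse_complement(pam_plus)
            if matcher.matches(pam_seq):
                hits.append((lo, strand, int(mism[lo]), site_seq, pam_seq))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def write_fixture(
    records: Sequence[NucSequence], ledger: list[dict], out_dir: str | Path, stem: str
) -> None:
    """Write a fixture as FASTA + JSON ledger side by side."""
    from cbei.seqcore import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(records, out / f"{stem}.fasta")
    (out / f"{stem}.ledger.json").write_text(json.dumps(ledger, indent=2))
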