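"""Batch design across a CDS set and per-editor inactivation ability.

The *inactivation ability* of an editor on a CDS set is the fraction of
CDSs carrying at least one qualifying site whose premature stop falls
within a given 5' search region ("top N% of the CDS body").  Restricting
the region pushes the stop toward the start of the gene, making a true
loss-of-function allele more likely; an editor whose ability curve rises
fastest toward the upper-left inactivates the most genes with the most
stringent truncation requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cbei.cbe_model import CbeModel, PRESETS
from cbei.cbei_design import DesignReport, find_cbei_sites, region_filter
from cbei.orf_finder import validate_cds
from cbei.seqcore import GeneticCode, NucSequence

__all__ = [
    "AbilityReport", "CdsSetSummary", "BatchResult",
    "run_batch", "cbei_ability", "ability_curve", "cds_set_stats",
    "plot_ability_curves", "DEFAULT_REGIONS",
]

logger = logging.getLogger(__name__)

DEFAULT_REGIONS: tuple[float, ...] = (25.0, 50.0, 75.0)

SITE_COLUMNS = [
    "cds_id", "cbe", "strand", "proto_start", "spacer", "pam", "window",
    "codon_index", "codon_before", "codon_after", "edit_positions",
    "context", "context_rank", "cds_fraction", "annotation",
]


@dataclass
class AbilityReport:
    """Per-editor inactivation ability over a grid of search regions."""

    cbe_name: str
    n_cds_total: int
    regions: list[float]  # percent
    n_available: list[int]
    ability: list[float]


@dataclass
class CdsSetSummary:
    """Length/GC statistics of a CDS set plus per-editor ability reports."""

    n_cds: int
    lengths: list[int]
    gc: list[float]
    ability_reports: list[AbilityReport]

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"length_nt": self.lengths, "gc": self.gc})

    def ability_frame(self) -> pd.DataFrame:
        rows = []
        for rep in self.ability_reports:
            for f, n, a in zip(rep.regions, rep.n_available, rep.ability):
                rows.append((rep.cbe_name, f, n, rep.n_cds_total, a))
        return pd.DataFrame(
            rows, columns=["cbe", "region_pct", "n_available", "n_cds_total", "ability"]
        )


@dataclass
class BatchResult:
    """Everything one batch run produces."""

    region_tables: dict[float, pd.DataFrame]  # region percent -> site table
    summary: CdsSetSummary
    reports: dict[tuple[str, str], DesignReport]  # (cds_id, cbe) -> whole-CDS report
    skipped: list[str] = field(default_factory=list)


def _site_rows(report: DesignReport, model: CbeModel) -> list[list]:
    rows = []
    for s in report.sites:
        rows.append([
            s.cds_id, s.cbe_name, s.strand, s.proto_start, s.spacer_seq, s.pam_seq,
            f"{model.window_start}-{model.window_end}", s.edited_codon_index,
            s.codon_before, s.codon_after,
            ",".join(map(str, s.edit_positions)), s.context,
            s.context_rank if s.context_rank is not None else 0,
            round(s.cds_fraction, 6), s.annotation,
        ])
    return rows


def run_batch(
    cds_set: Sequence[NucSequence],
    models: Sequence[CbeModel] | None,
    code: GeneticCode,
    regions: Iterable[float] = DEFAULT_REGIONS,
) -> BatchResult:
    """Design across a CDS set for many editors; one site table per region.

    ``models=None`` runs all built-in presets.  CDSs failing validation
    (bad frame, missing terminal stop, internal stop) are logged and kept:
    dropping them would silently change the ability denominator.
    Deterministic: identical inputs give identical tables.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    models = list(PRESETS.values()) if models is None else list(models)
    if not models:
        raise ValueError("empty model list")
    regions = sorted(float(r) for r in regions)

    skipped: list[str] = []
    for cds in cds_set:
        problems = validate_cds(cds, code)
        if problems:
            msg = f"{cds.id}: {'; '.join(problems)}"
            logger.warning(msg)
            skipped.append(msg)

    reports: dict[tuple[str, str], DesignReport] = {}
    for cds in cds_set:
        for model in models:
            reports[(cds.id, model.name)] = find_cbei_sites(
                cds, model, code, region_fraction=100.0
            )

    region_tables: dict[float, pd.DataFrame] = {}
    for f in regions:
        rows = []
        for cds in cds_set:
            for model in models:
                rows.extend(_site_rows(region_filter(reports[(cds.id, model.name)], f), model))
        region_tables[f] = pd.DataFrame(rows, columns=SITE_COLUMNS)

    ability_reports = []
    for model in models:
        per_cds = [
            [s.cds_fraction for s in reports[(cds.id, model.name)].sites]
            for cds in cds_set
        ]
        n_avail = [
            sum(1 for fr_list in per_cds if any(fr <= f / 100.0 for fr in fr_list))
            for f in regions
        ]
        ability_reports.append(
            AbilityReport(
                cbe_name=model.name,
                n_cds_total=len(cds_set),
                regions=list(regions),
                n_available=n_avail,
                ability=[n / len(cds_set) for n in n_avail],
            )
        )

    summary = cds_set_stats(cds_set)
    summary.ability_reports = ability_reports
    return BatchResult(
        region_tables=region_tables, summary=summary, reports=reports, skipped=skipped
    )


def cbei_ability(
    site_fractions_per_cds: Sequence[Sequence[float]],
    n_cds_total: int,
    fraction: float,
) -> float:
    """Fraction of CDSs with >= 1 site whose edited codon starts within the region.

    ``site_fractions_per_cds`` holds, per CDS, the cds_fraction of each of
    its sites (whole-CDS search).
    """
    if n_cds_total < 1:
        raise ValueError("n_cds_total must be >= 1")
    limit = fraction / 100.0
    n = sum(1 for fr_list in site_fractions_per_cds if any(f <= limit for f in fr_list))
    return n / n_cds_total


def ability_curve(
    site_fractions_per_cds: Sequence[Sequence[float]],
    n_cds_total: int,
    grid: Sequence[float] = tuple(range(1, 101)),
) -> pd.DataFrame:
    """Ability as a step function of the search-region percentage."""
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    # min site fraction per CDS decides the smallest region that counts it
    mins = sorted(min(fr) for fr in site_fractions_per_cds if fr)
    mins_arr = np.asarray(mins)
    abilities = [
        float(np.searchsorted(mins_arr, f / 100.0, side="right")) / n_cds_total
        for f in grid
    ]
    return pd.DataFrame({"region_pct": grid, "ability": abilities})


def cds_set_stats(cds_set: Sequence[NucSequence]) -> CdsSetSummary:
    """Per-CDS length and GC fraction with empirical CDFs available as tables."""
    if not cds_set:
        raise ValueError("empty CDS set")
    lengths = [len(c.seq) for c in cds_set]
    gc = [
        (c.seq.count("G") + c.seq.count("C")) / len(c.seq) for c in cds_set
    ]
    return CdsSetSummary(n_cds=len(cds_set), lengths=lengths, gc=gc, ability_reports=[])


def ecdf_table(values: Sequence[float]) -> pd.DataFrame:
    """Empirical CDF of a sample as (value, cumulative fraction) rows."""
    x = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"value": x, "ecdf": np.arange(1, len(x) + 1) / len(x)})


def plot_ability_curves(result: BatchResult, path: str, grid=tuple(range(1, 101))) -> None:
    """Plot per-editor ability curves to an image file (headless backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    by_cbe: dict[str, list[list[float]]] = {}
    for (cds_id, cbe), rep in result.reports.items():
        by_cbe.setdefault(cbe, []).append([s.cds_fraction for s in rep.sites])
    n_total = result.summary.n_cds
    for cbe, per_cds in by_cbe.items():
        curve = ability_curve(per_cds, n_total, grid)
        ax.step(curve["region_pct"], curve["ability"], where="post", label=cbe)
    ax.set_xlabel("search region (% of CDS body)")
    ax.set_ylabel("inactivation ability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
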