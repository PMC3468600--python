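"""Chromosome-level and locus-level genomic parameters.

Windowed neighbor-gene counts (with the one-sided edge rule for loci at
chromosome ends), gene-density / GC correlations over autosomes, structure
length medians, head-to-head divergent pair detection, and annotation of
binding sites (50 kb of a TSS, one highest-signal site per locus) and of
methylation probes (2 kb of the nearest TSS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneLocus
from .utils import circular_phase_distance

__all__ = [
    "BindingSite",
    "MethylationProbe",
    "LocusIndex",
    "count_neighbors",
    "neighbor_profile",
    "chromosome_stats",
    "correlate_group_gc",
    "length_statistics",
    "find_divergent_pairs",
    "annotate_sites_to_tss",
    "annotate_methylation_probes",
    "DEFAULT_WINDOW_GRID",
]

DEFAULT_WINDOW_GRID = tuple(range(0, 1_500_001, 15_000))  # 0-1.5 Mb step 15 kb
SITE_TSS_MAX_DISTANCE = 50_000
METHYLATION_TSS_MAX_DISTANCE = 2_000
TOP_SITE_BINS = (10, 20, 50, 100, 200, 500, None)  # None = all retained sites


@dataclass
class BindingSite:
    site_id: str
    chromosome: str
    position: int
    signals: tuple[float, ...]
    annotated_locus: str | None = None
    distance_to_tss: int | None = None

    @property
    def mean_signal(self) -> float:
        return float(np.mean(self.signals))


@dataclass
class MethylationProbe:
    probe_id: str
    chromosome: str
    center: int
    m_value: float
    cpg_class: str
    annotated_locus: str | None = None


class LocusIndex:
    """Per-chromosome sorted interval/TSS index over an annotation."""

    def __init__(self, annotation: Sequence[GeneLocus]) -> None:
        self.loci = {l.locus_id: l for l in annotation}
        if len(self.loci) != len(annotation):
            raise ValueError("duplicate locus ids in annotation")
        self.by_chrom: dict[str, list[GeneLocus]] = {}
        for l in annotation:
            self.by_chrom.setdefault(l.chromosome, []).append(l)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._tss: dict[str, np.ndarray] = {}
        self._tss_ids: dict[str, list[str]] = {}
        for chrom, loci in self.by_chrom.items():
            loci.sort(key=lambda l: (l.start, l.end, l.locus_id))
            self._starts[chrom] = np.sort(np.array([l.start for l in loci]))
            self._ends[chrom] = np.sort(np.array([l.end for l in loci]))
            order = sorted(loci, key=lambda l: (l.tss, l.locus_id))
            self._tss[chrom] = np.array([l.tss for l in order])
            self._tss_ids[chrom] = [l.locus_id for l in order]

    def extended_interval(self, locus: GeneLocus, window: float) -> tuple[float, float]:
        """The neighbor-search interval for a locus at a given window size.

        Interior loci extend half a window on both sides; the first (last)
        locus of a chromosome extends a full window on its inner side only.
        """
        loci = self.by_chrom[locus.chromosome]
        first = loci[0].locus_id == locus.locus_id
        last = loci[-1].locus_id == locus.locus_id
        if first and last:
            return float(locus.start), float(locus.end)
        if first:
            return float(locus.start), float(locus.end + window)
        if last:
            return max(0.0, locus.start - window), float(locus.end)
        return max(0.0, locus.start - window / 2.0), float(locus.end + window / 2.0)

    def count_overlapping(self, chrom: str, lo: float, hi: float) -> int:
        """Loci overlapping [lo, hi) by at least one base."""
        if chrom not in self._starts:
            return 0
        n_start = np.searchsorted(self._starts[chrom], hi, side="left")
        n_gone = np.searchsorted(self._ends[chrom], lo, side="right")
        return int(n_start - n_gone)

    def nearest_tss(self, chrom: str, position: int) -> tuple[str, int] | None:
        """(locus_id, signed distance position - tss) of the nearest TSS."""
        if chrom not in self._tss or self._tss[chrom].size == 0:
            return None
        tss = self._tss[chrom]
        i = np.searchsorted(tss, position)
        best = None
        for j in (i - 1, i):
            if 0 <= j < tss.size:
                d = position - int(tss[j])
                if best is None or abs(d) < abs(best[1]):
                    best = (self._tss_ids[chrom][j], d)
        return best


def count_neighbors(
    annotation: Sequence[GeneLocus] | LocusIndex,
    locus: GeneLocus | str,
    window: float,
) -> int:
    """Number of other loci (any strand) overlapping the extended interval."""
    if window < 0:
        raise ValueError("window must be >= 0")
    index = annotation if isinstance(annotation, LocusIndex) else LocusIndex(annotation)
    if isinstance(locus, str):
        locus_id = locus
    else:
        locus_id = locus.locus_id
    if locus_id not in index.loci:
        raise ValueError(f"locus {locus_id!r} not in annotation")
    locus = index.loci[locus_id]
    lo, hi = index.extended_interval(locus, window)
    return index.count_overlapping(locus.chromosome, lo, hi) - 1  # minus itself


def neighbor_profile(
    annotation: Sequence[GeneLocus] | LocusIndex,
    group: Iterable[str],
    windows: Sequence[float] = DEFAULT_WINDOW_GRID,
) -> pd.Series:
    """Mean neighbor count over a gene group at each window size."""
    index = annotation if isinstance(annotation, LocusIndex) else LocusIndex(annotation)
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    counts = np.zeros((len(group), len(windows)))
    for i, locus_id in enumerate(group):
        locus = index.loci[locus_id]
        for j, w in enumerate(windows):
            lo, hi = index.extended_interval(locus, w)
            counts[i, j] = index.count_overlapping(locus.chromosome, lo, hi) - 1
    return pd.Series(counts.mean(axis=0), index=list(windows), name="mean_neighbors")


def chromosome_stats(
    annotation: Sequence[GeneLocus],
    chrom_lengths: Mapping[str, int],
    chrom_gc: Mapping[str, float],
    groups: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-chromosome gene counts, density (genes/Mb), GC and group percentages.

    ``group_percent`` is the share of genes on the chromosome belonging to the
    group, in percent of all genes there.
    """
    rows = {}
    for chrom in chrom_lengths:
        loci_here = [l for l in annotation if l.chromosome == chrom]
        row = {
            "gc_percent": float(chrom_gc[chrom]),
            "length": int(chrom_lengths[chrom]),
            "gene_count": len(loci_here),
            "density": len(loci_here) / (chrom_lengths[chrom] / 1e6),
        }
        if groups:
            ids_here = {l.locus_id for l in loci_here}
            for name, members in groups.items():
                n = len(ids_here & set(members))
                row[f"pct_{name}"] = 100.0 * n / len(loci_here) if loci_here else 0.0
        rows[chrom] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def correlate_group_gc(gc_percent: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    """Pearson R and two-sided t-test P over autosomes."""
    x = np.asarray(gc_percent, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired chromosome values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def length_statistics(group: Sequence[GeneLocus]) -> dict[str, float]:
    """Median genomic / 5'-UTR / 3'-UTR / CDS lengths over a gene group.

    Loci lacking a structure are excluded from that structure's median.
    """
    if not group:
        raise ValueError("group must be non-empty")
    out = {"genomic": float(np.median([l.genomic_length for l in group]))}
    for name in ("utr5", "utr3", "cds"):
        vals = [getattr(l, f"{name}_length") for l in group]
        vals = [v for v in vals if v is not None and v > 0]
        out[name] = float(np.median(vals)) if vals else float("nan")
    return out


def find_divergent_pairs(
    annotation: Sequence[GeneLocus],
    phases: Mapping[str, float],
    max_tss_gap: int = 1_000,
    max_phase_diff: float = 6.0,
) -> list[tuple[str, str]]:
    """Head-to-head rhythmic pairs with a small TSS gap and close phases.

    A pair is a minus-strand locus transcribing leftward whose TSS lies at
    most ``max_tss_gap`` bases upstream (left) of a plus-strand locus's TSS,
    both rhythmic, circular phase distance <= ``max_phase_diff`` h.  Pairs are
    emitted once, ordered by coordinate (minus-strand partner first).
    """
    pairs = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in annotation:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom, loci in sorted(by_chrom.items()):
        minus = sorted((l for l in loci if l.strand == "-"), key=lambda l: l.tss)
        plus = sorted((l for l in loci if l.strand == "+"), key=lambda l: l.tss)
        plus_tss = np.array([l.tss for l in plus])
        for m in minus:
            if m.locus_id not in phases:
                continue
            lo = np.searchsorted(plus_tss, m.tss, side="left")
            hi = np.searchsorted(plus_tss, m.tss + max_tss_gap, side="right")
            for p in plus[lo:hi]:
                if p.locus_id not in phases:
                    continue
                if circular_phase_distance(phases[m.locus_id], phases[p.locus_id]) <= max_phase_diff:
                    pairs.append((m.locus_id, p.locus_id))
    pairs.sort()
    return pairs


def annotate_sites_to_tss(
    sites: Sequence[BindingSite],
    annotation: Sequence[GeneLocus] | LocusIndex,
    max_distance: int = SITE_TSS_MAX_DISTANCE,
    groups: Mapping[str, Iterable[str]] | None = None,
    top_ns: Sequence[int | None] = TOP_SITE_BINS,
) -> tuple[list[BindingSite], pd.DataFrame | None]:
    """Assign sites to their nearest TSS and rank them by mean signal.

    A site is kept iff its nearest TSS is within ``max_distance``; per locus
    only the highest-mean-signal site survives.  With ``groups`` given, the
    percentage of top-N sites whose locus belongs to each group is tabulated
    for every N in ``top_ns`` (None = all retained sites).
    """
    index = annotation if isinstance(annotation, LocusIndex) else LocusIndex(annotation)
    annotated: list[BindingSite] = []
    for site in sites:
        hit = index.nearest_tss(site.chromosome, site.position)
        if hit is None:
            warnings.warn(
                f"site {site.site_id} on chromosome {site.chromosome} absent from annotation"
            )
            continue
        locus_id, dist = hit
        if abs(dist) <= max_distance:
            site.annotated_locus = locus_id
            site.distance_to_tss = dist
            annotated.append(site)
    best_per_locus: dict[str, BindingSite] = {}
    for site in annotated:
        cur = best_per_locus.get(site.annotated_locus)
        if cur is None or (site.mean_signal, site.site_id) > (cur.mean_signal, cur.site_id):
            best_per_locus[site.annotated_locus] = site
    retained = sorted(
        best_per_locus.values(), key=lambda s: (-s.mean_signal, s.site_id)
    )
    table = None
    if groups is not None:
        rows = {}
        for n in top_ns:
            top = retained if n is None else retained[:n]
            label = "all" if n is None else str(n)
            if not top:
                rows[label] = {name: 0.0 for name in groups}
                continue
            rows[label] = {
                name: 100.0 * sum(s.annotated_locus in set(members) for s in top) / len(top)
                for name, members in groups.items()
            }
        table = pd.DataFrame.from_dict(rows, orient="index")
    return retained, table


def annotate_methylation_probes(
    probes: Sequence[MethylationProbe],
    annotation: Sequence[GeneLocus] | LocusIndex,
    max_distance: int = METHYLATION_TSS_MAX_DISTANCE,
    groups: Mapping[str, Iterable[str]] | None = None,
) -> tuple[list[MethylationProbe], dict[tuple[str, str], np.ndarray]]:
    """Annotate probes within 2 kb of their nearest TSS.

    Returns the annotated probes (several per locus allowed; no per-locus
    reduction) and, when gene groups are supplied, M-value vectors keyed by
    (group, cpg_class) for rank-sum comparisons.
    """
    index = annotation if isinstance(annotation, LocusIndex) else LocusIndex(annotation)
    annotated = []
    for probe in probes:
        hit = index.nearest_tss(probe.chromosome, probe.center)
        if hit is None:
            continue
        locus_id, dist = hit
        if abs(dist) <= max_distance:
            probe.annotated_locus = locus_id
            annotated.append(probe)
    vectors: dict[tuple[str, str], np.ndarray] = {}
    if groups is not None:
        for name, members in groups.items():
            members = set(members)
            for cls in sorted({p.cpg_class for p in annotated}):
                vals = [
                    p.m_value
                    for p in annotated
                    if p.cpg_class == cls and p.annotated_locus in members
                ]
                vectors[(name, cls)] = np.asarray(vals)
    return annotated, vectors
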