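"""Locus construction and circadian / non-circadian gene-set partitioning.

Transcript features are clustered into loci (shared splice site for
multi-exon features, overlap for single-exon ones, transitive closure), each
locus keeps a representative transcript (most exons, then longest) whose
structure feeds the length statistics.  Rhythmic probes are reduced to one
representative per locus under a period/phase consistency filter, the
expressed/non-expressed cutoff is estimated from the bimodal log10 expression
density, and loci are partitioned into LCG / LNLCG / LNCG and friends.

Coordinates are 0-based half-open throughout; GFF3 conversion happens at the
I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .rhythm import RhythmCall, TimeCourseMatrix
from .utils import circular_phase_distance

__all__ = [
    "TranscriptFeature",
    "GeneLocus",
    "GeneSetPartition",
    "RepresentativeSelection",
    "cluster_features_to_loci",
    "select_representative_probe",
    "estimate_expression_cutoff",
    "partition_gene_sets",
    "estimate_false_positive_rate",
]

DEFAULT_CUTOFF = 1.45  # log10 intensity separating expressed from background


@dataclass
class TranscriptFeature:
    transcript_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    cds: tuple[int, int] | None = None  # genomic span of the coding region

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ex = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if any(s >= e for s, e in ex):
            raise ValueError(f"{self.transcript_id}: empty exon")
        self.exons = ex

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def splice_sites(self) -> set[tuple[str, int]]:
        """Internal exon boundaries as (kind, position): donor-side exon ends
        and acceptor-side exon starts, excluding the transcript's outer ends."""
        sites: set[tuple[str, int]] = set()
        for i, (s, e) in enumerate(self.exons):
            if i > 0:
                sites.add(("a", s))
            if i < len(self.exons) - 1:
                sites.add(("d", e))
        return sites

    def _exonic_length_between(self, lo: int, hi: int) -> int:
        return sum(max(0, min(e, hi) - max(s, lo)) for s, e in self.exons)

    @property
    def cds_length(self) -> int | None:
        if self.cds is None:
            return None
        return self._exonic_length_between(*self.cds)

    @property
    def utr5_length(self) -> int | None:
        if self.cds is None:
            return None
        if self.strand == "+":
            return self._exonic_length_between(self.start, self.cds[0])
        return self._exonic_length_between(self.cds[1], self.end)

    @property
    def utr3_length(self) -> int | None:
        if self.cds is None:
            return None
        if self.strand == "+":
            return self._exonic_length_between(self.cds[1], self.end)
        return self._exonic_length_between(self.start, self.cds[0])


@dataclass
class GeneLocus:
    locus_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    cds_length: int | None = None
    utr5_length: int | None = None
    utr3_length: int | None = None
    representative_transcript: str | None = None
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.locus_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def genomic_length(self) -> int:
        return self.end - self.start


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_features_to_loci(features: Sequence[TranscriptFeature]) -> list[GeneLocus]:
    """Group transcript features into loci by transitive closure.

    Multi-exon features on the same chromosome and strand join when they share
    at least one identical splice site; a single-exon feature joins any
    same-strand feature whose span it overlaps.  The representative transcript
    has the most exons, ties broken by transcript length, then by id.
    """
    uf = _UnionFind(len(features))
    by_site: dict[tuple, list[int]] = {}
    for i, f in enumerate(features):
        if f.n_exons > 1:
            for site in f.splice_sites:
                by_site.setdefault((f.chromosome, f.strand) + site, []).append(i)
    for members in by_site.values():
        for j in members[1:]:
            uf.union(members[0], j)

    by_group: dict[tuple[str, str], list[int]] = {}
    for i, f in enumerate(features):
        by_group.setdefault((f.chromosome, f.strand), []).append(i)
    for idxs in by_group.values():
        idxs = sorted(idxs, key=lambda i: (features[i].start, features[i].end))
        active: list[int] = []
        for i in idxs:
            f = features[i]
            active = [j for j in active if features[j].end > f.start]
            if f.n_exons == 1:
                for j in active:
                    uf.union(i, j)
            else:
                for j in active:
                    if features[j].n_exons == 1:
                        uf.union(i, j)
            active.append(i)

    clusters: dict[int, list[int]] = {}
    for i in range(len(features)):
        clusters.setdefault(uf.find(i), []).append(i)

    loci = []
    for idxs in clusters.values():
        members = [features[i] for i in idxs]
        rep = max(
            members,
            key=lambda f: (f.n_exons, f.transcript_length, f.transcript_id),
        )
        loci.append(
            GeneLocus(
                locus_id=f"locus_{rep.transcript_id}",
                chromosome=rep.chromosome,
                strand=rep.strand,
                start=rep.start,
                end=rep.end,
                cds_length=rep.cds_length,
                utr5_length=rep.utr5_length,
                utr3_length=rep.utr3_length,
                representative_transcript=rep.transcript_id,
                members=tuple(sorted(f.transcript_id for f in members)),
            )
        )
    loci.sort(key=lambda l: (l.chromosome, l.start, l.locus_id))
    return loci


@dataclass
class RepresentativeSelection:
    call: RhythmCall | None
    excluded: bool
    reason: str | None = None
    n_rhythmic: int = 0
    n_failing: int = 0


def select_representative_probe(
    locus_probes: Sequence[RhythmCall],
    period_tol: float = 4.0,
    phase_tol: float = 6.0,
) -> RepresentativeSelection:
    """Pick one rhythmic probe per locus under the period/phase consistency rule.

    The lowest-q probe represents the locus; every other rhythmic probe must
    agree with it within ``period_tol`` hours of period and ``phase_tol``
    hours of circular phase distance (phases compared on the 24-h scale after
    period normalization).  If the failing probes outnumber half of the
    locus's rhythmic probes the locus is excluded from the circadian list.
    """
    probes = list(locus_probes)
    if not probes:
        return RepresentativeSelection(None, excluded=True, reason="no rhythmic probes")
    rep = min(probes, key=lambda c: (c.p_value if np.isnan(c.q_value) else c.q_value, c.row_id))
    rep_ct = (rep.phase % rep.period) * 24.0 / rep.period
    n_fail = 0
    for c in probes:
        if c is rep:
            continue
        ct = (c.phase % c.period) * 24.0 / c.period
        if abs(c.period - rep.period) > period_tol or circular_phase_distance(ct, rep_ct) > phase_tol:
            n_fail += 1
    excluded = 2 * n_fail > len(probes)
    return RepresentativeSelection(
        call=None if excluded else rep,
        excluded=excluded,
        reason="inconsistent period/phase across probes" if excluded else None,
        n_rhythmic=len(probes),
        n_failing=n_fail,
    )


def estimate_expression_cutoff(
    values: Iterable[float], grid_size: int = 1024
) -> float:
    """Midpoint between the non-expressed and expressed density peaks.

    A Gaussian-kernel density estimate of the log10 expression values must be
    bimodal; the cutoff is the midpoint of the two highest local maxima.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 100:
        raise ValueError(f"need at least 100 values for the density estimate, got {v.size}")
    kde = gaussian_kde(v)
    pad = 0.05 * (v.max() - v.min() + 1e-9)
    grid = np.linspace(v.min() - pad, v.max() + pad, grid_size)
    dens = kde(grid)
    # prominence floor suppresses sampling wiggles of the density estimate
    peaks, _ = find_peaks(dens, prominence=0.05 * dens.max())
    if peaks.size < 2:
        raise ValueError("no bimodal separation in the expression density")
    top_two = peaks[np.argsort(dens[peaks])[::-1][:2]]
    return float(grid[top_two].mean())


LABELS = ("LCG", "LNLCG", "LNCG", "NLCG-unexpressed", "AL-only", "unexpressed")


@dataclass
class GeneSetPartition:
    labels: dict[str, str]
    cutoff: float

    def members(self, label: str) -> set[str]:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return {g for g, l in self.labels.items() if l == label}

    @property
    def lcg(self) -> set[str]:
        return self.members("LCG")

    @property
    def lnlcg(self) -> set[str]:
        return self.members("LNLCG")

    @property
    def lncg(self) -> set[str]:
        return self.members("LNCG")

    @property
    def nlcg(self) -> set[str]:
        """All general-list circadian loci not rhythmic in this tissue."""
        return self.members("LNLCG") | self.members("NLCG-unexpressed")

    @property
    def al(self) -> set[str]:
        """All expressed loci."""
        return self.lcg | self.lnlcg | self.lncg | self.members("AL-only")


def partition_gene_sets(
    circadian: Iterable[str],
    expression: TimeCourseMatrix,
    general_circadian_list: Iterable[str],
    cutoff: float = DEFAULT_CUTOFF,
    ambiguous: Iterable[str] = (),
) -> GeneSetPartition:
    """Label every locus of the expression universe.

    ``circadian`` are the final per-locus circadian calls; ``ambiguous`` are
    loci dropped by the probe-consistency filter (kept out of both the
    circadian list and the LNCG control).  Expressed means the maximum
    expression over timepoints exceeds the cutoff.
    """
    circ = set(circadian)
    amb = set(ambiguous) - circ
    general = set(general_circadian_list)
    universe = set(expression.row_ids)
    missing = (circ | amb) - universe
    if missing:
        raise ValueError(f"loci absent from the expression matrix: {sorted(missing)[:5]}")
    expressed_mask = expression.values.max(axis=1) > cutoff
    labels: dict[str, str] = {}
    for locus, expressed in zip(expression.row_ids, expressed_mask):
        if locus in circ:
            labels[locus] = "LCG" if expressed else "unexpressed"
        elif locus in general:
            labels[locus] = "LNLCG" if expressed else "NLCG-unexpressed"
        elif locus in amb:
            labels[locus] = "AL-only" if expressed else "unexpressed"
        else:
            labels[locus] = "LNCG" if expressed else "unexpressed"
    return GeneSetPartition(labels=labels, cutoff=float(cutoff))


def estimate_false_positive_rate(
    gene_set: Iterable[str], control_list: Iterable[str]
) -> float:
    """Percentage of control genes falling in the set, one decimal place."""
    controls = set(control_list)
    if not controls:
        raise ValueError("control list must be non-empty")
    hits = len(set(gene_set) & controls)
    return round(100.0 * hits / len(controls), 1)
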