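"""Ground-truth synthetic data for the whole pipeline.

Everything the analysis consumes can be generated here with a known truth
table: a stranded genome annotation with exon/CDS/UTR structure and planted
head-to-head pairs, a probe-level temporal expression matrix with planted
rhythmic loci (cosine and non-cosine waveforms, phases concentrated in four
temporal windows), a multi-tissue matrix with planted expression breadths,
and the auxiliary tables (TSS-proximal binding sites, methylation probes,
mRNA half-lives, miRNA/3'-UTR sequences with planted seed sites, and a
gene -> term annotation with planted phase-specific terms).

The planted rhythmic-locus count is exact (floor(fraction * n_loci)), so
sensitivity and false-discovery proportions downstream are exact set
comparisons, not estimates against a random draw.  A fixed seed makes every
emitted file byte-identical across runs (generator algorithm version 1; any
change to the draw order is a breaking change to that contract).

The rhythmic signal model for a locus with baseline m (log10), planted
peak-to-trough ratio A, period tau, phase phi and waveform w is

    y(t) = m + (log10(A) / 2) * w((t - phi) / tau) + eps,   eps ~ N(0, sd)

with w ranging over [-1, 1] and peaking at its phase, so the planted ratio
is exactly the ratio of peak to trough linear intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import waveforms
from .config import SimulationConfig
from .expression import HalfLifeRecord, TissueMatrix
from .genesets import GeneLocus
from .genome import BindingSite, MethylationProbe
from .rhythm import TimeCourseMatrix

__all__ = [
    "TruthRecord",
    "GenomeAnnotation",
    "SyntheticAux",
    "SyntheticDataset",
    "generate_annotation",
    "generate_timecourse",
    "generate_tissue_matrix",
    "generate_aux_tables",
    "generate_dataset",
]

GENERATOR_VERSION = 1

_WINDOW_SPANS = {
    "dawn": (22.0, 26.0),  # wraps through midnight
    "day": (2.0, 10.0),
    "dusk": (10.0, 14.0),
    "night": (14.0, 22.0),
}

_MIN_EXON = 30
_MIN_INTRON = 60


@dataclass
class TruthRecord:
    locus_id: str
    is_rhythmic: bool
    waveform: str | None = None
    period: float | None = None
    phase: float | None = None  # CT hours in [0, 24)
    relative_amplitude: float | None = None
    baseline: float = 0.0
    planted_window: str = "none"
    expressed: bool = True
    in_general_list: bool = False


@dataclass
class GenomeAnnotation:
    loci: list[GeneLocus]
    chrom_lengths: dict[str, int]
    chrom_gc: dict[str, float]
    exons: dict[str, list[tuple[int, int]]]
    cds_spans: dict[str, tuple[int, int] | None]
    divergent_pairs: list[tuple[str, str]]

    def locus(self, locus_id: str) -> GeneLocus:
        if not hasattr(self, "_by_id"):
            self._by_id = {l.locus_id: l for l in self.loci}
        return self._by_id[locus_id]


@dataclass
class SyntheticAux:
    binding_sites: list[BindingSite]
    site_truth: dict[str, str | None]  # site_id -> intended locus (None = decoy)
    methylation_probes: list[MethylationProbe]
    halflife_records: list[HalfLifeRecord]
    mirnas: dict[str, str]  # RNA alphabet, 5'->3'
    utr_sequences: dict[str, str]  # DNA alphabet, sense strand
    seed_site_truth: dict[tuple[str, str], int]  # (locus, mirna) -> planted count
    gene_terms: dict[str, list[str]]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: list[TruthRecord]
    timecourse: TimeCourseMatrix  # probe-level
    probe_map: dict[str, str]  # probe_id -> locus_id
    tissue: TissueMatrix
    planted_breadth: dict[str, int]
    aux: SyntheticAux
    general_circadian_list: set[str]
    negative_controls: list[str]
    positive_controls: list[str]

    @property
    def truth_by_id(self) -> dict[str, TruthRecord]:
        return {t.locus_id: t for t in self.truth}


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Deterministically apportion ``total`` items proportionally to weights."""
    ideal = weights / weights.sum() * total
    counts = np.floor(ideal).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _split_lengths(
    rng: np.random.Generator, total: int, parts: int, minimum: int
) -> list[int]:
    if parts * minimum > total:
        parts = max(1, total // minimum)
    extra = total - parts * minimum
    if parts == 1:
        return [total]
    cuts = rng.multinomial(extra, np.full(parts, 1.0 / parts))
    return [minimum + int(c) for c in cuts]


def _build_gene_structure(
    rng: np.random.Generator, start: int, strand: str
) -> dict:
    """Draw UTR/CDS/intron lengths and lay out an exon chain from ``start``."""
    utr5 = max(20, int(rng.lognormal(math.log(150), 0.6)))
    cds = max(150, int(rng.lognormal(math.log(1300), 0.6)))
    utr3 = max(50, int(rng.lognormal(math.log(800), 0.8)))
    transcript_len = utr5 + cds + utr3
    n_exons = 1 + int(rng.poisson(6.0))
    exon_lens = _split_lengths(rng, transcript_len, n_exons, _MIN_EXON)
    n_exons = len(exon_lens)
    if n_exons > 1:
        intron_total = max(
            (n_exons - 1) * _MIN_INTRON, int(rng.lognormal(math.log(20_000), 0.9))
        )
        intron_lens = _split_lengths(rng, intron_total, n_exons - 1, _MIN_INTRON)
    else:
        intron_lens = []
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    end = exons[-1][1]
    # CDS span: exonic offsets are counted in genomic (plus-strand) order, so
    # on the minus strand the 3'-UTR occupies the left end of the chain.
    lo_off = utr5 if strand == "+" else utr3
    cds_span = (
        _exonic_offset_to_genomic(exons, lo_off),
        _exonic_offset_to_genomic(exons, lo_off + cds),
    )
    return {
        "exons": exons,
        "end": end,
        "cds_span": cds_span,
        "utr5": utr5,
        "cds": cds,
        "utr3": utr3,
    }


def _exonic_offset_to_genomic(exons: list[tuple[int, int]], offset: int) -> int:
    walked = 0
    for s, e in exons:
        if offset <= walked + (e - s):
            return s + (offset - walked)
        walked += e - s
    raise ValueError("offset beyond transcript length")


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Stranded loci with exon structure, planted head-to-head pairs, and a
    GC gradient across chromosomes (denser chromosomes are GC-richer)."""
    rng = _child_rngs(config.seed, 8)[0]
    n_chrom = config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    if n_chrom > 1:
        gc = np.linspace(37.0, 52.0, n_chrom)
    else:
        gc = np.array([42.0])
    weights = gc - 30.0
    counts = _largest_remainder(weights, config.n_loci)
    n_pairs_total = int(config.divergent_fraction * config.n_loci / 2)
    pair_counts = _largest_remainder(np.maximum(counts, 1).astype(float), n_pairs_total)
    pair_counts = np.minimum(pair_counts, counts // 2)
    missing = n_pairs_total - pair_counts.sum()
    for i in np.argsort(-(counts - 2 * pair_counts), kind="stable"):
        if missing <= 0:
            break
        room = counts[i] // 2 - pair_counts[i]
        take = min(room, missing)
        pair_counts[i] += take
        missing -= take

    loci: list[GeneLocus] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    cds_spans: dict[str, tuple[int, int] | None] = {}
    chrom_lengths: dict[str, int] = {}
    divergent_pairs: list[tuple[str, str]] = []
    locus_no = 0

    for ci, chrom in enumerate(chrom_names):
        pos = 10_000
        # GC-rich chromosomes are gene-denser: shorter intergenic gaps
        gap_mean = 2_000.0 + 2_500.0 * max(2.0, 54.0 - gc[ci])
        n_here = int(counts[ci])
        pairs_left = int(pair_counts[ci])
        i = 0
        while i < n_here:
            make_pair = pairs_left > 0 and i + 1 < n_here
            if make_pair:
                pairs_left -= 1
                # minus-strand partner first (transcribing leftward) ...
                left = _build_gene_structure(rng, pos, "-")
                left_id = f"L{locus_no:05d}"
                locus_no += 1
                gap = int(rng.integers(100, 901))
                right_start = left["end"] - 1 + gap
                right = _build_gene_structure(rng, right_start, "+")
                right_id = f"L{locus_no:05d}"
                locus_no += 1
                for lid, s, info in ((left_id, "-", left), (right_id, "+", right)):
                    loci.append(
                        GeneLocus(
                            locus_id=lid,
                            chromosome=chrom,
                            strand=s,
                            start=info["exons"][0][0],
                            end=info["end"],
                            cds_length=info["cds"],
                            utr5_length=info["utr5"],
                            utr3_length=info["utr3"],
                            representative_transcript=f"{lid}.1",
                        )
                    )
                    exons[lid] = info["exons"]
                    cds_spans[lid] = info["cds_span"]
                divergent_pairs.append((left_id, right_id))
                pos = right["end"] + 2_000 + int(rng.exponential(gap_mean))
                i += 2
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                info = _build_gene_structure(rng, pos, strand)
                lid = f"L{locus_no:05d}"
                locus_no += 1
                loci.append(
                    GeneLocus(
                        locus_id=lid,
                        chromosome=chrom,
                        strand=strand,
                        start=info["exons"][0][0],
                        end=info["end"],
                        cds_length=info["cds"],
                        utr5_length=info["utr5"],
                        utr3_length=info["utr3"],
                        representative_transcript=f"{lid}.1",
                    )
                )
                exons[lid] = info["exons"]
                cds_spans[lid] = info["cds_span"]
                pos = info["end"] + 2_000 + int(rng.exponential(gap_mean))
                i += 1
        chrom_lengths[chrom] = pos + 10_000

    return GenomeAnnotation(
        loci=loci,
        chrom_lengths=chrom_lengths,
        chrom_gc=dict(zip(chrom_names, (float(g) for g in gc))),
        exons=exons,
        cds_spans=cds_spans,
        divergent_pairs=divergent_pairs,
    )


_WINDOW_CENTERS = {"dawn": 24.0, "day": 6.5, "dusk": 12.0, "night": 15.5}
_PHASE_SD = 1.3  # hours; phases concentrate near the window centers


def _draw_phase(rng: np.random.Generator, window: str) -> float:
    lo, hi = _WINDOW_SPANS[window]
    raw = rng.normal(_WINDOW_CENTERS[window], _PHASE_SD)
    return float(np.clip(raw, lo + 0.05, hi - 0.05) % 24.0)


def _window_of_ct(ct: float) -> str:
    for window, (lo, hi) in _WINDOW_SPANS.items():
        if lo <= ct < hi or lo <= ct + 24.0 < hi:
            return window
    raise AssertionError("unreachable: windows cover [0, 24)")


def generate_timecourse(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[TimeCourseMatrix, dict[str, str], list[TruthRecord]]:
    """Probe-level temporal matrix plus the exact ground-truth table.

    Exactly floor(rhythmic_fraction * n_loci) loci are rhythmic, preferring
    AT-rich chromosomes; rhythmic loci are always expressed.  Each locus
    carries 1..k probe rows sharing the truth with independent noise.
    """
    rng = _child_rngs(config.seed, 8)[1]
    loci = annotation.loci
    n = len(loci)
    times = np.arange(config.n_timepoints) * config.sampling_interval

    n_rhythmic = int(config.rhythmic_fraction * n)
    gc = np.array([annotation.chrom_gc[l.chromosome] for l in loci])
    at_weight = np.maximum(56.0 - gc, 1.0)
    rhythmic_idx = (
        rng.choice(n, size=n_rhythmic, replace=False, p=at_weight / at_weight.sum())
        if n_rhythmic
        else np.array([], dtype=int)
    )
    is_rhythmic = np.zeros(n, dtype=bool)
    is_rhythmic[rhythmic_idx] = True

    # head-to-head partners share a bidirectional promoter: complete half of
    # the singly-rhythmic pairs by transferring rhythmicity from an unpaired
    # locus, keeping the planted total exact
    idx_of = {l.locus_id: i for i, l in enumerate(loci)}
    paired = {idx_of[x] for pair in annotation.divergent_pairs for x in pair}
    donor_pool = [i for i in np.flatnonzero(is_rhythmic) if i not in paired]
    partner_of: dict[int, int] = {}
    for a, b in annotation.divergent_pairs:
        ia, ib = idx_of[a], idx_of[b]
        partner_of[ia], partner_of[ib] = ib, ia
        if bool(is_rhythmic[ia]) != bool(is_rhythmic[ib]) and donor_pool and rng.random() < 0.5:
            off = ib if is_rhythmic[ia] else ia
            donor = donor_pool.pop(int(rng.integers(len(donor_pool))))
            is_rhythmic[donor] = False
            is_rhythmic[off] = True

    n_expressed = max(n_rhythmic, int(config.expressed_fraction * n))
    expressed = is_rhythmic.copy()
    silent_pool = np.flatnonzero(~is_rhythmic)
    extra = n_expressed - n_rhythmic
    if extra > 0 and silent_pool.size:
        expressed[rng.choice(silent_pool, size=min(extra, silent_pool.size), replace=False)] = True

    mode_lo, mode_hi = config.baseline_log10_modes
    windows = list(config.phase_window_weights)
    window_p = np.array([config.phase_window_weights[w] for w in windows])
    wave_names = list(config.waveform_mix)
    wave_p = np.array([config.waveform_mix[w] for w in wave_names])

    truth: list[TruthRecord] = []
    probe_ids: list[str] = []
    probe_map: dict[str, str] = {}
    rows: list[np.ndarray] = []
    plo, phi_ = config.probes_per_locus_range

    for i, locus in enumerate(loci):
        if expressed[i]:
            baseline = float(np.clip(rng.normal(mode_hi, 0.30), 1.70, None))
        else:
            baseline = float(np.clip(rng.normal(mode_lo, 0.20), None, 1.20))
        if is_rhythmic[i]:
            partner = partner_of.get(i)
            partner_truth = truth[partner] if partner is not None and partner < i else None
            if partner_truth is not None and partner_truth.is_rhythmic:
                # co-rhythmic divergent pair: phase close to the partner's
                phase = float((partner_truth.phase + rng.normal(0.0, 1.5)) % 24.0)
                window = _window_of_ct(phase)
            else:
                window = str(rng.choice(windows, p=window_p))
                phase = _draw_phase(rng, window)
            wave = str(rng.choice(wave_names, p=wave_p))
            amp = float(rng.uniform(*config.relative_amplitude_range))
            signal = baseline + (math.log10(amp) / 2.0) * waveforms.evaluate(
                wave, times, phase, config.period_hours
            )
            truth.append(
                TruthRecord(
                    locus_id=locus.locus_id,
                    is_rhythmic=True,
                    waveform=wave,
                    period=config.period_hours,
                    phase=phase,
                    relative_amplitude=amp,
                    baseline=baseline,
                    planted_window=window,
                    expressed=True,
                )
            )
        else:
            signal = np.full_like(times, baseline)
            truth.append(
                TruthRecord(
                    locus_id=locus.locus_id,
                    is_rhythmic=False,
                    baseline=baseline,
                    planted_window="none",
                    expressed=bool(expressed[i]),
                )
            )
        n_probes = int(rng.integers(plo, phi_ + 1))
        for j in range(n_probes):
            pid = f"{locus.locus_id}_p{j + 1}"
            probe_ids.append(pid)
            probe_map[pid] = locus.locus_id
            rows.append(signal + rng.normal(0.0, config.noise_sd, size=times.size))

    matrix = TimeCourseMatrix(probe_ids, times, np.vstack(rows))
    return matrix, probe_map, truth


def generate_tissue_matrix(
    config: SimulationConfig, truth: list[TruthRecord]
) -> tuple[TissueMatrix, dict[str, int]]:
    """Multi-tissue matrix with planted expression breadths.

    A ``ubiquitous_fraction`` of genes is expressed in every tissue; the rest
    get a planted breadth (genes expressed in the focal tissue always include
    it).  Values are drawn clear of the cutoff midpoint between the two
    baseline modes, so the planted breadth is exactly recoverable.
    """
    rng = _child_rngs(config.seed, 8)[2]
    n_t = config.n_tissues
    mode_lo, mode_hi = config.baseline_log10_modes
    cutoff = (mode_lo + mode_hi) / 2.0
    tissue_ids = ["liver"] + [f"tissue{i + 2:02d}" for i in range(n_t - 1)]
    gene_ids = [t.locus_id for t in truth]
    values = np.empty((len(truth), n_t))
    planted_breadth: dict[str, int] = {}
    for i, rec in enumerate(truth):
        if rng.random() < config.ubiquitous_fraction:
            breadth = n_t
        elif rec.expressed:
            breadth = int(rng.integers(1, n_t))
        else:
            breadth = int(rng.integers(0, max(1, n_t // 2)))
        on = np.zeros(n_t, dtype=bool)
        if breadth >= n_t:
            on[:] = True
        elif breadth > 0:
            if rec.expressed:
                on[0] = True
                others = 1 + rng.choice(n_t - 1, size=breadth - 1, replace=False)
                on[others] = True
            else:
                on[rng.choice(n_t, size=breadth, replace=False)] = True
        hi = np.clip(rng.normal(mode_hi, 0.35, size=n_t), cutoff + 0.25, None)
        lo = np.clip(rng.normal(mode_lo, 0.25, size=n_t), None, cutoff - 0.25)
        values[i] = np.where(on, hi, lo)
        planted_breadth[rec.locus_id] = int(on.sum())
    return TissueMatrix(gene_ids, tissue_ids, values), planted_breadth


_DNA = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> list[str]:
    return list(_DNA[rng.integers(0, 4, size=length)])


def _find_all(seq: str, pat: str) -> list[int]:
    out = []
    pos = seq.find(pat)
    while pos != -1:
        out.append(pos)
        pos = seq.find(pat, pos + 1)
    return out


def _scrub_and_plant(
    rng: np.random.Generator,
    length: int,
    plant: dict[str, int],
    site_seqs: dict[str, str],
) -> tuple[str, dict[str, int]]:
    """A random sequence carrying exactly the planted seed-site counts.

    Planted sites are inserted at evenly spread, non-overlapping positions;
    accidental occurrences of any site are then mutated away at a base
    outside every planted span until each count is exact.
    """
    total_sites = sum(plant.values())
    length = max(length, total_sites * 14 + 20)
    seq = _random_dna(rng, length)
    planted_spans: list[tuple[int, int]] = []
    planted_pos: dict[str, set[int]] = {m: set() for m in plant}
    slot = length // max(1, total_sites)
    k = 0
    for name in sorted(plant):
        site = site_seqs[name]
        for _ in range(plant[name]):
            pos = k * slot + int(rng.integers(0, max(1, slot - 7)))
            pos = min(pos, length - 7)
            seq[pos : pos + 7] = list(site)
            planted_spans.append((pos, pos + 7))
            planted_pos[name].add(pos)
            k += 1
    s = "".join(seq)
    for _ in range(200):
        dirty = False
        for name, site in site_seqs.items():
            want = planted_pos.get(name, set())
            for pos in _find_all(s, site):
                if pos in want:
                    continue
                dirty = True
                for off in range(7):
                    b = pos + off
                    if not any(lo <= b < hi for lo, hi in planted_spans):
                        old = s[b]
                        choices = [c for c in "ACGT" if c != old]
                        s = s[:b] + str(rng.choice(choices)) + s[b + 1 :]
                        break
                else:  # fully inside planted spans: count it as planted
                    planted_pos.setdefault(name, set()).add(pos)
                break
            if dirty:
                break
        if not dirty:
            break
    realized = {name: len(planted_pos.get(name, set())) for name in site_seqs}
    return s, realized


def generate_aux_tables(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: list[TruthRecord],
) -> SyntheticAux:
    """Binding sites, methylation probes, half-lives, sequences, and terms.

    Rhythmic loci get more and stronger TSS-proximal binding sites, slightly
    lower promoter methylation, shorter half-lives, and denser seed sites,
    mirroring the direction of the contrasts the analysis measures.
    """
    rng = _child_rngs(config.seed, 8)[3]
    truth_by_id = {t.locus_id: t for t in truth}

    binding_sites: list[BindingSite] = []
    site_truth: dict[str, str | None] = {}
    site_no = 0
    for locus in annotation.loci:
        rec = truth_by_id[locus.locus_id]
        p_site = 0.25 if rec.is_rhythmic else 0.10
        if rng.random() >= p_site:
            continue
        offset = int(rng.integers(-45_000, 45_001))
        pos = max(0, locus.tss + offset)
        base = rng.lognormal(2.0 if rec.is_rhythmic else 1.2, 0.6)
        signals = tuple(float(base * rng.lognormal(0, 0.2)) for _ in range(6))
        site_no += 1
        sid = f"site{site_no:05d}"
        binding_sites.append(BindingSite(sid, locus.chromosome, pos, signals))
        site_truth[sid] = locus.locus_id
    n_decoys = max(1, len(binding_sites) // 20)
    for _ in range(n_decoys):
        chrom = str(rng.choice(list(annotation.chrom_lengths)))
        pos = int(rng.integers(0, annotation.chrom_lengths[chrom]))
        site_no += 1
        sid = f"site{site_no:05d}"
        signals = tuple(float(rng.lognormal(1.0, 0.5)) for _ in range(6))
        binding_sites.append(BindingSite(sid, chrom, pos, signals))
        site_truth[sid] = None

    methylation_probes: list[MethylationProbe] = []
    probe_no = 0
    for locus in annotation.loci:
        rec = truth_by_id[locus.locus_id]
        if rng.random() >= 0.6:
            continue
        for _ in range(int(rng.integers(1, 3))):
            probe_no += 1
            offset = int(rng.integers(-1_800, 1_801))
            m = rng.normal(-0.3 if rec.is_rhythmic else 0.1, 0.6)
            methylation_probes.append(
                MethylationProbe(
                    probe_id=f"meth{probe_no:05d}",
                    chromosome=locus.chromosome,
                    center=max(0, locus.tss + offset),
                    m_value=float(m),
                    cpg_class=str(rng.choice(["strong", "weak", "poor"])),
                )
            )

    halflife_records: list[HalfLifeRecord] = []
    for locus in annotation.loci:
        if rng.random() >= 0.9:
            continue
        rec = truth_by_id[locus.locus_id]
        median = 7.0 if rec.is_rhythmic else 8.4
        hl = float(rng.lognormal(math.log(median), 0.45))
        halflife_records.append(
            HalfLifeRecord(
                gene_id=locus.locus_id,
                halflife_es=hl,
                halflife_diff=float(hl * rng.lognormal(0, 0.15)),
                diff_p=float(rng.uniform(0, 1)),
            )
        )

    mirnas: dict[str, str] = {}
    site_seqs: dict[str, str] = {}
    from .enrichment import reverse_complement

    while len(mirnas) < config.n_mirnas:
        name = f"mir-{len(mirnas) + 1:03d}"
        seq = "".join(_random_dna(rng, 22)).replace("T", "U")
        site = reverse_complement(seq[1:8])
        if site in site_seqs.values():
            continue
        mirnas[name] = seq
        site_seqs[name] = site

    utr_sequences: dict[str, str] = {}
    seed_site_truth: dict[tuple[str, str], int] = {}
    mirna_names = sorted(mirnas)
    for locus in annotation.loci:
        rec = truth_by_id[locus.locus_id]
        lam = 5.0 if rec.is_rhythmic else 4.2
        n_sites = int(rng.poisson(lam))
        plant: dict[str, int] = {}
        for _ in range(n_sites):
            name = str(rng.choice(mirna_names))
            plant[name] = plant.get(name, 0) + 1
        if rec.is_rhythmic and rec.planted_window == "day":
            plant[mirna_names[0]] = plant.get(mirna_names[0], 0) + 3
        length = int(np.clip(locus.utr3_length or 300, 100, 2_500))
        seq, realized = _scrub_and_plant(rng, length, plant, site_seqs)
        utr_sequences[locus.locus_id] = seq
        for name in mirna_names:
            seed_site_truth[(locus.locus_id, name)] = realized.get(name, 0)

    gene_terms: dict[str, list[str]] = {}
    for locus in annotation.loci:
        rec = truth_by_id[locus.locus_id]
        terms = []
        if rng.random() < 0.20:
            terms.append("BP:housekeeping")
        for window in _WINDOW_SPANS:
            p = 0.35 if rec.planted_window == window else 0.02
            if rng.random() < p:
                terms.append(f"BP:{window}_process")
        if terms:
            gene_terms[locus.locus_id] = terms

    return SyntheticAux(
        binding_sites=binding_sites,
        site_truth=site_truth,
        methylation_probes=methylation_probes,
        halflife_records=halflife_records,
        mirnas=mirnas,
        utr_sequences=utr_sequences,
        seed_site_truth=seed_site_truth,
        gene_terms=gene_terms,
    )


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """All pipeline inputs plus the truth needed to score every stage."""
    annotation = generate_annotation(config)
    timecourse, probe_map, truth = generate_timecourse(config, annotation)
    tissue, planted_breadth = generate_tissue_matrix(config, truth)
    aux = generate_aux_tables(config, annotation, truth)

    rng = _child_rngs(config.seed, 8)[4]
    rhythmic = [t.locus_id for t in truth if t.is_rhythmic]
    non_rhythmic = [t.locus_id for t in truth if not t.is_rhythmic]
    n_extra = int(config.general_list_extra_fraction * len(truth))
    extra = (
        list(rng.choice(non_rhythmic, size=min(n_extra, len(non_rhythmic)), replace=False))
        if non_rhythmic
        else []
    )
    general = set(rhythmic) | set(extra)
    for t in truth:
        t.in_general_list = t.locus_id in general

    neg_pool = sorted(set(non_rhythmic) - set(extra))
    negative_controls = (
        list(rng.choice(neg_pool, size=min(111, len(neg_pool)), replace=False))
        if neg_pool
        else []
    )
    positive_controls = (
        list(rng.choice(rhythmic, size=min(104, len(rhythmic)), replace=False))
        if rhythmic
        else []
    )

    return SyntheticDataset(
        config=config,
        annotation=annotation,
        truth=truth,
        timecourse=timecourse,
        probe_map=probe_map,
        tissue=tissue,
        planted_breadth=planted_breadth,
        aux=aux,
        general_circadian_list=general,
        negative_controls=[str(x) for x in negative_controls],
        positive_controls=[str(x) for x in positive_controls],
    )
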