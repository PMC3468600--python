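"""Set-enrichment statistics and miRNA seed-match target counting.

2x2 contingency tests (Fisher's exact when any expected cell is small, else
Pearson chi-squared without continuity correction), proportion-ratio
enrichment folds, the pairwise phase-specific criterion (a term is flagged
for a cluster when at least 3 of the 4 comparisons against the other
clusters and the background set have P < 0.05 and fold > 1.5; the miRNA
variant requires all 3 inter-cluster comparisons to pass), and exact
seed-complement site counting in 3'-UTR sequences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .clustering import ConsensusCluster

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "contingency_test",
    "enrichment_fold",
    "phase_specific_terms",
    "seed_match_targets",
]

PAIRWISE_P = 0.05
PAIRWISE_FOLD = 1.5


@dataclass
class ContingencyTable:
    """Membership counts for a property in a focal vs a comparison set."""

    k_in: int
    n_in: int
    k_out: int
    n_out: int

    def __post_init__(self) -> None:
        for name in ("k_in", "n_in", "k_out", "n_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_in > self.n_in or self.k_out > self.n_out:
            raise ValueError("k cannot exceed n")


@dataclass
class EnrichmentResult:
    term: str
    cluster: str
    comparisons: list[tuple[str, float, float]]  # (against, P, fold)
    passes: int
    flagged: bool


def contingency_test(table: ContingencyTable) -> float:
    """Two-sided 2x2 test P: Fisher's exact if any expected cell < 5, else
    Pearson chi-squared without continuity correction."""
    if table.n_in < 1 or table.n_out < 1:
        raise ValueError("both sets must be non-empty")
    obs = np.array(
        [
            [table.k_in, table.n_in - table.k_in],
            [table.k_out, table.n_out - table.k_out],
        ]
    )
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(obs, alternative="two-sided")
    else:
        _, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(p)


def enrichment_fold(table: ContingencyTable) -> float:
    """Proportion-ratio fold: (k_in/n_in) / (k_out/n_out); inf when the
    comparison set has no members with the property but the focal set does."""
    if table.n_in == 0:
        raise ValueError("focal set must be non-empty")
    p_in = table.k_in / table.n_in
    if table.k_out == 0:
        return math.inf if table.k_in > 0 else float("nan")
    p_out = table.k_out / table.n_out
    return float(p_in / p_out)


def _term_count(genes: set[str], term_genes: set[str]) -> int:
    return len(genes & term_genes)


def phase_specific_terms(
    clusters: Sequence[ConsensusCluster] | Mapping[str, Iterable[str]],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    mode: str = "go",
) -> list[EnrichmentResult]:
    """Flag terms specifically enriched in one temporal cluster.

    For each (cluster, term) the focal cluster is compared against each other
    cluster and, in ``go`` mode, also against the background (non-circadian)
    set: flagged when >= 3 of the 4 comparisons have P < 0.05 and fold > 1.5.
    In ``mirna`` mode only the three inter-cluster comparisons are used and
    all must pass.

    ``annotation`` maps gene -> iterable of terms.  Cluster genes without any
    annotation simply contribute no terms.
    """
    if mode not in ("go", "mirna"):
        raise ValueError("mode must be 'go' or 'mirna'")
    if isinstance(clusters, Mapping):
        cluster_genes = {str(k): set(v) for k, v in clusters.items()}
    else:
        cluster_genes = {
            (c.window or f"cluster{i}"): set(c.member_gene_ids)
            for i, c in enumerate(clusters)
        }
    background = set(background)

    gene_terms = {g: set(t) for g, t in annotation.items()}
    term_genes: dict[str, set[str]] = {}
    for g, terms in gene_terms.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(g)

    results = []
    for name, focal in sorted(cluster_genes.items()):
        others = {k: v for k, v in cluster_genes.items() if k != name}
        comparisons_sets = dict(others)
        if mode == "go":
            comparisons_sets["background"] = background
        for term in sorted(term_genes):
            tg = term_genes[term]
            k_in = _term_count(focal, tg)
            if k_in == 0:
                continue
            comps = []
            n_pass = 0
            for against, other in sorted(comparisons_sets.items()):
                table = ContingencyTable(k_in, len(focal), _term_count(other, tg), len(other))
                p = contingency_test(table)
                fold = enrichment_fold(table)
                ok = p < PAIRWISE_P and fold > PAIRWISE_FOLD
                n_pass += ok
                comps.append((against, p, fold))
            needed = 3 if mode == "go" else len(comps)
            results.append(
                EnrichmentResult(
                    term=term,
                    cluster=name,
                    comparisons=comps,
                    passes=n_pass,
                    flagged=n_pass >= needed,
                )
            )
    return results


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return _normalize_seq(seq).translate(_COMPLEMENT)[::-1]


def seed_match_targets(
    utr_sequences: Mapping[str, str],
    mirnas: Mapping[str, str],
) -> dict[str, dict[str, int]]:
    """Exact seed-complement site counts per (gene, miRNA).

    The seed is bases 2-8 from the miRNA 5' end (a 7-mer); a site is an exact
    occurrence of its reverse complement on the 3'-UTR sense strand.
    Overlapping occurrences count separately.  miRNAs shorter than 8 bases
    are skipped with a warning.
    """
    sites: dict[str, str] = {}
    for name, seq in mirnas.items():
        seq = _normalize_seq(seq)
        if len(seq) < 8:
            warnings.warn(f"miRNA {name} shorter than 8 bases; skipped")
            continue
        sites[name] = reverse_complement(seq[1:8])
    counts: dict[str, dict[str, int]] = {}
    for gene, utr in utr_sequences.items():
        utr = _normalize_seq(utr)
        per_gene = {}
        for name, site in sites.items():
            n = 0
            pos = utr.find(site)
            while pos != -1:
                n += 1
                pos = utr.find(site, pos + 1)
            per_gene[name] = n
        counts[gene] = per_gene
    return counts
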