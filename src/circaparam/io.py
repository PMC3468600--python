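"""File formats at the pipeline boundary.

Expression matrices, probe maps, rhythm calls, truth tables and auxiliary
tables travel as tab-separated text; annotation as GFF3 (1-based closed on
disk, 0-based half-open in memory); sequences as FASTA via Biopython.  All
writers format floats explicitly so a fixed seed yields byte-identical
files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import HalfLifeRecord, TissueMatrix
from .genesets import GeneLocus, TranscriptFeature
from .genome import BindingSite, MethylationProbe
from .rhythm import RhythmCall, TimeCourseMatrix
from .simulate import GenomeAnnotation, TruthRecord

__all__ = [
    "write_timecourse",
    "read_timecourse",
    "write_tissue_matrix",
    "read_tissue_matrix",
    "write_probe_map",
    "read_probe_map",
    "write_calls",
    "read_calls",
    "write_gff3",
    "read_gff3_features",
    "write_sites",
    "read_sites",
    "write_methylation",
    "read_methylation",
    "write_halflife",
    "read_halflife",
    "write_fasta",
    "read_fasta",
    "write_gene_list",
    "read_gene_list",
    "write_truth",
]


def _ct_label(t: float) -> str:
    return f"CT{int(round(t)):02d}" if abs(t - round(t)) < 1e-9 else f"CT{t:g}"


def write_timecourse(matrix: TimeCourseMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("row_id\t" + "\t".join(_ct_label(t) for t in matrix.times) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_timecourse(path: str | Path) -> TimeCourseMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    times = [float(c.removeprefix("CT")) for c in df.columns]
    return TimeCourseMatrix(list(df.index.astype(str)), np.array(times), df.to_numpy())


def write_tissue_matrix(matrix: TissueMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.tissue_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_tissue_matrix(path: str | Path) -> TissueMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TissueMatrix(list(df.index.astype(str)), list(df.columns), df.to_numpy())


def write_probe_map(probe_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tlocus_id\n")
        for probe, locus in probe_map.items():
            fh.write(f"{probe}\t{locus}\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["probe_id"], df["locus_id"]))


_CALL_COLUMNS = ["row_id", "detector", "period", "phase", "statistic", "p_value", "q_value", "waveform"]


def write_calls(calls: Sequence[RhythmCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.row_id}\t{c.detector}\t{c.period:.4f}\t{c.phase:.4f}\t"
                f"{c.statistic:.6g}\t{c.p_value:.6g}\t{c.q_value:.6g}\t"
                f"{c.waveform or ''}\n"
            )


def read_calls(path: str | Path) -> list[RhythmCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        RhythmCall(
            row_id=str(r.row_id),
            period=float(r.period),
            phase=float(r.phase),
            statistic=float(r.statistic),
            p_value=float(r.p_value),
            q_value=float(r.q_value),
            detector=str(r.detector),
            waveform=str(r.waveform) or None,
        )
        for r in df.itertuples()
    ]


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Gene / mRNA / exon / CDS rows, converting to 1-based closed intervals."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chrom_lengths:
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}\n")
        for locus in annotation.loci:
            lid = locus.locus_id
            tid = locus.representative_transcript or f"{lid}.1"
            row = (
                f"{locus.chromosome}\tcircaparam\t{{kind}}\t{{start}}\t{{end}}\t.\t"
                f"{locus.strand}\t.\t{{attrs}}\n"
            )
            fh.write(
                row.format(kind="gene", start=locus.start + 1, end=locus.end, attrs=f"ID={lid}")
            )
            fh.write(
                row.format(
                    kind="mRNA", start=locus.start + 1, end=locus.end,
                    attrs=f"ID={tid};Parent={lid}",
                )
            )
            for s, e in annotation.exons.get(lid, [(locus.start, locus.end)]):
                fh.write(row.format(kind="exon", start=s + 1, end=e, attrs=f"Parent={tid}"))
            cds = annotation.cds_spans.get(lid)
            if cds is not None:
                for s, e in annotation.exons.get(lid, [(locus.start, locus.end)]):
                    lo, hi = max(s, cds[0]), min(e, cds[1])
                    if lo < hi:
                        fh.write(
                            row.format(kind="CDS", start=lo + 1, end=hi, attrs=f"Parent={tid}")
                        )


def read_gff3_features(path: str | Path) -> list[TranscriptFeature]:
    """mRNA features with exon chains and CDS spans, 0-based half-open."""
    mrna: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, _, kind, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            start0, end0 = int(start) - 1, int(end)
            if kind == "mRNA":
                mrna[fields["ID"]] = {
                    "chromosome": chrom, "strand": strand, "exons": [], "cds": None,
                }
            elif kind == "exon":
                mrna[fields["Parent"]]["exons"].append((start0, end0))
            elif kind == "CDS":
                rec = mrna[fields["Parent"]]
                cds = rec["cds"]
                rec["cds"] = (
                    (start0, end0) if cds is None else (min(cds[0], start0), max(cds[1], end0))
                )
    return [
        TranscriptFeature(
            transcript_id=tid,
            chromosome=rec["chromosome"],
            strand=rec["strand"],
            exons=sorted(rec["exons"]),
            cds=rec["cds"],
        )
        for tid, rec in mrna.items()
    ]


def write_sites(sites: Sequence[BindingSite], path: str | Path) -> None:
    """BED-like: 0-based half-open single-base interval plus temporal signals."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsite_id\tsignals\n")
        for s in sites:
            sig = ",".join(f"{v:.4f}" for v in s.signals)
            fh.write(f"{s.chromosome}\t{s.position}\t{s.position + 1}\t{s.site_id}\t{sig}\n")


def read_sites(path: str | Path) -> list[BindingSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "site_id": str})
    return [
        BindingSite(
            site_id=r.site_id,
            chromosome=r.chrom,
            position=int(r.start),
            signals=tuple(float(x) for x in str(r.signals).split(",")),
        )
        for r in df.itertuples()
    ]


def write_methylation(probes: Sequence[MethylationProbe], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchrom\tcenter\tm_value\tcpg_class\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.chromosome}\t{p.center}\t{p.m_value:.5f}\t{p.cpg_class}\n")


def read_methylation(path: str | Path) -> list[MethylationProbe]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "cpg_class": str})
    return [
        MethylationProbe(r.probe_id, r.chrom, int(r.center), float(r.m_value), r.cpg_class)
        for r in df.itertuples()
    ]


def write_halflife(records: Sequence[HalfLifeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\thalflife_es\thalflife_diff\tdiff_p\n")
        for r in records:
            p = "" if r.diff_p is None else f"{r.diff_p:.5f}"
            fh.write(f"{r.gene_id}\t{r.halflife_es:.4f}\t{r.halflife_diff:.4f}\t{p}\n")


def read_halflife(path: str | Path) -> list[HalfLifeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        HalfLifeRecord(
            gene_id=r.gene_id,
            halflife_es=float(r.halflife_es),
            halflife_diff=float(r.halflife_diff),
            diff_p=None if pd.isna(r.diff_p) else float(r.diff_p),
        )
        for r in df.itertuples()
    ]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [l for l in Path(path).read_text().splitlines() if l.strip()]


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tis_rhythmic\twaveform\tperiod\tphase\trelative_amplitude\t"
            "baseline\tplanted_window\texpressed\tin_general_list\n"
        )
        for t in truth:
            fh.write(
                f"{t.locus_id}\t{int(t.is_rhythmic)}\t{t.waveform or 'NA'}\t"
                f"{'NA' if t.period is None else f'{t.period:.2f}'}\t"
                f"{'NA' if t.phase is None else f'{t.phase:.4f}'}\t"
                f"{'NA' if t.relative_amplitude is None else f'{t.relative_amplitude:.4f}'}\t"
                f"{t.baseline:.4f}\t{t.planted_window}\t{int(t.expressed)}\t"
                f"{int(t.in_general_list)}\n"
            )
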