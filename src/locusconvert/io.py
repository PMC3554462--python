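"""Readers and writers for on-disk formats, with exact coordinate handling.

The single point where coordinate conventions are translated: BED is 0-based
half-open on disk and becomes 1-based closed in memory (``start + 1`` on
read, the reverse on write); GFF3 is already 1-based closed and passes
through; FASTA goes through Biopython.  Conversion results are written as
TSV tables and as UCSC-browser custom tracks (BED with a ``track`` line).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .convert import ConversionReport
from .core import GenomicInterval
from .evaluate import ConfusionCounts, rounded_metrics
from .registry import IdentifierRecord, Registry

CONVERSION_COLUMNS = (
    "query_id",
    "query_locus",
    "target_namespace",
    "target_id",
    "target_locus",
    "overlap_bases",
    "gap_bases",
)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered mapping of record name -> sequence string."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED (0-based, half-open on disk)


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Parse BED3/4/6; returns internal 1-based closed intervals with names.

    A line ``chr1  0  10  x`` becomes ``chr1:[1,10]``.  Track and comment
    lines are skipped.  Malformed lines raise :class:`FormatError` with the
    line number.
    """
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start0 < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            if end0 <= start0:
                raise FormatError(f"{path}:{lineno}: end must exceed start")
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start0}-{end0}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            out.append((GenomicInterval(chrom, start0 + 1, end0, strand), name))
    return out


def write_bed(path, records: Iterable[tuple[GenomicInterval, str]]) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            score = "0"
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def write_track(path, report: ConversionReport, track_name: str, description: str = "") -> None:
    """Conversion hits as a UCSC custom track (one BED record per hit)."""
    with open(path, "w") as fh:
        desc = description or track_name
        fh.write(f'track name="{track_name}" description="{desc}"\n')
        for h in report.hits:
            iv = h.subject_interval
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{h.subject_id}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{h.subject_id}\t0\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# GFF3 (1-based, closed on disk)


def read_gff3_exons(path, namespace: str) -> list[IdentifierRecord]:
    """Exon features grouped by their ``Parent`` into exon-union records.

    Exons are ordered by start coordinate within each record; records come
    back sorted by id.  Exons without a Parent attribute use their own ID.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    groups: dict[str, list[GenomicInterval]] = {}
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start} lacks Parent/ID")
        iv = GenomicInterval(
            feat.seqid, feat.start, feat.end, feat.strand if feat.strand in "+-" else "."
        )
        for pid in parents:
            groups.setdefault(pid, []).append(iv)
    return [
        IdentifierRecord(
            pid,
            namespace,
            tuple(sorted(ivs, key=lambda v: (v.start, v.end))),
            mode="exon_union",
        )
        for pid, ivs in sorted(groups.items())
    ]


# ---------------------------------------------------------------------------
# identifier lists, truth mappings, reports


def read_id_list(path) -> list[str]:
    """One identifier per line (first tab-separated column); order kept."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def read_truth_tsv(path) -> dict[str, set[str]]:
    """Two-column (query_id, target_id) TSV -> truth mapping.

    A row with an empty second column declares a query with an empty truth
    set (the authority annotates it to nothing).
    """
    truth: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            qid = fields[0]
            truth.setdefault(qid, set())
            if len(fields) > 1 and fields[1]:
                truth[qid].add(fields[1])
    return truth


def write_truth_tsv(path, truth: Mapping[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for qid in sorted(truth):
            if truth[qid]:
                for tid in sorted(truth[qid]):
                    fh.write(f"{qid}\t{tid}\n")
            else:
                fh.write(f"{qid}\t\n")


def _locus(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def write_conversion_tsv(path, report: ConversionReport) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CONVERSION_COLUMNS)
        for h in report.hits:
            w.writerow(
                [
                    h.query_id,
                    _locus(h.query_interval),
                    h.subject_namespace,
                    h.subject_id,
                    _locus(h.subject_interval),
                    h.overlap_bases,
                    h.gap_bases,
                ]
            )


def write_unconverted_tsv(path, report: ConversionReport) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query_id", "reason"])
        for qid, reason in report.unconverted:
            w.writerow([qid, reason])


def write_metrics_tsv(path, rows: Mapping[str, ConfusionCounts]) -> None:
    """Contingency-table report: one row per converter/configuration."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["tool", "totalMapped", "TP", "FP", "FN", "TN", "TPR", "FPR", "ACC", "FDR", "F1_score"]
        )
        for name, c in rows.items():
            m = rounded_metrics(c)
            w.writerow(
                [name, c.total_mapped, c.tp, c.fp, c.fn, c.tn]
                + [("NA" if m[k] is None else f"{m[k]:.2f}") for k in ("TPR", "FPR", "ACC", "FDR", "F1")]
            )


# ---------------------------------------------------------------------------
# registry serialization: flat sorted interval tables


def dump_registry(path, reg: Registry) -> None:
    """Write the registry as one flat sorted TSV; reload rebuilds the trees."""
    rows = []
    for ns in sorted(reg.namespaces):
        for rid in sorted(reg.namespaces[ns]):
            rec = reg.namespaces[ns][rid]
            for ordinal, iv in enumerate(rec.intervals):
                rows.append(
                    [ns, rid, rec.mode, iv.chrom, iv.start, iv.end, iv.strand, ordinal]
                )
    rows.sort(key=lambda r: (r[0], r[3], r[4], r[5], r[1], r[7]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["namespace", "id", "mode", "chrom", "start", "end", "strand", "ordinal"])
        w.writerows(rows)


def load_registry(path) -> Registry:
    groups: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for fields in reader:
            ns, rid, mode, chrom, start, end, strand, ordinal = fields
            g = groups.setdefault((ns, rid), {"mode": mode, "ivs": []})
            g["ivs"].append(
                (int(ordinal), GenomicInterval(chrom, int(start), int(end), strand))
            )
    reg = Registry()
    for (ns, rid), g in sorted(groups.items()):
        ivs = tuple(iv for _, iv in sorted(g["ivs"], key=lambda t: t[0]))
        reg.register(IdentifierRecord(rid, ns, ivs, mode=g["mode"]))
    return reg


# ---------------------------------------------------------------------------
# registry manifest (YAML): namespace -> annotation file + mode


def build_registry_from_manifest(manifest_path) -> Registry:
    """Build a registry from a YAML manifest.

    The manifest is a list of entries, each with keys ``namespace``,
    ``path`` (relative paths resolve against the manifest), ``format``
    (``bed`` or ``gff3``) and, for BED, ``mode`` (``span`` default; BED name
    column = identifier, one line per interval — repeated names in
    ``exon_union`` mode accumulate exons of one record).
    """
    import yaml

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        entries = yaml.safe_load(fh)
    reg = Registry()
    for entry in entries:
        ns = entry["namespace"]
        p = Path(entry["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        fmt = entry.get("format", "bed")
        mode = entry.get("mode", "span")
        if fmt == "gff3":
            reg.register_all(read_gff3_exons(p, ns))
        elif fmt == "bed":
            grouped: dict[str, list[GenomicInterval]] = {}
            for iv, name in read_bed(p):
                grouped.setdefault(name, []).append(iv)
            for name, ivs in grouped.items():
                reg.register(IdentifierRecord(name, ns, tuple(ivs), mode=mode))
        else:
            raise FormatError(f"unknown annotation format {fmt!r}")
    return reg
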