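"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Biopython; GFF3 is read by a small validating parser
restricted to the gene/mRNA/CDS dialect this pipeline emits and consumes
(readers reject structural violations rather than repairing them, always
naming the offending record or line).  Homology tables use the de-facto
12-column tabular layout of pairwise protein search tools, so any engine's
output can be substituted for the internal search.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AnnotationSet, GeneLocus, HomologyHit, HomologyTable

logger = logging.getLogger("sbpkit")

# IUPAC nucleotide + amino-acid one-letter codes, stop and gap.
_IUPAC = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-") | set("acdefghiklmnpqrstvwybxzjuo")

HOMOLOGY_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    Duplicate ids and non-IUPAC characters are errors naming the record.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seq = str(rec.seq)
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(
                f"record {rec.id}: non-IUPAC characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _parse_attributes(column: str) -> dict[str, str]:
    out = {}
    for item in column.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def read_gff3(path: str | Path) -> AnnotationSet:
    """Read gene features from a GFF3 file into an AnnotationSet.

    Only ``gene`` features become loci; ``group=<label>`` attributes set
    the family/group labels.  Malformed lines (end < start, bad strand,
    missing ID) raise with the 1-based line number.
    """
    genes: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            if end < start:
                raise ValueError(f"line {lineno}: end ({end}) < start ({start})")
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: unknown strand {strand!r}")
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("ID")
            if not gene_id:
                raise ValueError(f"line {lineno}: gene feature without ID attribute")
            if gene_id in seen:
                raise ValueError(f"line {lineno}: duplicate gene id {gene_id}")
            seen.add(gene_id)
            group = attributes.get("group")
            family = attributes.get("family", "0") == "1" or group is not None
            genes.append(
                GeneLocus(
                    id=gene_id, chromosome=chrom, start=start, end=end,
                    strand=strand, family_member=family, group=group,
                )
            )
    return AnnotationSet(genes)


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Write gene/mRNA/CDS features (one single-exon CDS per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            attrs = [f"ID={g.id}"]
            if g.family_member:
                attrs.append("family=1")
            if g.group is not None:
                attrs.append(f"group={g.group}")
            base = f"{g.chromosome}\tsbpkit\t"
            tail = f"\t{g.start}\t{g.end}\t.\t{g.strand}\t"
            fh.write(base + "gene" + tail + ".\t" + ";".join(attrs) + "\n")
            fh.write(base + "mRNA" + tail + ".\t" + f"ID={g.id}.t1;Parent={g.id}\n")
            fh.write(base + "CDS" + tail + "0\t" + f"ID={g.id}.cds;Parent={g.id}.t1\n")


def read_homology_table(path: str | Path, max_evalue: float = 1e-10) -> HomologyTable:
    """Read a 12-column tabular hit file, dropping rows above max_evalue.

    The E-value threshold mirrors the stringency used for micro-fragment
    homology support (<= 1e-10 by default).
    """
    hits: list[HomologyHit] = []
    n_total = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hit = HomologyHit(
                    query=fields[0], subject=fields[1],
                    pident=float(fields[2]), length=int(fields[3]),
                    mismatch=int(fields[4]), gapopen=int(fields[5]),
                    qstart=int(fields[6]), qend=int(fields[7]),
                    sstart=int(fields[8]), send=int(fields[9]),
                    evalue=float(fields[10]), bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed row ({exc})") from None
            n_total += 1
            if hit.evalue <= max_evalue:
                hits.append(hit)
    if n_total == 0:
        logger.warning("homology table %s is empty", path)
    logger.info(
        "homology table %s: %d rows in, %d retained (E <= %g)",
        path, n_total, len(hits), max_evalue,
    )
    return HomologyTable(hits)


def write_homology_table(table: HomologyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in table:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.pident:.2f}\t{h.length}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t"
                f"{h.sstart}\t{h.send}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV, first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dupes}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_config(path: str | Path) -> dict[str, object]:
    """Read a flat key-value configuration file (YAML subset)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key: value mapping")
    return data


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
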