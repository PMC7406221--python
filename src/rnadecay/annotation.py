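"""Genome annotation handling and strand-aware window extraction.

Internal coordinates are 0-based half-open on the forward genomic strand;
GFF3 I/O converts from/to 1-based inclusive at the boundary.  UTR proxies
are fixed flanks: a window upstream of the start codon
(default 150 nt, "5' UTR") and downstream of the stop codon (default
100 nt, "3' UTR"), both reported on the coding strand.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ReferenceError_

ANNOTATION_COLUMNS = ["gene_id", "seq_id", "start", "end", "strand",
                      "category", "operon_id", "operon_index"]


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann["gene_id"].duplicated().any():
        raise FormatError("duplicate gene_id in annotation")
    if not ann["strand"].isin(["+", "-"]).all():
        raise FormatError("strand must be '+' or '-'")
    if (ann["start"] >= ann["end"]).any():
        raise FormatError("annotation requires start < end (0-based half-open)")
    has_op = ann["operon_id"].fillna("") != ""
    idx = pd.to_numeric(ann.loc[has_op, "operon_index"], errors="coerce")
    if (idx < 1).any() or idx.isna().any():
        raise FormatError("operon_index must be >= 1 where operon_id is set")
    return ann


def read_annotation(gff_path, fasta_path):
    """Read a GFF3 + FASTA pair.

    Returns ``(annotation DataFrame, genome dict of str)``.  Coordinates are
    converted from GFF 1-based inclusive to 0-based half-open.  Optional
    attributes ``category``, ``operon_id`` and ``operon_index`` are kept.
    """
    import gffutils

    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene_id = (feat.attributes.get("ID") or
                   feat.attributes.get("locus_tag") or [feat.id])[0]
        if feat.seqid not in genome:
            raise ReferenceError_(
                f"annotation sequence {feat.seqid!r} absent from FASTA")
        rows.append({
            "gene_id": gene_id,
            "seq_id": feat.seqid,
            "start": feat.start - 1,   # 1-based inclusive -> 0-based half-open
            "end": feat.end,
            "strand": feat.strand,
            "category": (feat.attributes.get("category") or [""])[0],
            "operon_id": (feat.attributes.get("operon_id") or [""])[0],
            "operon_index": (feat.attributes.get("operon_index") or [""])[0],
        })
    # a gene may carry both a gene and a CDS record; keep the first
    ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    ann = ann.drop_duplicates(subset="gene_id", keep="first").reset_index(drop=True)
    ann["operon_index"] = pd.to_numeric(ann["operon_index"], errors="coerce")
    return validate_annotation(ann), genome


def write_annotation(ann: pd.DataFrame, path, source="rnadecay") -> None:
    """Write GFF3 (converting back to 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in ann.iterrows():
            attrs = [f"ID={r.gene_id}"]
            if r.get("category"):
                attrs.append(f"category={r.category}")
            if r.get("operon_id"):
                attrs.append(f"operon_id={r.operon_id}")
                attrs.append(f"operon_index={int(r.operon_index)}")
            fh.write("\t".join([
                r.seq_id, source, "gene", str(int(r.start) + 1), str(int(r.end)),
                ".", r.strand, ".", ";".join(attrs)]) + "\n")


def write_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_utrs(ann: pd.DataFrame, genome: dict, up: int = 150,
                 down: int = 100) -> pd.DataFrame:
    """Fixed UTR-proxy windows on the coding strand for every gene.

    Windows are truncated at contig ends (flagged).  Minus-strand genes are
    reverse-complemented so both windows read 5'->3' on the coding strand.
    """
    rows = []
    for _, r in ann.iterrows():
        if r.seq_id not in genome:
            raise ReferenceError_(f"contig {r.seq_id!r} not in genome")
        contig = genome[r.seq_id]
        n = len(contig)
        if r.strand == "+":
            u_lo, u_hi = max(0, r.start - up), r.start
            d_lo, d_hi = r.end, min(n, r.end + down)
            utr5, utr3 = contig[u_lo:u_hi], contig[d_lo:d_hi]
            trunc5, trunc3 = (u_hi - u_lo) < up, (d_hi - d_lo) < down
        else:
            u_lo, u_hi = r.end, min(n, r.end + up)
            d_lo, d_hi = max(0, r.start - down), r.start
            utr5, utr3 = revcomp(contig[u_lo:u_hi]), revcomp(contig[d_lo:d_hi])
            trunc5, trunc3 = (u_hi - u_lo) < up, (d_hi - d_lo) < down
        rows.append({"gene_id": r.gene_id, "utr5": utr5, "utr3": utr3,
                     "utr5_truncated": trunc5, "utr3_truncated": trunc3})
    return pd.DataFrame(rows).set_index("gene_id")


def threeprime_flank(ann: pd.DataFrame, genome: dict, length: int = 270,
                     truncate_at_next: bool = True) -> pd.Series:
    """Coding-strand 3' flank used for the terminator scan.

    The flank starts immediately after the stop codon and extends ``length``
    nt, truncated at the contig end and (by default) at the next annotated
    gene on the same contig.
    """
    flanks = {}
    by_contig = {c: g.sort_values("start") for c, g in ann.groupby("seq_id")}
    for _, r in ann.iterrows():
        contig = genome[r.seq_id]
        n = len(contig)
        sibs = by_contig[r.seq_id]
        if r.strand == "+":
            lo = r.end
            hi = min(n, r.end + length)
            if truncate_at_next:
                nxt = sibs.loc[sibs["start"] >= r.end, "start"]
                if len(nxt):
                    hi = min(hi, int(nxt.iloc[0]))
            flanks[r.gene_id] = contig[lo:hi]
        else:
            hi = r.start
            lo = max(0, r.start - length)
            if truncate_at_next:
                prv = sibs.loc[sibs["end"] <= r.start, "end"]
                if len(prv):
                    lo = max(lo, int(prv.iloc[-1]))
            flanks[r.gene_id] = revcomp(contig[lo:hi])
    return pd.Series(flanks, name="flank")
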