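"""Readers and writers for the on-disk formats the pipeline touches.

BED3/BED6, GFF3 genes, BEDPE loops, bedGraph tracks, header-free dense
Hi-C matrices (one square TSV per chromosome), two-column expression
TSVs, genome-layout TSVs and FASTA. Coordinates are converted to the
internal 0-based half-open convention on read.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FragmentSet, GeneAnnotation, GenomeLayout, Interval

log = logging.getLogger(__name__)

_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "transposable_element": "TE_gene",
    "transposable_element_gene": "TE_gene",
    "TE_gene": "TE_gene",
    "pseudogene": "pseudogene",
}


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- BED


def read_bed(path: str | os.PathLike, layout: GenomeLayout | None = None) -> list[Interval]:
    """Read BED3/BED6 into Interval records; validates against layout if given."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = Interval(chrom, start, end, name=name, score=score, strand=strand)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if layout is not None:
                layout.validate_interval(iv)
            out.append(iv)
    return out


def write_bed(intervals: list[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                cols += [
                    iv.name if iv.name is not None else ".",
                    format(iv.score, "g") if iv.score is not None else ".",
                    iv.strand,
                ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------- GFF3


def read_gff3_genes(
    path: str | os.PathLike,
    expression: dict[str, float] | None = None,
) -> list[GeneAnnotation]:
    """Read gene features from GFF3, in file order.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    The ``biotype`` (or ``gene_biotype``) attribute is mapped onto the
    closed set {protein_coding, TE_gene, pseudogene}; unknown biotypes are
    recorded as protein_coding with a logged warning. A missing ID raises.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneAnnotation] = []
    for feat in db.all_features(featuretype="gene", order_by=None):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ParseError(f"{path}: gene feature without ID attribute at "
                             f"{feat.seqid}:{feat.start}")
        raw_biotype = (feat.attributes.get("biotype")
                       or feat.attributes.get("gene_biotype") or ["protein_coding"])[0]
        biotype = _BIOTYPE_MAP.get(raw_biotype)
        if biotype is None:
            log.warning("unknown biotype %r for gene %s; recording as protein_coding",
                        raw_biotype, ids[0])
            biotype = "protein_coding"
        strand = feat.strand if feat.strand in {"+", "-"} else "."
        expr = (expression or {}).get(ids[0], 0.0)
        out.append(GeneAnnotation(
            gene_id=ids[0],
            interval=Interval(feat.seqid, feat.start - 1, feat.end, strand=strand),
            strand=strand,
            biotype=biotype,
            expression=expr,
        ))
    return out


def write_gff3_genes(genes: list[GeneAnnotation], path: str | os.PathLike) -> None:
    inverse = {"TE_gene": "transposable_element", "protein_coding": "protein_coding",
               "pseudogene": "pseudogene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={inverse[g.biotype]}"
            fh.write("\t".join([
                g.interval.chrom, "padscan", "gene",
                str(g.interval.start + 1), str(g.interval.end),
                ".", g.strand, ".", attrs,
            ]) + "\n")


# ---------------------------------------------------------------- bedGraph


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              float_format="%.6g")


# ---------------------------------------------------------------- matrices


def read_dense_matrix(path: str | os.PathLike, tol: float = 1e-9) -> np.ndarray:
    """Read a square header-free dense TSV matrix; symmetrise if needed.

    NaN cells are allowed (masked bins). Asymmetry beyond ``tol`` is
    repaired by averaging with the transpose, with a logged warning.
    """
    mat = np.loadtxt(path, dtype=float, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ParseError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmax(np.abs(mat - mat.T)) if mat.size else 0.0
    if delta > tol:
        log.warning("%s: matrix asymmetric (max |A - A^T| = %.3g); symmetrising by averaging",
                    path, delta)
        mat = (mat + mat.T) / 2.0
    return mat


def write_dense_matrix(mat: np.ndarray, path: str | os.PathLike) -> None:
    np.savetxt(path, mat, delimiter="\t", fmt="%.8g")


# ---------------------------------------------------------------- BEDPE


def read_bedpe(path: str | os.PathLike) -> list[tuple[Interval, Interval]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}: line {lineno}: BEDPE needs >=6 columns")
            try:
                a = Interval(f[0], int(f[1]), int(f[2]))
                b = Interval(f[3], int(f[4]), int(f[5]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            out.append((a, b))
    return out


def write_bedpe(loops: list[tuple[Interval, Interval]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in loops:
            fh.write("\t".join(map(str, [a.chrom, a.start, a.end,
                                         b.chrom, b.start, b.end])) + "\n")


# ---------------------------------------------------------------- expression


def read_expression_tsv(path: str | os.PathLike) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    gene_col, expr_col = df.columns[:2]
    return dict(zip(df[gene_col].astype(str), df[expr_col].astype(float)))


def write_expression_tsv(expr: dict[str, float], path: str | os.PathLike) -> None:
    df = pd.DataFrame({"gene_id": list(expr), "expression": list(expr.values())})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------- layout


def read_layout(path: str | os.PathLike) -> GenomeLayout:
    """Layout TSV: chrom, length, peri_start, peri_end, cen_start, cen_end."""
    df = pd.read_csv(path, sep="\t")
    chroms, peri, cen = [], {}, {}
    for row in df.itertuples(index=False):
        chroms.append((str(row.chrom), int(row.length)))
        peri[str(row.chrom)] = (int(row.peri_start), int(row.peri_end))
        cen[str(row.chrom)] = (int(row.cen_start), int(row.cen_end))
    return GenomeLayout(chromosomes=chroms, centromere=cen, pericentromere=peri)


def write_layout(layout: GenomeLayout, path: str | os.PathLike) -> None:
    rows = []
    for chrom, length in layout.chromosomes:
        ps, pe = layout.peri(chrom)
        cs, ce = layout.centromere.get(chrom, (0, 0))
        rows.append((chrom, length, ps, pe, cs, ce))
    pd.DataFrame(rows, columns=["chrom", "length", "peri_start", "peri_end",
                                "cen_start", "cen_end"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------- fragments


def read_fragments(path: str | os.PathLike, label: str | None = None,
                   layout: GenomeLayout | None = None) -> FragmentSet:
    label = label or Path(path).stem
    return FragmentSet(label=label, fragments=read_bed(path, layout=layout))


def write_fragments(fragments: FragmentSet, path: str | os.PathLike) -> None:
    write_bed(fragments.fragments, path)
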