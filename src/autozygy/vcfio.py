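"""File formats: VCF (read via cyvcf2, written as minimal v4.2 text),
BED masks and gene intervals, and segment BED output.

Internally every table is a pandas DataFrame with 0-based half-open
coordinates.  Variant tables use columns ``chrom``, ``pos`` (0-based),
``ref``, ``alt``, ``gt`` (one of ``hom_ref``/``het``/``hom_alt``/
``missing``), ``consequence`` (``non_synonymous``/``synonymous``/
``other`` or empty) and ``gene`` (may be empty).  VCF files carry the
annotation in INFO tags ``GENE`` and ``CSQ`` and a single sample with a
GT field; positions are converted to/from VCF's 1-based convention at
the file boundary.
"""

from __future__ import annotations

import pandas as pd

from .genome import GenomeBuild

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gt", "consequence", "gene"]

_GT_STRINGS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_vcf(variants: pd.DataFrame, path, build: GenomeBuild, sample: str = "sample") -> None:
    """Write a variant table as a minimal single-sample VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=autozygy\n")
        for name, length in build.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">\n')
        fh.write(
            '##INFO=<ID=CSQ,Number=1,Type=String,Description='
            '"Consequence: non_synonymous, synonymous or other">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        df = variants.sort_values(["chrom", "pos"], key=_chrom_sort_key(build))
        for row in df.itertuples(index=False):
            info = []
            gene = getattr(row, "gene", None)
            csq = getattr(row, "consequence", None)
            if isinstance(gene, str) and gene:
                info.append(f"GENE={gene}")
            if isinstance(csq, str) and csq:
                info.append(f"CSQ={csq}")
            gt = _GT_STRINGS[getattr(row, "gt", "het")]
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{getattr(row, 'ref', 'A')}\t"
                f"{getattr(row, 'alt', 'T')}\t.\tPASS\t{';'.join(info) or '.'}\t"
                f"GT\t{gt}\n"
            )


def _chrom_sort_key(build: GenomeBuild):
    order = {name: i for i, name in enumerate(build.names)}

    def key(col: pd.Series) -> pd.Series:
        if col.name == "chrom":
            return col.map(lambda c: order.get(c, len(order)))
        return col

    return key


def read_vcf(path) -> pd.DataFrame:
    """Read a single-sample VCF into the internal variant table."""
    from cyvcf2 import VCF

    gt_names = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}
    rows = []
    vcf = VCF(str(path))
    for v in vcf:
        gt = gt_names.get(int(v.gt_types[0]), "missing") if len(v.gt_types) else "missing"
        rows.append(
            (
                v.CHROM,
                v.POS - 1,
                v.REF,
                v.ALT[0] if v.ALT else ".",
                gt,
                v.INFO.get("CSQ") or "",
                v.INFO.get("GENE") or "",
            )
        )
    vcf.close()
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_bed(intervals: pd.DataFrame, path) -> None:
    """3-column BED (plus name/score/strand when a ``name`` column exists)."""
    cols = ["chrom", "start", "end"]
    df = intervals.copy()
    if "name" in df.columns:
        df["score"] = 0
        df["strand"] = "+"
        cols += ["name", "score", "strand"]
    df.sort_values(["chrom", "start"]).to_csv(
        path, sep="\t", header=False, index=False, columns=cols
    )


def read_bed(path) -> pd.DataFrame:
    """BED3/BED6 into a DataFrame (name column kept when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    keep = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df = df[keep]
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: malformed interval with end <= start")
    return df


def segments_to_bed(segments, path) -> None:
    """Write ROH segments (objects with chrom/start/end) as BED3+length."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.end - s.start}\n")


def read_segments_bed(path):
    from .roh import ROHSegment

    df = read_bed(path)
    return [
        ROHSegment(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
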