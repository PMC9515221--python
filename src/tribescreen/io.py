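"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* sgRNA count samples are named ``<CONDITION>_<replicate>`` (e.g. ``DMSO_1``);
  condition labels carry no underscores.
* Pileup tables are 1-based; annotation intervals are stored 0-based
  half-open internally (GTF is converted on read/write, BED is native).
* Pileup per-sample columns are ``<sample>.A/.C/.G/.T/.depth`` and the four
  base counts must sum to the stated depth.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from tribescreen.errors import ParseError, SchemaError

GUIDE_CLASSES = ("targeting", "non-targeting", "safe-harbor")

REGION_LABELS = ("5UTR", "CDS", "3UTR")

# tolerated spellings of UTR features in third-party GTFs
_GTF_REGION_ALIASES = {
    "five_prime_utr": "5UTR",
    "5utr": "5UTR",
    "five_prime_UTR": "5UTR",
    "cds": "CDS",
    "three_prime_utr": "3UTR",
    "3utr": "3UTR",
    "three_prime_UTR": "3UTR",
}


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# sgRNA library manifest and count matrix
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read an sgRNA library manifest TSV (guide_id, sequence, gene, class)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["guide_id", "sequence", "gene", "class"], f"manifest {path}")
    df["gene"] = df["gene"].replace("", None)
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    dup = df["guide_id"][df["guide_id"].duplicated()]
    if len(dup):
        raise ParseError(f"duplicate guide_id(s): {sorted(dup.unique())[:5]}")
    bad_class = set(df["class"]) - set(GUIDE_CLASSES)
    if bad_class:
        raise ParseError(f"unknown guide class(es): {sorted(bad_class)}")
    targeting = df["class"] == "targeting"
    if df.loc[targeting, "gene"].isna().any():
        bad = df.loc[targeting & df["gene"].isna(), "guide_id"]
        raise ParseError(f"targeting guides without a gene: {list(bad[:5])}")
    return df.reset_index(drop=True)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["gene"] = out["gene"].fillna("")
    out.to_csv(path, sep="\t", index=False)


_SAMPLE_RE = re.compile(r"^(?P<condition>[^_]+)_(?P<replicate>\d+)$")


def parse_samples(sample_names: list[str]) -> pd.DataFrame:
    """Split ``COND_rep`` sample names into a (sample, condition, replicate) table."""
    rows = []
    for name in sample_names:
        m = _SAMPLE_RE.match(name)
        if m is None:
            raise ParseError(
                f"sample name {name!r} does not follow the CONDITION_replicate pattern"
            )
        rows.append((name, m["condition"], int(m["replicate"])))
    return pd.DataFrame(rows, columns=["sample", "condition", "replicate"])


def read_counts(path: str | Path, manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read an sgRNA x sample count TSV, indexed by guide_id.

    When a manifest is given, count rows whose guide is absent from it are an
    error (the message lists the offending ids).
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["guide_id"], f"counts {path}")
    df = df.set_index("guide_id")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals[~vals.apply(lambda v: float(v).is_integer())]
            if len(bad):
                raise ParseError(
                    f"non-integer counts in sample {col!r}, e.g. guide "
                    f"{bad.index[0]!r} = {bad.iloc[0]!r}"
                )
            df[col] = vals.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ParseError("negative counts present")
    if manifest is not None:
        unknown = df.index.difference(manifest["guide_id"])
        if len(unknown):
            raise ParseError(f"count rows for guides absent from manifest: {list(unknown[:10])}")
    parse_samples(list(df.columns))  # validates naming
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="guide_id")


# ---------------------------------------------------------------------------
# Transcript annotation (GTF / BED12)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["gene", "transcript", "chrom", "strand", "region", "start", "end"]


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ANNOTATION_COLUMNS, "annotation")
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ParseError(
            f"malformed interval (end <= start) for transcript {bad['transcript']!r}: "
            f"[{bad['start']}, {bad['end']})"
        )
    bad_strand = set(df["strand"]) - {"+", "-"}
    if bad_strand:
        raise ParseError(f"unknown strand value(s): {sorted(bad_strand)}")
    bad_region = set(df["region"]) - set(REGION_LABELS)
    if bad_region:
        raise ParseError(f"unknown region label(s): {sorted(bad_region)}")
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


_ATTR_RE = re.compile(r'(\w+)\s+"?([^";]+)"?\s*(?:;|$)')


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read UTR/CDS features from a GTF into the internal annotation table.

    Attribute parsing tolerates quoted and unquoted values and both ``;`` and
    ``; `` separators.  Coordinates convert from 1-based inclusive to 0-based
    half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            region = _GTF_REGION_ALIASES.get(feature.lower().replace("'", ""))
            if region is None:
                continue
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            attr = dict(_ATTR_RE.findall(attrs))
            try:
                gene = attr.get("gene_id") or attr["gene_name"]
                transcript = attr.get("transcript_id") or gene
            except KeyError:
                raise ParseError(f"{path}:{lineno}: no gene_id/gene_name attribute") from None
            start0, end0 = int(start) - 1, int(end)
            if end0 <= start0:
                raise ParseError(f"{path}:{lineno}: malformed interval (end <= start)")
            rows.append((gene, transcript, chrom, strand, region, start0, end0))
    return validate_annotation(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


def write_gtf(annotation: pd.DataFrame, path: str | Path, source: str = "tribescreen") -> None:
    feature_of = {"5UTR": "five_prime_utr", "CDS": "CDS", "3UTR": "three_prime_utr"}
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            attrs = f'gene_id "{row.gene}"; transcript_id "{row.transcript}";'
            fh.write(
                f"{row.chrom}\t{source}\t{feature_of[row.region]}\t{row.start + 1}\t"
                f"{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_bed12(path: str | Path) -> pd.DataFrame:
    """Read BED12 transcripts, deriving UTR/CDS labels from the thick range.

    Exon block stretches left of ``thickStart`` are 5'UTR on the + strand and
    3'UTR on the - strand (and conversely on the right), matching the region
    model produced by :func:`read_gtf` on an equivalent annotation.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: malformed interval (end <= start)")
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            gene = name.split("|")[0]
            transcript = name.split("|")[1] if "|" in name else name
            for bs, sz in zip(starts, sizes):
                b0, b1 = start + bs, start + bs + sz
                # split the exon block at the thick (CDS) boundaries
                cuts = sorted({b0, b1, min(max(thick_start, b0), b1), min(max(thick_end, b0), b1)})
                for s, e in zip(cuts[:-1], cuts[1:]):
                    if e <= s:
                        continue
                    if e <= thick_start:
                        region = "5UTR" if strand == "+" else "3UTR"
                    elif s >= thick_end:
                        region = "3UTR" if strand == "+" else "5UTR"
                    else:
                        region = "CDS"
                    rows.append((gene, transcript, chrom, strand, region, s, e))
    return validate_annotation(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


def write_bed12(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write one BED12 line per transcript (blocks = annotated intervals)."""
    with open(path, "w") as fh:
        for (gene, transcript), grp in annotation.groupby(["gene", "transcript"], sort=True):
            grp = grp.sort_values("start")
            chrom = grp["chrom"].iloc[0]
            strand = grp["strand"].iloc[0]
            start, end = int(grp["start"].min()), int(grp["end"].max())
            cds = grp[grp["region"] == "CDS"]
            thick_start = int(cds["start"].min()) if len(cds) else start
            thick_end = int(cds["end"].max()) if len(cds) else start
            # merge touching intervals into exon blocks
            blocks: list[list[int]] = []
            for row in grp.itertuples(index=False):
                if blocks and row.start <= blocks[-1][1]:
                    blocks[-1][1] = max(blocks[-1][1], row.end)
                else:
                    blocks.append([int(row.start), int(row.end)])
            sizes = ",".join(str(b1 - b0) for b0, b1 in blocks)
            offsets = ",".join(str(b0 - start) for b0, b1 in blocks)
            fh.write(
                f"{chrom}\t{start}\t{end}\t{gene}|{transcript}\t0\t{strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(blocks)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Pileup, SNP list, dose matrix, DE table
# ---------------------------------------------------------------------------

def pileup_samples(df: pd.DataFrame) -> list[str]:
    """Sample names inferred from ``<sample>.depth`` pileup columns."""
    return [c[: -len(".depth")] for c in df.columns if c.endswith(".depth")]


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read a per-site nucleotide pileup TSV (1-based positions).

    Each sample contributes A/C/G/T count columns plus a stated depth; rows
    whose base counts do not sum to the stated depth are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "pos", "ref"], f"pileup {path}")
    samples = pileup_samples(df)
    if not samples:
        raise SchemaError(f"pileup {path}: no '<sample>.depth' columns found")
    for s in samples:
        cols = [f"{s}.{b}" for b in "ACGT"]
        _require_columns(df, cols + [f"{s}.depth"], f"pileup {path}")
        total = df[cols].sum(axis=1)
        bad = total != df[f"{s}.depth"]
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"pileup {path} row {i + 2}: base counts for sample {s!r} sum to "
                f"{int(total.iloc[i])} but stated depth is {int(df[f'{s}.depth'].iloc[i])}"
            )
    if (df["pos"] < 1).any():
        raise ParseError(f"pileup {path}: positions must be 1-based (>= 1)")
    return df


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_snp_list(path: str | Path) -> set[tuple[str, int]]:
    """Read known-SNP positions (chrom, 1-based pos) into a set."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["chrom", "pos"], f"snp list {path}")
    return {(str(c), int(p)) for c, p in zip(df["chrom"], df["pos"])}


def write_snp_list(snps: set[tuple[str, int]], path: str | Path) -> None:
    df = pd.DataFrame(sorted(snps), columns=["chrom", "pos"])
    df.to_csv(path, sep="\t", index=False)


def read_dose_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format checkerboard viability CSV."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["drug_a_dose", "drug_b_dose", "replicate", "viability"], f"dose csv {path}"
    )
    if (df[["drug_a_dose", "drug_b_dose"]].to_numpy() < 0).any():
        raise ParseError(f"dose csv {path}: negative doses present")
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression summary TSV (gene, log2fc, padj, fpkm[, rpk])."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "log2fc", "padj", "fpkm"], f"DE table {path}")
    return df


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) records as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
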