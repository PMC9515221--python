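"""Downstream synthesis: DE-table threshold filters, three-way gene-set
overlap, and the CDF-shift comparison of target expression changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from tribescreen.errors import SchemaError

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene: str) -> str:
    """Upper-case and strip a trailing Ensembl-style version suffix."""
    return _VERSION_SUFFIX.sub("", str(gene).strip()).upper()


def filter_de(
    table: pd.DataFrame,
    fpkm_min: float = 1.0,
    fold_min: float = 2.0,
    padj_max: float = 0.05,
    rpk_min: float | None = 500.0,
) -> tuple[set[str], set[str]]:
    """Differential-expression threshold filter.

    Keeps genes with FPKM above ``fpkm_min`` and adjusted p below
    ``padj_max`` whose fold change exceeds ``fold_min`` (|log2FC| >=
    log2(fold_min)); returns (up, down) gene-id sets, case-normalized.  The
    RPK prefilter applies only when the table carries an ``rpk`` column.
    """
    for col in ("gene", "log2fc", "padj", "fpkm"):
        if col not in table.columns:
            raise SchemaError(f"DE table missing column {col!r}")
    lfc_min = np.log2(fold_min)
    keep = (table["fpkm"] > fpkm_min) & (table["padj"] < padj_max)
    if rpk_min is not None and "rpk" in table.columns:
        keep &= table["rpk"] >= rpk_min
    up = table.loc[keep & (table["log2fc"] >= lfc_min), "gene"]
    down = table.loc[keep & (table["log2fc"] <= -lfc_min), "gene"]
    return ({normalize_gene_id(g) for g in up}, {normalize_gene_id(g) for g in down})


@dataclass
class OverlapResult:
    """All regions of a three-set Venn decomposition.

    ``regions`` maps membership keys like ``"AB"`` (in sets A and B only) to
    sorted member lists; ``"ABC"`` is the triple intersection.
    """

    names: tuple[str, str, str]
    regions: dict[str, list[str]]

    @property
    def triple(self) -> list[str]:
        return self.regions["ABC"]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}


def three_way_overlap(
    set_a, set_b, set_c, names: tuple[str, str, str] = ("A", "B", "C")
) -> OverlapResult:
    """Exact three-set Venn decomposition with case-normalized gene ids."""
    a = {normalize_gene_id(g) for g in set_a}
    b = {normalize_gene_id(g) for g in set_b}
    c = {normalize_gene_id(g) for g in set_c}
    if not (a | b | c):
        raise ValueError("union of the three sets is empty")
    regions: dict[str, list[str]] = {}
    for in_a, in_b, in_c in product((True, False), repeat=3):
        if not (in_a or in_b or in_c):
            continue
        members = set.intersection(*(
            s if flag else (a | b | c) - s
            for s, flag in ((a, in_a), (b, in_b), (c, in_c))
        ))
        key = "".join(k for k, flag in zip("ABC", (in_a, in_b, in_c)) if flag)
        regions[key] = sorted(members)
    return OverlapResult(names=tuple(names), regions=regions)


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step-function ECDF as (sorted values, cumulative probabilities)."""
    x = np.sort(np.asarray(values, dtype=float))
    return x, np.arange(1, len(x) + 1) / len(x)


def cdf_shift_test(values_targets, values_background):
    """Two-sample Kolmogorov-Smirnov comparison of expression changes.

    Returns (KS statistic, two-sided asymptotic p, target ECDF, background
    ECDF); the ECDFs are (x, F(x)) pairs ready for a CDF-shift plot.
    """
    t = np.asarray(values_targets, dtype=float)
    b = np.asarray(values_background, dtype=float)
    if len(t) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two values")
    res = stats.ks_2samp(t, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue), ecdf(t), ecdf(b)
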