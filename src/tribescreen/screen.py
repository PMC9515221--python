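"""Pooled CRISPR screen statistics.

Pipeline: TMM between-sample normalisation of sgRNA counts, per-guide
log2 fold changes on the CPM scale, a correlation-adjusted mean-rank gene
test (Wilcoxon-Mann-Whitney of a gene's guides against all other guides,
variance inflated by ``VIF = 1 + (m - 1) * rho`` for inter-guide
correlation ``rho``), essential-gene exclusion, resistance/sensitizer hit
calling, and deterministic validation-library design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tribescreen.errors import ContrastError, DesignError, NormalizationError
from tribescreen.io import parse_samples


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th percentile of library-size-
    scaled counts is closest to the across-sample mean of those percentiles.
    Per guide, M (log2 ratio) and A (average log2 abundance) are computed on
    scaled counts; guides zero in either sample are excluded; values are
    doubly trimmed (``trim_m`` on each M tail, ``trim_a`` on each A tail) and
    the retained M values are combined by a precision-weighted mean whose
    exponential is the factor.
    """
    if counts.shape[1] < 2:
        raise NormalizationError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0]
        raise NormalizationError(f"sample(s) with zero total counts: {list(bad)}")
    scaled = x / lib
    uq = np.quantile(scaled, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    xr, nr = x[:, ref], lib[ref]
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        xk, nk = x[:, k], lib[k]
        keep = (xk > 0) & (xr > 0)
        if not keep.any():
            raise NormalizationError(
                f"sample {counts.columns[k]!r} shares no nonzero guides with the "
                f"reference {counts.columns[ref]!r}"
            )
        pk, pr = xk[keep] / nk, xr[keep] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # asymptotic (delta-method) variance of M -> precision weights
        w = (nk - xk[keep]) / (nk * xk[keep]) + (nr - xr[keep]) / (nr * xr[keep])
        w = np.maximum(w, 1e-12)  # a guide taking a whole library would zero its variance

        n = m.size
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        retained = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not retained.any():
            factors[k] = 1.0
            continue
        inv_w = 1.0 / w[retained]
        factors[k] = 2 ** (np.sum(inv_w * m[retained]) / np.sum(inv_w))

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    return counts / lib * 1e6


# ---------------------------------------------------------------------------
# Fold changes and the rank test
# ---------------------------------------------------------------------------

def guide_log2fc(
    counts: pd.DataFrame,
    factors: pd.Series,
    contrast: tuple[str, str],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-guide log2 fold change of mean normalized CPM for a contrast.

    ``contrast = (numerator_condition, denominator_condition)``; the
    denominator conditions may be several, joined by ``+`` (e.g.
    ``"DMSO+DRUG"`` pools both end-of-experiment arms against T0).
    Returns a frame with per-condition mean CPM, ``log2fc`` and its midrank.
    """
    samples = parse_samples(list(counts.columns))
    norm = cpm(counts, factors)

    def condition_mean(cond_spec: str) -> pd.Series:
        conds = cond_spec.split("+")
        missing = [c for c in conds if c not in set(samples["condition"])]
        if missing:
            raise ContrastError(f"condition(s) {missing} absent from samples")
        cols = samples.loc[samples["condition"].isin(conds), "sample"]
        return norm[cols].mean(axis=1)

    num, den = contrast
    mean_num, mean_den = condition_mean(num), condition_mean(den)
    lfc = np.log2((mean_num + pseudocount) / (mean_den + pseudocount))
    out = pd.DataFrame(
        {
            "guide_id": counts.index,
            f"cpm_{num}": mean_num.to_numpy(),
            f"cpm_{den}": mean_den.to_numpy(),
            "log2fc": lfc.to_numpy(),
        }
    )
    out["rank"] = stats.rankdata(out["log2fc"])
    return out


def estimate_guide_correlation(
    counts: pd.DataFrame, manifest: pd.DataFrame, default: float = 0.01
) -> float:
    """Mean within-gene correlation of CPM residuals across >= 3 replicates.

    With fewer than three samples the correlation is inestimable and the
    small-sample ``default`` is returned.
    """
    if counts.shape[1] < 3:
        return default
    logcpm = np.log2(cpm(counts) + 0.5)
    resid = logcpm.sub(logcpm.mean(axis=1), axis=0)
    gene_of = manifest.set_index("guide_id")["gene"]
    rs = []
    for _gene, grp in resid.groupby(gene_of.reindex(resid.index)):
        if len(grp) < 2:
            continue
        c = np.corrcoef(grp.to_numpy())
        iu = np.triu_indices_from(c, k=1)
        rs.extend(c[iu][np.isfinite(c[iu])])
    if not rs:
        return default
    return float(np.clip(np.mean(rs), 0.0, 0.99))


def camera_rank_test(
    guide_stats: pd.DataFrame,
    grouping: dict[str, list[str]],
    inter_guide_corr: float = 0.01,
) -> pd.DataFrame:
    """Correlation-adjusted Wilcoxon-Mann-Whitney rank test per gene.

    Each gene's guides are compared against all other guides by their
    log2 fold-change midranks.  The rank-sum statistic is standardized with
    the tie-corrected two-sample variance inflated by
    ``VIF = 1 + (m - 1) * inter_guide_corr``; two-sided p from the normal
    approximation.
    """
    lfc = guide_stats.set_index("guide_id")["log2fc"]
    n = len(lfc)
    ranks = pd.Series(stats.rankdata(lfc.to_numpy()), index=lfc.index)

    # tie correction term shared by every gene: sum(t^3 - t) over tie groups
    _, tie_counts = np.unique(lfc.to_numpy(), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))

    rows = []
    for gene, guides in grouping.items():
        r = ranks.reindex(guides).dropna()
        m = len(r)
        if m == 0:
            continue
        if m >= n:
            raise ValueError(f"gene {gene!r} groups all {n} guides; no background left")
        mu = m * (n + 1) / 2.0
        var = m * (n - m) / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        vif = 1.0 + (m - 1) * inter_guide_corr
        z = (r.sum() - mu) / np.sqrt(var * vif)
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((gene, m, z, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["gene", "n_guides", "z", "p"])


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Gene-level summaries and hit calling
# ---------------------------------------------------------------------------

def gene_results(
    guide_stats: pd.DataFrame,
    manifest: pd.DataFrame,
    inter_guide_corr: float = 0.01,
    lfc_thresh: float = 2.0,
    direction_only: bool = False,
) -> pd.DataFrame:
    """Per-gene screen summary: median guide log2FC, rank-test z/p/padj and
    the count of concordant guides.

    A guide is concordant when its log2FC exceeds ``lfc_thresh`` in the
    direction of the gene's median log2FC; with ``direction_only`` the
    magnitude cutoff is dropped and mere sign agreement counts.
    Non-targeting and safe-harbor guides contribute to the rank background
    but receive no gene row.
    """
    targeting = manifest[manifest["class"] == "targeting"]
    grouping = targeting.groupby("gene")["guide_id"].apply(list).to_dict()
    rank_res = camera_rank_test(guide_stats, grouping, inter_guide_corr)
    rank_res["padj"] = bh_adjust(rank_res["p"])

    lfc = guide_stats.set_index("guide_id")["log2fc"]
    med, conc = {}, {}
    for gene, guides in grouping.items():
        g = lfc.reindex(guides).dropna()
        med[gene] = float(g.median())
        direction = np.sign(med[gene]) or 1.0
        if direction_only:
            conc[gene] = int((np.sign(g) == direction).sum())
        else:
            conc[gene] = int((g * direction > lfc_thresh).sum())
    rank_res["lfc"] = rank_res["gene"].map(med)
    rank_res["n_concordant"] = rank_res["gene"].map(conc)
    rank_res["class"] = "none"
    return rank_res[["gene", "n_guides", "lfc", "z", "p", "padj", "n_concordant", "class"]]


def call_essential(
    results: pd.DataFrame, fdr_max: float = 0.05, lfc_max: float = -2.0
) -> set[str]:
    """Essential genes: depleted from every arm relative to T0.

    ``results`` must come from an end-of-experiment vs T0 contrast; genes with
    ``padj < fdr_max`` and median log2FC below ``lfc_max`` are flagged.
    """
    hit = (results["padj"] < fdr_max) & (results["lfc"] < lfc_max)
    return set(results.loc[hit, "gene"])


def call_hits(
    results: pd.DataFrame,
    essential: set[str],
    adjp_max: float = 0.1,
    lfc_thresh: float = 2.0,
    min_concordant: int = 3,
) -> pd.DataFrame:
    """Classify genes on the drug-vs-vehicle contrast.

    Essential genes are excluded from hit calling (their class stays
    ``essential``).  A sensitizer depletes under drug (padj < ``adjp_max``,
    median log2FC < -``lfc_thresh``, >= ``min_concordant`` guides concordant);
    a resistance gene enriches symmetrically.
    """
    out = results.copy()
    out["class"] = "none"
    is_ess = out["gene"].isin(essential)
    out.loc[is_ess, "class"] = "essential"
    sig = (out["padj"] < adjp_max) & (out["n_concordant"] >= min_concordant) & ~is_ess
    out.loc[sig & (out["lfc"] < -lfc_thresh), "class"] = "sensitizer"
    out.loc[sig & (out["lfc"] > lfc_thresh), "class"] = "resistance"
    return out


def design_validation_library(
    hit_genes: list[str],
    source_manifest: pd.DataFrame,
    n_nontargeting: int = 200,
    n_safe_harbor: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Focused validation library: every source guide of each hit gene plus
    deterministically sampled non-targeting and safe-harbor controls.

    Mirrors the published validation design: 316 + 89 hit genes at 4 guides
    each plus 200 + 200 controls gives a 2020-guide library over 405 genes.
    """
    rng = np.random.default_rng(seed)
    targeting = source_manifest[source_manifest["class"] == "targeting"]
    present = set(targeting["gene"])
    missing = [g for g in hit_genes if g not in present]
    if missing:
        raise DesignError(f"hit gene(s) absent from source manifest: {missing[:10]}")
    parts = [targeting[targeting["gene"].isin(set(hit_genes))]]
    for cls, want in (("non-targeting", n_nontargeting), ("safe-harbor", n_safe_harbor)):
        pool = source_manifest[source_manifest["class"] == cls]
        if len(pool) < want:
            raise DesignError(
                f"source manifest has only {len(pool)} {cls} guides, {want} requested"
            )
        pick = rng.choice(len(pool), size=want, replace=False)
        parts.append(pool.iloc[np.sort(pick)])
    return pd.concat(parts, ignore_index=True)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
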