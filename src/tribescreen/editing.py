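"""HyperTRIBE edit-site detection and beta-binomial differential editing.

An RNA-binding protein fused to a hyperactive ADAR deaminase marks its
binding sites as A-to-I(G) edits readable from RNA-seq.  Candidate sites
are restricted to the deamination signature consistent with transcription:
A-to-G on plus-strand transcripts, T-to-C on minus-strand transcripts;
known SNP positions are excluded.  Differential editing between conditions
is tested per site with a beta-binomial likelihood-ratio test (shared
intra-class correlation under both hypotheses, chi-square with 1 df),
followed by Benjamini-Hochberg correction and the significance filters
adjusted p < 0.05, |diff.frequency| >= 0.1 and host-gene FPKM >= 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from tribescreen.errors import FitError
from tribescreen.io import parse_samples, pileup_samples
from tribescreen.screen import bh_adjust

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Beta-binomial likelihood
# ---------------------------------------------------------------------------

_MU_EPS = 1e-8
_RHO_EPS = 1e-9


@dataclass(frozen=True)
class BetaBinomFit:
    """Maximum-likelihood beta-binomial fit.

    mu is the mean edit frequency, rho the intra-class correlation
    (overdispersion); rho = 0 collapses to the binomial.
    """

    mu: float
    rho: float
    loglik: float


def _loglik_core(alt, depth, comb, mu: float, rho: float) -> float:
    # comb = log C(depth, alt), precomputed once per fit
    mu = min(max(mu, _MU_EPS), 1.0 - _MU_EPS)
    if rho < _RHO_EPS:
        return float(np.sum(comb + alt * np.log(mu) + (depth - alt) * np.log1p(-mu)))
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return float(np.sum(comb + special.betaln(alt + a, depth - alt + b) - special.betaln(a, b)))


def _log_comb(alt, depth):
    return (special.gammaln(depth + 1) - special.gammaln(alt + 1)
            - special.gammaln(depth - alt + 1))


def betabinom_loglik(alt: np.ndarray, depth: np.ndarray, mu: float, rho: float) -> float:
    """Log-likelihood of (alt, depth) pairs under BetaBinomial(mu, rho).

    Parameterised by mean and intra-class correlation:
    alpha = mu(1-rho)/rho, beta = (1-mu)(1-rho)/rho.  The rho -> 0 limit is
    evaluated as the exact binomial log-likelihood.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    return _loglik_core(alt, depth, _log_comb(alt, depth), mu, rho)


def _expit_clipped(t: float, eps: float) -> float:
    return float(np.clip(special.expit(t), eps, 1.0 - eps))


_NM_OPTS = {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 300}


def fit_betabinom(alt, depth, max_rho: float = 0.999) -> BetaBinomFit:
    """Maximum-likelihood (mu, rho) for one group of (alt, depth) pairs.

    Optimises on the (logit mu, logit rho) scale and compares against the
    rho = 0 binomial boundary, whose mean MLE is the pooled frequency.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if depth.sum() <= 0:
        raise FitError("cannot fit beta-binomial: all depths are zero")
    comb = _log_comb(alt, depth)
    pooled = float(np.clip(alt.sum() / depth.sum(), _MU_EPS, 1.0 - _MU_EPS))

    # binomial boundary candidate
    best_mu, best_rho = pooled, 0.0
    best_ll = _loglik_core(alt, depth, comb, pooled, 0.0)

    def nll(t):
        mu = _expit_clipped(t[0], _MU_EPS)
        rho = _expit_clipped(t[1], 1e-6) * max_rho
        return -_loglik_core(alt, depth, comb, mu, rho)

    res = optimize.minimize(nll, x0=[special.logit(pooled), special.logit(0.05)],
                            method="Nelder-Mead", options=_NM_OPTS)
    if -res.fun > best_ll:
        best_ll = -res.fun
        best_mu = _expit_clipped(res.x[0], _MU_EPS)
        best_rho = _expit_clipped(res.x[1], 1e-6) * max_rho
    return BetaBinomFit(mu=best_mu, rho=best_rho, loglik=best_ll)


def _fit_two_groups(alt_a, depth_a, alt_b, depth_b) -> tuple[float, float, float, float]:
    """Alternative-hypothesis fit: group means mu_a, mu_b with shared rho.

    Returns (mu_a, mu_b, rho, loglik)."""
    comb_a, comb_b = _log_comb(alt_a, depth_a), _log_comb(alt_b, depth_b)
    pa = float(np.clip(alt_a.sum() / depth_a.sum(), _MU_EPS, 1 - _MU_EPS))
    pb = float(np.clip(alt_b.sum() / depth_b.sum(), _MU_EPS, 1 - _MU_EPS))

    best = (pa, pb, 0.0, _loglik_core(alt_a, depth_a, comb_a, pa, 0.0)
            + _loglik_core(alt_b, depth_b, comb_b, pb, 0.0))

    def nll(t):
        mu_a = _expit_clipped(t[0], _MU_EPS)
        mu_b = _expit_clipped(t[1], _MU_EPS)
        rho = _expit_clipped(t[2], 1e-6) * 0.999
        return -(_loglik_core(alt_a, depth_a, comb_a, mu_a, rho)
                 + _loglik_core(alt_b, depth_b, comb_b, mu_b, rho))

    res = optimize.minimize(
        nll, x0=[special.logit(pa), special.logit(pb), special.logit(0.05)],
        method="Nelder-Mead", options=_NM_OPTS)
    if -res.fun > best[3]:
        best = (_expit_clipped(res.x[0], _MU_EPS), _expit_clipped(res.x[1], _MU_EPS),
                _expit_clipped(res.x[2], 1e-6) * 0.999, -res.fun)
    return best


# ---------------------------------------------------------------------------
# Edit-site detection
# ---------------------------------------------------------------------------

def _transcript_lengths(annotation: pd.DataFrame) -> pd.Series:
    widths = annotation["end"] - annotation["start"]
    return widths.groupby(annotation["transcript"]).sum()


def detect_edit_sites(
    pileup: pd.DataFrame,
    annotation: pd.DataFrame,
    snp_set: set[tuple[str, int]],
    min_depth: int = 10,
) -> pd.DataFrame:
    """Call candidate edit sites from a pileup table.

    A position is retained when it falls inside an annotated transcript and
    carries the strand-consistent deamination signature — reference A with
    G-supporting reads on a plus-strand gene, reference T with C reads on a
    minus-strand gene — is not a known SNP, and reaches ``min_depth`` in at
    least one sample.  Positions covered by transcripts of conflicting
    strands are excluded as ambiguous.

    Returns a frame with site coordinates, gene/region annotation and
    per-sample ``<sample>.alt`` / ``<sample>.depth`` columns; a tally of the
    filtering steps is attached as ``.attrs['filter_report']``.
    """
    samples = pileup_samples(pileup)
    tx_len = _transcript_lengths(annotation)
    report = {"input": len(pileup), "outside_annotation": 0, "ambiguous_strand": 0,
              "wrong_signature": 0, "snp": 0, "low_depth": 0, "kept": 0}

    ann = annotation.assign(tx_len=annotation["transcript"].map(tx_len))
    ann_by_chrom = {
        c: (g["start"].to_numpy(), g["end"].to_numpy(), g.reset_index(drop=True))
        for c, g in ann.groupby("chrom")
    }
    base_counts = {b: pileup[[f"{s}.{b}" for s in samples]].to_numpy() for b in ("G", "C")}
    depths = pileup[[f"{s}.depth" for s in samples]].to_numpy()
    chroms = pileup["chrom"].to_numpy()
    positions = pileup["pos"].to_numpy()
    refs = pileup["ref"].to_numpy()

    rows = []
    for i in range(len(pileup)):
        chrom, pos, ref = chroms[i], int(positions[i]), refs[i]
        entry = ann_by_chrom.get(chrom)
        if entry is None:
            report["outside_annotation"] += 1
            continue
        starts, ends, grp = entry
        pos0 = pos - 1
        hit_idx = np.flatnonzero((starts <= pos0) & (pos0 < ends))
        if hit_idx.size == 0:
            report["outside_annotation"] += 1
            continue
        hit = grp.iloc[hit_idx]
        strands = set(hit["strand"])
        if len(strands) > 1:
            report["ambiguous_strand"] += 1
            continue
        strand = strands.pop()
        alt_base, ref_needed = ("G", "A") if strand == "+" else ("C", "T")
        alt = base_counts[alt_base][i]
        depth = depths[i]
        if ref != ref_needed or alt.sum() == 0:
            report["wrong_signature"] += 1
            continue
        if (chrom, pos) in snp_set:
            report["snp"] += 1
            continue
        if not (depth >= min_depth).any():
            report["low_depth"] += 1
            continue
        # region label from the longest transcript covering the site
        longest = hit.iloc[int(np.argmax(hit["tx_len"].to_numpy()))]
        rec = {"chrom": chrom, "pos": pos, "strand": strand, "ref": ref,
               "gene": longest["gene"], "region": longest["region"]}
        for s, a, d in zip(samples, alt, depth):
            rec[f"{s}.alt"] = int(a)
            rec[f"{s}.depth"] = int(d)
        rows.append(rec)
        report["kept"] += 1

    sites = pd.DataFrame(rows)
    sites.attrs["filter_report"] = report
    return sites


# ---------------------------------------------------------------------------
# Differential editing
# ---------------------------------------------------------------------------

def _loglik_rows(alt, depth, comb, mu, rho: float) -> np.ndarray:
    """Per-site log-likelihood over a sites x samples matrix, per-site mu."""
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)[:, None]
    if rho < _RHO_EPS:
        return np.sum(comb + alt * np.log(mu) + (depth - alt) * np.log1p(-mu), axis=1)
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return np.sum(comb + special.betaln(alt + a, depth - alt + b) - special.betaln(a, b), axis=1)


def estimate_common_dispersion(alt_a, dep_a, alt_b, dep_b) -> float:
    """Pooled intra-class correlation across all sites.

    Maximises a Cox-Reid adjusted profile likelihood of a single rho shared
    by every site under the two-group-means model: each site keeps its own
    condition means (plugged in as pooled frequencies, so genuinely
    differential sites do not inflate the estimate), and half the summed
    log observed information of those means is subtracted to undo the
    downward bias that fitting two means per site from a handful of
    replicates otherwise induces.  A pooled estimate over thousands of
    sites is what keeps the per-site likelihood-ratio test calibrated.
    """
    groups = []
    for alt, dep in ((alt_a, dep_a), (alt_b, dep_b)):
        with np.errstate(invalid="ignore"):
            mu = alt.sum(axis=1) / dep.sum(axis=1)
        mu = np.clip(np.nan_to_num(mu, nan=_MU_EPS), _MU_EPS, 1 - _MU_EPS)
        groups.append((alt, dep, _log_comb(alt, dep), mu))

    def neg_apl(t):
        rho = special.expit(t) * 0.999
        h = 1e-4
        total = 0.0
        for alt, dep, comb, mu in groups:
            f0 = _loglik_rows(alt, dep, comb, mu, rho)
            fp = _loglik_rows(alt, dep, comb, np.minimum(mu + h, 1 - _MU_EPS), rho)
            fm = _loglik_rows(alt, dep, comb, np.maximum(mu - h, _MU_EPS), rho)
            info = np.maximum(-(fp - 2 * f0 + fm) / h**2, 1e-12)
            total += f0.sum() - 0.5 * np.sum(np.log(info))
        return -total

    res = optimize.minimize_scalar(neg_apl, bounds=(-14.0, 0.0), method="bounded",
                                   options={"xatol": 1e-6})
    rho = float(special.expit(res.x) * 0.999)
    if neg_apl(-30.0) <= res.fun:  # rho ~ 0 boundary fits at least as well
        return 0.0
    return rho


def _profile_mu_loglik(alt, depth, comb, rho: float) -> float:
    """Max log-likelihood over mu with rho fixed (1-D bounded search)."""
    res = optimize.minimize_scalar(
        lambda t: -_loglik_core(alt, depth, comb, _expit_clipped(t, _MU_EPS), rho),
        bounds=(-16.0, 16.0), method="bounded", options={"xatol": 1e-7})
    return -res.fun


def differential_editing(
    sites: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    fpkm: pd.DataFrame | None = None,
    dispersion: str = "pooled",
) -> pd.DataFrame:
    """Beta-binomial likelihood-ratio test of edit frequency, B vs A, per site.

    Null: one mean frequency per site; alternative: condition-specific
    means; both hypotheses share the same dispersion, so the LRT has one
    degree of freedom (chi-square reference).  With ``dispersion="pooled"``
    (default) a single intra-class correlation is estimated across all
    sites under the two-group model and held fixed per site — a moderated
    estimate that keeps the test calibrated with few replicates.
    ``dispersion="per-site"`` re-estimates rho within each site (the purely
    site-local variant; anticonservative below ~10 replicates).

    BH correction is applied over all tested sites; ``diff_frequency`` is
    pooled frequency(B) - pooled frequency(A).  Sites with zero total depth
    in either condition are skipped (flagged in ``.attrs['skipped']``).

    ``fpkm``, if given, is a gene x condition frame whose per-condition
    values are merged onto the results as ``fpkm_a`` / ``fpkm_b``.
    """
    if dispersion not in {"pooled", "per-site"}:
        raise ValueError(f"dispersion must be 'pooled' or 'per-site', got {dispersion!r}")
    alt_a = sites[[f"{s}.alt" for s in samples_a]].to_numpy(dtype=float)
    dep_a = sites[[f"{s}.depth" for s in samples_a]].to_numpy(dtype=float)
    alt_b = sites[[f"{s}.alt" for s in samples_b]].to_numpy(dtype=float)
    dep_b = sites[[f"{s}.depth" for s in samples_b]].to_numpy(dtype=float)

    testable = (dep_a.sum(axis=1) > 0) & (dep_b.sum(axis=1) > 0)
    skipped = sites.loc[~testable, ["chrom", "pos"]]
    idx = np.flatnonzero(testable)

    rho_common = None
    if dispersion == "pooled" and len(idx):
        rho_common = estimate_common_dispersion(alt_a[idx], dep_a[idx], alt_b[idx], dep_b[idx])

    rows = []
    for i in idx:
        aa, da, ab, db = alt_a[i], dep_a[i], alt_b[i], dep_b[i]
        alt_all = np.concatenate([aa, ab])
        dep_all = np.concatenate([da, db])
        if dispersion == "pooled":
            comb_a, comb_b = _log_comb(aa, da), _log_comb(ab, db)
            ll_null = _profile_mu_loglik(alt_all, dep_all, np.concatenate([comb_a, comb_b]),
                                         rho_common)
            ll_alt = (_profile_mu_loglik(aa, da, comb_a, rho_common)
                      + _profile_mu_loglik(ab, db, comb_b, rho_common))
        else:
            ll_null = fit_betabinom(alt_all, dep_all).loglik
            _mu_a, _mu_b, _rho, ll_alt = _fit_two_groups(aa, da, ab, db)
        lrt = max(2.0 * (ll_alt - ll_null), 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        freq_a = aa.sum() / da.sum()
        freq_b = ab.sum() / db.sum()
        rows.append((i, freq_a, freq_b, freq_b - freq_a, lrt, p))

    res = pd.DataFrame(rows, columns=["_i", "freq_a", "freq_b", "diff_frequency", "lrt", "p"])
    out = sites.iloc[res["_i"]][["chrom", "pos", "strand", "ref", "gene", "region"]].reset_index(drop=True)
    out = pd.concat([out, res.drop(columns="_i").reset_index(drop=True)], axis=1)
    out["padj"] = bh_adjust(out["p"]) if len(out) else out.get("p")
    if fpkm is not None:
        cond_a = parse_samples(samples_a)["condition"].iloc[0]
        cond_b = parse_samples(samples_b)["condition"].iloc[0]
        out["fpkm_a"] = out["gene"].map(fpkm[cond_a])
        out["fpkm_b"] = out["gene"].map(fpkm[cond_b])
    out.attrs["skipped"] = skipped
    out.attrs["common_dispersion"] = rho_common
    return out


def compute_fpkm(
    gene_counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM per gene and sample: count / (length/1e3 * libsize/1e6)."""
    lengths = lengths.reindex(gene_counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every gene needs a positive transcript length")
    if library_sizes is None:
        library_sizes = gene_counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return gene_counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


def condition_fpkm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Average per-sample FPKM into a gene x condition frame."""
    meta = parse_samples(list(fpkm.columns))
    return fpkm.T.groupby(meta.set_index("sample")["condition"]).mean().T


def filter_significant(
    tests: pd.DataFrame,
    padj_max: float = 0.05,
    diff_cut: float = 0.1,
    direction: str = "loss",
    fpkm_min: float = 5.0,
) -> tuple[pd.DataFrame, int]:
    """Apply the significance filters to a differential-editing table.

    ``loss`` keeps diff_frequency <= -diff_cut (binding lost in condition B),
    ``gain`` keeps >= +diff_cut.  The FPKM criterion is evaluated on the
    condition with the higher expression, keeping sites whose host gene is
    expressed in at least one arm.  Returns the retained rows and the number
    of distinct host genes among them.
    """
    if direction not in {"loss", "gain"}:
        raise ValueError(f"direction must be 'loss' or 'gain', got {direction!r}")
    keep = tests["padj"] < padj_max
    if direction == "loss":
        keep &= tests["diff_frequency"] <= -diff_cut
    else:
        keep &= tests["diff_frequency"] >= diff_cut
    if fpkm_min > 0 and "fpkm_a" in tests.columns:
        keep &= tests[["fpkm_a", "fpkm_b"]].max(axis=1) >= fpkm_min
    retained = tests[keep].reset_index(drop=True)
    return retained, retained["gene"].nunique()


# ---------------------------------------------------------------------------
# Site annotation summaries and motif windows
# ---------------------------------------------------------------------------

def utr3_fraction(sites: pd.DataFrame) -> float:
    """Fraction of sites annotated to the 3'UTR."""
    if len(sites) == 0:
        raise ValueError("no sites")
    return float((sites["region"] == "3UTR").mean())


def extract_motif_windows(
    sites: pd.DataFrame,
    genome_fasta: str,
    flank: int = 100,
) -> list[tuple[str, str, bool]]:
    """Genomic sequence windows of ±``flank`` nt around each edit site.

    Each record is (site id, sequence, truncated flag); minus-strand windows
    are reverse-complemented so the edited base reads as A at the window
    centre.  Windows clipped by contig ends are flagged truncated.
    """
    from pyfaidx import Fasta

    genome = Fasta(genome_fasta)
    records = []
    for row in sites.itertuples(index=False):
        contig = genome[row.chrom]
        pos0 = row.pos - 1
        lo, hi = pos0 - flank, pos0 + flank + 1
        truncated = lo < 0 or hi > len(contig)
        lo, hi = max(lo, 0), min(hi, len(contig))
        seq = str(contig[lo:hi]).upper()
        if row.strand == "-":
            seq = reverse_complement(seq)
        site_id = f"{row.chrom}:{row.pos}:{row.strand}"
        records.append((site_id, seq, truncated))
    return records
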