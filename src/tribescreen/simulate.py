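"""Synthetic data generators with the statistical structure each pipeline
stage assumes, plus ground-truth labels for recovery tests.

Three generators cover the three experimental designs:

* :func:`simulate_screen` — a pooled knockout screen in the Brunello mould
  (4 guides/gene plus non-targeting and safe-harbor controls) with a T0
  reference arm and DMSO/DRUG end-of-experiment arms sequenced to a fixed
  depth; counts are negative-binomial around log-normal guide baselines with
  multiplicative effects planted per gene class (essential genes deplete in
  both treated arms, sensitizers deplete and resistance genes enrich under
  drug only).
* :func:`simulate_hypertribe` — per-site nucleotide pileups over a synthetic
  transcriptome: beta-binomial edit counts at annotated 5'UTR/CDS/3'UTR
  positions with the strand-consistent A-to-G / T-to-C signature, planted
  condition effects on a target subset, and SNP contaminants (alt fraction
  0.5 or 1 at A/T reference bases) listed in the accompanying SNP table.
* :func:`simulate_dose_response` — checkerboard viability surfaces built
  from 4PL single-agent curves combined under Bliss independence, with an
  optional multiplicative interaction and truncated-Gaussian noise.

All randomness flows through an explicit per-config seed; identical config
and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tribescreen.errors import ConfigError
from tribescreen.synergy import DoseResponseMatrix, four_pl

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Pooled CRISPR screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Design of a simulated pooled knockout screen.

    ``reads_per_guide`` is the mean sequencing depth per guide per sample;
    each sample is "sequenced" to a fixed total so planted effects also
    perturb the composition, as in a real pooled screen.  Effect sizes are
    log2: essentials deplete in DMSO and DRUG vs T0, sensitizers deplete and
    resistance genes enrich in DRUG vs DMSO.
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    n_nontargeting: int = 1000
    n_safe_harbor: int = 200
    samples: tuple[tuple[str, int], ...] = (
        ("T0", 1), ("T0", 2), ("DMSO", 1), ("DMSO", 2), ("DRUG", 1), ("DRUG", 2),
    )
    reads_per_guide: float = 500.0
    baseline_log_sd: float = 0.5
    dispersion: float = 0.05
    frac_essential: float = 0.05
    frac_sensitizer: float = 0.05
    frac_resistance: float = 0.05
    essential_lfc: float = -4.0
    sensitizer_lfc: float = -3.0
    resistance_lfc: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.guides_per_gene < 1:
            raise ConfigError("guides_per_gene must be >= 1")
        if self.dispersion <= 0:
            raise ConfigError("NB dispersion must be positive")
        fracs = (self.frac_essential, self.frac_sensitizer, self.frac_resistance)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ConfigError("class fractions must be nonnegative and sum to <= 1")


@dataclass
class ScreenTruth:
    """Planted per-gene class labels (essential/sensitizer/resistance/neutral)."""

    gene_classes: pd.Series

    def genes_of(self, cls: str) -> set[str]:
        return set(self.gene_classes.index[self.gene_classes == cls])


def _random_sequences(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    idx = rng.integers(0, 4, size=(n, length))
    return ["".join(_BASES[r]) for r in idx]


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, ScreenTruth]:
    """Simulate (manifest, counts, truth) for a pooled screen."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    classes = np.array(["neutral"] * config.n_genes, dtype=object)
    n_ess = round(config.frac_essential * config.n_genes)
    n_sen = round(config.frac_sensitizer * config.n_genes)
    n_res = round(config.frac_resistance * config.n_genes)
    order = rng.permutation(config.n_genes)
    classes[order[:n_ess]] = "essential"
    classes[order[n_ess:n_ess + n_sen]] = "sensitizer"
    classes[order[n_ess + n_sen:n_ess + n_sen + n_res]] = "resistance"
    truth = ScreenTruth(gene_classes=pd.Series(classes, index=genes, name="class"))

    guide_ids, guide_gene, guide_class = [], [], []
    for g in genes:
        for j in range(1, config.guides_per_gene + 1):
            guide_ids.append(f"{g}_sg{j}")
            guide_gene.append(g)
            guide_class.append("targeting")
    for i in range(config.n_nontargeting):
        guide_ids.append(f"NTC_{i:05d}")
        guide_gene.append(None)
        guide_class.append("non-targeting")
    for i in range(config.n_safe_harbor):
        guide_ids.append(f"SH_{i:05d}")
        guide_gene.append(None)
        guide_class.append("safe-harbor")
    n_guides = len(guide_ids)
    manifest = pd.DataFrame({
        "guide_id": guide_ids,
        "sequence": _random_sequences(rng, n_guides),
        "gene": guide_gene,
        "class": guide_class,
    })

    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=n_guides)
    lfc_of_class = {
        "T0": {},
        "DMSO": {"essential": config.essential_lfc},
        "DRUG": {"essential": config.essential_lfc,
                 "sensitizer": config.sensitizer_lfc,
                 "resistance": config.resistance_lfc},
    }
    class_of_gene = truth.gene_classes.to_dict()
    guide_cls = np.array([class_of_gene.get(g, "control") for g in guide_gene])

    r = 1.0 / config.dispersion
    counts = {}
    for condition, replicate in config.samples:
        if condition not in lfc_of_class:
            raise ConfigError(f"unknown condition {condition!r} in samples")
        mult = np.ones(n_guides)
        for cls, lfc in lfc_of_class[condition].items():
            mult[guide_cls == cls] = 2.0 ** lfc
        weight = baseline * mult
        mu = config.reads_per_guide * n_guides * weight / weight.sum()
        counts[f"{condition}_{replicate}"] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"))
    return manifest, counts_df, truth


# ---------------------------------------------------------------------------
# HyperTRIBE editing
# ---------------------------------------------------------------------------

@dataclass
class TribeSimConfig:
    """Design of a simulated HyperTRIBE experiment.

    Region placement probabilities default to a heavily 3'UTR-weighted
    profile (0.92), the hallmark of RBP-ADAR editing.  Baseline edit
    frequencies are site-specific, drawn uniformly from
    ``baseline_freq_range``; target sites shift by ``delta_freq`` in the
    second condition (negative = binding lost).  ``rho`` is the beta-binomial
    intra-class correlation across replicates.
    """

    n_genes: int = 500
    sites_per_gene: int = 4
    region_probs: tuple[float, float, float] = (0.03, 0.05, 0.92)  # 5UTR, CDS, 3UTR
    mean_depth: float = 200.0
    baseline_freq_range: tuple[float, float] = (0.2, 0.6)
    target_fraction: float = 0.1
    delta_freq: float = -0.3
    rho: float = 0.02
    n_snp_contaminants: int = 50
    conditions: tuple[str, str] = ("DMSO", "RO")
    n_replicates: int = 3
    utr5_len: int = 150
    cds_len: int = 600
    utr3_len: int = 750
    mean_gene_count: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.region_probs) - 1.0) > 1e-9:
            raise ConfigError("region placement probabilities must sum to 1")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("rho must lie in [0, 1)")
        lo, hi = self.baseline_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("baseline frequencies must lie in [0, 1]")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ConfigError("target_fraction must lie in [0, 1]")


@dataclass
class TribeSim:
    """Bundle of simulated HyperTRIBE inputs plus ground truth."""

    annotation: pd.DataFrame
    pileup: pd.DataFrame
    snp_set: set[tuple[str, int]]
    gene_counts: pd.DataFrame
    genome: dict[str, str]
    truth: pd.DataFrame  # per simulated site: coords, is_target, true frequencies
    samples: list[str]
    conditions: tuple[str, str]


def _betabinom_draw(rng, depth: np.ndarray, mu: float, rho: float) -> np.ndarray:
    if rho <= 0:
        return rng.binomial(depth, mu)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return rng.binomial(depth, rng.beta(a, b, size=depth.shape))


def simulate_hypertribe(config: TribeSimConfig) -> TribeSim:
    """Simulate annotation, pileup, SNP list, expression counts and truth."""
    rng = np.random.default_rng(config.seed)
    chrom = "chrS"
    gap = 100
    gene_len = config.utr5_len + config.cds_len + config.utr3_len
    samples = [f"{c}_{r}" for c in config.conditions for r in range(1, config.n_replicates + 1)]
    cond_b = config.conditions[1]

    ann_rows, truth_rows = [], []
    cursor = gap
    region_lens = {"5UTR": config.utr5_len, "CDS": config.cds_len, "3UTR": config.utr3_len}
    gene_span = {}
    for i in range(config.n_genes):
        gene = f"T{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        # genomic order of regions follows transcription direction
        order = ["5UTR", "CDS", "3UTR"] if strand == "+" else ["3UTR", "CDS", "5UTR"]
        pos = cursor
        for region in order:
            ann_rows.append((gene, f"{gene}.t1", chrom, strand, region,
                             pos, pos + region_lens[region]))
            pos += region_lens[region]
        gene_span[gene] = (cursor, cursor + gene_len, strand)
        cursor += gene_len + gap
    annotation = pd.DataFrame(
        ann_rows, columns=["gene", "transcript", "chrom", "strand", "region", "start", "end"]
    )
    region_intervals = {
        (r.gene, r.region): (r.start, r.end) for r in annotation.itertuples(index=False)
    }

    # --- edit sites -------------------------------------------------------
    used_positions: set[int] = set()
    region_names = ("5UTR", "CDS", "3UTR")
    genes = sorted(gene_span)
    pileup_rows = []
    for gene in genes:
        _g0, _g1, strand = gene_span[gene]
        for _ in range(config.sites_per_gene):
            region = region_names[rng.choice(3, p=config.region_probs)]
            lo, hi = region_intervals[(gene, region)]
            for _try in range(50):
                pos0 = int(rng.integers(lo, hi))
                if pos0 not in used_positions:
                    break
            else:
                continue
            used_positions.add(pos0)
            is_target = rng.random() < config.target_fraction
            base_freq = float(rng.uniform(*config.baseline_freq_range))
            freq_b = float(np.clip(base_freq + (config.delta_freq if is_target else 0.0),
                                   0.005, 0.995))
            freqs = {config.conditions[0]: base_freq, cond_b: freq_b}
            rec = {"chrom": chrom, "pos": pos0 + 1,
                   "ref": "A" if strand == "+" else "T"}
            alt_base = "G" if strand == "+" else "C"
            for s in samples:
                cond = s.rsplit("_", 1)[0]
                depth = max(int(rng.poisson(config.mean_depth)), 1)
                alt = int(_betabinom_draw(rng, np.array([depth]), freqs[cond], config.rho)[0])
                for b in "ACGT":
                    rec[f"{s}.{b}"] = 0
                rec[f"{s}.{rec['ref']}"] = depth - alt
                rec[f"{s}.{alt_base}"] = alt
                rec[f"{s}.depth"] = depth
            pileup_rows.append(rec)
            truth_rows.append({"chrom": chrom, "pos": pos0 + 1, "strand": strand,
                               "gene": gene, "region": region, "is_target": is_target,
                               "freq_a": base_freq, "freq_b": freq_b,
                               "delta": freq_b - base_freq})

    # --- SNP contaminants -------------------------------------------------
    snp_set: set[tuple[str, int]] = set()
    snp_genes = rng.choice(genes, size=config.n_snp_contaminants, replace=True)
    for gene in snp_genes:
        g0, g1, strand = gene_span[gene]
        for _try in range(50):
            pos0 = int(rng.integers(g0, g1))
            if pos0 not in used_positions:
                break
        else:
            continue
        used_positions.add(pos0)
        # het or hom alt at an A(+)/T(-) base: passes the strand filter,
        # only the SNP list can remove it
        alt_fraction = 0.5 if rng.random() < 0.5 else 1.0
        ref = "A" if strand == "+" else "T"
        alt_base = "G" if strand == "+" else "C"
        rec = {"chrom": chrom, "pos": pos0 + 1, "ref": ref}
        for s in samples:
            depth = max(int(rng.poisson(config.mean_depth)), 1)
            alt = depth if alt_fraction == 1.0 else int(rng.binomial(depth, 0.5))
            for b in "ACGT":
                rec[f"{s}.{b}"] = 0
            rec[f"{s}.{ref}"] = depth - alt
            rec[f"{s}.{alt_base}"] = alt
            rec[f"{s}.depth"] = depth
        pileup_rows.append(rec)
        snp_set.add((chrom, pos0 + 1))

    pileup = pd.DataFrame(pileup_rows).sort_values("pos", kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows).sort_values("pos", kind="stable").reset_index(drop=True)

    # --- gene-level expression for FPKM filters ---------------------------
    expr = rng.lognormal(mean=np.log(config.mean_gene_count), sigma=1.0, size=len(genes))
    r = 10.0  # NB size for mild count overdispersion
    gene_counts = pd.DataFrame(
        {s: rng.negative_binomial(r, r / (r + expr)) for s in samples},
        index=pd.Index(genes, name="gene"),
    )

    # --- genome sequence with the correct reference bases -----------------
    seq = rng.integers(0, 4, size=cursor + gap)
    a_idx, t_idx = 0, 3
    for df in (truth[["pos", "strand"]], ):
        for pos, strand in zip(df["pos"], df["strand"]):
            seq[pos - 1] = a_idx if strand == "+" else t_idx
    for c, pos in snp_set:
        strand = next(s for g, (g0, g1, s) in gene_span.items() if g0 <= pos - 1 < g1)
        seq[pos - 1] = a_idx if strand == "+" else t_idx
    genome = {chrom: "".join(_BASES[seq])}

    return TribeSim(annotation=annotation, pileup=pileup, snp_set=snp_set,
                    gene_counts=gene_counts, genome=genome, truth=truth,
                    samples=samples, conditions=config.conditions)


# ---------------------------------------------------------------------------
# Dose-response checkerboards
# ---------------------------------------------------------------------------

@dataclass
class DoseSimConfig:
    """Design of a simulated drug-combination checkerboard.

    Single agents follow decreasing 4PL curves; the combination surface is
    their Bliss product times ``interaction ** (w_a * w_b)`` with dose
    weights ``w = dose / max_dose`` — ``interaction`` is the multiplicative
    deviation factor at the top dose pair, 1 meaning exact Bliss
    independence and values < 1 synergy.  Noise is truncated Gaussian on the
    viability fraction.
    """

    doses_a: tuple[float, ...] = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0)
    doses_b: tuple[float, ...] = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0)
    top_a: float = 1.0
    bottom_a: float = 0.05
    hill_a: float = 1.2
    ic50_a: float = 1.0
    top_b: float = 1.0
    bottom_b: float = 0.05
    hill_b: float = 1.2
    ic50_b: float = 2.0
    interaction: float = 1.0
    noise_sd: float = 0.02
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(d < 0 for d in self.doses_a + self.doses_b):
            raise ConfigError("doses must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigError("noise sd must be nonnegative")
        if self.interaction <= 0:
            raise ConfigError("interaction factor must be positive")


@dataclass
class DoseTruth:
    ic50_a: float
    ic50_b: float
    interaction: float


def simulate_dose_response(config: DoseSimConfig) -> tuple[DoseResponseMatrix, DoseTruth]:
    """Simulate a replicated checkerboard viability matrix plus truth."""
    rng = np.random.default_rng(config.seed)
    da = np.sort(np.asarray(config.doses_a, dtype=float))
    db = np.sort(np.asarray(config.doses_b, dtype=float))
    sa = four_pl(da, config.top_a, config.bottom_a, config.hill_a, config.ic50_a)
    sb = four_pl(db, config.top_b, config.bottom_b, config.hill_b, config.ic50_b)
    wa = da / da.max() if da.max() > 0 else da
    wb = db / db.max() if db.max() > 0 else db
    surface = np.outer(sa, sb) * config.interaction ** np.outer(wa, wb)
    grid = np.repeat(surface[None, :, :], config.replicates, axis=0)
    if config.noise_sd > 0:
        grid = np.clip(grid + rng.normal(0.0, config.noise_sd, size=grid.shape), 0.0, 1.0)
    matrix = DoseResponseMatrix("A", "B", da, db, grid)
    return matrix, DoseTruth(ic50_a=config.ic50_a, ic50_b=config.ic50_b,
                             interaction=config.interaction)


def dose_matrix_to_long(matrix: DoseResponseMatrix) -> pd.DataFrame:
    """Flatten a checkerboard to the long CSV schema."""
    rows = []
    for r in range(matrix.viability.shape[0]):
        for i, a in enumerate(matrix.doses_a):
            for j, b in enumerate(matrix.doses_b):
                rows.append((a, b, r + 1, matrix.viability[r, i, j]))
    return pd.DataFrame(rows, columns=["drug_a_dose", "drug_b_dose", "replicate", "viability"])
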