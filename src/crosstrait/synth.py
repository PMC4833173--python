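"""Synthetic paired-trait case-control GWAS generator.

Emulates the data substrate of a cross-disorder polygenic analysis: two
case-control cohorts (a *discovery* cohort for trait A and a *test*
cohort for trait B) drawn from the same variant set, where the per-SNP
causal effects of the two traits have a controlled correlation r_g.

Model
-----
* Haplotypes come from a latent Gaussian with AR(1) correlation
  ``rho**|i-j|`` between SNPs inside fixed-size blocks and exact
  independence across blocks; thresholding at the normal quantile of the
  allele frequency yields 0/1 haplotypes, and a genotype is the sum of
  two independent haplotypes.  Block boundaries are therefore exact
  linkage-equilibrium points.
* A fraction ``causal_fraction`` of SNPs carries effects drawn from a
  bivariate normal with correlation ``effect_correlation`` and marginal
  variances ``h2 / n_causal`` (standardized-genotype scale, so the
  liability-scale heritability bookkeeping is exact under linkage
  equilibrium).
* Disease status follows a liability-threshold model: liability is the
  genetic score on standardized dosages plus N(0, 1-h2) noise; cases
  exceed the ``Phi^{-1}(1-prevalence)`` threshold.  Case-control panels
  are ascertained by rejection sampling until the requested counts are
  reached.
* Population structure (optional): with ``n_subpops > 1`` the subpopulation
  allele frequencies are Balding-Nichols Beta perturbations of the
  ancestral frequency with divergence ``fst``.

All randomness descends from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` children, so identical configs reproduce
byte-identical outputs while the two cohorts and the effect draw stay
independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import GenotypePanel, PHENO_UNKNOWN, SummaryStatRecord

logger = logging.getLogger("crosstrait.synth")

_MAX_ATTEMPTS = 10_000_000  # rejection-sampling budget (individuals drawn)

# SeedSequence spawn keys, so each source of randomness is independent
_KEY_FREQS = 0
_KEY_EFFECTS = 1
_KEY_GENO = {"discovery": 2, "test": 3}
_KEY_PHENO = {"discovery": 4, "test": 5}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired-trait simulation.

    Defaults emulate the motivating cross-disorder study: a
    schizophrenia-like discovery cohort (3,322 cases / 3,587 controls),
    a rheumatoid-arthritis-like test cohort (1,989 cases / 1,588
    controls), liability-scale heritabilities 0.81 and 0.65, point
    prevalences 0.46% and 0.6%, causal effects at 1% of SNPs, and an
    effect correlation of 0.078.
    """

    n_snps: int = 10_000
    block_size: int = 20
    rho: float = 0.9
    maf_low: float = 0.05
    maf_high: float = 0.5
    causal_fraction: float = 0.01
    h2_a: float = 0.81
    h2_b: float = 0.65
    effect_correlation: float = 0.078
    prevalence_a: float = 0.0046
    prevalence_b: float = 0.006
    n_disc_cases: int = 3_322
    n_disc_controls: int = 3_587
    n_test_cases: int = 1_989
    n_test_controls: int = 1_588
    n_subpops: int = 1
    fst: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0 or self.block_size <= 0:
            raise ValueError("n_snps and block_size must be positive")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if not (0 <= self.causal_fraction <= 1):
            raise ValueError("causal_fraction must be in [0, 1]")
        for name in ("h2_a", "h2_b"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (-1 <= self.effect_correlation <= 1):
            raise ValueError("effect_correlation must be in [-1, 1]")
        for name in ("prevalence_a", "prevalence_b"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("n_disc_cases", "n_disc_controls", "n_test_cases", "n_test_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_subpops < 1 or self.fst < 0:
            raise ValueError("n_subpops >= 1 and fst >= 0 required")

    def cohort_sizes(self, which_cohort: str) -> tuple[int, int]:
        if which_cohort == "discovery":
            return self.n_disc_cases, self.n_disc_controls
        if which_cohort == "test":
            return self.n_test_cases, self.n_test_controls
        raise ValueError(f"unknown cohort {which_cohort!r}")

    def cohort_trait(self, which_cohort: str) -> tuple[float, float]:
        """(heritability, prevalence) of the trait measured in a cohort."""
        if which_cohort == "discovery":
            return self.h2_a, self.prevalence_a
        return self.h2_b, self.prevalence_b


def _rng(config: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), key]))


def ancestral_freqs(config: SimConfig) -> np.ndarray:
    """Allele-1 frequencies, uniform on [maf_low, maf_high]; shared by cohorts."""
    rng = _rng(config, _KEY_FREQS)
    return rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)


def _subpop_freqs(config: SimConfig, anc: np.ndarray) -> np.ndarray:
    """Balding-Nichols Beta(f(1-F)/F, (1-f)(1-F)/F) frequencies per subpopulation."""
    if config.n_subpops == 1 or config.fst == 0:
        return np.tile(anc, (config.n_subpops, 1))
    rng = _rng(config, _KEY_FREQS + 100)
    scale = (1 - config.fst) / config.fst
    freqs = rng.beta(anc * scale, (1 - anc) * scale, size=(config.n_subpops, anc.size))
    return np.clip(freqs, 1e-4, 1 - 1e-4)


def _variant_table(config: SimConfig, freqs: np.ndarray) -> pd.DataFrame:
    m = config.n_snps
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": 1 + 1000 * np.arange(m),  # one SNP per kb
            "allele1": "A",
            "allele2": "G",
            "freq": freqs,
        }
    )


def _draw_genotypes(
    config: SimConfig,
    freqs: np.ndarray,
    n: int,
    rng: np.random.Generator,
    block_idx: np.ndarray | None = None,
) -> np.ndarray:
    """n x m dosage matrix under the block-AR(1) latent Gaussian model.

    ``freqs`` may be (n_snps,) or (n, n_snps) for per-individual
    (subpopulation-specific) frequencies; it always spans the full
    variant set.  With ``block_idx`` only those LD blocks are generated
    (valid because blocks are mutually independent) and the returned
    columns are the blocks' SNPs in order.
    """
    m = config.n_snps
    b = min(config.block_size, m)
    n_blocks_all = math.ceil(m / b)
    blocks = np.arange(n_blocks_all) if block_idx is None else np.asarray(block_idx)
    cols = _block_columns(m, b, blocks)
    n_blocks = len(blocks)
    # Cholesky of the AR(1) block correlation, shared by all blocks
    ar1 = config.rho ** np.abs(np.subtract.outer(np.arange(b), np.arange(b)))
    chol = np.linalg.cholesky(ar1).astype(np.float32)
    thresh = stats.norm.ppf(freqs)[..., cols].astype(np.float32)

    # column mask removing the padding of a short trailing block
    keep = np.concatenate(
        [np.arange(min(b, m - blk * b)) + i * b for i, blk in enumerate(blocks)]
    )
    dosages = np.zeros((n, len(cols)), dtype=np.float32)
    for _ in range(2):  # two independent haplotypes
        z = rng.standard_normal((n * n_blocks, b), dtype=np.float32) @ chol.T
        z = z.reshape(n, n_blocks * b)[:, keep]
        dosages += z < thresh
    return dosages


def _block_columns(m: int, b: int, blocks: np.ndarray) -> np.ndarray:
    return np.concatenate([np.arange(blk * b, min((blk + 1) * b, m)) for blk in blocks])


def simulate_panel(
    config: SimConfig,
    which_cohort: str = "test",
    *,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
    id_offset: int = 0,
) -> GenotypePanel:
    """Draw an unlabeled genotype panel (phenotypes unknown).

    ``n_samples`` defaults to the cohort's total (cases + controls).
    Allele frequencies depend only on the seed, not the cohort, so the
    discovery and test panels share the same variant set.
    """
    n_cases, n_controls = config.cohort_sizes(which_cohort)
    n = n_samples if n_samples is not None else n_cases + n_controls
    if n <= 0:
        raise ValueError("sample count must be positive")
    if rng is None:
        rng = _rng(config, _KEY_GENO[which_cohort])
    anc = ancestral_freqs(config)
    variants = _variant_table(config, anc)
    if config.n_subpops > 1:
        sub = _subpop_freqs(config, anc)
        labels = rng.integers(0, config.n_subpops, size=n)
        dosages = _draw_genotypes(config, sub[labels], n, rng)
    else:
        labels = np.zeros(n, dtype=int)
        dosages = _draw_genotypes(config, anc, n, rng)
    panel = GenotypePanel(
        sample_ids=[f"{which_cohort}_{id_offset + i + 1}" for i in range(n)],
        phenotypes=np.full(n, PHENO_UNKNOWN, dtype=int),
        variants=variants,
        dosages=dosages,
    )
    panel.subpop_labels = labels  # ancillary, used by structure tests
    return panel


def draw_effects(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Paired causal effect vectors (liability scale, standardized-genotype units).

    A uniformly chosen fraction ``causal_fraction`` of SNPs gets effects
    from a bivariate normal with correlation ``effect_correlation`` and
    marginal variances ``h2 / n_causal``; all other SNPs are exactly 0
    for both traits.
    """
    rng = _rng(config, _KEY_EFFECTS)
    m = config.n_snps
    beta_a = np.zeros(m)
    beta_b = np.zeros(m)
    n_causal = int(round(config.causal_fraction * m))
    if n_causal == 0:
        return beta_a, beta_b
    causal = rng.choice(m, size=n_causal, replace=False)
    r = config.effect_correlation
    sd_a = math.sqrt(config.h2_a / n_causal)
    sd_b = math.sqrt(config.h2_b / n_causal)
    # bivariate normal via its Cholesky factor, written out so the
    # degenerate cases (|r| = 1, zero heritability) are exact
    z1 = rng.standard_normal(n_causal)
    z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n_causal)
    beta_a[causal] = sd_a * z1
    beta_b[causal] = sd_b * z2
    return beta_a, beta_b


def genetic_liability(panel: GenotypePanel, beta: np.ndarray) -> np.ndarray:
    """Genetic liability on standardized dosages: sum_j beta_j (d_ij - 2f_j)/sqrt(2f_j(1-f_j))."""
    beta = np.asarray(beta, dtype=float)
    if len(beta) != panel.n_variants:
        raise ValueError("effect vector length must equal variant count")
    nz = np.flatnonzero(beta)  # zero-effect SNPs cannot contribute
    if nz.size == 0:
        return np.zeros(panel.n_samples)
    f = panel.allele1_freqs()[nz]
    scale = np.sqrt(2 * f * (1 - f))
    d = np.nan_to_num(panel.dosages[:, nz]).astype(float)
    return ((d - 2 * f) / scale) @ beta[nz]


def assign_phenotypes(
    panel: GenotypePanel,
    beta: np.ndarray,
    prevalence: float,
    h2: float,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.SeedSequence,
    genotype_factory=None,
    max_attempts: int = _MAX_ATTEMPTS,
) -> GenotypePanel:
    """Ascertain an exact case-control panel under the liability threshold.

    Individuals in ``panel`` receive liability = genetic score +
    N(0, 1-h2) noise and become cases iff liability exceeds
    ``Phi^{-1}(1 - prevalence)``.  The first ``n_cases`` cases and
    ``n_controls`` controls are retained; if the panel is exhausted,
    further batches are drawn from ``genotype_factory(n, rng)`` until the
    counts are met or the attempt budget (total individuals examined) is
    exceeded.
    """
    rng = np.random.default_rng(seed)
    threshold = stats.norm.ppf(1 - prevalence)
    noise_sd = math.sqrt(max(0.0, 1 - h2))

    case_parts: list[np.ndarray] = []
    control_parts: list[np.ndarray] = []
    case_ids: list[str] = []
    control_ids: list[str] = []
    n_case_kept = n_control_kept = 0
    attempts = 0
    batch = panel
    while True:
        g = genetic_liability(batch, beta)
        liability = g + noise_sd * rng.standard_normal(batch.n_samples)
        is_case = liability > threshold
        attempts += batch.n_samples

        need_cases = n_cases - n_case_kept
        case_idx = np.flatnonzero(is_case)[:need_cases]
        need_controls = n_controls - n_control_kept
        control_idx = np.flatnonzero(~is_case)[:need_controls]
        if case_idx.size:
            case_parts.append(batch.dosages[case_idx])
            case_ids.extend(batch.sample_ids[i] for i in case_idx)
            n_case_kept += case_idx.size
        if control_idx.size:
            control_parts.append(batch.dosages[control_idx])
            control_ids.extend(batch.sample_ids[i] for i in control_idx)
            n_control_kept += control_idx.size
        if n_case_kept >= n_cases and n_control_kept >= n_controls:
            break
        if genotype_factory is None or attempts >= max_attempts:
            raise RuntimeError(
                f"rejection sampling exhausted after {attempts} individuals "
                f"({n_case_kept}/{n_cases} cases, {n_control_kept}/{n_controls} controls)"
            )
        # draw roughly what the acceptance rate suggests is still needed
        rate_case = max(n_case_kept / attempts, prevalence / 4)
        n_more = int(min(
            max((n_cases - n_case_kept) / rate_case * 1.2, 200),
            max_attempts - attempts,
        ))
        batch = genotype_factory(n_more, rng)

    dosages = np.vstack(case_parts + control_parts)
    phenotypes = np.concatenate(
        [np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
    )
    return GenotypePanel(
        sample_ids=case_ids + control_ids,
        phenotypes=phenotypes,
        variants=panel.variants.copy(),
        dosages=dosages,
    )


def simulate_study(config: SimConfig, which_cohort: str) -> GenotypePanel:
    """Simulate one ascertained case-control cohort end to end.

    Uses the trait (A for discovery, B for test) and sample sizes the
    config assigns to the cohort; both cohorts share allele frequencies
    and causal-effect draws.

    Ascertainment exploits across-block independence: only the LD blocks
    containing causal SNPs are generated for the rejection pool (they
    fully determine the genetic liability), and the remaining blocks are
    drawn afterwards for the retained individuals alone.  This is an
    exact sampling scheme, not an approximation, because non-causal
    blocks are independent of case status given the causal blocks.
    """
    beta_a, beta_b = draw_effects(config)
    beta = beta_a if which_cohort == "discovery" else beta_b
    h2, prevalence = config.cohort_trait(which_cohort)
    n_cases, n_controls = config.cohort_sizes(which_cohort)
    m = config.n_snps
    b = min(config.block_size, m)
    n_blocks = math.ceil(m / b)

    geno_rng = _rng(config, _KEY_GENO[which_cohort])
    pheno_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _KEY_PHENO[which_cohort]])
    )
    anc = ancestral_freqs(config)
    variants = _variant_table(config, anc)
    sub = _subpop_freqs(config, anc) if config.n_subpops > 1 else None

    causal = np.flatnonzero(beta)
    causal_blocks = np.unique(causal // b)
    causal_cols = (
        _block_columns(m, b, causal_blocks) if causal_blocks.size else np.array([], dtype=int)
    )
    other_blocks = np.setdiff1d(np.arange(n_blocks), causal_blocks)
    other_cols = (
        _block_columns(m, b, other_blocks) if other_blocks.size else np.array([], dtype=int)
    )

    f_causal = anc[causal_cols]
    scale = np.sqrt(2 * f_causal * (1 - f_causal))
    beta_causal = beta[causal_cols]
    threshold = stats.norm.ppf(1 - prevalence)
    noise_sd = math.sqrt(max(0.0, 1 - h2))

    kept_causal: list[np.ndarray] = []
    kept_pheno: list[np.ndarray] = []
    kept_labels: list[np.ndarray] = []
    n_case = n_control = 0
    attempts = 0
    expected = n_cases / prevalence + n_controls / (1 - prevalence)
    n_batch = int(min(max(expected * 1.1, n_cases + n_controls), 100_000))
    while n_case < n_cases or n_control < n_controls:
        if attempts >= _MAX_ATTEMPTS:
            raise RuntimeError(
                f"rejection sampling exhausted after {attempts} individuals "
                f"({n_case}/{n_cases} cases, {n_control}/{n_controls} controls)"
            )
        n_draw = int(min(n_batch, _MAX_ATTEMPTS - attempts))
        if sub is not None:
            labels = geno_rng.integers(0, config.n_subpops, size=n_draw)
            freqs = sub[labels]
        else:
            labels = np.zeros(n_draw, dtype=int)
            freqs = anc
        if causal_cols.size:
            d_causal = _draw_genotypes(config, freqs, n_draw, geno_rng, causal_blocks)
            g = ((d_causal.astype(float) - 2 * f_causal) / scale) @ beta_causal
        else:
            d_causal = np.zeros((n_draw, 0), dtype=np.float32)
            g = np.zeros(n_draw)
        liability = g + noise_sd * pheno_rng.standard_normal(n_draw)
        is_case = liability > threshold
        attempts += n_draw
        case_idx = np.flatnonzero(is_case)[: n_cases - n_case]
        ctl_idx = np.flatnonzero(~is_case)[: n_controls - n_control]
        take = np.concatenate([case_idx, ctl_idx])
        if take.size:
            kept_causal.append(d_causal[take])
            kept_pheno.append(is_case[take].astype(int))
            kept_labels.append(labels[take])
        n_case += case_idx.size
        n_control += ctl_idx.size
        n_batch = max(n_batch // 2, 2 * (n_cases + n_controls))

    n_total = n_cases + n_controls
    phenotypes = np.concatenate(kept_pheno)
    labels = np.concatenate(kept_labels)
    dosages = np.empty((n_total, m), dtype=np.float32)
    if causal_cols.size:
        dosages[:, causal_cols] = np.vstack(kept_causal)
    if other_cols.size:
        freqs = sub[labels] if sub is not None else anc
        dosages[:, other_cols] = _draw_genotypes(
            config, freqs, n_total, geno_rng, other_blocks
        )
    panel = GenotypePanel(
        sample_ids=[f"{which_cohort}_{i + 1}" for i in range(n_total)],
        phenotypes=phenotypes,
        variants=variants,
        dosages=dosages,
    )
    panel.subpop_labels = labels
    return panel


# ---------------------------------------------------------------------------
# discovery GWAS
# ---------------------------------------------------------------------------

def discovery_gwas(panel: GenotypePanel, *, info: float = 1.0) -> list[SummaryStatRecord]:
    """Per-SNP univariate logistic regression of status on dosage.

    Returns one record per polymorphic, non-separated SNP with
    OR = exp(beta-hat), a two-sided Wald p-value, and a constant INFO
    score.  Monomorphic SNPs and SNPs where the fit diverges
    (separation) are dropped with a logged count.
    """
    mask = panel.phenotypes != PHENO_UNKNOWN
    y = panel.phenotypes[mask].astype(float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("panel must contain both cases and controls")
    d = panel.dosages[mask]
    # mean-impute missing dosages for the vectorized fit
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)

    poly = np.nanstd(d, axis=0) > 0
    n_mono = int(np.sum(~poly))
    if n_mono:
        logger.info("discovery_gwas: dropped %d monomorphic SNPs", n_mono)

    b0, b1, se1, converged = _batched_logistic(y, d[:, poly])
    ok = converged & np.isfinite(b1) & (np.abs(b1) < 15) & np.isfinite(se1)
    n_sep = int(np.sum(~ok))
    if n_sep:
        logger.warning("discovery_gwas: dropped %d separated/non-converged SNPs", n_sep)

    z = b1[ok] / se1[ok]
    pvals = np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    var = panel.variants.loc[poly, :].loc[ok, :]
    records = [
        SummaryStatRecord(
            snp_id=row.snp_id,
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=row.allele1,
            other_allele=row.allele2,
            odds_ratio=float(np.exp(b)),
            p_value=float(p),
            info=info,
        )
        for row, b, p in zip(var.itertuples(index=False), b1[ok], pvals)
    ]
    return records


def _batched_logistic(
    y: np.ndarray, X: np.ndarray, max_iter: int = 25, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Newton fits of logit P(y=1) = b0 + b1 x, batched across columns of X.

    Returns (b0, b1, se(b1), converged).  The 2x2 Newton system is
    solved in closed form per SNP, so the whole GWAS is a handful of
    dense matrix operations.
    """
    n, m = X.shape
    ybar = y.mean()
    b0 = np.full(m, math.log(ybar / (1 - ybar)))
    b1 = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    resid_y = y[:, None]
    for _ in range(max_iter):
        eta = b0 + X * b1
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        g0 = (resid_y - p).sum(axis=0)
        g1 = (X * (resid_y - p)).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X * X).sum(axis=0)
        det = h00 * h11 - h01 * h01
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = (h11 * g0 - h01 * g1) / det
            d1 = (h00 * g1 - h01 * g0) / det
        d0 = np.where(np.isfinite(d0), d0, 0.0)
        d1 = np.where(np.isfinite(d1), d1, 0.0)
        b0 += d0
        b1 += d1
        newly = (np.abs(g0) < tol) & (np.abs(g1) < tol)
        converged |= newly
        if converged.all():
            break
    eta = b0 + X * b1
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    h00 = w.sum(axis=0)
    h01 = (w * X).sum(axis=0)
    h11 = (w * X * X).sum(axis=0)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(np.where(det > 0, h00 / det, np.nan))
    return b0, b1, se1, converged
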