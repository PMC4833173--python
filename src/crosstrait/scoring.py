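"""Polygenic risk scores across p-value thresholds, and fixed-panel profile scores.

A polygenic risk score at threshold p_T is the weighted sum, over
discovery SNPs with p strictly below p_T, of the individual's counted-
allele dosage times ln(OR) oriented to that allele.  Scores are sums
(not averages over SNP number), and missing dosages are mean-imputed
per SNP so samples with different missingness stay comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ld
from .gwas_io import GenotypePanel, HarmonizedStudy

logger = logging.getLogger("crosstrait.scoring")

#: default p_T grid for the threshold sweep
DEFAULT_THRESHOLDS = (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class ScoreSet:
    """Per-sample polygenic scores at each p_T threshold."""

    thresholds: tuple[float, ...]
    scores: np.ndarray  # samples x thresholds
    snp_counts: np.ndarray  # per threshold
    sample_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.snp_counts = np.asarray(self.snp_counts, dtype=int)
        if self.scores.shape != (len(self.sample_ids), len(self.thresholds)):
            raise ValueError("score matrix shape mismatch")
        if np.any(np.diff(self.snp_counts) < 0):
            raise ValueError("snp counts must be non-decreasing in p_T")

    def column(self, p_t: float) -> np.ndarray:
        return self.scores[:, self.thresholds.index(p_t)]

    def to_frame(self, phenotypes: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids})
        if phenotypes is not None:
            df["phenotype"] = phenotypes
        for k, t in enumerate(self.thresholds):
            df[f"pT_{t:g}"] = self.scores[:, k]
        return df


@dataclass
class WeightPanel:
    """Fixed external SNP panel with per-SNP weights (profile scoring)."""

    table: pd.DataFrame  # columns: snp_id, allele, weight

    def __post_init__(self) -> None:
        if self.table["snp_id"].duplicated().any():
            raise ValueError("weight panel ids must be unique")
        if not np.all(np.isfinite(self.table["weight"].to_numpy(float))):
            raise ValueError("weights must be finite")


def read_weight_panel(path: str | Path) -> WeightPanel:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return WeightPanel(table=df[["snp_id", "allele", "weight"]])


def polygenic_score(
    harmonized: HarmonizedStudy,
    panel: GenotypePanel,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> ScoreSet:
    """Threshold-indexed weighted-sum scores for every panel sample.

    score_i(p_T) = sum over harmonized SNPs with p < p_T (strict) of
    weight_j * dosage_ij, with per-SNP mean imputation of missing
    dosages.
    """
    if len(thresholds) == 0:
        raise ValueError("threshold list must not be empty")
    thresholds = tuple(thresholds)
    if any(not (0 < t <= 1) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")

    t = harmonized.table
    cols = t["panel_index"].to_numpy(int)
    weights = t["weight"].to_numpy(float)
    pvals = t["p_value"].to_numpy(float)

    d = panel.dosages[:, cols]
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    d = np.where(np.isnan(d), col_mean, d)

    scores = np.empty((panel.n_samples, len(thresholds)))
    counts = np.empty(len(thresholds), dtype=int)
    for k, p_t in enumerate(thresholds):
        sel = pvals < p_t
        counts[k] = int(sel.sum())
        scores[:, k] = d[:, sel] @ weights[sel]
    logger.info(
        "polygenic_score: SNPs per threshold %s",
        dict(zip(map(str, thresholds), counts.tolist())),
    )
    return ScoreSet(
        thresholds=thresholds,
        scores=scores,
        snp_counts=counts,
        sample_ids=list(panel.sample_ids),
    )


def standardize(scores: ScoreSet) -> ScoreSet:
    """Mean-0, SD-1 transform per threshold, cases and controls pooled.

    Uses the sample (n-1) standard deviation.
    """
    if len(scores.sample_ids) < 2:
        raise ValueError("need at least 2 samples to standardize")
    out = np.empty_like(scores.scores)
    for k, t in enumerate(scores.thresholds):
        col = scores.scores[:, k]
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero score variance at threshold {t:g}")
        out[:, k] = (col - col.mean()) / sd
    return ScoreSet(
        thresholds=scores.thresholds,
        scores=out,
        snp_counts=scores.snp_counts.copy(),
        sample_ids=list(scores.sample_ids),
        standardized=True,
    )


@dataclass
class ProfileScoreReport:
    n_genotyped: int
    n_proxied: int
    n_dropped: int
    proxy_map: dict[str, str] = field(default_factory=dict)


def profile_score(
    weights: WeightPanel,
    panel: GenotypePanel,
    proxy_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, ProfileScoreReport]:
    """Weighted score over a fixed external SNP panel, with LD proxies.

    Each weight-panel entry resolves to its genotyped SNP, or to an LD
    proxy (r2 > ``r2_min``) via :func:`crosstrait.ld.find_proxy`, or is
    dropped and counted.  Proxy dosages are re-oriented so their
    correlation with the original SNP's counted allele is positive where
    determinable.
    """
    idx_by_id = {s: j for j, s in enumerate(panel.variants["snp_id"])}
    genotyped_ids = list(panel.variants["snp_id"])
    proxy_map = dict(proxy_map or {})

    score = np.zeros(panel.n_samples)
    n_geno = n_proxy = n_drop = 0
    used_proxies: dict[str, str] = {}
    for row in weights.table.itertuples(index=False):
        sid, allele, w = row.snp_id, str(row.allele).upper(), float(row.weight)
        j = idx_by_id.get(sid)
        if j is not None:
            d = _oriented_dosage(panel, j, allele)
            if d is None:
                n_drop += 1
                continue
            score += w * _mean_impute(d)
            n_geno += 1
            continue
        proxy = proxy_map.get(sid)
        if proxy is not None and proxy in idx_by_id:
            pj = idx_by_id[proxy]
            d = _mean_impute(panel.dosages[:, pj])
            # orientation against the original SNP is not determinable from
            # the test panel alone; if the original is also genotyped in a
            # reference, the caller encodes the sign in the proxy_map value
            score += w * d
            n_proxy += 1
            used_proxies[sid] = proxy
            continue
        n_drop += 1
    if n_geno + n_proxy == 0:
        raise ValueError("no weight-panel SNPs resolvable in the genotype panel")
    report = ProfileScoreReport(
        n_genotyped=n_geno, n_proxied=n_proxy, n_dropped=n_drop, proxy_map=used_proxies
    )
    logger.info(
        "profile_score: %d genotyped, %d proxied, %d dropped",
        n_geno, n_proxy, n_drop,
    )
    return score, report


def resolve_proxies(
    weights: WeightPanel,
    reference: GenotypePanel,
    genotyped_ids: set[str],
    r2_min: float = 0.6,
    window_kb: float = 500.0,
) -> dict[str, str]:
    """Build a proxy map for weight-panel SNPs missing from a study panel.

    Uses a reference panel that contains both the targets and the
    candidate (genotyped) SNPs, mirroring proxy lookup against an
    external LD reference.
    """
    candidates = [s for s in reference.variants["snp_id"] if s in genotyped_ids]
    mapping: dict[str, str] = {}
    for sid in weights.table["snp_id"]:
        if sid in genotyped_ids:
            continue
        if sid not in set(reference.variants["snp_id"]):
            continue
        proxy = ld.find_proxy(sid, candidates, reference, r2_min=r2_min, window_kb=window_kb)
        if proxy is not None:
            mapping[sid] = proxy
    return mapping


def _oriented_dosage(panel: GenotypePanel, j: int, allele: str) -> np.ndarray | None:
    a1 = str(panel.variants.at[j, "allele1"]).upper()
    a2 = str(panel.variants.at[j, "allele2"]).upper()
    d = panel.dosages[:, j]
    if allele == a1:
        return d
    if allele == a2:
        return 2.0 - d
    return None


def _mean_impute(d: np.ndarray) -> np.ndarray:
    if not np.any(np.isnan(d)):
        return d
    m = np.nanmean(d)
    return np.where(np.isnan(d), 0.0 if np.isnan(m) else m, d)
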