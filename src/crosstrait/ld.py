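"""Linkage-disequilibrium utilities: r2, clumping, pruning, proxy search.

LD is measured as the squared Pearson correlation of dosages (composite
LD) over pairwise-complete observations — phase is never required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_io import GenotypePanel, HarmonizedStudy

logger = logging.getLogger("crosstrait.ld")


@dataclass(frozen=True)
class ClumpSpec:
    """Greedy clumping parameters.

    Defaults (250 kb window, r2 >= 0.25 removal) follow common polygenic
    scoring practice; both are configurable and logged.
    """

    window_kb: float = 250.0
    r2_threshold: float = 0.25
    tag: str = "default"

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")


def pairwise_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairs with a missing value in either vector are excluded; at least
    two complete pairs with variance in both vectors are required.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    va = a - a.mean()
    vb = b - b.mean()
    denom = (va @ va) * (vb @ vb)
    if denom == 0:
        raise ValueError("undefined LD: zero variance after missing-pair removal")
    r = (va @ vb) ** 2 / denom
    return float(min(r, 1.0))


def _r2_one_vs_many(x: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Pairwise-complete r2 between vector x and each column of block.

    Vectorized version of :func:`pairwise_r2`; columns with no valid
    pairing (fewer than 2 complete pairs or zero variance) get nan.
    """
    mx = ~np.isnan(x)
    xb = np.where(mx, x, 0.0)
    mb = ~np.isnan(block)
    bb = np.where(mb, block, 0.0)

    n = mx @ mb.astype(float)
    sx = xb @ mb
    sy = mx @ bb
    sxx = (xb * xb) @ mb
    syy = mx @ (bb * bb)
    sxy = xb @ bb
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vx * vy)
    r2 = np.where((n >= 2) & (vx > 0) & (vy > 0), r2, np.nan)
    return np.minimum(r2, 1.0)


def _normalized_or_none(D: np.ndarray, cols: np.ndarray) -> np.ndarray | None:
    """Centered unit-norm copy of selected dosage columns, or None if any
    value is missing (callers then fall back to pairwise-complete r2).

    Zero-variance columns become all-zero, so their r2 with anything is
    0 (undefined LD never claims or drops a neighbour).
    """
    X = D[:, cols].astype(float)
    if np.isnan(X).any():
        return None
    X = X - X.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", X, X))
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(norms > 0, X / norms, 0.0)
    return X


def clump(
    harmonized: HarmonizedStudy,
    panel: GenotypePanel,
    spec: ClumpSpec = ClumpSpec(),
) -> list[str]:
    """P-value-informed greedy clumping; returns retained (index) SNP ids.

    Repeatedly the unclaimed SNP with smallest p becomes an index SNP
    and claims every unclaimed SNP on its chromosome within
    ``window_kb`` having r2 >= ``r2_threshold`` with it.  Ties on p are
    broken by (chrom, pos) ascending.  The retained set is exactly the
    index SNPs, hence near-independent at the chosen threshold.
    """
    t = harmonized.table
    missing = set(t["snp_id"]) - set(panel.variants["snp_id"])
    if missing:
        raise ValueError(f"{len(missing)} harmonized SNPs absent from panel")
    logger.info(
        "clump: window=%.0f kb, r2>=%.2f (%s), %d SNPs in",
        spec.window_kb, spec.r2_threshold, spec.tag, len(t),
    )
    idx_by_id = {s: j for j, s in enumerate(panel.variants["snp_id"])}
    df = pd.DataFrame(
        {
            "snp_id": t["snp_id"].to_numpy(),
            "chrom": t["chrom"].astype(str).to_numpy(),
            "pos": t["pos"].astype(int).to_numpy(),
            "p": t["p_value"].to_numpy(dtype=float),
            "col": [idx_by_id[s] for s in t["snp_id"]],
        }
    )
    order = np.lexsort((df["pos"], df["chrom"], df["p"]))
    claimed = np.zeros(len(df), dtype=bool)
    window_bp = spec.window_kb * 1000.0
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    cols = df["col"].to_numpy()
    retained: list[str] = []
    D = panel.dosages
    Z = _normalized_or_none(D, cols)
    snp_ids = df["snp_id"].to_numpy()
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        retained.append(snp_ids[i])
        near = np.flatnonzero(
            (~claimed) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        )
        if near.size == 0:
            continue
        if Z is not None:
            r2 = (Z[:, i] @ Z[:, near]) ** 2
        else:
            r2 = _r2_one_vs_many(D[:, cols[i]], D[:, cols[near]])
        claimed[near[np.nan_to_num(r2) >= spec.r2_threshold]] = True
    logger.info("clump: %d index SNPs retained", len(retained))
    return retained


def prune(
    panel: GenotypePanel, window_kb: float = 250.0, r2_threshold: float = 0.25
) -> list[str]:
    """Sliding-window LD pruning; returns retained variant ids.

    Variants are scanned in (chrom, pos) order; a variant is dropped if
    it has r2 >= threshold with any already-retained variant within
    ``window_kb`` of it (the later member of each correlated pair is
    always the one removed).
    """
    var = panel.variants
    order = np.lexsort((var["pos"].to_numpy(int), var["chrom"].astype(str).to_numpy()))
    window_bp = window_kb * 1000.0
    D = panel.dosages
    Z = _normalized_or_none(D, np.arange(panel.n_variants))
    pos = var["pos"].to_numpy(int)
    chrom = var["chrom"].astype(str).to_numpy()
    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    trim: dict[str, int] = {}  # per-chromosome window start (monotone: scan is in position order)
    for j in order:
        prior = kept_by_chrom.setdefault(chrom[j], [])
        lo = trim.get(chrom[j], 0)
        while lo < len(prior) and pos[j] - pos[prior[lo]] > window_bp:
            lo += 1
        trim[chrom[j]] = lo
        active = prior[lo:]
        drop = False
        if active:
            if Z is not None:
                r2 = (Z[:, j] @ Z[:, active]) ** 2
            else:
                r2 = _r2_one_vs_many(D[:, j], D[:, active])
            drop = bool(np.any(np.nan_to_num(r2) >= r2_threshold))
        if not drop:
            kept.append(j)
            prior.append(j)
    kept.sort()
    ids = var["snp_id"].to_numpy()
    return [ids[j] for j in kept]


def find_proxy(
    target_id: str,
    candidate_ids: list[str],
    panel: GenotypePanel,
    r2_min: float = 0.6,
    window_kb: float = 500.0,
) -> str | None:
    """Best LD proxy for a target SNP among genotyped candidates.

    Candidates within ``window_kb`` of the target with r2 strictly above
    ``r2_min`` qualify; the highest-r2 one wins, with ties broken by
    proximity and then id.  Returns None when no candidate qualifies.
    """
    var = panel.variants
    idx_by_id = {s: j for j, s in enumerate(var["snp_id"])}
    tj = idx_by_id.get(target_id)
    if tj is None:
        raise ValueError(f"target {target_id!r} not in panel: position unknown")
    tpos = int(var.at[tj, "pos"])
    tchrom = str(var.at[tj, "chrom"])
    best: tuple[float, float, str] | None = None  # (-r2, distance, id)
    for cid in candidate_ids:
        cj = idx_by_id.get(cid)
        if cj is None or cid == target_id:
            continue
        if str(var.at[cj, "chrom"]) != tchrom:
            continue
        dist = abs(int(var.at[cj, "pos"]) - tpos)
        if dist > window_kb * 1000.0:
            continue
        try:
            r2 = pairwise_r2(panel.dosages[:, tj], panel.dosages[:, cj])
        except ValueError:
            continue
        if r2 > r2_min:
            key = (-r2, dist, cid)
            if best is None or key < best:
                best = key
    return best[2] if best else None
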