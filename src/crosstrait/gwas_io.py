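"""Reading, validation, filtering and harmonization of GWAS inputs.

Two kinds of input meet here: discovery-side GWAS summary statistics
(one odds ratio + p-value per SNP) and an individual-level case-control
genotype panel (PLINK BED/BIM/FAM).  Harmonization joins them on SNP id
and orients every log-odds weight to the allele the panel counts, which
is the precondition for polygenic scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("crosstrait.gwas_io")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header names for summary-statistic files
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "odds_ratio": "OR",
    "p_value": "P",
    "info": "INFO",
}


@dataclass(frozen=True, slots=True)
class SummaryStatRecord:
    """One SNP's association result from a discovery GWAS.

    ``odds_ratio`` is reported for ``effect_allele``; ``info`` is the
    imputation-quality score in [0, 1] (``None`` for directly genotyped
    SNPs).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    odds_ratio: float
    p_value: float
    info: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.odds_ratio) or self.odds_ratio <= 0:
            raise ValueError(f"{self.snp_id}: odds ratio must be positive")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.snp_id}: p-value must be in (0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if self.info is not None and not (0 <= self.info <= 1):
            raise ValueError(f"{self.snp_id}: info score must be in [0, 1]")

    @property
    def is_ambiguous(self) -> bool:
        """True for A/T and C/G SNPs, whose strand cannot be resolved."""
        return COMPLEMENT.get(self.effect_allele) == self.other_allele


PHENO_UNKNOWN = -9


@dataclass
class GenotypePanel:
    """Samples-by-variants dosage matrix with phenotypes and metadata.

    ``dosages[i, j]`` counts copies of ``variants.allele1[j]`` carried by
    sample ``i`` (0/1/2, ``nan`` for missing).  ``phenotypes`` uses
    0=control, 1=case, -9=unknown.  A ``freq`` column in ``variants``
    (the generating allele-1 frequency) is present for synthetic panels
    and preferred over the empirical frequency where available.
    """

    sample_ids: list[str]
    phenotypes: np.ndarray
    variants: pd.DataFrame  # columns: snp_id, chrom, pos, allele1, allele2[, freq]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes)
        self.dosages = np.asarray(self.dosages)
        if not np.issubdtype(self.dosages.dtype, np.floating):
            self.dosages = self.dosages.astype(float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.phenotypes) != n:
            raise ValueError("sample dimension mismatch")
        if len(self.variants) != m:
            raise ValueError("variant dimension mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele1_freqs(self, *, empirical: bool = False) -> np.ndarray:
        """Allele-1 frequency per variant.

        Uses the generating frequency column when present (synthetic
        panels), otherwise the empirical frequency from dosages.
        """
        if not empirical and "freq" in self.variants.columns:
            return self.variants["freq"].to_numpy(dtype=float)
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_samples(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in idx],
            phenotypes=self.phenotypes[idx].copy(),
            variants=self.variants.copy(),
            dosages=self.dosages[idx].copy(),
        )

    def subset_variants(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            phenotypes=self.phenotypes.copy(),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx].copy(),
        )


@dataclass
class HarmonizedStudy:
    """Summary statistics joined to a panel with weights allele-aligned.

    ``table`` has one row per retained SNP: ``snp_id, chrom, pos,
    panel_index, weight, p_value`` where ``weight`` is ln(OR) oriented to
    the panel's counted allele.  ``exclusions`` logs every dropped SNP
    with a reason.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    def __post_init__(self) -> None:
        if len(self.table) and not np.all(np.isfinite(self.table["weight"])):
            raise ValueError("harmonized weights must be finite")

    @property
    def n_snps(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    *,
    max_reject_fraction: float = 0.10,
) -> list[SummaryStatRecord]:
    """Read summary statistics from delimited text.

    Rows violating the record invariants (non-positive OR, p outside
    (0,1], identical alleles) are rejected with a logged line number;
    more than ``max_reject_fraction`` rejected rows is a hard error.
    Duplicate SNP ids are resolved by keeping the smallest p-value.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", comment="#", dtype=str)
    mandatory = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "odds_ratio", "p_value"]
    for key in mandatory:
        if cmap[key] not in df.columns:
            raise ValueError(f"missing mandatory column {cmap[key]!r} in {path}")
    has_info = cmap["info"] in df.columns

    records: list[SummaryStatRecord] = []
    n_rejected = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            info_raw = row.get(cmap["info"]) if has_info else None
            info = None
            if info_raw is not None and str(info_raw).upper() not in ("NA", "NAN", ""):
                info = float(info_raw)
            records.append(
                SummaryStatRecord(
                    snp_id=str(row[cmap["snp_id"]]),
                    chrom=str(row[cmap["chrom"]]),
                    pos=int(float(row[cmap["pos"]])),
                    effect_allele=str(row[cmap["effect_allele"]]).upper(),
                    other_allele=str(row[cmap["other_allele"]]).upper(),
                    odds_ratio=float(row[cmap["odds_ratio"]]),
                    p_value=float(row[cmap["p_value"]]),
                    info=info,
                )
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("rejected line %d of %s: %s", line_no, path, exc)
    n_total = len(df)
    if n_total and n_rejected / n_total > max_reject_fraction:
        raise ValueError(
            f"{n_rejected}/{n_total} rows rejected in {path}; above the "
            f"{max_reject_fraction:.0%} tolerance"
        )

    # dedupe on snp_id keeping smallest p
    best: dict[str, SummaryStatRecord] = {}
    n_dup = 0
    for rec in records:
        prev = best.get(rec.snp_id)
        if prev is None:
            best[rec.snp_id] = rec
        else:
            n_dup += 1
            if rec.p_value < prev.p_value:
                best[rec.snp_id] = rec
    if n_dup:
        logger.info("%d duplicate snp ids collapsed (kept smallest p)", n_dup)
    return list(best.values())


def write_summary_stats(records: list[SummaryStatRecord], path: str | Path) -> None:
    """Write records as tab-separated text: SNP CHR BP A1 A2 OR P INFO."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "BP": [r.pos for r in records],
            "A1": [r.effect_allele for r in records],
            "A2": [r.other_allele for r in records],
            "OR": [r.odds_ratio for r in records],
            "P": [r.p_value for r in records],
            "INFO": [r.info if r.info is not None else "NA" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def filter_info(
    records: list[SummaryStatRecord], min_info: float = 0.7
) -> list[SummaryStatRecord]:
    """Drop poorly imputed SNPs: info strictly below ``min_info``.

    Records with no info score are treated as directly genotyped and
    retained.
    """
    kept = [r for r in records if r.info is None or r.info >= min_info]
    logger.info("info filter (< %.2f): %d -> %d SNPs", min_info, len(records), len(kept))
    return kept


def exclude_region_except_top(
    records: list[SummaryStatRecord],
    chrom: str = "6",
    start_bp: int = 26_000_000,
    end_bp: int = 33_000_000,
    keep_ids: set[str] | None = None,
) -> list[SummaryStatRecord]:
    """Remove a long-range-LD region, keeping only its top SNP(s).

    Intended for the MHC/HLA block (chr6 26-33 Mb), whose extended LD
    would otherwise let many correlated SNPs through clumping.  The
    interval is half-open [start_bp, end_bp) in 1-based coordinates.
    When ``keep_ids`` is not supplied, the region's smallest-p record is
    retained as its single representative.
    """
    if start_bp >= end_bp:
        raise ValueError("start_bp must be < end_bp")
    chrom = str(chrom)
    in_region = [r for r in records if r.chrom == chrom and start_bp <= r.pos < end_bp]
    if keep_ids is None:
        keep_ids = set()
        if in_region:
            keep_ids = {min(in_region, key=lambda r: r.p_value).snp_id}
    kept = [
        r
        for r in records
        if not (r.chrom == chrom and start_bp <= r.pos < end_bp) or r.snp_id in keep_ids
    ]
    logger.info(
        "region filter chr%s:%d-%d: %d -> %d SNPs (kept %s)",
        chrom, start_bp, end_bp, len(records), len(kept), sorted(keep_ids),
    )
    return kept


def harmonize(
    records: list[SummaryStatRecord],
    panel: GenotypePanel,
    drop_ambiguous: bool = True,
) -> HarmonizedStudy:
    """Join records to a panel and orient ln(OR) to the counted allele.

    Matching is by snp_id; a chrom:pos disagreement is logged but does
    not drop the SNP.  If the record's effect allele equals the panel's
    counted allele the weight is +ln(OR); if it equals the other allele,
    -ln(OR); failing that the strand complement is tried under the same
    rules.  A/T and C/G SNPs are dropped when ``drop_ambiguous`` (their
    strand cannot be verified), and irreconcilable allele sets are
    dropped with a log entry.
    """
    var = panel.variants
    index_by_id: dict[str, int] = {}
    for j, sid in enumerate(var["snp_id"]):
        index_by_id.setdefault(sid, j)
    a1_all = var["allele1"].astype(str).str.upper().to_numpy()
    a2_all = var["allele2"].astype(str).str.upper().to_numpy()
    chrom_all = var["chrom"].astype(str).to_numpy()
    pos_all = var["pos"].to_numpy(int)

    rows = []
    excl = []
    n_pos_mismatch = 0
    for rec in records:
        j = index_by_id.get(rec.snp_id)
        if j is None:
            excl.append((rec.snp_id, "absent_from_panel"))
            continue
        if drop_ambiguous and rec.is_ambiguous:
            excl.append((rec.snp_id, "strand_ambiguous"))
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if chrom_all[j] != rec.chrom or pos_all[j] != rec.pos:
            n_pos_mismatch += 1
        sign = _orient(ea, oa, a1_all[j], a2_all[j])
        if sign is None and ea in COMPLEMENT and oa in COMPLEMENT:
            sign = _orient(COMPLEMENT[ea], COMPLEMENT[oa], a1_all[j], a2_all[j])
        if sign is None:
            excl.append((rec.snp_id, "allele_mismatch"))
            continue
        rows.append(
            (rec.snp_id, rec.chrom, rec.pos, j, sign * np.log(rec.odds_ratio), rec.p_value)
        )
    if n_pos_mismatch:
        logger.warning("%d SNPs matched by id but disagree on chrom:pos", n_pos_mismatch)
    if not rows:
        raise ValueError("no SNPs could be harmonized between records and panel")
    table = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "panel_index", "weight", "p_value"]
    )
    exclusions = pd.DataFrame(excl, columns=["snp_id", "reason"])
    logger.info(
        "harmonize: %d records -> %d aligned SNPs (%d dropped)",
        len(records), len(table), len(exclusions),
    )
    return HarmonizedStudy(table=table, exclusions=exclusions)


def _orient(ea: str, oa: str, a1: str, a2: str) -> int | None:
    """+1 if effect allele is the counted allele, -1 if the other, else None."""
    if ea == a1 and oa == a2:
        return +1
    if ea == a2 and oa == a1:
        return -1
    return None


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM codec
# ---------------------------------------------------------------------------
# BED: 3 magic bytes 0x6c 0x1b 0x01 (SNP-major), then one row of
# ceil(n/4) bytes per variant, 2 bits per sample, little-endian within a
# byte: 00=hom allele1 (dosage 2), 01=missing, 10=het, 11=hom allele2.

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_genotype_panel(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK BED/BIM/FAM file set given its shared prefix.

    Dosages count BIM allele1; FAM phenotype 1/2 maps to 0/1 (control /
    case), anything else to unknown (-9).
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "allele1", "allele2"], dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a SNP-major PLINK BED file (bad magic)")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * m:
        raise ValueError(
            f"{bed_path}: size mismatch ({body.size} data bytes, expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants)"
        )
    codes = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    rows = body.reshape(m, bytes_per_variant)
    for shift in range(4):
        codes[:, shift::4] = (rows >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # samples x variants

    pheno_raw = pd.to_numeric(fam["pheno"], errors="coerce")
    phenotypes = np.full(n, PHENO_UNKNOWN, dtype=int)
    phenotypes[pheno_raw == 1] = 0
    phenotypes[pheno_raw == 2] = 1

    variants = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "allele1": bim["allele1"],
            "allele2": bim["allele2"],
        }
    )
    return GenotypePanel(
        sample_ids=list(fam["iid"]),
        phenotypes=phenotypes,
        variants=variants,
        dosages=dosages,
    )


def write_genotype_panel(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK BED/BIM/FAM (phenotype 1=control, 2=case)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = panel.n_samples, panel.n_variants

    pheno_out = np.full(n, -9, dtype=int)
    pheno_out[panel.phenotypes == 0] = 1
    pheno_out[panel.phenotypes == 1] = 2
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids,
            "iid": panel.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": pheno_out,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"],
            "snp_id": panel.variants["snp_id"],
            "cm": 0,
            "pos": panel.variants["pos"],
            "allele1": panel.variants["allele1"],
            "allele2": panel.variants["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    d = panel.dosages
    codes = np.full(d.shape, 1, dtype=np.uint8)  # 01 = missing
    codes[d == 2] = 0
    codes[d == 1] = 2
    codes[d == 0] = 3
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.zeros((pad, m), dtype=np.uint8)])
    per_byte = codes.T.reshape(m, -1, 4)
    packed = (
        per_byte[:, :, 0]
        | (per_byte[:, :, 1] << 2)
        | (per_byte[:, :, 2] << 4)
        | (per_byte[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
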