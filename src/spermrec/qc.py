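"""Site-, call-, cell-, and density-level filters for the haploid matrix.

The filter chain is fixed: hard site filters (INFO annotations, SNP
clusters) → per-call cleaning (allele read support, raw heterozygous calls)
→ cell-level QC (depth / coverage) → heterozygous-site selection → low-
density masking.  Each stage logs what it removed; every filter is
idempotent.

Threshold boundary semantics follow the rules as written: "less than" /
"greater than" are strict (a site with QD exactly 2 is kept), while the
30% minor-allele frequency bound is inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HET_RAW, MISSING, GenotypeMatrix
from .io import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    qd_min: float = 2.0
    fs_max: float = 30.0
    sor_max: float = 3.0
    mq_min: float = 40.0
    qual_min: float = 40.0
    cluster_window_bp: int = 35
    cluster_size: int = 3
    min_allele_reads: int = 2
    min_allele_freq: float = 0.30
    min_allele_cells: int = 2
    cell_min_depth: float = 0.5     # mean sequencing depth, x coverage
    cell_min_coverage: float = 0.10  # fraction of genome covered
    density_window_bp: int = 1_000_000
    density_min_htsnp: int = 50

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if val < 0:
                raise ValueError(f"{name} must be non-negative")


def hard_filter_sites(
    sites: pd.DataFrame, config: QCConfig | None = None
) -> tuple[np.ndarray, dict]:
    """Hard INFO/QUAL filters plus the clustered-SNP filter.

    Removes sites with QD < 2, FS > 30, SOR > 3, MQ < 40 or QUAL < 40
    (strict comparisons; a missing annotation does not fail the site but is
    logged), then removes every SNP belonging to a run of >= 3 SNPs spanning
    <= 35 bp on one chromosome.  Returns a keep-mask over ``sites`` plus a
    removal log.
    """
    config = config or QCConfig()
    n = len(sites)

    def col(name: str) -> np.ndarray:
        if name in sites.columns:
            return sites[name].to_numpy(dtype=float)
        return np.full(n, np.nan)

    qd, fs, sor, mq, qual = (col(c) for c in ("qd", "fs", "sor", "mq", "qual"))
    n_noinfo = int(np.isnan(qd).sum())
    if n_noinfo:
        logger.info("%d sites lack INFO annotations; hard filters pass them", n_noinfo)

    with np.errstate(invalid="ignore"):
        fail = (
            (qd < config.qd_min)
            | (fs > config.fs_max)
            | (sor > config.sor_max)
            | (mq < config.mq_min)
            | (qual < config.qual_min)
        )
    fail = np.where(np.isnan(qd) & np.isnan(qual), False, fail)

    # clustered-SNP filter: any run of `cluster_size` SNPs spanning
    # <= cluster_window_bp removes all of its members (INDELs not counted)
    is_indel = (
        sites["is_indel"].to_numpy(dtype=bool)
        if "is_indel" in sites.columns
        else np.zeros(n, dtype=bool)
    )
    cluster = np.zeros(n, dtype=bool)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy(dtype=np.int64)
    k = config.cluster_size
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero((chrom_arr == chrom) & ~is_indel)
        pos = pos_arr[idx]
        order = np.argsort(pos, kind="mergesort")
        idx, pos = idx[order], pos[order]
        if len(pos) < k:
            continue
        span = pos[k - 1:] - pos[: len(pos) - k + 1]
        for start in np.flatnonzero(span <= config.cluster_window_bp):
            cluster[idx[start:start + k]] = True

    keep = ~(fail | cluster)
    log = {
        "n_input": n,
        "n_hard_filtered": int(fail.sum()),
        "n_cluster_filtered": int((cluster & ~fail).sum()),
        "n_no_info": n_noinfo,
        "n_kept": int(keep.sum()),
    }
    logger.info("hard_filter_sites: %s", log)
    return keep, log


def clean_haploid_calls(
    calls: np.ndarray,
    allele_depths: np.ndarray | None = None,
    config: QCConfig | None = None,
) -> np.ndarray:
    """Set unsupported and raw-heterozygous calls to missing.

    A call needs at least ``min_allele_reads`` reads supporting its allele
    when allele depths are available (skipped with a warning otherwise);
    raw heterozygous calls are always removed — in a haploid cell they stem
    from amplification/sequencing error or chromosome-scale anomalies.
    """
    config = config or QCConfig()
    out = calls.copy()
    out[out == HET_RAW] = MISSING
    if allele_depths is None:
        logger.warning("no AD available; read-support filter skipped")
        return out
    called = out >= 0
    support = np.where(
        out == 1, allele_depths[..., 1], allele_depths[..., 0]
    )
    out[called & (support < config.min_allele_reads)] = MISSING
    return out


def filter_cells(
    cell_metrics: pd.DataFrame, config: QCConfig | None = None
) -> tuple[list[str], dict]:
    """Drop cells with depth < 0.5x or genome coverage < 10%.

    ``cell_metrics`` carries one row per cell with columns ``cell``,
    ``depth`` and ``coverage``; a missing (NaN) metric retains the cell
    with a warning.
    """
    config = config or QCConfig()
    kept, removed_depth, removed_cov = [], [], []
    for row in cell_metrics.itertuples(index=False):
        depth, cov = float(row.depth), float(row.coverage)
        if np.isnan(depth) or np.isnan(cov):
            logger.warning("cell %s lacks QC metrics; retained", row.cell)
            kept.append(row.cell)
        elif depth < config.cell_min_depth:
            removed_depth.append(row.cell)
        elif cov < config.cell_min_coverage:
            removed_cov.append(row.cell)
        else:
            kept.append(row.cell)
    log = {
        "n_input": len(cell_metrics),
        "removed_low_depth": removed_depth,
        "removed_low_coverage": removed_cov,
        "n_kept": len(kept),
    }
    logger.info("filter_cells: %s", log)
    return kept, log


def cell_metrics_from_matrix(
    matrix: GenotypeMatrix, depth_per_coverage: float = 4.5
) -> pd.DataFrame:
    """Proxy per-cell QC metrics from a genotype matrix.

    The call rate stands in for genome coverage; depth is approximated as
    proportional to coverage (``depth_per_coverage`` ~ mean depth divided by
    mean coverage in low-pass single-cell data).
    """
    call_rate = (matrix.calls >= 0).mean(axis=0)
    return pd.DataFrame({
        "cell": matrix.cells,
        "depth": call_rate * depth_per_coverage,
        "coverage": call_rate,
    })


def select_het_sites(
    calls: np.ndarray, config: QCConfig | None = None
) -> np.ndarray:
    """Keep sites where both alleles are common enough across sperm.

    Among non-missing cells at a site, each allele must reach a frequency of
    at least ``min_allele_freq`` (inclusive) and be observed in at least
    ``min_allele_cells`` cells.  In a haploid sample of a heterozygous
    donor these are the sites informative for phasing (htSNPs); sites with
    every call missing are dropped.
    """
    config = config or QCConfig()
    n1 = (calls == 1).sum(axis=1)
    n0 = (calls == 0).sum(axis=1)
    total = n0 + n1
    n_minor = np.minimum(n0, n1)
    with np.errstate(invalid="ignore", divide="ignore"):
        # count comparison with a tiny slack so that e.g. 3/10 meets 0.30
        freq_ok = n_minor >= config.min_allele_freq * total - 1e-9
    return (total > 0) & (n_minor >= config.min_allele_cells) & freq_ok


def mask_low_density(
    positions_by_chrom: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    config: QCConfig | None = None,
) -> list[GenomicInterval]:
    """Flag 1-Mb windows with fewer than 50 htSNPs, merged when adjacent.

    Chromosomes are tiled with non-overlapping windows from position 1; the
    trailing partial window is held to a prorated threshold
    (``density_min_htsnp`` x window fraction).  Crossover inference excludes
    these regions: with sparse informative sites (e.g. runs of
    homozygosity) state switches cannot be localized reliably.
    """
    config = config or QCConfig()
    w = config.density_window_bp
    out: list[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(positions_by_chrom.get(chrom, np.empty(0, dtype=np.int64)))
        n_windows = int(np.ceil(length / w))
        flagged = []
        for k in range(n_windows):
            start, end = k * w, min((k + 1) * w, length)
            count = int(np.count_nonzero((pos > start) & (pos <= end)))
            threshold = config.density_min_htsnp * (end - start) / w
            if count < threshold:
                flagged.append((start, end))
        # merge adjacent flagged windows
        for start, end in flagged:
            if out and out[-1].chrom == chrom and out[-1].end == start:
                out[-1] = GenomicInterval(chrom, out[-1].start, end)
            else:
                out.append(GenomicInterval(chrom, start, end))
    return out


def run_site_qc(
    matrix: GenotypeMatrix, config: QCConfig | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Full fixed-order site/call/cell/htSNP filter chain on a raw matrix."""
    config = config or QCConfig()
    keep, site_log = hard_filter_sites(matrix.sites, config)
    matrix = matrix.subset_sites(keep)
    cleaned = clean_haploid_calls(matrix.calls, matrix.ad, config)
    matrix = GenotypeMatrix(matrix.sites, cleaned, matrix.cells, matrix.ad)
    metrics = cell_metrics_from_matrix(matrix)
    kept_cells, cell_log = filter_cells(metrics, config)
    if len(kept_cells) < matrix.n_cells:
        matrix = matrix.subset_cells(kept_cells)
    snv = ~matrix.sites.get("is_indel", pd.Series(False, index=matrix.sites.index)).to_numpy(bool)
    het = select_het_sites(matrix.calls, config) & snv
    out = matrix.subset_sites(het)
    log = {
        "hard_filter": site_log,
        "cells": cell_log,
        "n_htsnp": int(het.sum()),
        "n_indel_excluded": int((~snv).sum()),
    }
    return out, log
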