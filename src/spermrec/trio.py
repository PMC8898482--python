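"""Mendelian trio phasing of the donor's htSNPs and agreement scoring.

A diploid offspring genotype carries one paternal and one maternal allele;
at an offspring-heterozygous site the parental genotypes determine which
allele came from which parent whenever at most one parent is heterozygous.
Trio-phased haplotypes serve as an independent yardstick for the
sperm-linkage phaser: the agreement rate over doubly-phased sites, after
per-chromosome orientation matching, measures phasing accuracy without any
shared assumptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DonorHaplotypes

logger = logging.getLogger(__name__)

PHASED = "phased"
UNPHASABLE = "unphasable"
MENDELIAN_ERROR = "mendelian_error"


def phase_offspring_site(
    off: tuple[int, int], sire: tuple[int, int], dam: tuple[int, int]
) -> tuple[str, int | None, int | None]:
    """Phase one offspring-heterozygous site from parental genotypes.

    Returns ``(outcome, paternal, maternal)`` where outcome is ``"phased"``
    (exactly one Mendelian-consistent assignment — one parent homozygous
    and the other homozygous for the opposite allele or heterozygous),
    ``"unphasable"`` (both parents heterozygous: both assignments fit) or
    ``"mendelian_error"`` (no assignment fits).  The offspring must be
    heterozygous; the logic is symmetric under relabeling ref/alt.
    """
    if off[0] == off[1]:
        raise ValueError("offspring must be heterozygous")
    a, b = off
    consistent = []
    for pat, mat in ((a, b), (b, a)):
        if pat in sire and mat in dam:
            consistent.append((pat, mat))
    if len(consistent) == 1:
        pat, mat = consistent[0]
        return PHASED, pat, mat
    if len(consistent) == 2:
        return UNPHASABLE, None, None
    return MENDELIAN_ERROR, None, None


@dataclass
class TrioPhaseResult:
    table: pd.DataFrame  # chrom, pos, outcome, paternal, maternal
    counts: dict[str, int]

    @property
    def rate(self) -> float:
        """Fraction of offspring-het sites phased by the trio."""
        total = sum(self.counts.values())
        return self.counts.get(PHASED, 0) / total if total else float("nan")


def trio_phase_all(trio: pd.DataFrame) -> TrioPhaseResult:
    """Apply Mendelian phasing at every offspring-heterozygous site.

    ``trio`` carries columns ``chrom, pos, off1, off2, sire1, sire2, dam1,
    dam2`` with alleles coded 0/1 (see :func:`spermrec.io.read_trio_vcf`).
    Homozygous-offspring rows are ignored (they carry no phase).
    """
    rows = []
    counts = {PHASED: 0, UNPHASABLE: 0, MENDELIAN_ERROR: 0}
    for r in trio.itertuples(index=False):
        if r.off1 == r.off2:
            continue
        outcome, pat, mat = phase_offspring_site(
            (int(r.off1), int(r.off2)), (int(r.sire1), int(r.sire2)),
            (int(r.dam1), int(r.dam2)),
        )
        counts[outcome] += 1
        rows.append((r.chrom, r.pos, outcome, pat, mat))
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "outcome", "paternal", "maternal"]
    )
    if counts[MENDELIAN_ERROR]:
        logger.info("%d Mendelian-inconsistent sites", counts[MENDELIAN_ERROR])
    return TrioPhaseResult(table=table, counts=counts)


def agreement_rate(
    sperm_profile: DonorHaplotypes, trio_result: TrioPhaseResult
) -> tuple[float, int, int, dict[str, str]]:
    """Consistency of sperm-linkage and trio phasings on shared sites.

    Restricted to sites phased by BOTH methods.  Sperm haplotype labels are
    arbitrary per chromosome, so for each chromosome the orientation
    (hap1 = paternal, or swapped) maximizing matches is chosen, ties toward
    identity.  Returns ``(rate, matched, total, orientation_by_chrom)``.
    """
    trio_phased = trio_result.table[trio_result.table["outcome"] == PHASED]
    matched = 0
    total = 0
    orientations: dict[str, str] = {}
    for chrom, ch in sperm_profile.chroms.items():
        sub = trio_phased[trio_phased["chrom"] == chrom]
        if sub.empty:
            continue
        pos_to_pat = dict(zip(sub["pos"].to_numpy(), sub["paternal"].to_numpy()))
        mask = ch.phased_mask
        both_pos = [
            (i, pos_to_pat[p])
            for i, p in enumerate(ch.positions)
            if mask[i] and p in pos_to_pat
        ]
        if not both_pos:
            continue
        idx = np.array([i for i, _ in both_pos])
        pat = np.array([a for _, a in both_pos])
        m_id = int(np.count_nonzero(ch.hap1[idx] == pat))
        m_sw = int(np.count_nonzero(ch.hap2[idx] == pat))
        if m_id >= m_sw:
            matched += m_id
            orientations[chrom] = "identity"
        else:
            matched += m_sw
            orientations[chrom] = "swapped"
        total += len(idx)
    if total == 0:
        raise ValueError("agreement undefined: no doubly-phased sites")
    return matched / total, matched, total, orientations
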