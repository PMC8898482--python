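"""Two-stage chromosome-level haplotype phasing from sperm linkage.

Because each sperm is a haploid draw from the donor's two homologous
chromosomes, alleles observed together in one cell at two nearby htSNPs are
overwhelmingly in *cis* — a crossover or a genotyping error between the two
sites is rare.  The phaser exploits this:

1. **Anchor profile.**  htSNPs covered in more than ``anchor_min_cells``
   sperm are chained left-to-right per chromosome.  For a candidate pair the
   four allele combinations across jointly covered cells are tallied; the
   link is accepted when one complementary pair of combinations (the *true
   links*) clearly dominates and the opposing pair (the *false links*,
   produced by errors or an intervening crossover) is essentially absent.
   On rejection the next anchor is tried; after ``max_skip`` consecutive
   rejections a fresh segment is re-anchored and segment orientations are
   reconciled afterwards from aggregated boundary linkage.
2. **Window imputation.**  Remaining sites are phased recursively from the
   five nearest phased htSNPs: every covering cell with at least
   ``window_min_agree`` confirmed matches to one haplotype implies a phase
   assignment for the target; unanimous implied assignments are accepted,
   to a fixpoint.
3. **Cross-cell imputation.**  For each haplotype the ten sperm most
   concordant with it act as haplotype representatives; a still-unphased
   site is assigned from representatives covering it when at least
   ``cross_cell_min`` agree on the allele and that haplotype out-covers the
   other.

Haplotype labels are arbitrary per chromosome (fixed deterministically as
hap1 := allele 0 at each chromosome's first chained anchor); all accuracy
comparisons downstream are label-swap invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    PHASE_ANCHOR,
    PHASE_CELL,
    PHASE_UNPHASED,
    PHASE_WINDOW,
    ChromHaplotypes,
    DonorHaplotypes,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PhasingConfig:
    """Tunables of the two-stage phaser (defaults follow the assay design).

    ``link_mode`` selects how the true-link threshold is applied to a
    candidate pair: ``"total"`` (default) requires the dominant
    complementary pair's combined count to reach ``true_link_min``;
    ``"each"`` requires both of its counts to reach it individually.  The
    strict per-link reading needs roughly twice as many jointly covered
    cells and is impractical at the deep dropout typical of ~1.8x
    single-sperm coverage; see docs/methods.md.
    """

    anchor_min_cells: int = 20
    true_link_min: int = 8
    false_link_max: int = 1
    window_size: int = 5
    window_min_agree: int = 3
    top_k_cells: int = 10
    cross_cell_min: int = 2
    max_skip: int = 50
    max_iter: int = 100
    link_mode: str = "total"

    def __post_init__(self) -> None:
        if self.true_link_min <= self.false_link_max:
            raise ValueError("true_link_min must exceed false_link_max")
        if self.window_min_agree > self.window_size:
            raise ValueError("window_min_agree cannot exceed window_size")
        if self.link_mode not in ("total", "each"):
            raise ValueError("link_mode must be 'total' or 'each'")


def count_links(
    calls: np.ndarray, site_a: int, site_b: int
) -> tuple[int, int, int, int]:
    """Counts of the four allele combinations (0-0, 0-1, 1-0, 1-1).

    Tallied over cells non-missing at both sites; the counts sum to at most
    the number of cells.
    """
    if site_a == site_b:
        raise ValueError("site_a and site_b must differ")
    a, b = calls[site_a], calls[site_b]
    both = (a >= 0) & (b >= 0)
    a, b = a[both], b[both]
    return (
        int(np.count_nonzero((a == 0) & (b == 0))),
        int(np.count_nonzero((a == 0) & (b == 1))),
        int(np.count_nonzero((a == 1) & (b == 0))),
        int(np.count_nonzero((a == 1) & (b == 1))),
    )


def accept_link(
    counts: tuple[int, int, int, int], config: PhasingConfig | None = None
) -> int | None:
    """Decide whether a neighboring-htSNP pair is confidently linked.

    Returns ``+1`` when the same-orientation pair (0-0 / 1-1) is the true
    link (site B's hap1 allele equals site A's), ``-1`` when the cross pair
    (0-1 / 1-0) is, and ``None`` when neither passes.  A pair passes when
    its true-link evidence reaches ``true_link_min`` (combined or per-link
    count depending on ``link_mode``) while both opposing counts stay at or
    below ``false_link_max``.  The two orientations cannot both pass.
    """
    config = config or PhasingConfig()
    n00, n01, n10, n11 = counts
    if min(counts) < 0:
        raise ValueError("counts must be non-negative")

    def passes(true_pair: tuple[int, int], false_pair: tuple[int, int]) -> bool:
        if max(false_pair) > config.false_link_max:
            return False
        if config.link_mode == "each":
            return min(true_pair) >= config.true_link_min
        return sum(true_pair) >= config.true_link_min

    same = passes((n00, n11), (n01, n10))
    cross = passes((n01, n10), (n00, n11))
    if same:
        return 1
    if cross:
        return -1
    return None


def _resolve_segments(
    calls: np.ndarray,
    hap1: np.ndarray,
    segments: list[list[int]],
    config: PhasingConfig,
) -> tuple[np.ndarray, int]:
    """Reconcile relative orientation of re-anchored chain segments.

    For each consecutive segment pair the linkage is aggregated over the
    boundary site pairs (last x first ``window_size`` sites): each cell
    covering both sites of a pair is scored as same- or cross-orientation
    given the segments' internal labels.  The dominant orientation is
    accepted when its count reaches ``true_link_min`` and exceeds the
    opposing count by the factor ``true_link_min/false_link_max`` (the
    pairwise 8:1 evidence ratio, generalized).  Unresolvable boundaries
    conservatively unphase the smaller side.
    """
    ratio = config.true_link_min / max(config.false_link_max, 1)
    n_unresolved = 0
    current = segments[0]
    for nxt in segments[1:]:
        tail = current[-config.window_size:]
        head = nxt[: config.window_size]
        n_same = n_cross = 0
        for a in tail:
            for b in head:
                ca, cb = calls[a], calls[b]
                both = (ca >= 0) & (cb >= 0)
                match_a = ca[both] == hap1[a]
                match_b = cb[both] == hap1[b]
                agree = match_a == match_b
                n_same += int(np.count_nonzero(agree))
                n_cross += int(np.count_nonzero(~agree))
        hi, lo = max(n_same, n_cross), min(n_same, n_cross)
        if hi >= config.true_link_min and hi >= ratio * max(lo, 1):
            if n_cross > n_same:
                hap1[nxt] = 1 - hap1[nxt]
            current = current + nxt
        else:
            n_unresolved += 1
            drop = nxt if len(nxt) <= len(current) else current
            keepseg = current if drop is nxt else nxt
            hap1[drop] = -1
            current = keepseg
    return hap1, n_unresolved


def build_profile(
    matrix: GenotypeMatrix, config: PhasingConfig | None = None
) -> tuple[DonorHaplotypes, dict]:
    """Stage 0: phase the well-covered anchor htSNPs by chained linkage."""
    config = config or PhasingConfig()
    chroms: dict[str, ChromHaplotypes] = {}
    report: dict[str, dict] = {}
    for chrom, positions, calls in matrix.by_chrom():
        n = len(positions)
        hap1 = np.full(n, -1, dtype=np.int8)
        status = np.full(n, PHASE_UNPHASED, dtype=np.int8)
        coverage = (calls >= 0).sum(axis=1)
        anchors = np.flatnonzero(coverage > config.anchor_min_cells)
        info = {"n_sites": n, "n_anchors": len(anchors), "n_segments": 0,
                "n_rejected_links": 0, "n_unresolved_boundaries": 0}
        if len(anchors) < 2:
            if len(anchors):
                logger.info("%s: <2 anchors, nothing phased by linkage", chrom)
            chroms[chrom] = ChromHaplotypes(positions, hap1, _complement(hap1), status)
            report[chrom] = info
            continue

        segments: list[list[int]] = []
        seg: list[int] = [int(anchors[0])]
        hap1[anchors[0]] = 0  # label convention: hap1 := allele 0 at root
        cur = int(anchors[0])
        skip = 0
        for idx in anchors[1:]:
            idx = int(idx)
            orient = accept_link(count_links(calls, cur, idx), config)
            if orient is not None:
                base = hap1[cur] if orient == 1 else 1 - hap1[cur]
                hap1[idx] = base
                seg.append(idx)
                cur = idx
                skip = 0
            else:
                info["n_rejected_links"] += 1
                skip += 1
                if skip > config.max_skip:
                    segments.append(seg)
                    seg = [idx]
                    hap1[idx] = 0
                    cur = idx
                    skip = 0
                    logger.info("%s: max_skip hit, re-anchoring at site %d",
                                chrom, idx)
        segments.append(seg)
        # a lone anchor that never linked carries no phase information
        segments = [s for s in segments if len(s) > 1 or _unphase_lone(hap1, s)]
        info["n_segments"] = len(segments)
        if len(segments) > 1:
            hap1, unresolved = _resolve_segments(calls, hap1, segments, config)
            info["n_unresolved_boundaries"] = unresolved
        if segments:
            status[hap1 >= 0] = PHASE_ANCHOR
        chroms[chrom] = ChromHaplotypes(positions, hap1, _complement(hap1), status)
        report[chrom] = info
    return DonorHaplotypes(chroms), report


def _unphase_lone(hap1: np.ndarray, seg: list[int]) -> bool:
    hap1[seg] = -1
    return False


def _complement(hap1: np.ndarray) -> np.ndarray:
    hap2 = np.where(hap1 >= 0, 1 - hap1, -1).astype(np.int8)
    return hap2


def _nearest_phased_window(
    positions: np.ndarray, phased_idx: np.ndarray, target: int, k: int
) -> np.ndarray:
    """Indices of the k phased sites nearest the target by coordinate."""
    tpos = positions[target]
    j = np.searchsorted(positions[phased_idx], tpos)
    lo, hi = j - 1, j
    picked = []
    while len(picked) < k and (lo >= 0 or hi < len(phased_idx)):
        dl = tpos - positions[phased_idx[lo]] if lo >= 0 else np.inf
        dr = positions[phased_idx[hi]] - tpos if hi < len(phased_idx) else np.inf
        if dl <= dr:  # distance tie prefers the left neighbor
            picked.append(phased_idx[lo])
            lo -= 1
        else:
            picked.append(phased_idx[hi])
            hi += 1
    return np.array(sorted(picked), dtype=np.int64)


def impute_stage1(
    profile: DonorHaplotypes,
    matrix: GenotypeMatrix,
    config: PhasingConfig | None = None,
) -> DonorHaplotypes:
    """Stage 1: recursive sliding-window imputation of unphased htSNPs.

    Passes are synchronous — every decision in a pass uses the phase set as
    it stood at the start of the pass — so the outcome is independent of the
    order sites are visited in.  Newly phased sites become usable in the
    next pass; iteration stops at a fixpoint (or at ``max_iter`` passes).
    """
    config = config or PhasingConfig()
    for chrom, positions, calls in matrix.by_chrom():
        ch = profile[chrom]
        hap1 = ch.hap1.copy()
        status = ch.status.copy()
        for _ in range(config.max_iter):
            phased_idx = np.flatnonzero(hap1 >= 0)
            if len(phased_idx) < config.window_size:
                break
            targets = np.flatnonzero(hap1 < 0)
            new_hap1 = {}
            for t in targets:
                widx = _nearest_phased_window(
                    positions, phased_idx, t, config.window_size
                )
                sub = calls[widx]                       # (w, n_cells)
                confirmed = sub >= 0
                m1 = ((sub == hap1[widx, None]) & confirmed).sum(axis=0)
                m2 = ((sub == (1 - hap1)[widx, None]) & confirmed).sum(axis=0)
                covering = calls[t] >= 0
                vote1 = covering & (m1 >= config.window_min_agree) & (m2 < config.window_min_agree)
                vote2 = covering & (m2 >= config.window_min_agree) & (m1 < config.window_min_agree)
                voters = vote1 | vote2
                if not voters.any():
                    continue
                # a cell on background h carrying allele a implies hap_h = a,
                # i.e. hap1 = a on background 1 and hap1 = 1 - a on background 2
                implied = np.where(vote1, calls[t], 1 - calls[t])[voters]
                if np.all(implied == implied[0]):
                    new_hap1[t] = int(implied[0])
            if not new_hap1:
                break
            for t, a in new_hap1.items():
                hap1[t] = a
                status[t] = PHASE_WINDOW
        profile.chroms[chrom] = ChromHaplotypes(
            positions, hap1, _complement(hap1), status
        )
    return profile


def impute_stage2(
    profile: DonorHaplotypes,
    matrix: GenotypeMatrix,
    config: PhasingConfig | None = None,
) -> DonorHaplotypes:
    """Stage 2: impute remaining htSNPs from top haplotype-concordant cells.

    Per chromosome and haplotype, cells are ranked by genotype concordance
    with that haplotype over its phased sites; the ``top_k_cells`` act as
    representatives.  An unphased site is assigned to haplotype h when at
    least ``cross_cell_min`` of h's representatives covering it agree on
    one allele and h's covering-representative count exceeds the other
    haplotype's.
    """
    config = config or PhasingConfig()
    for chrom, positions, calls in matrix.by_chrom():
        ch = profile[chrom]
        hap1 = ch.hap1.copy()
        status = ch.status.copy()
        phased_idx = np.flatnonzero(hap1 >= 0)
        targets = np.flatnonzero(hap1 < 0)
        if len(phased_idx) == 0 or len(targets) == 0:
            continue
        sub = calls[phased_idx]
        nonmiss = sub >= 0
        denom = nonmiss.sum(axis=0)
        match1 = ((sub == hap1[phased_idx, None]) & nonmiss).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            conc1 = np.where(denom > 0, match1 / denom, 0.0)
        conc2 = np.where(denom > 0, 1.0 - conc1, 0.0)
        # representatives of a haplotype: cells strictly more concordant
        # with it than with the other, best `top_k_cells` of them
        order1 = np.argsort(-conc1, kind="stable")
        order2 = np.argsort(-conc2, kind="stable")
        top1 = order1[conc1[order1] > 0.5][: config.top_k_cells]
        top2 = order2[conc2[order2] > 0.5][: config.top_k_cells]
        for t in targets:
            stats = []
            for top in (top1, top2):
                cov = top[calls[t, top] >= 0]
                if len(cov) == 0:
                    stats.append((0, 0, -1))
                    continue
                alleles = calls[t, cov]
                ones = int((alleles == 1).sum())
                zeros = len(alleles) - ones
                # modal allele; count tie prefers allele 0
                a, s = (0, zeros) if zeros >= ones else (1, ones)
                stats.append((len(cov), s, a))
            (n1, s1, a1), (n2, s2, a2) = stats
            if s1 >= config.cross_cell_min and n1 > n2:
                hap1[t] = a1
                status[t] = PHASE_CELL
            elif s2 >= config.cross_cell_min and n2 > n1:
                hap1[t] = 1 - a2
                status[t] = PHASE_CELL
        profile.chroms[chrom] = ChromHaplotypes(
            positions, hap1, _complement(hap1), status
        )
    return profile


def phase_sperm(
    matrix: GenotypeMatrix, config: PhasingConfig | None = None
) -> tuple[DonorHaplotypes, dict]:
    """Run the full phaser: anchor profile, then both imputation stages."""
    config = config or PhasingConfig()
    profile, report = build_profile(matrix, config)
    anchor_phased = profile.n_phased
    profile = impute_stage1(profile, matrix, config)
    stage1_phased = profile.n_phased
    profile = impute_stage2(profile, matrix, config)
    report["_summary"] = {
        "anchor_phased": anchor_phased,
        "stage1_phased": stage1_phased,
        "stage2_phased": profile.n_phased,
        "n_sites": profile.n_sites,
    }
    return profile, report


def phasing_rate(profile: DonorHaplotypes) -> tuple[float, int, int]:
    """Fraction of covered htSNPs phased, with the underlying counts."""
    covered = profile.n_sites
    if covered == 0:
        raise ValueError("phasing rate undefined: no covered htSNPs")
    phased = profile.n_phased
    return phased / covered, phased, covered
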