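"""End-to-end orchestration and truth-based evaluation helpers.

`run_end_to_end` drives the full chain on synthetic gametes — QC,
two-stage phasing, trio phasing and agreement, low-density masking, HMM
crossover inference, abnormal-cell exclusion, and map construction — and
returns everything a recovery experiment needs.  The evaluation helpers
compare pipeline output against the simulator's recorded truth, always up
to the per-chromosome haplotype label swap that the phaser cannot (and
need not) determine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import maps as maps_mod
from .datatypes import DonorHaplotypes, GenotypeMatrix
from .hmm import HmmParams, flag_abnormal_cells, infer_crossovers, resolution_summary
from .io import GenomicInterval
from .phasing import PhasingConfig, phase_sperm, phasing_rate
from .qc import QCConfig, mask_low_density, run_site_qc
from .simulate import SimConfig, SimTruth, simulate_donor, simulate_gametes, simulate_trio
from .trio import TrioPhaseResult, agreement_rate, trio_phase_all

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# evaluation against simulator truth
# ---------------------------------------------------------------------------

def phasing_accuracy(
    profile: DonorHaplotypes, truth: DonorHaplotypes
) -> tuple[float, int, int]:
    """Fraction of phased sites matching truth, up to per-chromosome swap.

    For each chromosome the orientation (identity or swap) maximizing
    matches is chosen; returns ``(accuracy, correct, phased)``.
    """
    correct = 0
    phased = 0
    for chrom, ch in profile.chroms.items():
        tr = truth[chrom]
        if len(tr.positions) != len(ch.positions) or not np.array_equal(
            tr.positions, ch.positions
        ):
            # align on shared positions
            common, ia, ib = np.intersect1d(
                ch.positions, tr.positions, return_indices=True
            )
            hap1, th1 = ch.hap1[ia], tr.hap1[ib]
        else:
            hap1, th1 = ch.hap1, tr.hap1
        mask = hap1 >= 0
        if not mask.any():
            continue
        m_id = int(np.count_nonzero(hap1[mask] == th1[mask]))
        n = int(mask.sum())
        correct += max(m_id, n - m_id)
        phased += n
    if phased == 0:
        return float("nan"), 0, 0
    return correct / phased, correct, phased


def crossover_recovery(
    events: pd.DataFrame,
    truth: SimTruth,
    profile: DonorHaplotypes,
    cells: list[str] | None = None,
) -> dict:
    """Recall/precision of called events against true crossover positions.

    A true crossover is *identifiable* when it falls between the first and
    last phased htSNP of its chromosome and no other crossover of the same
    gamete shares its flanking-htSNP interval (two exchanges between the
    same adjacent informative sites cancel and are invisible in
    principle).  Recall is measured over identifiable truth; precision
    counts called events whose interval contains >= 1 true crossover of
    that gamete.
    """
    tr = truth.crossovers
    if cells is not None:
        tr = tr[tr["cell"].isin(cells)]
    n_identifiable = 0
    n_recalled = 0
    contained = np.zeros(len(events), dtype=bool)
    ev_by = {
        key: grp for key, grp in events.groupby(["cell", "chrom"], sort=False)
    }
    for (cell, chrom), grp in tr.groupby(["cell", "chrom"], sort=False):
        ch = profile[chrom]
        ppos = ch.positions[ch.phased_mask]
        if len(ppos) < 2:
            continue
        xpos = np.sort(grp["position"].to_numpy(dtype=float))
        inside = (xpos > ppos[0]) & (xpos < ppos[-1])
        # interval index between adjacent phased sites for each crossover
        iv = np.searchsorted(ppos, xpos)
        unique_iv = pd.Series(iv).value_counts()
        solo = pd.Series(iv).map(unique_iv) == 1
        identifiable = inside & solo.to_numpy()
        n_identifiable += int(identifiable.sum())
        sub = ev_by.get((cell, chrom))
        if sub is None:
            continue
        left = sub["left_pos"].to_numpy(dtype=float)
        right = sub["right_pos"].to_numpy(dtype=float)
        for x, ok in zip(xpos, identifiable):
            hit = (left < x) & (x < right)
            if ok and hit.any():
                n_recalled += 1
        for i, (l, r) in zip(sub.index, zip(left, right)):
            if np.any((xpos > l) & (xpos < r)):
                contained[events.index.get_loc(i)] = True
    recall = n_recalled / n_identifiable if n_identifiable else float("nan")
    precision = float(contained.mean()) if len(events) else float("nan")
    return {
        "recall": recall,
        "precision": precision,
        "n_identifiable_true": n_identifiable,
        "n_called": int(len(events)),
    }


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    matrix: GenotypeMatrix
    truth: SimTruth
    profile: DonorHaplotypes
    phasing_report: dict
    masks: list[GenomicInterval]
    events: pd.DataFrame
    per_cell_counts: pd.Series
    flagged_cells: list[str]
    recomb_map: maps_mod.RecombMap
    window_rates: pd.DataFrame
    trio_result: TrioPhaseResult | None = None
    trio_agreement: tuple | None = None


def run_end_to_end(
    sim_config: SimConfig,
    phasing_config: PhasingConfig | None = None,
    qc_config: QCConfig | None = None,
    hmm_params: HmmParams | None = None,
    with_trio: bool = True,
    trio_uninformative: float = 0.2,
    roh_regions: list[tuple[str, int, int]] | None = None,
    apply_qc: bool = True,
) -> PipelineResult:
    """Simulate a donor and sperm panel, then run the entire analysis."""
    from .simulate import inject_roh

    phasing_config = phasing_config or PhasingConfig()
    qc_config = qc_config or QCConfig()
    hmm_params = hmm_params or HmmParams()

    donor, _sites = simulate_donor(sim_config)
    if roh_regions:
        donor = inject_roh(donor, roh_regions)
    matrix, truth = simulate_gametes(donor, sim_config)
    if apply_qc:
        matrix, _qc_log = run_site_qc(matrix, qc_config)

    profile, report = phase_sperm(matrix, phasing_config)

    positions_by_chrom = {
        chrom: ch.positions[ch.phased_mask] for chrom, ch in profile.chroms.items()
    }
    masks = mask_low_density(positions_by_chrom, sim_config.chrom_lengths, qc_config)

    events, counts = infer_crossovers(matrix, profile, masks, hmm_params)
    flagged = flag_abnormal_cells(counts) if len(counts) >= 3 else []
    kept_cells = [c for c in matrix.cells if c not in flagged]
    events = events[events["cell"].isin(kept_cells)].reset_index(drop=True)

    rmap = maps_mod.map_summary(
        events, len(kept_cells), sim_config.chrom_lengths, masks, cells=kept_cells
    )
    rates = maps_mod.window_rates(
        events, len(kept_cells), sim_config.chrom_lengths, masks
    )

    trio_result = None
    agreement = None
    if with_trio:
        trio_table = simulate_trio(
            truth.donor, uninformative_fraction=trio_uninformative,
            seed=sim_config.seed,
        )
        trio_result = trio_phase_all(trio_table)
        try:
            agreement = agreement_rate(profile, trio_result)
        except ValueError:
            agreement = None

    return PipelineResult(
        matrix=matrix, truth=truth, profile=profile, phasing_report=report,
        masks=masks, events=events,
        per_cell_counts=counts.loc[kept_cells],
        flagged_cells=flagged, recomb_map=rmap, window_rates=rates,
        trio_result=trio_result, trio_agreement=agreement,
    )
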