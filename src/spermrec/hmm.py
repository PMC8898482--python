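"""Haplotype-of-origin decoding and crossover event calling.

Along the phased htSNPs of one chromosome, each sperm's calls are recoded
as matching haplotype 1 or haplotype 2.  The true haplotype of origin is a
two-state hidden sequence: it switches at each crossover and is observed
through a symmetric genotyping-error channel.  Viterbi decoding under

* emission ``P(obs = h' | state = h) = 1 - e`` if ``h' = h`` else ``e``,
* per-informative-interval switch probability ``t``,

yields the maximum a posteriori origin path; every state switch is one
crossover, localized to the interval between the flanking informative
sites, with the event position reported at the interval midpoint.

Sites that are missing in the cell, unphased, or inside low-density masks
are simply skipped: they contribute no emission and no transition step.
An isolated discordant call is absorbed as an error rather than a double
switch whenever ``2*ln(t) < ln(e/(1-e))``, which holds for the defaults
(e = 0.005, t = 1e-4).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .datatypes import CrossoverEvent, DonorHaplotypes, GenotypeMatrix, events_to_frame
from .io import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class HmmParams:
    """Emission error ``e`` and per-interval switch probability ``t``.

    Neither is identified by the assay itself, so both are explicit,
    reported in output metadata, and chosen so that single-call errors are
    absorbed (see module docstring).  ``distance_scaled`` optionally scales
    the switch probability by the physical gap between informative sites
    relative to the mean gap.
    """

    emission_error: float = 0.005
    transition_prob: float = 1e-4
    initial: tuple[float, float] = (0.5, 0.5)
    distance_scaled: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.emission_error < 0.5:
            raise ValueError("emission_error must lie in (0, 0.5)")
        if not 0.0 < self.transition_prob < 0.5:
            raise ValueError("transition_prob must lie in (0, 0.5)")
        if abs(sum(self.initial) - 1.0) > 1e-9 or min(self.initial) <= 0:
            raise ValueError("initial must be a positive distribution")

    def metadata(self) -> dict:
        return {
            "emission_error": self.emission_error,
            "transition_prob": self.transition_prob,
            "initial": list(self.initial),
            "distance_scaled": self.distance_scaled,
        }


def _interval_log_t(
    params: HmmParams, gaps: np.ndarray | None, n_steps: int
) -> list[tuple[float, float]]:
    """(log t_i, log(1-t_i)) per informative interval."""
    if not params.distance_scaled or gaps is None:
        lt = math.log(params.transition_prob)
        ls = math.log1p(-params.transition_prob)
        return [(lt, ls)] * n_steps
    mean_gap = float(np.mean(gaps)) if len(gaps) else 1.0
    out = []
    for g in gaps:
        t = min(0.49, params.transition_prob * g / mean_gap)
        out.append((math.log(t), math.log1p(-t)))
    return out


def viterbi_path(
    observations: np.ndarray,
    params: HmmParams | None = None,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Most probable origin path for one cell's informative observations.

    ``observations`` are coded 0 (matches hap1) / 1 (matches hap2); the
    returned path uses the same coding.  Ties are broken toward fewer
    switches and then toward state 0, deterministically; arithmetic is in
    log space.  An empty observation vector yields an empty path.
    """
    params = params or HmmParams()
    obs = np.asarray(observations)
    n = len(obs)
    if n == 0:
        return np.empty(0, dtype=np.int8)
    gaps = np.diff(positions) if positions is not None else None

    if not params.distance_scaled:
        # Uniform transitions: a path's log-probability is
        #   const + n_mismatch * (ln e - ln(1-e)) + n_switch * (ln t - ln(1-t))
        # so paths compare exactly through the integer pair (n_mismatch,
        # n_switch), evaluated canonically — equal-probability paths tie
        # bit-exactly and the tie-break (fewest switches, then the
        # lexicographically smallest path) is applied deterministically.
        return _viterbi_uniform(obs, params)
    return _viterbi_float(obs, params, gaps)


def _viterbi_uniform(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    n = len(obs)
    e, t = params.emission_error, params.transition_prob
    dm = math.log(e) - math.log1p(-e)   # cost of one mismatching emission
    dt = math.log(t) - math.log1p(-t)   # cost of one switch
    i0, i1 = (math.log(p) for p in params.initial)
    o = obs.tolist()

    # backward DP: best-suffix (n_mismatch, n_switch) per (site, state)
    mis0 = [0] * n
    mis1 = [0] * n
    sw0 = [0] * n
    sw1 = [0] * n
    mis0[n - 1] = 1 if o[n - 1] != 0 else 0
    mis1[n - 1] = 1 - mis0[n - 1]
    for k in range(n - 2, -1, -1):
        m0, m1 = mis0[k + 1], mis1[k + 1]
        w0, w1 = sw0[k + 1], sw1[k + 1]
        f0 = m0 * dm + w0 * dt
        f1 = m1 * dm + w1 * dt
        # candidate scores are evaluated with one canonical expression so
        # that equal (mismatch, switch) costs compare bit-exactly
        # state 0: stay -> (m0, w0); switch -> (m1, w1 + 1)
        fx = m1 * dm + (w1 + 1) * dt
        if fx > f0 or (fx == f0 and w1 + 1 < w0):
            bm0, bw0 = m1, w1 + 1
        else:
            bm0, bw0 = m0, w0
        # state 1: stay -> (m1, w1); switch -> (m0, w0 + 1)
        fx = m0 * dm + (w0 + 1) * dt
        if fx > f1 or (fx == f1 and w0 + 1 < w1):
            bm1, bw1 = m0, w0 + 1
        else:
            bm1, bw1 = m1, w1
        ok = o[k]
        mis0[k] = bm0 + (1 if ok != 0 else 0)
        sw0[k] = bw0
        mis1[k] = bm1 + (1 if ok != 1 else 0)
        sw1[k] = bw1

    path = np.empty(n, dtype=np.int8)
    k0 = (i0 + mis0[0] * dm + sw0[0] * dt, -sw0[0], 0)
    k1 = (i1 + mis1[0] * dm + sw1[0] * dt, -sw1[0], -1)
    s = 0 if k0 >= k1 else 1
    path[0] = s
    for k in range(n - 1):
        m0, m1 = mis0[k + 1], mis1[k + 1]
        w0, w1 = sw0[k + 1], sw1[k + 1]
        if s == 0:
            c0 = (m0 * dm + w0 * dt, -w0)
            c1 = (m1 * dm + (w1 + 1) * dt, -(w1 + 1))
        else:
            c0 = (m0 * dm + (w0 + 1) * dt, -(w0 + 1))
            c1 = (m1 * dm + w1 * dt, -w1)
        # prefer state 0 on a full tie (lexicographically smallest path)
        s = 0 if c0 >= c1 else 1
        path[k + 1] = s
    return path


def _viterbi_float(
    obs: np.ndarray, params: HmmParams, gaps: np.ndarray | None
) -> np.ndarray:
    """Distance-scaled variant: per-interval transition terms, float DP."""
    n = len(obs)
    le = math.log(params.emission_error)
    lm = math.log1p(-params.emission_error)
    trans = _interval_log_t(params, gaps, n - 1)

    def emit(o: int, s: int) -> float:
        return lm if o == s else le

    suffix_lp = np.empty((n, 2))
    suffix_sw = np.empty((n, 2), dtype=np.int64)
    for s in (0, 1):
        suffix_lp[n - 1, s] = emit(obs[n - 1], s)
        suffix_sw[n - 1, s] = 0
    for k in range(n - 2, -1, -1):
        lt, ls = trans[k]
        for s in (0, 1):
            stay = (ls + suffix_lp[k + 1, s], -suffix_sw[k + 1, s])
            switch = (lt + suffix_lp[k + 1, 1 - s], -(suffix_sw[k + 1, 1 - s] + 1))
            best = max(stay, switch)
            suffix_lp[k, s] = emit(obs[k], s) + best[0]
            suffix_sw[k, s] = -best[1]

    path = np.empty(n, dtype=np.int8)
    path[0] = max(
        (0, 1),
        key=lambda s: (math.log(params.initial[s]) + suffix_lp[0, s],
                       -suffix_sw[0, s], -s),
    )
    for k in range(n - 1):
        lt, ls = trans[k]
        s = int(path[k])
        cand = {
            s: (ls + suffix_lp[k + 1, s], -suffix_sw[k + 1, s]),
            1 - s: (lt + suffix_lp[k + 1, 1 - s], -(suffix_sw[k + 1, 1 - s] + 1)),
        }
        path[k + 1] = max((0, 1), key=lambda s2: (*cand[s2], -s2))
    return path


def brute_force_path(
    observations: np.ndarray,
    params: HmmParams | None = None,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Exhaustive maximum-probability path — the test oracle for Viterbi.

    Enumerates all state sequences (limited to 20 sites), accumulating log
    probabilities in the same left-to-right order as the Viterbi recursion
    so that ties are bit-exact, and applies the identical tie-break rule
    (max log-prob, then fewest switches, then lexicographically smallest
    path with state 0 first).
    """
    params = params or HmmParams()
    obs = np.asarray(observations)
    n = len(obs)
    if n == 0:
        return np.empty(0, dtype=np.int8)
    if n > 20:
        raise ValueError("brute force limited to 20 sites")
    best = None
    best_key = None
    if not params.distance_scaled:
        e, t = params.emission_error, params.transition_prob
        dm = math.log(e) - math.log1p(-e)
        dt = math.log(t) - math.log1p(-t)
        for path in product((0, 1), repeat=n):
            n_mis = sum(int(o != s) for o, s in zip(obs, path))
            n_sw = sum(int(a != b) for a, b in zip(path, path[1:]))
            key = (
                math.log(params.initial[path[0]]) + n_mis * dm + n_sw * dt,
                -n_sw,
            )
            if best_key is None or key > best_key:
                best_key = key
                best = path
        return np.array(best, dtype=np.int8)

    le = math.log(params.emission_error)
    lm = math.log1p(-params.emission_error)
    gaps = np.diff(positions) if positions is not None else None
    trans = _interval_log_t(params, gaps, n - 1)
    for path in product((0, 1), repeat=n):
        # accumulate right-to-left with the same association as the Viterbi
        # recursion so equal-probability paths tie bit-exactly
        lp = lm if obs[n - 1] == path[n - 1] else le
        nsw = 0
        for k in range(n - 2, -1, -1):
            lt, ls = trans[k]
            if path[k] != path[k + 1]:
                step = lt
                nsw += 1
            else:
                step = ls
            lp = (lm if obs[k] == path[k] else le) + (step + lp)
        lp = math.log(params.initial[path[0]]) + lp
        key = (lp, -nsw)
        if best_key is None or key > best_key:
            best_key = key
            best = path
    return np.array(best, dtype=np.int8)


def call_crossovers(
    states: np.ndarray, positions: np.ndarray, cell: str, chrom: str
) -> list[CrossoverEvent]:
    """One event per state switch, localized between flanking sites.

    The interval runs from the last informative site decoded in the old
    state to the first site in the new state; the event position is the
    interval midpoint.
    """
    states = np.asarray(states)
    positions = np.asarray(positions)
    switches = np.flatnonzero(np.diff(states) != 0)
    return [
        CrossoverEvent(
            cell=cell, chrom=chrom,
            left_pos=int(positions[i]), right_pos=int(positions[i + 1]),
        )
        for i in switches
    ]


def informative_observations(
    profile_chrom, calls_cell: np.ndarray, masks: list[GenomicInterval] | None,
    chrom: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and hap-match codes of one cell's informative sites.

    Informative = phased in the profile, non-missing in the cell, outside
    the low-density mask intervals.
    """
    phased = profile_chrom.phased_mask
    nonmiss = calls_cell >= 0
    keep = phased & nonmiss
    if masks:
        pos = profile_chrom.positions
        masked = np.zeros(len(pos), dtype=bool)
        for iv in masks:
            if iv.chrom == chrom:
                masked |= (pos > iv.start) & (pos <= iv.end)
        keep &= ~masked
    idx = np.flatnonzero(keep)
    obs = (calls_cell[idx] != profile_chrom.hap1[idx]).astype(np.int8)
    return profile_chrom.positions[idx], obs


def infer_crossovers(
    matrix: GenotypeMatrix,
    profile: DonorHaplotypes,
    masks: list[GenomicInterval] | None = None,
    params: HmmParams | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Decode every cell x chromosome and collect crossover events.

    Returns the event table (see :data:`spermrec.datatypes.EVENT_COLUMNS`)
    and the per-cell event counts (including zero-event cells).
    """
    params = params or HmmParams()
    events: list[CrossoverEvent] = []
    for chrom, positions, calls in matrix.by_chrom():
        if chrom not in profile.chroms:
            continue
        ch = profile[chrom]
        for j, cell in enumerate(matrix.cells):
            pos, obs = informative_observations(ch, calls[:, j], masks, chrom)
            if len(obs) == 0:
                continue
            path = viterbi_path(obs, params, positions=pos)
            events.extend(call_crossovers(path, pos, cell, chrom))
    df = events_to_frame(events)
    counts = (
        df.groupby("cell").size().reindex(matrix.cells, fill_value=0)
        if len(df)
        else pd.Series(0, index=pd.Index(matrix.cells, name="cell"))
    )
    return df, counts


def resolution_summary(
    events: pd.DataFrame,
    thresholds: tuple[int, ...] = (200_000, 100_000, 30_000),
) -> dict[int, float]:
    """Fraction of events localized to at most each interval width."""
    if len(events) == 0:
        raise ValueError("resolution summary undefined for zero events")
    res = events["resolution_bp"].to_numpy()
    return {thr: float(np.mean(res <= thr)) for thr in thresholds}


def flag_abnormal_cells(
    counts: pd.Series, n_mad: float = 3.0
) -> list[str]:
    """Cells with grossly abnormal crossover counts (robust outlier rule).

    Flags counts above ``median + n_mad * 1.4826 * MAD``; the scaled MAD
    estimates the spread robustly so a single aberrant cell (e.g. a
    contaminated or diploid droplet) cannot inflate its own threshold.
    """
    if len(counts) < 3:
        raise ValueError("need at least 3 cells to assess abnormality")
    vals = counts.to_numpy(dtype=float)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    threshold = med + n_mad * 1.4826 * mad
    return [str(c) for c in counts.index[vals > threshold]]
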