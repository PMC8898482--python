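"""Individual recombination maps, hotspots, QTL enrichment, comparisons.

Genetic distances follow the standard definitions: a chromosome's map
length in Morgans is the mean number of crossovers per gamete on it, and a
window's recombination rate in cM/Mb is ``100 * (events / n_cells)`` per
physical megabase.  Windows flagged by the low-density mask are excluded
from every denominator — they are reported as absent, never as rate zero.

Hotspots are windows whose rate exceeds the genome-wide mean by ``k``
standard deviations (default 2.5, sample SD over unmasked autosomal
windows).  Enrichment of hotspots in QTL uses one-sided Fisher exact tests
on the 1-Mb window unit, BH-adjusted across traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval

logger = logging.getLogger(__name__)

WINDOW_BP = 1_000_000


def _windows_for_chrom(length: int, window: int = WINDOW_BP) -> np.ndarray:
    """0-based half-open window boundaries tiling one chromosome."""
    starts = np.arange(0, length, window, dtype=np.int64)
    ends = np.minimum(starts + window, length)
    return np.column_stack([starts, ends])


def _window_grid(
    chrom_lengths: dict[str, int],
    masks: list[GenomicInterval] | None,
    window: int = WINDOW_BP,
) -> pd.DataFrame:
    rows = []
    masks = masks or []
    for chrom, length in chrom_lengths.items():
        for start, end in _windows_for_chrom(length, window):
            masked = any(
                iv.chrom == chrom and iv.start < end and start < iv.end
                for iv in masks
            )
            rows.append((chrom, int(start), int(end), masked))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "masked"])


def _assign_windows(
    events: pd.DataFrame, window: int = WINDOW_BP
) -> pd.Series:
    """Window start for each event midpoint (boundary goes right, half-open)."""
    mid = events["midpoint"].to_numpy(dtype=float)
    return pd.Series((np.floor(mid / window) * window).astype(np.int64),
                     index=events.index)


@dataclass
class RecombMap:
    """Per-chromosome and genome-wide recombination summaries."""

    per_chrom: pd.DataFrame     # chrom, events, morgans, length_bp
    mean_per_cell: float        # mean crossovers per cell (genome)
    sd: float                   # SD of per-cell totals
    se: float                   # SD / sqrt(n_cells)
    n_cells: int
    total_events: int
    rate_cm_per_mb: float       # 100 * mean Morgans / unmasked Mb
    unmasked_mb: float

    @property
    def genome_morgans(self) -> float:
        return float(self.per_chrom["morgans"].sum())


def _unmasked_events(
    events: pd.DataFrame, grid: pd.DataFrame, window: int = WINDOW_BP
) -> pd.DataFrame:
    """Events whose midpoint falls in an unmasked window."""
    if len(events) == 0:
        return events
    masked = set(
        map(tuple, grid.loc[grid["masked"], ["chrom", "start"]].itertuples(index=False))
    )
    win = _assign_windows(events, window)
    keep = [
        (c, s) not in masked
        for c, s in zip(events["chrom"].to_numpy(), win.to_numpy())
    ]
    return events.loc[keep]


def map_summary(
    events: pd.DataFrame,
    n_cells: int,
    chrom_lengths: dict[str, int],
    masks: list[GenomicInterval] | None = None,
    cells: list[str] | None = None,
) -> RecombMap:
    """Build the individual recombination map from called events.

    ``cells`` lists every analyzed cell so that zero-event cells enter the
    per-cell mean/SD (defaults to the cells present in ``events``).
    Events with midpoints inside masked windows are excluded throughout.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    grid = _window_grid(chrom_lengths, masks)
    used = _unmasked_events(events, grid)
    per_chrom_counts = used.groupby("chrom").size() if len(used) else pd.Series(dtype=int)
    rows = []
    for chrom, length in chrom_lengths.items():
        k = int(per_chrom_counts.get(chrom, 0))
        rows.append((chrom, k, k / n_cells, length))
    per_chrom = pd.DataFrame(rows, columns=["chrom", "events", "morgans", "length_bp"])
    if cells is None:
        cells = sorted(used["cell"].unique()) if len(used) else []
    per_cell = (
        used.groupby("cell").size().reindex(cells, fill_value=0)
        if cells else pd.Series(dtype=float)
    )
    total = int(len(used))
    mean = total / n_cells
    sd = float(per_cell.std(ddof=1)) if len(per_cell) > 1 else 0.0
    if len(per_cell) <= 1 or np.isnan(sd):
        sd = 0.0
    se = sd / np.sqrt(n_cells)
    unmasked_mb = float((~grid["masked"]).mul(grid["end"] - grid["start"]).sum()) / 1e6
    rate = 100.0 * mean / unmasked_mb if unmasked_mb > 0 else float("nan")
    return RecombMap(
        per_chrom=per_chrom, mean_per_cell=mean, sd=sd, se=se,
        n_cells=n_cells, total_events=total, rate_cm_per_mb=rate,
        unmasked_mb=unmasked_mb,
    )


def window_rates(
    events: pd.DataFrame,
    n_cells: int,
    chrom_lengths: dict[str, int],
    masks: list[GenomicInterval] | None = None,
    window: int = WINDOW_BP,
) -> pd.DataFrame:
    """Per-window crossover counts and rates in cM/Mb (masked absent).

    Events are assigned to windows by midpoint; a midpoint exactly on a
    boundary belongs to the right-hand (half-open) window.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    grid = _window_grid(chrom_lengths, masks, window)
    grid = grid[~grid["masked"]].drop(columns="masked").reset_index(drop=True)
    counts = np.zeros(len(grid), dtype=np.int64)
    if len(events):
        win = _assign_windows(events, window)
        tally = (
            pd.DataFrame({"chrom": events["chrom"], "start": win})
            .groupby(["chrom", "start"]).size()
        )
        key = pd.MultiIndex.from_frame(grid[["chrom", "start"]])
        counts = tally.reindex(key, fill_value=0).to_numpy()
    out = grid.copy()
    out["count"] = counts
    mb = (out["end"] - out["start"]) / 1e6
    out["rate_cm_per_mb"] = 100.0 * (out["count"] / n_cells) / mb
    return out


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    start: int
    end: int
    rate: float
    threshold: float

    def __post_init__(self) -> None:
        if not self.rate > self.threshold:
            raise ValueError("hotspot rate must exceed the threshold")


def detect_hotspots(
    window_df: pd.DataFrame, k: float = 2.5
) -> tuple[list[Hotspot], float]:
    """Windows whose rate strictly exceeds mean + k*SD (genome-wide).

    Mean and SD are computed over the unmasked windows provided; with all
    rates equal (SD = 0) nothing can strictly exceed the threshold.
    Returns the hotspot list and the threshold used.
    """
    if len(window_df) < 2:
        raise ValueError("need at least 2 unmasked windows")
    rates = window_df["rate_cm_per_mb"].to_numpy(dtype=float)
    threshold = float(np.mean(rates) + k * np.std(rates, ddof=1))
    hot = window_df[rates > threshold]
    return (
        [
            Hotspot(str(r.chrom), int(r.start), int(r.end),
                    float(r.rate_cm_per_mb), threshold)
            for r in hot.itertuples(index=False)
        ],
        threshold,
    )


def shared_hotspots(
    a: list[Hotspot], b: list[Hotspot]
) -> list[tuple[Hotspot, Hotspot]]:
    """Hotspot windows flagged in both maps (interval overlap)."""
    pairs = []
    for ha in a:
        for hb in b:
            if ha.chrom == hb.chrom and ha.start < hb.end and hb.start < ha.end:
                pairs.append((ha, hb))
    return pairs


def fisher_exact_2x2(
    table: np.ndarray | list[list[int]], alternative: str = "greater"
) -> float:
    """Fisher exact p-value for a 2x2 contingency table.

    Exact hypergeometric tail probability; an empty margin yields p = 1.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 and non-negative")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(t, alternative=alternative)[1])


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def qtl_enrichment(
    hotspots: list[Hotspot],
    all_windows: pd.DataFrame,
    qtl: pd.DataFrame,
) -> pd.DataFrame:
    """Per-trait hotspot x QTL enrichment table with Fisher p and BH q.

    ``all_windows`` is the unmasked window grid (from :func:`window_rates`);
    ``qtl`` carries columns ``chrom, start, end, trait`` (0-based
    half-open).  Per trait, the 2x2 classifies windows as hotspot vs not
    and overlapping >= 1 of the trait's intervals vs not; the test is
    one-sided (greater), BH-adjusted across traits.
    """
    hotset = {(h.chrom, h.start) for h in hotspots}
    is_hot = np.array([
        (c, s) in hotset
        for c, s in zip(all_windows["chrom"], all_windows["start"])
    ])
    rows = []
    for trait, sub in qtl.groupby("trait", sort=True):
        overlap = np.zeros(len(all_windows), dtype=bool)
        for r in sub.itertuples(index=False):
            overlap |= (
                (all_windows["chrom"].to_numpy() == r.chrom)
                & (all_windows["start"].to_numpy() < r.end)
                & (all_windows["end"].to_numpy() > r.start)
            )
        a = int((is_hot & overlap).sum())
        b = int((is_hot & ~overlap).sum())
        c = int((~is_hot & overlap).sum())
        d = int((~is_hot & ~overlap).sum())
        p = fisher_exact_2x2([[a, b], [c, d]], alternative="greater")
        rows.append((trait, a, b, c, d, p))
    out = pd.DataFrame(
        rows,
        columns=["trait", "hot_qtl", "hot_other", "cold_qtl", "cold_other", "p"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def compare_maps(
    rates_a: pd.DataFrame,
    rates_b: pd.DataFrame,
    chrom_lengths: dict[str, int],
    exclude_terminal_bp: int = 5_000_000,
    span: float = 0.3,
) -> tuple[pd.DataFrame, float, float]:
    """LOESS-smoothed comparison of two maps on relative coordinates.

    Windows intersecting the terminal ``exclude_terminal_bp`` of each
    chromosome can be excluded (array/pedigree data under-ascertain distal
    crossovers); window rates are placed at window midpoint / chromosome
    length and pooled across chromosomes, each curve is smoothed with
    locally weighted linear regression (tri-cube weights, fraction
    ``span``), and the Pearson correlation of the two smoothed curves on
    the shared support is returned as ``(table, r, p)``.
    """
    merged = rates_a.merge(
        rates_b, on=["chrom", "start", "end"], suffixes=("_a", "_b")
    )
    if exclude_terminal_bp:
        keep = []
        for r in merged.itertuples(index=False):
            L = chrom_lengths[r.chrom]
            keep.append(
                r.start >= exclude_terminal_bp and r.end <= L - exclude_terminal_bp
            )
        merged = merged[np.array(keep, dtype=bool)]
    if len(merged) < 3:
        raise ValueError("need at least 3 shared windows to compare maps")
    x = np.array([
        ((r.start + r.end) / 2) / chrom_lengths[r.chrom]
        for r in merged.itertuples(index=False)
    ])
    order = np.argsort(x, kind="stable")
    merged = merged.iloc[order].reset_index(drop=True)
    x = x[order]
    sm_a = lowess(merged["rate_cm_per_mb_a"], x, frac=span, return_sorted=False)
    sm_b = lowess(merged["rate_cm_per_mb_b"], x, frac=span, return_sorted=False)
    out = merged[["chrom", "start", "end"]].copy()
    out["rel_pos"] = x
    out["rate_a"], out["rate_b"] = merged["rate_cm_per_mb_a"], merged["rate_cm_per_mb_b"]
    out["smooth_a"], out["smooth_b"] = sm_a, sm_b
    r, p = stats.pearsonr(sm_a, sm_b)
    return out, float(r), float(p)


def cumulative_map(
    rates: pd.DataFrame, n_cells: int
) -> dict[str, pd.DataFrame]:
    """Per-chromosome cumulative genetic length vs physical position.

    Uses the per-window event counts of :func:`window_rates`; the curve is
    non-decreasing and ends at the chromosome's Morgans (over unmasked
    windows).
    """
    out = {}
    for chrom, sub in rates.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cum = sub["count"].cumsum() / n_cells
        out[str(chrom)] = pd.DataFrame({
            "pos": sub["end"].to_numpy(),
            "cum_morgans": cum.to_numpy(),
        })
    return out


def double_crossover_spacing(events: pd.DataFrame) -> tuple[float, int]:
    """Mean midpoint distance on (cell, chromosome) pairs with 2 events.

    Returns ``(mean_bp, n_pairs)``; with no qualifying chromosome the mean
    is NaN and the count 0.
    """
    if len(events) == 0:
        return float("nan"), 0
    spacings = []
    for _, grp in events.groupby(["cell", "chrom"]):
        if len(grp) == 2:
            mids = np.sort(grp["midpoint"].to_numpy(dtype=float))
            spacings.append(mids[1] - mids[0])
    if not spacings:
        return float("nan"), 0
    return float(np.mean(spacings)), len(spacings)
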