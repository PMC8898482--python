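"""Shared in-memory containers for the single-sperm recombination pipeline.

Coding conventions used throughout the package:

* haploid sperm calls are ``int8``: ``0`` (reference allele), ``1`` (first
  alternate allele), ``MISSING`` (``-1``) for dropout, and ``HET_RAW``
  (``-2``) for a raw heterozygous call observed in haploid mode (retained
  until variant QC converts it to missing);
* genomic positions are 1-based bp (VCF convention); interval arithmetic is
  0-based half-open (BED convention) — see :mod:`spermrec.io` for converters;
* donor haplotypes are complementary 0/1 allele vectors over the ordered
  htSNP positions of each chromosome, with ``-1`` marking unphased sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

MISSING = -1
HET_RAW = -2

# phase-status provenance codes
PHASE_UNPHASED = 0
PHASE_ANCHOR = 1
PHASE_WINDOW = 2
PHASE_CELL = 3

PHASE_STATUS_NAMES = {
    PHASE_UNPHASED: "unphased",
    PHASE_ANCHOR: "anchor",
    PHASE_WINDOW: "window_imputed",
    PHASE_CELL: "cell_imputed",
}
PHASE_STATUS_CODES = {v: k for k, v in PHASE_STATUS_NAMES.items()}


@dataclass
class ChromHaplotypes:
    """Phased (or partially phased) donor haplotypes on one chromosome.

    ``hap1``/``hap2`` hold the allele carried by each chromosome-level
    haplotype at every htSNP position; unphased sites carry ``-1`` in both.
    At phased sites the two haplotypes are complementary by construction
    (the donor is heterozygous at every htSNP).
    """

    positions: np.ndarray  # 1-based bp, strictly increasing, int64
    hap1: np.ndarray       # int8 in {-1, 0, 1}
    hap2: np.ndarray
    status: np.ndarray     # int8 phase-status codes

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        self.hap2 = np.asarray(self.hap2, dtype=np.int8)
        self.status = np.asarray(self.status, dtype=np.int8)
        n = len(self.positions)
        if not (len(self.hap1) == len(self.hap2) == len(self.status) == n):
            raise ValueError("haplotype arrays must share one length")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        ph = self.phased_mask
        if np.any(self.hap1[ph] == self.hap2[ph]):
            raise ValueError("hap1 and hap2 must differ at phased sites")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def phased_mask(self) -> np.ndarray:
        return self.hap1 >= 0

    @property
    def n_phased(self) -> int:
        return int(self.phased_mask.sum())


@dataclass
class DonorHaplotypes:
    """Per-chromosome phased allele pairs with phase-status provenance."""

    chroms: dict[str, ChromHaplotypes] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> ChromHaplotypes:
        return self.chroms[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.chroms)

    @property
    def n_sites(self) -> int:
        return sum(c.n_sites for c in self.chroms.values())

    @property
    def n_phased(self) -> int:
        return sum(c.n_phased for c in self.chroms.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, ch in self.chroms.items():
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "pos": ch.positions,
                "hap1": ch.hap1,
                "hap2": ch.hap2,
                "status": [PHASE_STATUS_NAMES[s] for s in ch.status],
            }))
        if not rows:
            return pd.DataFrame(columns=["chrom", "pos", "hap1", "hap2", "status"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DonorHaplotypes":
        chroms: dict[str, ChromHaplotypes] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            chroms[str(chrom)] = ChromHaplotypes(
                positions=grp["pos"].to_numpy(np.int64),
                hap1=grp["hap1"].to_numpy(np.int8),
                hap2=grp["hap2"].to_numpy(np.int8),
                status=np.array(
                    [PHASE_STATUS_CODES[s] for s in grp["status"]], dtype=np.int8
                ),
            )
        return cls(chroms)


@dataclass
class GenotypeMatrix:
    """Haploid calls at ordered variant sites × sperm cells.

    ``sites`` is a DataFrame with at least ``chrom``, ``pos``, ``ref``,
    ``alt`` (optionally the QC INFO columns ``qd``, ``fs``, ``sor``, ``mq``,
    ``qual`` and the flag ``is_indel``); ``calls`` is an ``(n_sites,
    n_cells)`` int8 array; ``ad`` optionally holds per-call ref/alt read
    support as an ``(n_sites, n_cells, 2)`` array.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    cells: list[str]
    ad: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.cells)):
            raise ValueError("calls shape must be (n_sites, n_cells)")
        if self.ad is not None and self.ad.shape[:2] != self.calls.shape:
            raise ValueError("ad shape must match calls")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[mask],
            cells=list(self.cells),
            ad=None if self.ad is None else self.ad[mask],
        )

    def subset_cells(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.cells.index(c) for c in keep]
        return GenotypeMatrix(
            sites=self.sites.copy(),
            calls=self.calls[:, idx],
            cells=list(keep),
            ad=None if self.ad is None else self.ad[:, idx],
        )

    def by_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """Yield ``(chrom, positions, calls_slice)`` in order of appearance."""
        chrom_col = self.sites["chrom"].to_numpy()
        pos_col = self.sites["pos"].to_numpy(np.int64)
        for chrom in pd.unique(chrom_col):
            m = chrom_col == chrom
            yield str(chrom), pos_col[m], self.calls[m]

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.sites["chrom"].to_numpy() == chrom)


@dataclass(frozen=True)
class CrossoverEvent:
    """One inferred meiotic exchange, localized to a flanking-htSNP interval."""

    cell: str
    chrom: str
    left_pos: int
    right_pos: int

    def __post_init__(self) -> None:
        if self.left_pos >= self.right_pos:
            raise ValueError("left_pos must be < right_pos")

    @property
    def midpoint(self) -> float:
        return (self.left_pos + self.right_pos) / 2.0

    @property
    def resolution(self) -> int:
        return self.right_pos - self.left_pos


EVENT_COLUMNS = ["cell", "chrom", "left_pos", "right_pos", "midpoint", "resolution_bp"]


def events_to_frame(events: list[CrossoverEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.cell, e.chrom, e.left_pos, e.right_pos, e.midpoint, e.resolution)
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )


def frame_to_events(df: pd.DataFrame) -> list[CrossoverEvent]:
    return [
        CrossoverEvent(
            cell=str(r.cell), chrom=str(r.chrom),
            left_pos=int(r.left_pos), right_pos=int(r.right_pos),
        )
        for r in df.itertuples(index=False)
    ]
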