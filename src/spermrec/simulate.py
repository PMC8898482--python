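"""Synthetic gamete generator with known ground truth.

Generates a heterozygous diploid donor, single-sperm genotype matrices with
known crossovers, genotyping error and coverage-dependent dropout, and trio
genotypes consistent with the donor's haplotypes.  Every downstream stage of
the pipeline is testable against the recorded truth without external data.

The generative model is deliberately simple and is a stand-in — no published
generative model exists for this assay.  Its defaults emulate the regime of
low-pass single-sperm sequencing of a Holstein bull: dense htSNPs, roughly
one crossover per chromosome per gamete (about 30 Morgans genome-wide over
the autosomes), heavy per-call dropout from ~1.8x amplified coverage, and a
mild enrichment of crossovers near the distal chromosome ends.  What the
simulator does *not* emulate is documented in ``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    PHASE_ANCHOR,
    ChromHaplotypes,
    DonorHaplotypes,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)

_REF_ALT = ("A", "G")  # ref/alt alleles used for emitted sites


@dataclass
class SimConfig:
    """Parameters of the synthetic single-sperm experiment.

    Parameters
    ----------
    chrom_lengths
        Physical length in bp of each simulated chromosome.
    htsnp_density
        Expected heterozygous SNPs per Mb (sites are placed by a Poisson
        draw of the count, uniformly along the chromosome).
    map_length
        Expected crossovers per gamete per chromosome, in Morgans.  A scalar
        applies to every chromosome; a sequence gives one value per
        chromosome.
    distal_enrichment
        Weight in [0, 1] mixing uniform crossover placement with a U-shaped,
        end-biased placement density (Beta(0.5, 0.5) scaled to chromosome
        length).  0 = uniform, 1 = fully end-biased.
    error_rate
        Per-call probability that the emitted allele is flipped.
    missing_rate
        Per-call dropout probability (i.i.d. across sites and cells).
    n_cells
        Number of sperm cells to simulate.
    seed
        Seed of the generator; identical configs are bit-reproducible.
    """

    chrom_lengths: dict[str, int]
    htsnp_density: float = 60.0
    map_length: float | dict[str, float] = 1.0
    distal_enrichment: float = 0.3
    error_rate: float = 0.01
    missing_rate: float = 0.6
    n_cells: int = 72
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("need at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if self.htsnp_density <= 0:
            raise ValueError("htsnp_density must be > 0")
        for rate, name in (
            (self.distal_enrichment, "distal_enrichment"),
            (self.error_rate, "error_rate"),
            (self.missing_rate, "missing_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for m in self.map_lengths().values():
            if m < 0:
                raise ValueError("map_length must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def map_lengths(self) -> dict[str, float]:
        """Morgans per chromosome as a dict, whatever form was configured."""
        if isinstance(self.map_length, dict):
            return dict(self.map_length)
        return {c: float(self.map_length) for c in self.chrom_lengths}

    @classmethod
    def holstein_like(
        cls,
        n_cells: int = 72,
        seed: int = 0,
        scale: float = 1.0,
        **kwargs,
    ) -> "SimConfig":
        """A cattle-autosome-like preset: 29 acrocentric autosomes.

        Lengths decline smoothly from ~158 Mb to ~42 Mb (total ~2.5 Gb, the
        magnitude of the bovine autosomal genome, without copying any genome
        build), and per-chromosome map lengths are proportional to physical
        length, normalized to 30 Morgans genome-wide — about one expected
        crossover per chromosome per gamete.  ``scale`` shrinks all physical
        lengths (htSNP counts scale with them) for cheaper experiments.
        """
        n = 29
        lengths = np.linspace(158e6, 42e6, n) * scale
        chrom_lengths = {f"chr{i + 1}": int(L) for i, L in enumerate(lengths)}
        total = sum(chrom_lengths.values())
        map_length = {c: 30.0 * L / total for c, L in chrom_lengths.items()}
        return cls(
            chrom_lengths=chrom_lengths,
            map_length=map_length,
            n_cells=n_cells,
            seed=seed,
            **kwargs,
        )


@dataclass
class SimTruth:
    """Simulator ground truth for parameter-recovery experiments."""

    donor: DonorHaplotypes
    # chrom -> (n_sites, n_cells) int8 array of haplotype-of-origin (1 or 2)
    gamete_origins: dict[str, np.ndarray]
    # columns: cell, chrom, position (bp, float — crossovers fall between bp)
    crossovers: pd.DataFrame
    config: SimConfig | None = None

    def crossover_counts(self, cells: list[str]) -> pd.Series:
        counts = self.crossovers.groupby("cell").size()
        return counts.reindex(cells, fill_value=0)


def _donor_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, 101])


def simulate_donor(config: SimConfig) -> tuple[DonorHaplotypes, pd.DataFrame]:
    """Draw htSNP positions and complementary donor haplotypes.

    Returns the fully phased donor truth and a site table (``chrom``, ``pos``,
    ``ref``, ``alt`` plus INFO columns pre-filled with values that pass the
    default hard filters, so QC is exercised as a no-op on clean data).
    """
    rng = _donor_rng(config.seed)
    chroms: dict[str, ChromHaplotypes] = {}
    frames = []
    for chrom, length in config.chrom_lengths.items():
        n = rng.poisson(config.htsnp_density * length / 1e6)
        positions = np.unique(rng.integers(1, length + 1, size=n))
        hap1 = rng.integers(0, 2, size=len(positions)).astype(np.int8)
        chroms[chrom] = ChromHaplotypes(
            positions=positions,
            hap1=hap1,
            hap2=(1 - hap1).astype(np.int8),
            status=np.full(len(positions), PHASE_ANCHOR, dtype=np.int8),
        )
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": positions,
            "ref": _REF_ALT[0],
            "alt": _REF_ALT[1],
            "qd": 25.0,
            "fs": 1.0,
            "sor": 1.0,
            "mq": 60.0,
            "qual": 500.0,
            "is_indel": False,
        }))
    sites = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    )
    return DonorHaplotypes(chroms), sites


def _draw_crossover_positions(
    rng: np.random.Generator, k: int, length: int, distal_weight: float
) -> np.ndarray:
    """Positions of ``k`` crossovers: mixture of uniform and U-shaped draws."""
    if k == 0:
        return np.empty(0)
    from_ushape = rng.random(k) < distal_weight
    pos = np.empty(k)
    n_u = int(from_ushape.sum())
    if n_u:
        pos[from_ushape] = rng.beta(0.5, 0.5, size=n_u) * length
    if k - n_u:
        pos[~from_ushape] = rng.random(k - n_u) * length
    return np.sort(pos)


def simulate_gametes(
    donor: DonorHaplotypes, config: SimConfig
) -> tuple[GenotypeMatrix, SimTruth]:
    """Transmit haploid gametes from the donor with known crossovers.

    Per cell and chromosome the crossover count is Poisson(map_length);
    positions follow the configured mixture density.  The emitted call at a
    site is the allele of the haplotype of origin, flipped with probability
    ``error_rate`` and then dropped with probability ``missing_rate``.
    """
    if donor.n_sites == 0:
        raise ValueError("donor carries no htSNPs on any chromosome")
    rng = np.random.default_rng([config.seed, 202])
    cells = [f"cell{i:03d}" for i in range(config.n_cells)]
    map_lengths = config.map_lengths()

    call_blocks: list[np.ndarray] = []
    frames: list[pd.DataFrame] = []
    origins: dict[str, np.ndarray] = {}
    xover_rows: list[tuple[str, str, float]] = []

    for chrom, ch in donor.chroms.items():
        length = config.chrom_lengths[chrom]
        n_sites = ch.n_sites
        origin = np.empty((n_sites, config.n_cells), dtype=np.int8)
        calls = np.empty((n_sites, config.n_cells), dtype=np.int8)
        hap_alleles = np.stack([ch.hap1, ch.hap2])  # (2, n_sites)
        for j, cell in enumerate(cells):
            k = rng.poisson(map_lengths.get(chrom, 0.0))
            xpos = _draw_crossover_positions(rng, k, length, config.distal_enrichment)
            start = rng.integers(0, 2)  # 0 => hap1, 1 => hap2
            # origin state at a site flips once per crossover to its left
            n_left = np.searchsorted(xpos, ch.positions)
            state = (start + n_left) % 2
            origin[:, j] = state + 1
            calls[:, j] = hap_alleles[state, np.arange(n_sites)]
            for p in xpos:
                xover_rows.append((cell, chrom, float(p)))
        if config.error_rate > 0:
            flips = rng.random(calls.shape) < config.error_rate
            calls[flips] = 1 - calls[flips]
        if config.missing_rate > 0:
            drop = rng.random(calls.shape) < config.missing_rate
            calls[drop] = MISSING
        origins[chrom] = origin
        call_blocks.append(calls)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": ch.positions,
            "ref": _REF_ALT[0], "alt": _REF_ALT[1],
        }))

    sites = pd.concat(frames, ignore_index=True)
    matrix = GenotypeMatrix(
        sites=sites, calls=np.vstack(call_blocks), cells=cells
    )
    crossovers = pd.DataFrame(xover_rows, columns=["cell", "chrom", "position"])
    truth = SimTruth(
        donor=donor, gamete_origins=origins, crossovers=crossovers, config=config
    )
    return matrix, truth


def simulate_trio(
    donor: DonorHaplotypes, uninformative_fraction: float = 0.2, seed: int = 0
) -> pd.DataFrame:
    """Emit parental diploid genotypes Mendelian-consistent with the donor.

    The donor is treated as the offspring, receiving hap1 paternally and
    hap2 maternally.  At an ``uninformative_fraction`` of sites both parents
    are heterozygous (unphasable by trio logic); at the remaining sites one
    of the three phase-informative parental configurations is drawn
    uniformly: (sire hom P, dam hom M), (sire het, dam hom M),
    (sire hom P, dam het).

    Returns a table with columns ``chrom, pos, off1, off2, sire1, sire2,
    dam1, dam2`` (unordered allele pairs coded 0/1, ``off1`` paternal).
    """
    if not 0.0 <= uninformative_fraction <= 1.0:
        raise ValueError("uninformative_fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 303])
    rows = []
    for chrom, ch in donor.chroms.items():
        if not np.all(ch.phased_mask):
            raise ValueError("donor must be fully phased to simulate a trio")
        n = ch.n_sites
        uninf = rng.random(n) < uninformative_fraction
        condition = rng.integers(0, 3, size=n)
        p = ch.hap1.astype(np.int8)  # paternal allele
        m = ch.hap2.astype(np.int8)  # maternal allele
        sire1, sire2 = p.copy(), p.copy()
        dam1, dam2 = m.copy(), m.copy()
        het_sire = ~uninf & (condition == 1)
        het_dam = ~uninf & (condition == 2)
        sire2[het_sire | uninf] = 1 - p[het_sire | uninf]
        dam2[het_dam | uninf] = 1 - m[het_dam | uninf]
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": ch.positions,
            "off1": p, "off2": m,
            "sire1": sire1, "sire2": sire2,
            "dam1": dam1, "dam2": dam2,
        }))
    return pd.concat(rows, ignore_index=True)


def inject_roh(
    donor: DonorHaplotypes, regions: list[tuple[str, int, int]]
) -> DonorHaplotypes:
    """Remove htSNPs inside runs of homozygosity (0-based half-open bp).

    Emulates donor regions devoid of heterozygosity, which downstream QC
    must flag as low-htSNP-density masks.
    """
    for chrom, start, end in regions:
        if start >= end:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
    chroms: dict[str, ChromHaplotypes] = {}
    for chrom, ch in donor.chroms.items():
        keep = np.ones(ch.n_sites, dtype=bool)
        for rchrom, start, end in regions:
            if rchrom != chrom:
                continue
            # site pos is 1-based: inside the half-open region iff
            # start < pos <= end
            keep &= ~((ch.positions > start) & (ch.positions <= end))
        chroms[chrom] = ChromHaplotypes(
            positions=ch.positions[keep],
            hap1=ch.hap1[keep],
            hap2=ch.hap2[keep],
            status=ch.status[keep],
        )
    return DonorHaplotypes(chroms)
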