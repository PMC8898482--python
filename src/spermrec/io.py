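"""Reading and writing the standard formats the pipeline touches.

Coordinate conventions: VCF positions are 1-based; all interval arithmetic
(BED, density masks, windows) is 0-based half-open.  ``vcf_to_bed_interval``
and ``bed_interval_to_vcf_pos`` are the inverse converters.

Only the VCF fields the pipeline uses are handled (GT, AD, INFO keys
QD/FS/SOR/MQ plus QUAL); reading goes through :mod:`pysam`, writing emits
VCF 4.2 text directly.  Gzipped input/output is supported transparently
(pysam for reading, :mod:`gzip` for writing when the path ends in ``.gz``).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .datatypes import EVENT_COLUMNS, HET_RAW, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

INFO_KEYS = ("QD", "FS", "SOR", "MQ")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def vcf_to_bed_interval(chrom: str, pos: int) -> GenomicInterval:
    """The single-base interval covering a 1-based VCF position."""
    return GenomicInterval(chrom, pos - 1, pos)


def bed_interval_to_vcf_pos(iv: GenomicInterval) -> int:
    """1-based position of the first base of an interval."""
    return iv.start + 1


def _opener(path: str, mode: str = "wt"):
    if str(path).endswith(".gz"):
        if "w" in mode:
            # bgzip so that pysam/htslib tools can read the result
            import io as _io
            return _io.TextIOWrapper(pysam.BGZFile(str(path), "wb"))
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, ploidy_mode: str = "haploid"):
    """Read a VCF into a site table plus genotype (and AD) matrices.

    In haploid mode calls are coded 0/1/``MISSING`` with raw heterozygous
    diploid GTs retained as ``HET_RAW`` for variant QC to resolve.  In
    diploid mode an ``(n_sites, n_cells, 2)`` allele-pair array is returned
    (unordered, ``MISSING`` per allele).  Multi-allelic records are skipped
    with a logged count; unsorted input is sorted with a warning.
    """
    if ploidy_mode not in ("haploid", "diploid"):
        raise ValueError("ploidy_mode must be 'haploid' or 'diploid'")
    vcf = pysam.VariantFile(path)
    cells = list(vcf.header.samples)
    site_rows = []
    gt_rows = []
    ad_rows = []
    have_ad = False
    n_multi = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        info = {k.lower(): float(rec.info[k]) if k in rec.info else np.nan
                for k in INFO_KEYS}
        site_rows.append({
            "chrom": rec.chrom, "pos": rec.pos,
            "ref": rec.ref, "alt": rec.alts[0],
            "qual": np.nan if rec.qual is None else float(rec.qual),
            "is_indel": len(rec.ref) != 1 or len(rec.alts[0]) != 1,
            **info,
        })
        gts = []
        ads = []
        for cell in cells:
            sample = rec.samples[cell]
            gt = tuple(a for a in sample["GT"] if a is not None)
            if ploidy_mode == "haploid":
                if len(gt) == 0:
                    gts.append(MISSING)
                elif len(set(gt)) == 1:
                    gts.append(int(gt[0]))
                else:
                    gts.append(HET_RAW)
            else:
                if len(gt) == 0:
                    gts.append((MISSING, MISSING))
                elif len(gt) == 1:
                    gts.append((int(gt[0]), int(gt[0])))
                else:
                    gts.append((int(gt[0]), int(gt[1])))
            ad = sample.get("AD")
            if ad is not None and len(ad) >= 2 and ad[0] is not None:
                have_ad = True
                ads.append((int(ad[0]), int(ad[1])))
            else:
                ads.append((0, 0))
        gt_rows.append(gts)
        ad_rows.append(ads)
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    sites = pd.DataFrame(
        site_rows,
        columns=["chrom", "pos", "ref", "alt", "qual", "is_indel",
                 *(k.lower() for k in INFO_KEYS)],
    )
    if ploidy_mode == "haploid":
        calls = np.array(gt_rows, dtype=np.int8).reshape(len(sites), len(cells))
    else:
        calls = np.array(gt_rows, dtype=np.int8).reshape(len(sites), len(cells), 2)
    ad = (
        np.array(ad_rows, dtype=np.int32).reshape(len(sites), len(cells), 2)
        if have_ad else None
    )
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    if not np.array_equal(order, np.arange(len(sites))):
        logger.warning("input VCF not sorted by (chrom, pos); sorting")
        sites = sites.iloc[order].reset_index(drop=True)
        calls = calls[order]
        if ad is not None:
            ad = ad[order]
    return sites, calls, cells, ad


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depth">
"""


def _contig_lines(sites: pd.DataFrame, chrom_lengths: dict[str, int] | None) -> str:
    chroms = list(pd.unique(sites["chrom"])) if chrom_lengths is None else list(chrom_lengths)
    out = []
    for c in chroms:
        if chrom_lengths and c in chrom_lengths:
            out.append(f"##contig=<ID={c},length={chrom_lengths[c]}>")
        else:
            out.append(f"##contig=<ID={c}>")
    return "\n".join(out) + "\n" if out else ""


def _info_field(row) -> str:
    parts = []
    for key in INFO_KEYS:
        val = row.get(key.lower(), np.nan) if hasattr(row, "get") else np.nan
        if val == val:  # not NaN
            parts.append(f"{key}={val:g}")
    return ";".join(parts) if parts else "."


def write_haploid_vcf(
    matrix: GenotypeMatrix,
    path: str,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write haploid per-cell calls (GT "0"/"1", missing ".")."""
    code = {0: "0", 1: "1", MISSING: ".", HET_RAW: "0/1"}
    with _opener(path) as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(matrix.sites, chrom_lengths))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.cells) + "\n")
        has_ad = matrix.ad is not None
        fmt = "GT:AD" if has_ad else "GT"
        for i, row in enumerate(matrix.sites.itertuples(index=False)):
            d = row._asdict()
            qual = d.get("qual", np.nan)
            qual_s = f"{qual:g}" if qual == qual else "."
            fields = [
                str(d["chrom"]), str(d["pos"]), ".", str(d["ref"]), str(d["alt"]),
                qual_s, ".", _info_field(d), fmt,
            ]
            for j in range(matrix.n_cells):
                gt = code[int(matrix.calls[i, j])]
                if has_ad:
                    gt += f":{matrix.ad[i, j, 0]},{matrix.ad[i, j, 1]}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def write_trio_vcf(trio: pd.DataFrame, path: str,
                   chrom_lengths: dict[str, int] | None = None) -> None:
    """Write offspring/sire/dam diploid genotypes from a trio table."""
    with _opener(path) as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(trio, chrom_lengths))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 "offspring\tsire\tdam\n")
        for row in trio.itertuples(index=False):
            gts = "\t".join(
                f"{a}/{b}"
                for a, b in ((row.off1, row.off2), (row.sire1, row.sire2),
                             (row.dam1, row.dam2))
            )
            fh.write(f"{row.chrom}\t{row.pos}\t.\tA\tG\t500\t.\t.\tGT\t{gts}\n")


def read_trio_vcf(path: str) -> pd.DataFrame:
    """Read a trio VCF (samples offspring, sire, dam) into a trio table."""
    sites, calls, cells, _ = read_vcf(path, ploidy_mode="diploid")
    expected = ["offspring", "sire", "dam"]
    if cells != expected:
        raise ValueError(f"trio VCF must carry samples {expected}, got {cells}")
    return pd.DataFrame({
        "chrom": sites["chrom"], "pos": sites["pos"],
        "off1": calls[:, 0, 0], "off2": calls[:, 0, 1],
        "sire1": calls[:, 1, 0], "sire2": calls[:, 1, 1],
        "dam1": calls[:, 2, 0], "dam2": calls[:, 2, 1],
    })


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file into sorted 0-based half-open intervals.

    Records with start >= end are rejected with a message; overlapping
    intervals are preserved (no merging at read time).
    """
    intervals: list[GenomicInterval] = []
    with _opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                logger.warning("%s:%d: rejected interval with start >= end", path, ln)
                continue
            intervals.append(GenomicInterval(chrom, start, end))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str) -> None:
    with _opener(path) as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_qtl_bed(path: str) -> pd.DataFrame:
    """Read a BED4 of QTL intervals; column 4 is the trait name."""
    rows = []
    with _opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: QTL BED needs 4 columns")
            if int(parts[1]) >= int(parts[2]):
                logger.warning("%s:%d: rejected interval with start >= end", path, ln)
                continue
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "trait"])


def write_events_tsv(events: pd.DataFrame, path: str) -> None:
    """Write crossover events with the documented stable column set."""
    events.loc[:, EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "chrom": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events TSV missing columns: {sorted(missing)}")
    return df


def write_map_tsv(window_rates: pd.DataFrame, path: str) -> None:
    window_rates.to_csv(path, sep="\t", index=False)


def read_map_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_phase_tsv(df: pd.DataFrame, path: str) -> None:
    """Per-site phased alleles + phase-status provenance."""
    df.to_csv(path, sep="\t", index=False)


def read_phase_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "status": str})


def read_chrom_lengths(path: str) -> dict[str, int]:
    """Two-column TSV ``chrom<TAB>length_bp``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_lengths(chrom_lengths: dict[str, int], path: str) -> None:
    with _opener(path) as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
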