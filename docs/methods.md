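# Methods

`spermrec` reconstructs an individual's meiotic recombination landscape
from a panel of sequenced single sperm. This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## The inference problem

A sperm is a haploid draw from the donor's two homologous chromosomes, with
a handful of crossovers per chromosome pair. Low-pass single-cell
sequencing (~1–2× after whole-genome amplification) yields noisy, sparse
haploid genotype calls: most sites are missing in any given cell and a
small fraction of calls are wrong. Two quantities are unknown: the donor's
chromosome-level haplotypes, and each gamete's haplotype-of-origin path
along them. The package estimates both, in that order, using only the
linkage information carried by the sperm panel itself, then summarizes the
crossovers into genetic maps.

## Variant and cell QC (`spermrec.qc`)

Hard site filters follow GATK-style annotations with strict boundary
semantics as written: remove QD < 2, FS > 30, SOR > 3, MQ < 40, QUAL < 40
(so QD = 2 is kept), then remove every SNP in any run of ≥ 3 SNPs spanning
≤ 35 bp. Per-call cleaning requires ≥ 2 reads supporting the called allele
(when AD is present) and discards raw heterozygous calls — in a haploid
cell these indicate amplification artifacts or chromosome-scale anomalies.
Cells with depth < 0.5× or genome coverage < 10% are dropped; on synthetic
matrices the per-cell call rate proxies coverage.

Heterozygous-SNP (htSNP) selection keeps sites where, among non-missing
cells, each allele reaches a frequency of ≥ 30% (inclusive) and ≥ 2
supporting cells. INDELs pass through the site filters but are excluded
from phasing and crossover calling, which operate on htSNPs only.

Low-density masking tiles each chromosome with 1-Mb windows anchored at
position 1 and flags windows with < 50 htSNPs (the trailing partial window
is held to a prorated threshold, a choice made here since partial windows
are otherwise undefined); adjacent flagged windows merge. Regions devoid of
heterozygosity (ROH) cannot localize crossovers and are excluded from
decoding and from all map denominators.

## Sperm-linkage phasing (`spermrec.phasing`)

**Anchor chain.** htSNPs covered in > 20 cells act as anchors. Walking
anchors left-to-right, each candidate pair is tested by tallying the four
allele combinations over jointly covered cells. Two of the four
combinations (a complementary pair) are *true links* — produced whenever no
crossover or error intervenes — and the opposing pair are *false links*. A
link is accepted when the dominant complementary pair's combined count
reaches 8 while each opposing count stays ≤ 1; on rejection the next anchor
is tried (up to 50 skips before re-anchoring a new segment).

The threshold can alternatively be applied per link
(`link_mode="each"`: both true-link counts ≥ 8). That strict variant needs
≥ 16 jointly covered cells per pair; at 60% per-call dropout with ~72 cells
the expected joint coverage is ~11.5 cells, so almost every pair would be
rejected and the chain would fragment. The combined-count rule
(`link_mode="total"`, the default) preserves the 8:1 evidence-to-noise
ratio while remaining usable at realistic dropout, and is the reading under
which phasing rates above 80% are attainable at ~1.8× coverage.

When a chromosome does fragment into multiple segments, relative segment
orientation is resolved by aggregating linkage over the 5×5 boundary site
pairs, accepting the dominant orientation when its count is ≥ 8 and ≥ 8×
the opposing count (the same evidence ratio, generalized); an unresolved
boundary conservatively unphases the smaller segment rather than risk a
half-flipped chromosome.

Haplotype labels are arbitrary per chromosome and fixed deterministically
(hap1 := allele 0 at the first chained anchor); every downstream accuracy
or agreement measure is invariant to per-chromosome label swaps.

**Stage 1 — window imputation.** For each unphased htSNP, the five nearest
phased htSNPs by coordinate form the window. A cell covering the target
with ≥ 3 confirmed matches to one haplotype across the window implies an
assignment: "haplotype h carries the allele this cell shows at the
target". The target is phased when all implied assignments agree (cells of
*opposite* haplotype backgrounds routinely imply the same assignment — the
unanimity requirement applies to the implied assignment, not to which
haplotype each cell belongs to). Conflicts defer the site rather than
majority-voting, avoiding error propagation. Passes are synchronous
(each pass uses the phase set from the pass start), which makes the
fixpoint independent of site-processing order; iteration is capped at 100
passes and in practice terminates in a handful.

**Stage 2 — cross-cell imputation.** Per chromosome and haplotype, cells
strictly more concordant with that haplotype than the other (over phased
sites) are ranked and the top 10 act as representatives. A still-unphased
site is assigned to haplotype h when ≥ 2 of h's representatives covering it
agree on an allele and h's covering-representative count exceeds the other
haplotype's.

## Trio validation (`spermrec.trio`)

At an offspring-heterozygous site the parental genotypes phase the alleles
whenever at most one parent is heterozygous: exactly one of the two
paternal/maternal assignments is Mendelian-consistent. Both parents
heterozygous → unphasable; no consistent assignment → Mendelian error
(excluded from agreement numerator and denominator — such sites carry no
valid phase). Agreement between trio- and sperm-based phasing is computed
over doubly-phased sites with the per-chromosome sperm-label orientation
chosen to maximize matches (ties toward identity) — the only label-invariant
convention.

## Crossover decoding (`spermrec.hmm`)

Each cell × chromosome yields an observation sequence over its informative
sites (phased, non-missing, outside masks), coded as matching haplotype 1
or 2. The origin path is a two-state chain observed through a symmetric
error channel: emission error `e` (default 0.005), switch probability `t`
per informative interval (default 1e-4). Both are package choices — the
assay does not identify them — and they are echoed into output metadata.
The defaults satisfy `2·ln t < ln(e/(1−e))`, so an isolated discordant call
is explained as an error, not as a double switch; runs of ≥ 4 consecutive
discordant calls are decoded as real double exchanges.

Viterbi decoding uses an exact discrete formulation: with uniform
transitions a path's log-probability is an integer combination
`n_mismatch·(ln e − ln(1−e)) + n_switch·(ln t − ln(1−t))` plus a constant,
so candidate paths compare through integer pairs evaluated canonically —
equal-probability paths tie bit-exactly and the deterministic tie-break
(fewest switches, then the lexicographically smallest path, state 1 first)
is applied identically in the production decoder and in the exhaustive
enumeration oracle used by the tests. A distance-scaled transition variant
(`t` proportional to physical gap) is available and falls back to float
dynamic programming.

Each state switch becomes one crossover event, localized between the
flanking informative sites with the event position at the interval
midpoint. Cells with grossly abnormal event counts (count > median +
3 × 1.4826·MAD) are flagged and excluded from maps; on Poisson-distributed
counts the false-flag rate is far below 5%.

## Maps, hotspots, enrichment (`spermrec.maps`)

Per chromosome, Morgans = events/n_cells; per 1-Mb window, rate =
100·(events/n_cells)/window_Mb with events assigned by midpoint (boundary
midpoints go to the right-hand, half-open window). Masked windows are
excluded from every denominator and reported as absent, never as zero.
Genome summaries include the per-cell mean, SD (sample SD over per-cell
totals, zero-event cells included), and SE = SD/√n.

Hotspots are windows whose rate strictly exceeds mean + 2.5·SD over the
unmasked windows (sample SD; detection is scale-equivariant). QTL
enrichment classifies every unmasked 1-Mb window as hotspot/not ×
overlapping ≥ 1 interval of a trait/not — the window is the test unit,
which keeps the 2×2 well-defined — with a one-sided Fisher exact test per
trait and BH adjustment across traits. Fisher and BH are computed by
scipy/statsmodels behind this module's interface; the test suite verifies
them against full hypergeometric enumeration (all 5,551 tables with margins
≤ 12) and the definitional step-up formula.

Map comparison places window rates at window-midpoint/chromosome-length
(pooling acrocentric chromosomes of different lengths on one relative
axis), optionally excludes windows in the terminal 5 Mb (array- and
pedigree-based maps under-ascertain distal exchanges; the correction is
irrelevant when comparing two sequencing panels), smooths each curve by
LOESS (tri-cube local linear, span 0.3 — exact on linear profiles), and
reports the Pearson correlation of the smoothed curves.

## Synthetic gametes (`spermrec.simulate`)

No published generative model exists for this assay; the simulator is a
stand-in built to exercise every pipeline stage with recorded truth:

* htSNP positions: Poisson count at the configured density (default
  60/Mb), uniform along the chromosome; donor haplotypes complementary
  random alleles.
* Crossovers per gamete per chromosome: Poisson with mean = the
  chromosome's map length, positions from a mixture
  `w·Beta(0.5, 0.5) + (1−w)·Uniform` scaled to the chromosome
  (default w = 0.3), reproducing distal-end enrichment with one parameter.
  No crossover interference is modeled.
* Observation: origin-haplotype allele, flipped with probability
  `error_rate` (default 0.01), dropped i.i.d. with probability
  `missing_rate` (default 0.6, the regime of ~1.8× amplified coverage).
* Trio: parents Mendelian-consistent with the donor receiving hap1
  paternally; a configured fraction of sites is made both-parents-het
  (trio-unphasable), the rest drawn uniformly from the three
  phase-informative configurations.
* `holstein_like` preset: 29 acrocentric autosomes with lengths declining
  smoothly 158→42 Mb (≈2.5 Gb total, the magnitude of the bovine autosomal
  genome without copying a genome build) and per-chromosome map lengths
  proportional to physical length, normalized to 30 Morgans genome-wide.
  The recovery experiments use `scale=0.2` (~580 Mb, ~35k htSNPs), which
  preserves the quantity that controls crossover observability — Morgans
  per chromosome (~1) — while keeping runs to seconds.

What the simulator does **not** emulate: amplification-bias coverage
structure (dropout is i.i.d., so per-cell coverage is homogeneous and
joint coverage of site pairs is slightly pessimistic relative to real
panels with heavy-tailed depth), read-level errors correlated along
fragments, gene conversion, aneuploidy, and reference/mapping artifacts.
Passing recovery tests therefore demonstrate algorithmic correctness under
the stated noise model, not robustness to every artifact of MALBAC data.

## Recovery behavior and known limitations

At the study-shaped conditions (29 scaled autosomes, 30 M map, 1% error,
60% dropout, 72 cells) the pipeline phases > 99.5% of htSNPs at ≥ 99.9%
accuracy (per-chromosome label swap allowed) and agrees with trio phasing
at ≥ 99.9% of doubly-phased sites.

Called crossovers systematically undercount the truth by ~3–6%: exchanges
distal to a cell's first/last informative site are invisible in principle;
two exchanges inside one informative interval cancel; and with the default
`t = 1e-4` the decoder absorbs double exchanges separated by ≤ 3
informative sites as errors. The undercount shrinks with denser informative
sites or a larger `t`; the per-cell count bias stays within the
Monte-Carlo CI of the mean at the tested conditions. Resolution fractions
(events localized to ≤ 200/100/30 kb) depend directly on informative-site
spacing, hence on density × (1 − missing_rate).

Edge cases: chromosomes with < 2 anchors are left unphased and logged;
empty observation sequences yield zero events; `phasing_rate`,
`agreement_rate` and `resolution_summary` raise on empty denominators
rather than returning silent zeros; all randomness flows from explicit
integer seeds and every CLI stage is bit-reproducible under a fixed seed
and config.
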