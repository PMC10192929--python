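# Methods

`nucshield` analyses how radial 3D genome organization relates to UV
damage formation (Damage-seq-like data) and nucleotide excision repair
(XR-seq-like data). This note records the models, the numerical choices,
and what the synthetic data does and does not emulate.

## The bead model of the nucleus

Each chromosome is a chain of spherical beads tiling its length: one bead
per contact domain (TAD) and one per inter-domain gap. Overlapping domains
are merged into a single bead before tiling; abutting (book-ended) domains
are deliberately kept separate, since merging is defined on overlap only.
Bead volume is proportional to the genomic span it represents, and total
bead volume is scaled to an occupancy fraction of a spherical nucleus:

    V_i = occupancy * V_nucleus * bp_i / total_bp,   r_i = (3 V_i / 4π)^(1/3)

Defaults: nucleus diameter 10 µm (radius R = 5 µm), occupancy 0.15. The
normalisation is exact by construction for any partition.

### Placement

Beads are placed by Metropolis Monte Carlo on a constraint loss

    L = w_i Σ_inter max(0, d_ij − (r_i+r_j))²   (interacting pairs pulled to touching)
      + w_o Σ_all   max(0, (r_i+r_j) − d_ij)²   (no overlaps)
      + w_c Σ_chain max(0, d_ij − (r_i+r_j))²   (consecutive beads stay connected)
      + w_n Σ_i     max(0, |c_i| + r_i − R)²    (containment in the nucleus)

with all weights defaulting to 1. L = 0 iff every constraint is satisfied.
Interactions supplied as genomic-interval pairs are mapped to the beads
containing their midpoints. Proposals displace a single bead by an
isotropic Gaussian step (default 0.1 µm); the temperature schedule is
geometric (T₀ = 1, ratio 0.999) with floor 0, so the tail of a long run is
greedy and its accepted-loss trace is non-increasing. Initial placement
lays each chromosome as a clipped random walk of touching beads so the
chain term starts near zero. `fit_model` appends a fine-step greedy polish
(0.02 µm, T = 0) that settles residual envelope protrusions; after the
default budget (60k + 20k steps) total envelope excess on ~100-bead models
is below 0.01–0.05 µm. The loss is a deliberate simplification of
published interaction-constrained modelling protocols: the published
functional form and iteration budgets are not reproduced, only the
constraint set they encode.

### Radial shells

A placed bead belongs to the 1-µm shell containing its centre:
half-open bins [k, k+1) µm of centre distance, labelled "0-1" … "4-5" for
R = 5. Assigning by centre (rather than fractional volume overlap) is a
choice made here because it is unambiguous; beads are small relative to
shell width in realistic partitions, so the difference is minor.

Two deterministic layout helpers bypass optimization for planted-truth
studies: `place_on_radii` (beads at chosen radii, random directions) and
`cycle_shell_layout` (round-robin over shells at mid-shell radii, giving
every shell an equal bead count). These are synthetic layouts, not
physical placements; calibration results obtained with them quantify the
statistics, not the optimizer.

## Damage-window geometry

The UV lesion dinucleotide lies two nucleotides upstream of a Damage-seq
read's 5′ start. Reads are transformed to fixed 10-nt windows holding the
lesion at read-orientation positions 5–6:

    + strand read [s, e)  →  window [s−6, s+4)
    − strand read [s, e)  →  window [e−4, e+6)

Windows that would run past a chromosome end are dropped (and counted),
never clipped — a clipped window cannot hold positions 5–6. Duplicates are
removed on the exact key (chrom, start, end, strand); identical intervals
on opposite strands are distinct lesions. XR-seq excision fragments get no
window transform; they are used full length, sorted and deduplicated the
same way.

## Frequency-matched read simulation

The "expected" read set answers: where would reads fall if only sequence
content (and, in background mode, copy number) mattered? Per read length,
the target is the empirical position × base frequency matrix of the real
reads (mononucleotide, per position — a dinucleotide extension would be a
straightforward generalisation but is not implemented). Candidates are
drawn uniformly from the reference (chromosomes weighted by the number of
valid start positions) or uniformly from background read footprints;
strand is uniform. A candidate with bases b₁…b_L is accepted with
probability

    p = min(1,  (1/M) Π_j t_j(b_j)/ĝ_j(b_j)  ×  clip(Π_j t_j(b_j)/f̂_j(b_j), 0.2, 5))

where t is the target, ĝ the running per-position frequency of *candidates*
(the proposal estimate), f̂ the running frequency of *accepted* reads, and
M a running envelope (twice the largest proposal-ratio product seen). The
first factor is importance rejection against the estimated proposal; the
second is a closed-loop feedback correction whose fixed point is exactly
f = t — a feedback-only rule (accept ∝ t/f̂) equilibrates at f ∝ √(g·t)
and can miss a strongly biased target by several percent, which is why
both ratios are combined. The emitted-count prior (50 pseudo-reads at the
target) keeps early feedback neutral; processing happens in batches with
both estimates updated per batch.

Guarantees checked by tests: emitted sequences are bit-exact reference
substrings (reverse-complemented on minus); per-length MAD between emitted
and target frequencies ≤ 0.02 for n ≥ 5000 (in practice ~0.001 at
n = 50,000); MAD decreases with n; in background mode the simulated read
density tracks background density (r > 0.99 with a planted 3× copy gain).
If a length's quota is not filled within `max_attempts` (default 200)
candidates per read, the run aborts naming the positions with the largest
target deviation.

## Radial statistics

Reads are assigned to the bead containing their midpoint
(floor((start+end)/2); half-open intervals make the assignment unique and
conservative — counts plus skipped reads equal input reads). Per-bead
signal is RPKM = count / (bp/10³) / (total mapped/10⁶).

* observed/expected: per-bead RPKM_real / RPKM_simulated. Beads with zero
  expected signal are excluded and counted, not pseudocounted; figures in
  this field report unpseudocounted ratios and the exclusion count keeps
  the denominator choice auditable.
* double normalization: (repair/repair-sim) / (damage/damage-sim) per
  bead; isolates repair efficiency from the initial damage landscape. When
  repair inputs equal damage inputs the result is exactly 1.0 (a floating
  point identity, since numerator and denominator are the same numbers).
* Shell summaries are unweighted across beads (each bead one observation,
  regardless of size), and the central shell "0-1" is compared against
  every other shell with Welch's unequal-variance t-test
  (Welch–Satterthwaite df, two-sided p). No multiple-testing correction is
  applied by default — four comparisons per quantity, reported raw.

Calibration on radially uniform synthetic data (equal bead counts per
shell, 20k reads, ~120 beads): the 0-1 vs 4-5 Welch test fires at
0.025–0.07 over 200 seeded replicates, consistent with its nominal 5%
level given per-bead RPKM heteroscedasticity (bead lengths vary, so
per-bead variances differ — exactly the situation Welch's test tolerates).

## Synthetic data: what is emulated

Generators cover every pipeline input with controllable planted structure;
all are deterministic under a fixed seed.

* **Genome.** I.i.d. bases from a configurable composition (default
  uniform). A per-chromosome dipyrimidine gradient plants TT/TC dimers in
  non-overlapping 2-bp slots with linearly increasing 5′→3′ density
  (baseline 0.05 starts/bp, multiplier g at the 3′ end) and rewrites
  accidental TT/TC occurrences to A/G, so the realised plus-strand TT/TC
  density equals the planted profile exactly. Consequences: on gradient
  chromosomes the dimer landscape is periodic (even positions) and
  minus-strand lesion sites (genomic AA/GA) remain at background density,
  so a damage-read gradient measured over both strands is diluted roughly
  two-fold relative to g — the composition-correction study therefore
  asserts a monotone raw trend rather than the full g.
* **Reads.** Sampled per bead with expected counts ∝ bead weight × shell
  multiplier, where weight is the dipyrimidine-site count for damage reads
  (given a genome) and genomic span otherwise. Damage reads start 2 nt
  downstream of a lesion site with probability `purity` (default 0.95);
  excision-like repair reads draw lengths from a truncated mode-26
  distribution over 20–30 nt (the real excision-length distribution varies
  by protocol; this default is configurable and not asserted as any
  dataset's); input reads are uniform. Defaults for study sizes: 10-Mb
  genomes, ~60 domains of 50–120 kb, 150k–200k reads — large enough that
  per-bead Poisson noise is a few percent, small enough to run in seconds.
* **Replication counts.** 50-kb windows; early/late counts are Poisson
  with a planted symmetric log2 effect (default 1.0) inside labelled
  domains, depth 100 per window; trailing partial windows are flagged.
* **Interactions.** Distinct unordered bead pairs, optionally with a fixed
  fraction (default 0.8) drawn from within a designated central set,
  capped by the number of distinct within-set pairs.

What the synthetic data does *not* emulate: realistic Hi-C contact
matrices, sequencing errors and quality scores, adapter artefacts,
mappability, chromatin-state covariates, and the dinucleotide/k-mer
correlation structure of real genomes. Passing tests therefore demonstrate
that the statistics recover what was planted under clean conditions — not
that real-data confounders beyond base composition and copy number are
removed.

## Replication-domain calling

Per window r = log2((early + 0.5)/(late + 0.5)) — the 0.5 pseudocount
handles empty windows. Maximal runs of ≥ `min_windows` (default 3, i.e.
150 kb) contiguous same-sign windows become domains; r = 0 and window
gaps break runs. This sign-run rule is a declared stand-in for unpublished
segmentation scripts in this literature; on symmetric noise it calls
early and late domains at equal rates, and with a planted log2 effect of 2
at depth 100 it recovers ≥ 90% of planted domain bases.

## Known limitations

* The placement optimizer is a single-model Monte Carlo, not an ensemble;
  radial occupancy of a single fit is noisy for the innermost shell (its
  volume is 1/125 of the nucleus), which is why calibration studies use
  the deterministic layouts instead.
* Frequency matching is per-position mononucleotide. Under a strong
  planted composition gradient the joint (multi-position) enrichment makes
  the simulator very slightly super-linear in local dimer density, leaving
  the corrected outer/central ratio ~5–9% below 1 at a 3× gradient —
  within the 10% band the studies assert, but visible.
* Beads straddling shell boundaries are assigned wholly by centre; no
  fractional volume weighting.
* Genic/intergenic and early/late stratification re-uses full bead lengths
  in the RPKM denominator; per-stratum comparisons should therefore be
  made on observed/expected ratios (where mask geometry cancels), not raw
  RPKM.
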