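# Methods

## The inference model

Vertically inherited sequences in two species have been diverging since
the species split, so their synonymous divergence is set by the split time
and the host synonymous rate.  The dominant host modifier of that rate is
codon usage bias: strongly biased genes accept synonymous changes more
slowly.  `httscan` therefore models, per species pair,

    dS_gene = a + b * Nc_gene + e,    e ~ N(0, s^2),

fitted by ordinary least squares over single-copy orthologous genes
(default: at least 10 usable genes; the simulated studies use 50, each of
500 codons).  A TE family shared by the pair contributes one point
(Nc_TE, dS_TE), taken from the representative copy per species (the copy
most similar to the family consensus).  Under vertical inheritance that
point is exchangeable with the gene points; under horizontal transfer the
TE has only been diverging since the transfer, so dS_TE falls below the
regression.  The decision statistic is the studentized prediction
residual

    t = (dS_TE - a - b*Nc_TE) / (s * sqrt(w + 1/n + (Nc_TE - mean(Nc))^2 / Sxx))

referred to t_{n-2}, one-tailed (lower), significant at alpha = 0.01.

**Length weighting.**  The textbook prediction residual puts `w = 1`,
which presumes the new point carries the same sampling noise as a
regression point.  Pairwise dS noise scales inversely with the number of
comparable codons, so `w = (mean gene codons) / (TE codons)` when both
lengths are known (and 1 otherwise).  For equal lengths this is exactly
the textbook form; without it, a 600-codon TE tested against 500-codon
genes has null t-statistics with standard deviation ~sqrt(500/600) and
the test is conservative.  The same consideration motivates the length
weighting in the reference implementation of this class of test.

**What the test does not do.**  One family can show several significant
pairs; no attempt is made to reconstruct the minimal transfer scenario.
Family counting treats "at least one significant pair" as one HTT family,
and per-species/per-pair counts are derived from the significant pairs
directly.  No multiple-testing correction is applied by default (the
analysis uses a fixed per-test alpha); a Benjamini–Hochberg flag exists
but is off.

## Core statistics

* **dS (Nei–Gojobori 1986).**  Synonymous sites counted fractionally per
  codon (fraction of the three possible changes per position that are
  synonymous; changes to stops count as nonsynonymous), averaged over the
  two sequences.  Codons differing at d positions are averaged over all
  d! substitution orderings; orderings that pass through a stop codon are
  excluded unless all do.  Codons containing gaps, N, or a stop in either
  sequence are skipped pairwise.  Multiple hits corrected with
  dS = -3/4 ln(1 - 4/3 pS); pS >= 3/4 is flagged saturated and excluded
  downstream.  The implementation uses precomputed 64x64 tables; tests
  compare it against a direct enumeration oracle, and against
  Biopython's independent NG86 implementation.
* **CUB (Wright's ENC).**  Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk the
  mean codon homozygosity F = (n Σp² - 1)/(n - 1) over amino acids of
  degeneracy k observed at least twice; non-positive F are discarded.  A
  missing 3-fold class is imputed as (F2 + F4)/2; any other missing class
  by assuming the observed classes' mean usage flatness on the k·F scale.
  Clipped to [20, 61].  Larger Nc = weaker bias, so the gene regression
  has positive slope (dS rises with Nc).
* **K2P.**  Transition/transversion proportions over ungapped unambiguous
  columns, K = -1/2 ln((1-2p-q) sqrt(1-2q)); non-positive log arguments
  flag saturation.  Per-family copy-to-consensus K2P profiles (mean,
  median) serve as relative intragenomic ages.

## Sequence-level conventions

All coordinates are 0-based half-open and plus-strand ordered; BLAST-style
tabular input (1-based inclusive, descending subject coordinates on minus
hits) is normalized at read time.  Sequences are compared case-folded;
IUPAC ambiguity codes other than N are collapsed to N with a warning, and
N-containing columns/codons are ignored by the divergence statistics.

Pairwise global alignment (clustering, consensus, flank comparison,
copy-to-consensus K2P) uses fixed scores: match +1, mismatch -1, gap open
-2, gap extend -1, end gaps free.  Identity is matches over the core
columns (between the first and last column where both sequences carry a
residue); coverage is the smaller of the two sequences' fractions of
residues inside that core.  Mutual coverage — rather than coverage of the
shorter sequence alone — is used for clustering because with free end
gaps a contained fragment always covers itself completely, which would
let arbitrarily short fragments join full-length families.

Copy recovery keeps hits with bit-score strictly greater than 200 and
chains same-family/contig/strand hits whose gap is at most 1000 nt; the
merge is order-independent and idempotent.  ORFs are maximal stop-to-stop
(or edge-bounded) runs in any of six frames, no start codon required —
TE coding regions are routinely start-degraded in consensus sequences —
with "greater than 300/200 aa" read strictly.

## The simulator

The generator emulates the statistical structure the test assumes, with
complete ground truth:

* Protein sequence is frozen; only synonymous substitutions occur, so
  alignments are exact by construction and dS is the only divergence
  axis.  Root amino acids are uniform over the 20; each unit (gene or TE)
  has a bias parameter beta in [0, 1] and draws each amino acid's
  preferred codon (one shared preferred-codon table, alphabetically first
  codon per amino acid) with probability 1/k + beta(1 - 1/k).
* Along a branch of t My each codon accrues Poisson(r_s · t · s_c)
  substitutions (s_c = its fractional synonymous site count), resampled
  among single-step synonymous neighbours weighted by the codon
  preference.  The rate is r_s = r_max (1 - lambda · b(beta)) with
  b(beta) = (61 - E[Nc|beta]) / 41, so expected dS is linear in expected
  Nc — the linearity the regression assumes — while realized Nc carries
  natural sampling noise.  Defaults: r_max = 0.02 /syn site/My (of the
  order of the mosquito host-gene estimates), lambda = 0.5 (moderate
  coupling, clearly negative dS–bias relation without degeneracy at
  beta = 1), 50 genes x 500 codons, 600-codon TEs.
* Vertical TEs evolve like genes over the whole species tree.  Horizontal
  TEs evolve along the donor lineage; t_HT My before the present their
  state is copied into the recipient and both copies evolve independently
  to the tips, so donor–recipient dS reflects 2·t_HT.
* Intragenomic copy bursts place Poisson(rate · age · length)
  substitutions per copy with a kappa = 2 transition bias; expected
  copy-to-consensus K2P is rate · age.
* Determinism: one root seed; each unit's generator is seeded by
  (seed, CRC-32 of the unit id), so adding units never perturbs existing
  ones and bundles are byte-identical across runs.

What the generator deliberately omits: indels and alignment error,
nonsynonymous evolution and selection, rate variation among sites and
lineages, copy-number dynamics within genomes, and assembly artifacts.
Passing calibration/power tests on this generator therefore demonstrate
the statistical correctness of the inference chain under its own
assumptions, not robustness to misalignment or model violation in real
genomes.

## Simulation studies (tests and acceptance script)

* **Null calibration** — 1000 tests, each with its own 50-gene regression
  (two species split 10 My ago) and one fresh vertical TE.  One TE per
  test keeps the p-values independent, which the exact binomial interval
  for the significant fraction and the KS uniformity check both assume;
  reusing one TE across many species pairs induces strong dependence and
  invalidates the KS test even when the statistic is exactly calibrated.
* **Power** — 200 replicates of a transfer at 1 My on a 10-My divergence,
  600-codon TEs at a synonymous rate of 0.0176 (the within-Anophelinae
  host estimate), fresh 50-gene regressions; detection = p < 0.01.
* **Dating recovery** — 200 transfers at 2 My dated with the simulator's
  true rate; the median relative error of T = k/(2r) isolates Poisson
  substitution noise at 600 codons (expected ~2/sqrt(S·k) relative sd).

Problem sizes (codon counts, replicate numbers, tree depths) are the
study design stated above; smaller bundles used in unit tests (25–50
genes, 300–500 codons) are integration smoke tests, not measurements.

## Numerical and degenerate-input choices

Saturated dS or K2P values are flagged, never silently truncated; a
saturated TE dS suppresses the call with a reason.  Exact-fit regressions
(zero residuals, within 1e-10) are reported as degenerate: a TE on the
line gets p = 0.5, any deviation p -> 0/1.  Zero codon-usage variance or
fewer than the minimum usable genes raise errors rather than fitting.
Consensus ties break by fixed base order A < C < G < T; ORF ties prefer
the plus strand, then lower frame, then leftmost start; cluster joining
prefers the highest-identity representative, ties to the earliest
cluster.  The KS normality diagnostic is applied to standardized fitted
residuals against N(0,1) and is therefore conservative (location and
scale are estimated); it is a screen for gross non-normality, not an
exact test.

## Dating

T = k/(2r), with k the NG86 dS between the two species' representative TE
copies and r the host synonymous rate per lineage per My.  Built-in
per-taxon rates: within Anophelinae 17.567e-3, within Culicinae 9.205e-3,
between subfamilies 10.006e-3.  Rates can also be estimated from gene dS
as r = mean(dS) / (2 · divergence time) (median behind a flag; the mean is
the default aggregation).  Age histograms are tabulated per TE order and
per host-taxon class with conserved totals.

## Known limitations

The flank-sharing thresholds for introgression discrimination (identity
>= 0.70 over >= 0.50 mutual coverage, flanks clipped to 3–5 kb) and the
long-range screen's identity floor (0.80) are package defaults exposed in
the API — the underlying publications state only qualitative criteria.
The greedy clustering is a deterministic stand-in for CD-HIT-EST's
heuristics and will not reproduce its clusters exactly.  The star
consensus drops insertions relative to the longest member.  dS estimation
is counting-based (NG86); maximum-likelihood codon models are out of
scope.
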