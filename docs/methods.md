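# Methods

## The cytogenetic model

Moroccan *Clonopsis* stick insects form a numerical polyploid series on a
haploid base of n = 18 chromosomes: the bisexual *C. felicitatis*
(cn = 36/35, XX/X0), the parthenogenetic *C. gallica* (cn = 54) and
*C. soumiae* (cn = 72), alongside two clonal androgenetic male strains with
cn = 35 and cn = 53. All look karyotypically diploid despite being
numerically polyploid. The package implements the hypothesis that these
forms descend from an "intermediate triploid female" with altered meiosis.

A karyotype is a vector of copy counts over the n homologous groups; the X
is one designated group (default the last), so an X0 male is the female
karyotype minus one copy at that group. In a triploid oocyte each group
forms a trivalent that segregates 2:1 at meiosis I. We model each
trivalent's orientation as an independent fair coin: the doubled complement
goes to the oocyte-II pole with probability 1/2. Writing m for the number
of doubled complements at the oocyte pole, m ~ Binomial(n, 1/2) and the
oocyte II carries n + m chromosomes. Anaphasic restitution (retention of
the second polar body) then doubles every group, giving an egg with
cn = 2(n + m) and every chromosome in pairs — a diploid-looking karyotype
regardless of actual ploidy.

Two eggs matter:

* **Scheme A** — all trivalents concordant, one pole receives two complete
  series. Counting both poles, P = 2·(1/2)^n; for n = 18 this is
  7.63×10⁻⁴ % of eggs. After restitution: cn = 72, uniform ×4 — the
  *C. soumiae* constitution. The factor 2 is deliberate: either pole can be
  the one retaining both series, and only the two-sided count reproduces
  the probability the source analysis reports.
* **Scheme B** — exactly half the trivalents doubled (m = n/2),
  P = C(n, n/2)/2^n ≈ 18.5 % for n = 18. After restitution: cn = 54 with
  nine groups ×4 and nine ×2 — the *C. gallica* constitution.

Male (X0) derivations: loss of one X from a 54-chromosome gallica-like
genome gives cn = 53; the cn = 35 male arises either from a diploid species
hybrid that is X0 from the start, or from the triploid female when the 17
autosomal trivalents segregate concordantly and the X trivalent delivers a
single X **without** restitution. The no-restitution reading is our
modelling decision: restitution always yields an even total, and 35 is odd,
so it is the only arithmetic consistent with the observed karyotype. The
figure this derives from does not spell out the cytology.

Restitution is modelled as whole-complement doubling only; partial
restitution and recombination/chiasma placement are not modelled, nor are
the cn = 55–57 European *C. gallica* variants or its two-division
meiotic-like apomixis.

## Origin scenarios

Diploid hybrids (two complete series from two parental labels) produce
diploid gametes by pre-, intra- or post-meiotic restitution — the three
mechanisms are deliberately indistinguishable in their product. Fusion is
either syngamy (egg + one sperm, haploid-set counts add) or androgenesis
(sperm-only nuclear genome: one sperm doubled, or ≥2 sperm heads fused —
stick-insect eggs are polyspermic). mtDNA always follows the egg mother,
which is what lets androgenetic offspring combine a maternal mitochondrial
lineage with a fully paternal nuclear genome. Parental labels are opaque
strings; hybridity is just label distinctness. The triploid founder can be
built by either route — the data do not decide between them, so neither is
a default.

## Synthetic dominant-AFLP generator

The generator emulates the structure of the survey's marker matrix, not its
(unpublished) content: 27 diploid-scored individuals × 195 dominant
presence/absence markers after filtering, four parental populations plus
admixed hybrids, ≤5 % missing data per retained marker.

* Per-marker ancestral presence-allele frequencies ~ Uniform(0.05, 0.95);
  population frequencies from the Balding–Nichols Beta distribution
  Beta(a(1−F)/F, (1−a)(1−F)/F) with F = divergence (default 0.25, chosen as
  a between-species scale of differentiation consistent with four clearly
  separable source populations).
* An individual with admixture vector Q draws, per marker, the origin of
  each of its 2 allele copies from Q and the allele from the origin's
  frequency; the band is 1 iff any copy is a presence allele
  (band frequency 1 − (1 − p)² for a pure diploid). A copy-number-aware
  mode (1 − (1 − p)^c) exists for sensitivity analyses, but the default
  scores everyone diploid — mirroring the survey's own scoring decision.
* Unidirectional fragment elimination zeroes one parent's frequency at a
  random round(fraction·L) markers (allopolyploids can lose up to 14 % of
  one parental genome's loci in a generation; default fraction 0 — it is a
  scenario knob, not a standing condition).
* Missing cells are injected completely at random at 2 % before filtering
  (the real matrix's rate is unknown; 2 % is an arbitrary documented
  choice), then markers with >5 % missing are removed — the filter keeps a
  marker at exactly 5 %. The preset oversamples 240 markers and truncates
  the survivors to exactly 195.
* Default composition 1+8+6+2 pure individuals + 10 hybrids echoes the
  survey's groups (a lone outgroup female, a bisexual population, a
  parthenogen block, two androgenetic males).

What passing tests on these data do **not** show: robustness to marker
linkage, band-size homoplasy, non-random missingness, or real AFLP scoring
noise — none of which the generator emulates.

## Admixture inference

The inference target is the admixture model for dominant diploid markers:
P(band_il = 1) = 1 − (1 − π_il)², π_il = Σ_k Q_ik p_kl, with loci unlinked
and in linkage equilibrium. We estimate Q and p by maximum-likelihood EM
with multiple random restarts rather than MCMC: the estimand is identical,
the runs are deterministic per seed, and a desk-scale grid over K stays
cheap. Replicate counts (5 per K on the grid, 10 at the forced K = 2) are
retained as independent-fit counts.

EM details: the two allele copies of each cell are the latent data; the
E-step posterior copy counts have closed forms (see the module docstring),
and the M-step is count normalisation, so the likelihood is monotone — this
is asserted at every iteration. Convergence: relative log-likelihood change
≤ 1e-8 **and** max parameter move ≤ 3e-8, cap 2000 iterations. Monomorphic
markers (band frequency exactly 0 or 1) are initialised at their boundary
MLE, which is an exact fixed point of the updates; the interior EM map
approaches such boundaries only sublinearly, so starting there is a
numerical necessity, not a shortcut. p is clipped to [1e-9, 1−1e-9] to keep
logs finite. Restart ties break by start order. At K = 1 the MLE has the
closed form p = 1 − √(1 − band frequency), which serves as an oracle for
the EM in the tests.

### Choosing K

Two rules are computed on 5 replicate fits per K (each replicate keeps the
best of 3 random starts, so a start trapped in a poor local optimum cannot
leak into between-replicate variance):

* **Plateau rule** ("most probable K"): the MCMC quantity this emulates is
  a marginal likelihood, which plateaus beyond the true K. A maximised
  likelihood does not — every added cluster buys ~L extra free frequencies
  — so we penalise the mean replicate log-likelihood by the free-parameter
  count, mean L(K) − [K·L + N·(K−1)], and take the smallest K within one
  standard error of the penalised maximum.
* **deltaK**: |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) on the raw replicate
  log-likelihoods (natural log, sample sd), defined only at interior grid
  points with ≥3 replicates. The sd is floored at 1 natural-log unit:
  Evanno's denominator measures MCMC run-to-run noise, and with a
  convergent optimiser the replicates of a well-resolved K coincide almost
  exactly, so an unfloored ratio would be decided by numerical noise.

Assignment uses the q ≥ 80 % rule (inclusive): arg-max cluster if its
membership reaches the threshold, else "admixed". The forced-K = 2 contrast
drops listed outgroup-like individuals, fits 10 replicates, aligns them to
the best by Hungarian assignment on the p-tables, and averages into a
consensus Q.

## Pipeline and reproducibility

One master seed; every stochastic operation derives a named sub-stream via
SeedSequence(seed, crc32(name)), so stages re-run in isolation reproduce
the full run's draws. Pipeline outputs are plain CSV/JSON and byte-identical
across reruns with the same config. Problem sizes used throughout the test
and acceptance runs — 10⁵ simulated eggs, 40×195 and 27×195 matrices,
K = 1..8 with 5 replicates — were chosen as the smallest sizes at which the
Monte-Carlo and recovery behaviour is unambiguous.

## Known limitations

* The meiosis model is purely numerical: no chromosome morphology, banding,
  or homoeologue divergence below the label level.
* Fair, independent trivalent orientation is an assumption; any orientation
  bias would shift the scheme probabilities away from 2·(1/2)^n and the
  binomial mass.
* The EM stand-in reports no posterior uncertainty on Q; replicate spread
  is an optimisation diagnostic, not a credible interval.
* With ~10 individuals per source population, noise in the estimated allele
  frequencies leaves a small fraction of truly pure individuals below the
  q ≥ 0.80 assignment threshold; this is a sample-size effect of the study
  design, not an optimisation failure (the likelihood optimum is verified
  against direct maximisation, and recovery with known frequencies is near
  perfect).
* deltaK inherits its known inability to evaluate the grid endpoints
  (K = 1 in particular); the plateau rule covers the single-population case.
* Egg "viability" is a labelling convention: aneuploid classes are counted,
  never discarded, since only the 54/72 classes are known to have survived.
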