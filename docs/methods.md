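# Methods

## The model

The core quantity is the guanine-plus-cytosine content of a partial
archaeal 16S rRNA gene, *P*<sub>G+C</sub> = 100·(G+C)/(A+C+G+T), computed
case-insensitively with U counted as T and IUPAC ambiguity codes excluded
from both numerator and denominator. Three affine models map
*P*<sub>G+C</sub> (percent) to growth temperatures (°C):

| model | slope (±hw) | intercept (±hw) |
|-------|-------------|-----------------|
| T_min | 3.91 ± 0.12 | −201.1 ± 7.34 |
| T_opt | 4.24 ± 0.13 | −202.5 ± 7.62 |
| T_max | 4.28 ± 0.12 | −195.3 ± 7.11 |

These published coefficients ship as the default model set and are
overridable; the package does not refit them. Uncertainty is propagated
worst-case: `half_width = slope_hw·P + intercept_hw`. This linear-sum
convention, not quadrature, is what reproduces the published per-OTU
intervals (e.g. at *P*<sub>G+C</sub> 56.1: 0.12·56.1 + 7.34 = 14.07 →
±14.1 for T_min, where quadrature would give ≈9.96).

Community-level temperatures apply the same models to the clone-weighted
mean `P̄ = Σ count_i·P_i / Σ count_i`, using the **unrounded** P̄.
Because the models are affine, this equals the clone-weighted mean of the
unrounded per-OTU temperatures; the equivalence is asserted to 1e−9 °C in
the test suite ("affine commutation"). Estimates outside the
*P*<sub>G+C</sub> band [50, 70]% trigger a warning: the arithmetic is
fine but the extrapolation is biologically meaningless.

### Known discrepancies with the published table

Recomputing the published growth-temperature table from its own inputs
reproduces all 30 per-OTU point values and every T_min/T_max half-width
exactly at one decimal (half-up rounding). Residual differences, all
documented and tolerated rather than tuned away:

- printed per-OTU **T_opt half-widths** run 0.1–0.2 °C below linear
  propagation of the printed ±0.13/±7.62 (e.g. computed 15.0 vs printed
  14.8 at *P*<sub>G+C</sub> 56.5). A slope half-width near 0.127 — i.e.
  higher-precision source coefficients — explains most cells. Tests allow
  ±0.25 °C on T_opt half-widths only.
- the **13-months community T_opt** recomputes to 46.1 vs printed 46.2,
  and the **19-months community T_max** to 57.3 vs printed 57.4 (±0.1
  tolerance).
- the **26-months community row** is printed identically to the
  19-months row although its clone counts differ; recomputation gives
  29.4/47.5/57.0 vs printed 29.7/47.8/57.4. That row is held only to
  ±0.4 °C.
- the published prose quotes clone-library coverages of 90.4–95.6%,
  which is inconsistent with the stated formula 100·(1 − n/N) applied to
  the published clone counts (the 0-months block gives 98.6%). The
  formula as stated is implemented; the discrepancy is noted, not
  resolved.

## Sequence handling

- **Alphabet**: IUPAC nucleotide codes, case preserved on input,
  normalized (uppercase, U→T) for every computation.
- **Primer matching** is substitution-only (no indels): clone inserts
  begin at the primer, so indel tolerance adds failure modes without
  benefit. A degenerate primer code matches any base it encodes; a
  degenerate sequence base matches when the encoded sets intersect.
  Default mismatch budget 2 on the 17/20-mer defaults; ties broken
  leftmost for determinism.
- **Trimming** returns the region strictly *between* the primer sites
  (both primers excluded — "between" read literally; including them
  would shift *P*<sub>G+C</sub> slightly). Orientation is auto-detected
  by retrying on the reverse complement.
- The default primer profile (`arch_109aF_915aR`: ACKGCTCAGTAACACGT /
  GTGCTCCCCCGCCAATTCCT) is literature-derived configuration, not part of
  the method; profiles are overridable from a key-value file.

## Clustering

Pairwise identity comes from a global alignment (match +1, mismatch −1,
gap −2, end gaps penalized; Biopython's `PairwiseAligner`) as identical
columns over alignment length including gaps. The first optimal alignment
is used, making values deterministic; co-optimal alignments can differ
slightly in match count at equal score, so the test oracle (an
independent Needleman–Wunsch implementation) checks exact score equality
plus containment of the identity within min/max bounds over *all*
optimal alignments.

OTUs are built greedily in input order: a sequence joins the first OTU
whose founder exceeds the threshold identity (strict >0.97, matching the
"greater than 97%" convention), else founds a new OTU. Greedy
centroid clustering is order-dependent in general; on the well-separated
regime the synthetic generator guarantees (inter-centroid identity ≤
0.94, within-OTU ≥ 0.99), recovery of the planted partition is exact for
any input order, which the tests exercise over 20 seeds.

Coverage is 100·(1 − n/N): n singleton OTUs, N total clones.

## Diversity

Standard estimators implemented directly (no external pipeline):
bias-corrected Chao1 `S_obs + F1(F1−1)/(2(F2+1))` (classic F1²/2F2
variant switchable), ACE with rare-class threshold 10 (falls back to
Chao1 with a warning when every rare individual is a singleton and the
coverage term vanishes), Shannon −Σp·log p (natural log default, base 2
switchable, since index conventions vary across pipeline eras), Simpson
1 − Σp², Good's coverage 100(1 − F1/N). scikit-bio's implementations
serve as an independent reference in tests only.

## Groundwater statistics

With five sampling dates, asymptotic rank-correlation p-values are
meaningless, so `spearman_trend` enumerates all n! orderings (n ≤ 9;
362 880 permutations vectorized in numpy, <1 s) and reports the exact
two-sided fraction with |ρ| ≥ |ρ_obs|; ties get average ranks. Beyond
n = 9 the scipy asymptotic p is returned.

Deuterium excess d = δD − 8·δ¹⁸O locates a water sample relative to the
global meteoric water line δD = 8·δ¹⁸O + 10 (slope/intercept
configurable). The seawater mixing fraction is two-endmember
conservative mixing, 100·(v − f)/(s − f); the default seawater EC
endmember 5900 mS m⁻¹ is configuration with a round-number open-ocean
value, not a measured study quantity.

## Synthetic data

The generator emulates the study conditions: libraries of 70–92 clones,
3–7 OTUs with skewed abundances, ~800 nt internal regions with
*P*<sub>G+C</sub> between ~54 and 62%, flanked by realized primer sites,
a fraction of clones emitted reverse-complemented, and ≤1% within-OTU
divergence. Centroids carry an exact planted G+C count
(`round(p·L/100)` G/C bases placed uniformly); a warning reports the
achieved value when the target is not representable at the chosen
length. One-decimal percentage targets are exactly representable at
length 1000, which the exact-planting fixtures use; the 800 nt default
matches the study's region length at the cost of ≤0.06 percentage-point
quantization. Within-OTU mutation is substitution-only and, by default,
GC-preserving (A↔T, G↔C swaps), so planted per-OTU *P*<sub>G+C</sub>
survives the whole pipeline exactly. All randomness flows from a single
integer seed; identical seeds give byte-identical FASTA.

The default time-series scenario plants five library compositions whose
weighted *P*<sub>G+C</sub> rises strictly (≈56.3 → 59.8%), emulating the
observed succession from acetoclastic methanogens toward thermophilic
sulfate reducers, plus a physicochemical table generated as baseline +
slope·months + Gaussian noise with recorded trend directions (stable
temperature/pH/ORP/EC; rising δD and Cl⁻).

What passing these tests shows — and does not. Synthetic clones have no
chimeras, no indel sequencing error, no secondary-structure or
phylogenetic covariance, and their OTUs are separated by construction;
truth-recovery results therefore validate the arithmetic and the
bookkeeping of the pipeline, not the behaviour of greedy clustering on
borderline real-world divergences.

## Numerical conventions

- Reported values are rounded half-up (`decimal.Decimal`, not banker's
  rounding) to 1 decimal, as the published tables round; all internal
  arithmetic is full precision.
- Clustering ties (several eligible OTUs) resolve to the first-founded
  OTU; primer-search ties resolve leftmost.
- Reports embed a hash of the full configuration, and reruns with equal
  inputs are byte-identical (timestamps only ever go to logs).

## Problem sizes

The test suite and the acceptance script run on desk-scale inputs: the
published five-block clone table (73–92 clones per block), synthetic
libraries of 11–92 clones with 200–1000 nt internal regions, 20-seed
clustering replicates, 100 random alignment-oracle pairs, and full n!
permutation enumeration at n = 5–9. The complete suite runs in a few
seconds on one CPU.

## Limitations

- The regression coefficients are taken as given; no provenance-level
  uncertainty (e.g. covariance between slope and intercept) is
  available, hence the worst-case linear propagation.
- Greedy centroid clustering is a modelling choice, adequate for
  well-separated clone libraries, not a general-purpose OTU picker.
- Table mode trusts user-supplied per-OTU *P*<sub>G+C</sub>; it cannot
  detect trimming inconsistencies in upstream data.
- The NGS side of such studies (read QC, taxonomy assignment, chimera
  screening) is intentionally out of scope.
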