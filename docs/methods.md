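# Methods

This note documents the models, conventions and numerical choices behind
`denitcath`, and what the synthetic generators do and do not emulate.

## Nitrogen and electron ledgers (`stoichiometry`)

**Model.** The cathode is treated as a continuously fed, well-mixed
compartment at steady state with equal inflow and outflow Q (L d⁻¹). Daily
loads are concentration × Q. Denitrification is the linear chain
NO₃⁻ → NO₂⁻ → NO → N₂O → N₂ with electron costs 2, 1, 1, 1 per N atom per
step; NO is assumed not to accumulate (its load is pinned to zero, the step
cost is retained). Removed nitrogen is ΔNO₃⁻ − ΔNO₂⁻, with ΔNO₂⁻ the *net*
nitrite production — negative when nitrite is the feed and is consumed, in
which case it adds to removal.

**Closure.** Effluent N₂ is not measured; it is the unique value that closes
the nitrogen balance, removed N − N₂O. `close_balance` therefore always
returns a ledger with a zero closure residual, and `electron_demand` refuses
unclosed ledgers rather than silently absorbing a residual.

**Electron supply and demand.** Supply is I·86400/F mol e⁻ d⁻¹ with
F = 96485 C mol⁻¹ and I reconstructed as current density × compartment
volume (default 145 mL, the net cathodic compartment of the reference
reactor). The cell voltage plays no role in the molar balance — only charge
does — so it does not appear in the API. Demand counts 2 e⁻ per N of nitrate
reduced, 2 e⁻ per N reaching the gas phase (nitrite-fed N enters the chain
here), and 1 e⁻ per N reaching N₂; molar mass of N is fixed at
14.007 g mol⁻¹ and a day at 86400 s.

**Coulombic efficiency.** Defined here as 100 × supply / demand with demand
taken from the observed conversions. Published CE values for comparable
systems are not in general reproducible from tabulated current densities and
concentrations under any single convention of this family (the underlying
charge integration and exact demand convention differ between groups);
`denitcath` therefore treats CE as an internally consistent diagnostic and
validates it by its invariants — scale invariance, 100 % at supply = demand,
monotonicity in supply — rather than against any specific published value.

**Gas split.** When only total gaseous N is known,
`split_gas_by_electron_balance` allocates the final-step electron as the
marginal consumer: N₂ = (supply − pre-gas demand − 2·gas N)/1, clamped to
[0, gas N] with a feasibility flag when clamping occurred. The split is
monotone in supply and conserves gas N exactly.

**Messy inputs.** The library functions are strict (infeasible N₂O raises).
The `report.balance_table` layer, which may face noisy replicate chemistry
drawn independently per field, instead caps N₂O at removed N (flagged in an
`n2o_capped` column) and emits NaN gas columns when there is no net removal.

## qPCR calibration and ratios (`qpcr`)

Standard curves are ordinary least squares of Ct on log₁₀(copies per
reaction) over a serial dilution (canonically 10²–10⁹ copies);
efficiency E = 10^(−1/slope) − 1. Curves with non-negative slope are
rejected; r² < 0.98 flags a curve without rejecting it. Quantification
inverts the curve and normalises by template mass; Cts outside the
calibrated span are extrapolated but flagged. Replicate Cts are averaged
before quantification, with the SD reported. The inhibition test flags a
spiked-plasmid Ct shift beyond 0.5 cycles — a conventional criterion well
above the shifts seen in clean extracts. Ratio proxies: the five marker/16S
ratios carry a ×100 reporting convention; the three between-step ratios
((q*narG*+q*napA*)/q*nosZ*, (q*narG*+q*napA*)/(q*nirS*+q*nirK*),
(q*nirK*+q*nirS*)/q*nosZ*) are plain. All ratios are invariant to rescaling
every gene by a common factor, so per-ng and per-reaction units agree.

## OTU clustering and alpha diversity (`community`)

Clustering is furthest-neighbour (complete-linkage) agglomeration cut at the
gene cutoff: in complete linkage the merge height equals the merged
cluster's diameter, so every OTU has all pairwise distances ≤ cutoff. Labels
are sorted lexicographically before linkage so ties in equal-distance merges
resolve deterministically; OTUs are returned largest-first. The
implementation rides on scipy's `linkage`/`fcluster`; tests verify it
against an independent brute-force agglomeration that recomputes cluster
diameters by full enumeration.

A cutoff for a new marker gene is derived from paired
(functional, 16S) distances of reference genomes: a least-squares line
through the origin estimates the relative divergence rate, and the
functional cutoff is slope × 0.03 (the 16S species cutoff), rounded to two
decimals as cutoff tables conventionally print.

Estimators: Chao1 is always the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)) (well-defined at F₂ = 0; equals S_obs when
F₁ ≤ 1), delegated to scikit-bio. Good's coverage is 1 − F₁/n. Shannon uses
natural log with the large-sample variance
(Σp ln²p − H′²)/n + (S−1)/(2n²) and a z = 1.96 CI clipped at zero.
Rarefaction is the exact hypergeometric expectation
E[S_m] = S − Σᵢ C(n−nᵢ, m)/C(n, m), computed through log-gamma for
stability; it is monotone and concave in depth and is tested against
Monte-Carlo subsampling.

## Weighted UniFrac (`unifrac`)

The tree (any rooted, branch-length-bearing phylogeny — nucleotide or
amino-acid derived) is flattened to a branch table: lengths plus a
branch × tip membership matrix. The raw distance is Σ b·|p_A − p_B| over
branches, p_X the fraction of sample X's sequences descending through the
branch; the normalised variant (the default, giving values in [0, 1])
divides by Σ b·(p_A + p_B), the value attained at full segregation. The raw
variant is available behind a flag. Significance permutes the sample labels
of individual sequences (not tip totals), with
p = (1 + #{u* ≥ u}) / (1 + N); the default N = 1000 gives a resolution of
~0.001. Normalised weighted UniFrac is not guaranteed to be a metric;
triangle-inequality behaviour is observed empirically, not asserted.

## Group statistics (`stats`)

Comparisons follow the conventional gate at α = 0.05: optional log₁₀
transform, Shapiro-Wilk per group, Levene for homogeneity (the classical
pipeline says "when equal variance was observed" without naming a test;
Levene is the standard choice). If every group passes both, one-way ANOVA
with Tukey HSD and an insert-and-absorb compact letter display; otherwise
Kruskal-Wallis. Groups with n < 3 or zero variance cannot be
Shapiro-tested and route non-parametric, with the reason recorded in the
result's notes. No multiple-testing correction is applied across variables.
`correlate` is the Pearson correlation with r and r² reported; with only
three period means any such correlation is descriptive, and the package
makes no claim to reproduce specific published r² values (the exact
variable pairing behind such values is generally unrecoverable from printed
tables).

## Synthetic generators (`synthetic`)

The generators define the study conditions the tests run under:

* **Chemistry** — Gaussian draws about the per-period means and SDs of the
  three feeding regimes (autotrophic nitrate, heterotrophic nitrate,
  autotrophic nitrite), truncated at zero by redraw. Truncation leaves means
  essentially unchanged where mean ≥ 3 SD; near-zero fields (e.g. effluent
  nitrate under nitrite feeding) are upward-shifted by construction, which
  is why mean-recovery checks apply only where truncation is inactive.
  Fields are drawn independently, so a rare replicate can be momentarily
  infeasible (N₂O draw above removed N) — handled at the report layer as
  described above.
* **qPCR** — Ct = intercept + slope·log₁₀(copies) + N(0, σ) with slope from
  the chosen efficiency, default σ = 0.1 cycles and intercept 38 (a typical
  SYBR single-copy Ct), dilutions 10²–10⁹, duplicate sample wells, plus an
  inhibition-test pair per sample. Default fixture abundances put 16S in
  the 10⁶ copies/ng range with marker genes set from the reported ratio
  regimes (nirS dominant, nosZ at a few percent of 16S).
* **Communities** — multinomial draws from planted OTU frequency vectors
  (including the ~90 %-dominant regime of nitrous-oxide reducers), with a
  companion distance matrix drawn from two regimes: within-OTU in
  (0.1, 0.8)×cutoff, between-OTU in (1.3, 2.4)×cutoff. This guarantees
  complete linkage recovers the planted partition, by design: the unit
  under test is the clustering, not a sequence-evolution model. No
  alignment or distance estimation is simulated.
* **Trees** — random bifurcating topologies by iterative joining with
  Exp(1) branch lengths, and two-sample tip counts under `identical`,
  `disjoint` and `mixed` scenarios.

One master seed spawns independent substreams per output file
(`numpy.random.SeedSequence`), so `simulate_fixture_set` is byte-reproducible
and different files are statistically independent.

What passing tests on these inputs show — and what they do not: they
validate the estimators, the bookkeeping and the pipeline plumbing under
idealised noise (Gaussian chemistry, log-linear qPCR, cleanly separated
OTUs). They do not validate robustness to PCR bias, chimeras, alignment
error, or distance matrices whose block structure straddles a cutoff; real
sequence data adds all of these upstream of this package.

## Problem sizes and defaults

Default fixture sizes (50 sequences per community, 8–12 tree tips,
1000 permutations for UniFrac in production use, 200 in the quick
demonstration configs) match small clone-library studies, where per-gene
libraries run tens of sequences; everything scales to larger inputs
linearly except UniFrac permutations (linear in N × branches) and OTU
clustering (O(n²) memory in sequences).

## Known limitations

* The N₂O/N₂ electron-balance split assumes all current goes to
  denitrification; competing electron sinks bias the split toward N₂.
* Coulombic efficiency values depend on the demand convention; compare CE
  across runs of this package, not across publications.
* Shannon SDs from the large-sample formula undercover for very uneven
  communities at small n.
* The permutation test treats sequences as exchangeable between the two
  samples; it does not model clone-library size bias.
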