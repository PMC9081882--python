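# Methods

## Background and model

`cfosnet` infers condition-level functional connectivity from regional
c-Fos immunoreactivity. c-Fos is an immediate-early gene whose protein
peaks roughly 90 minutes after neuronal activity, so the density of
c-Fos-positive cells (cells/mm²) in a brain region is a one-shot proxy for
that region's recent activity. Because each animal yields a single
post-mortem snapshot, connectivity cannot be computed within an animal;
instead, two regions are called functionally connected within a condition
when their densities covary **across animals**. The inter-animal Spearman
rank correlation is the coupling measure: it is invariant under monotone
distortions of the staining/counting chain and robust to the right-skew of
count-derived densities.

The pipeline, per condition:

1. **Density tables.** One row per animal, one column per region of a
   30-node lateralized atlas (15 bilateral areas, frontal to caudal:
   Cg, PrL, IL, DG, CA1, CA3, BLA, LA, CeA, PVT, RSP, pRSP, LC, NTS, DMX;
   codes `<Name>-<L|R>`, left = ipsilateral to the stimulated left ear).
   Densities may be computed with `compute_density` (mean of repeated
   counts divided by ROI area); the number of determinations is not fixed.
2. **Correlation matrix.** Spearman ρ for each of the C(30,2) = 435
   unordered region pairs, pairwise-complete over animals.
3. **Thresholding.** Edges are pairs with two-sided p strictly below α
   (default 0.05), keeping both signs. No multiple-testing correction by
   default — the false-edge burden this implies is quantified below;
   Benjamini–Hochberg is available as a flag.
4. **Connectivity strength.** The Fisher transform z = atanh(ρ) of the
   significant **positive** coefficients forms a non-negative symmetric
   weight matrix — the weighted graph all metrics run on. The
   unthresholded all-pairs z vector (435 values) is kept separately for
   condition contrasts.

## Exact permutation p-values

The sampling distribution of Spearman's ρ at small n is far from the
asymptotic t approximation, and the design of interest has n = 8 animals
per condition. The default (`method="auto"`) therefore computes two-sided
p-values by **full enumeration of rank assignments** for n ≤ 9 and falls
back to the t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df beyond that.
Two implementation regimes keep enumeration affordable:

- tie-free data: the permutation null of ρ depends only on n, so the
  |ρ| null distribution over all n! assignments is tabulated once per n
  (40,320 values at n = 8) and shared by every pair;
- tied ranks: the observed tied rank vector is permuted explicitly for
  that pair (vectorized matrix product).

A two-sided p is the fraction of assignments with |ρ_perm| ≥ |ρ_obs| (to a
1e-12 float tolerance). Tie-free ρ itself uses the exact rank-difference
formula 1 − 6Σd²/(n(n²−1)) so that perfectly concordant data return
exactly ±1. Constant regions have undefined ρ: the pair is excluded from
edge sets and from the all-pairs z vector with a logged warning, never
imputed as zero. With strict p < 0.05 and the discrete exact null, the
realized per-pair false-positive rate at n = 8 is 0.0458 (the largest
attainable p below 0.05), which the calibration checks confirm.

## Graph metrics

Metrics follow the weighted-undirected conventions of the Brain
Connectivity Toolbox, computed on the positive-z weight matrix:

- nodal degree k_i (count of incident edges) and nodal strength s_i (sum
  of incident weights);
- Onnela clustering: with ŵ = W/max(W),
  C_i = Σ_{j,h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1)), zero when k_i < 2;
  the global max normalization makes C scale-free in the weights;
- global efficiency: edge lengths 1/W_ij, all-pairs shortest paths
  (Dijkstra via scipy.sparse.csgraph), E = mean over ordered pairs of
  1/d_ij with unreachable pairs contributing zero to the numerator while
  remaining in the N(N−1) denominator.

Hubs are ranked by nodal strength normalized to the network maximum
(ties: normalized degree, then atlas order); a degree-keyed ranking is
reported alongside, since both orderings are informative. Both rankings
and the four global metrics (efficiency, mean clustering, mean strength,
mean degree) are emitted per condition.

## Condition contrasts

Every two-group contrast reports **both** an unpaired equal-variance
Student t (df = n_a + n_b − 2; two length-435 all-pairs z vectors give
df = 868) and a Kruskal–Wallis H, with per-group mean ± SEM. Node-level
contrasts extract one region's z-scores against the 29 others per
condition. Caveat: entries of an all-pairs z vector share animals, so the
nominal df treats dependent values as independent; under full regional
independence the 435 entries are pairwise uncorrelated and the null
calibration below shows the resulting p-values are close to uniform, but
under strong true structure the tests should be read as descriptive
surfaces, not calibrated inference.

Hemispheric edge counts summarize, for the frontal (Cg/PrL/IL),
hippocampal (DG/CA1/CA3), amygdalar (BLA/LA/CeA) and brainstem
(LC/NTS/DMX) groups, the significant edges of either sign with at least
one endpoint in the group, split into intra-left / intra-right / inter.
An edge joining two groups is counted in both groups — the only simple
rule consistent with within-group counts exceeding the C(3,2) = 3 pair
limit a 3-region hemisphere group allows. PVT/RSP/pRSP participate in all
network computation but sit outside the four counted groups.

Per-region density contrasts (t and Mann–Whitney, uncorrected p, optional
BH columns) complete the report.

## Synthetic cohorts

No raw density tables are publicly available for this design, so the
generator emulates the study conditions with known ground truth: two
conditions × n = 8 animals × 30 regions. Sampling is by Gaussian copula:
a target Spearman matrix is mapped to latent Pearson correlations via the
exact bivariate-normal relation ρ_P = 2 sin(πρ_S/6), repaired to the
nearest positive semi-definite correlation when necessary (eigenvalue
clipping at 1e−8, diagonal renormalization; the Frobenius repair distance
is logged and distances above 0.1 abort with the worst pairs named), and
latent normal draws are pushed through per-region log-normal quantile
maps. Ranks are invariant under the marginal map, so the sample Spearman
structure converges to the target regardless of marginals; the log-normal
choice (per-system medians 120–250 cells/mm², CV 0.4) only shapes the
densities' scale and skew to a plausible order of magnitude.

The study-emulation preset plants, on top of a baseline within-system
coupling of ρ_S = 0.15 (same anatomical system, same hemisphere, both
conditions), three condition-B effects: a uniform +0.35 on all pairs, a
homotopic +0.15 (each region with its contralateral mirror), and +0.4 on
left–right LC and all LC–DG pairings. The inter-hemispheric effect is
homotopic by design: a uniform increment across all 225 cross-hemisphere
pairs of this size is not a valid correlation structure (cross-hemisphere
correlations cannot uniformly exceed within-hemisphere ones by that
margin — the latent matrix acquires eigenvalues near −1), whereas
homotopic coupling is both feasible and the standard form bilateral
coupling takes. The baseline 0.15 was fixed so that both condition
targets are exactly positive definite with no repair. All draws are
deterministic given the spec seed; condition seeds derive independently
from the base seed.

What the generator does **not** emulate: counting noise on top of the
latent activity (densities are drawn directly), inter-region distance
effects, batch/staining covariates, or missing data (tests inject NaNs
explicitly). Passing recovery tests therefore show the inference chain is
correct and calibrated under the copula model, not that real c-Fos data
meet its assumptions.

## Numerical and design choices

- Strict inequality p < α, matching the stated threshold convention.
- ±1 coefficients are clamped to ±(1 − 1e−7) before atanh (logged).
- Undefined correlations propagate as NaN with warnings, never as zeros.
- Unreachable node pairs contribute zero efficiency rather than being
  dropped from the average (toolbox convention).
- Hub ties break by the secondary metric, then atlas order, so rankings
  are deterministic.
- Seeds: every stochastic routine takes an explicit integer seed;
  derived seeds come from `numpy.random.SeedSequence` and stay below 2³¹.

## Validation and problem sizes

The test suite checks the exact permutation p-values against brute-force
enumeration over all rank assignments (n ≤ 7), and global efficiency /
clustering against a triple-loop Floyd–Warshall and a direct triple
enumeration on random graphs of ≤ 8 nodes. Calibration uses 500 simulated
null condition pairs at the design scale (n = 8): the mean fraction of
pairs passing α = 0.05 lands on the exact test's 0.0458 rejection rate,
and total-connectivity p-values are near-uniform. Recovery uses planted
couplings (ρ_S = 0.8 at n = 500 animals; LC-L–LC-R 0.6 at n = 300 over
100 seeds). The study-emulation smoke test measures how often the preset
reproduces the qualitative condition-B signature across 50 seeds; at
n = 8 with the exact test's critical |ρ| ≈ 0.74, per-group
inter-hemispheric counts in condition B (planted cross-pair couplings
0.35–0.5, means ≈ 4–6 edges) overlap the control condition's false-positive
counts (≈ 2–3), so the joint signature emerges in roughly half of seeds
rather than reliably — an honest statement of the power this design
affords, reported as `study_signature_rate_pct` by the acceptance script.

## Known limitations

- Inter-animal correlation networks confound shared state (arousal,
  handling) with genuine coupling; nothing in the statistics removes a
  common latent factor.
- With 435 uncorrected tests at α = 0.05, ≈ 20 false edges per condition
  are expected by design; the BH flag exists but changes the network
  materially at n = 8.
- The exact test's discreteness makes attainable p-values a coarse grid
  at n = 8 (multiples of 1/40320 in the tie-free case).
- Graph metrics are computed on positive edges only; negative
  significant correlations appear in edge lists, counts and plots but
  carry no weight in efficiency/clustering/strength.
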