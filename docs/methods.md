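# Methods

## Model and procedure

The pipeline clusters serum Raman spectra by exploiting the phase structure
of an inhomogeneous ferromagnetic Potts model.

1. **Data matrix.** Preprocessed spectra become columns of a matrix whose
   rows are Raman shifts (2330 rows for the reference 400-1800 cm⁻¹ grid).
   Pairwise Euclidean distances between columns give the distance matrix.
2. **Coupling graph.** Interacting neighbors are the *mutual* K-nearest
   -neighbor pairs (K = 10 by default), augmented with the minimum-spanning
   -tree edges of the distance matrix so the graph is connected and the
   low-temperature phase is a single cluster. Each edge carries
   `J_ij = exp(−d_ij²/(2 d̄²))/K̂` with `d̄` the mean edge distance and
   `K̂ = 2|E|/n`; non-neighbors do not interact. Nearest-neighbor ties
   break toward the lower index, so graphs are deterministic.
3. **Monte Carlo.** Each point carries a q-state spin (q = 20; results in
   this family of methods are insensitive to q ≳ 10). One Swendsen-Wang
   update freezes every satisfied edge independently with probability
   `1 − exp(−J_ij/T)`, finds the connected components of frozen edges and
   redraws one uniform spin per component. This satisfies detailed balance
   for `exp(−H/T)` with `H = Σ J_ij (1 − δ_{s_i s_j})` and decorrelates in
   a few sweeps even near transitions. The temperature grid is linear
   (default step 10⁻³ in coupling units); the chain warm-starts from the
   all-aligned state at the lowest temperature and carries over between
   adjacent temperatures. When no upper bound is given the sweep stops
   once the largest cluster has stayed below 5% of the points for 20
   consecutive temperatures.
4. **Correlations, susceptibility, partitions.** Edge correlations
   `g_ij = ⟨δ_{s_i s_j}⟩` use the variance-reduced estimator
   `g = ((q−1)c + 1)/q`, where `c` is the fraction of retained sweeps in
   which i and j share a frozen component (plain δ-counting is available
   as a config option). Per sweep the magnetization is
   `m = (qN_max − N)/((q−1)N)` with `N_max` the largest spin-value class,
   and `χ = (N/T)·Var(m)` over the retained sweeps. The data partition at
   each temperature keeps edges with `g > 0.5` and takes connected
   components.
5. **Cluster tree.** Clusters at adjacent temperatures are identified as
   one *lineage* when their Jaccard overlap is ≥ 0.8. A lineage that
   vanishes may reappear within 2 grid steps and continue as itself: near
   a transition the finite-sample partition flickers (split, re-merge,
   split), and without this grace period every flicker would restart all
   lifetimes and collapse the hierarchy. Lineage parentage (which cluster
   a newborn split from) defines the tree. Per node the tree records
   `T_ferro` (its unsplit lifetime), `T_cl` (the lifetime of its most
   stable child), `T_max` (the temperature at which a majority of its
   members are singletons) and `s_T` (lifetime divided by the root span).
6. **Natural clusters.** A child of size ≥ 2 counts as *real* substructure
   when its lifetime is at least `s_Θ = 0.5` times the parent's own
   lifetime; a node with no real substructure is emitted as a natural
   cluster, otherwise extraction recurses into the qualifying children and
   the remainder forms the residual. Points in no natural cluster stay
   residual singletons.
7. **PCA cross-check.** PCA treats spectra as observations (mean-centered,
   unscaled, deterministic signs). k-means on the first two score
   coordinates provides an independent partition whose agreement with the
   natural leaves is measured by the adjusted Rand index; loading-versus-
   wavenumber curves identify the discriminating spectral regions.

### Design choices in the open parts

The stability rule deserves a note: the verbal prescription in the source
literature ("largest T-range extensions", "less stable than a threshold")
is ambiguous about direction. We compared candidate rules on planted data
and on the published tree topology and adopted the parent-relative one
above: it reproduces the published four-leaf tree shape from the printed
per-node statistics, terminates the peeling exactly when remaining
substructure is ephemeral, and needs no extra parameter beyond `s_Θ`. The
published stability values themselves (e.g. 0.666667 for the largest leaf)
come from an unstated temperature normalization, so `s_T` here is defined
relative to the root span (lowest temperature to the root's paramagnetic
melt) and is comparable only within one run.

The published temperature axis is likewise not unit-reproducible (printed
values such as T_ferro = 0.00227273 presuppose an unstated scale), so all
temperatures here are in coupling units of Eq. above and comparisons with
the published per-node temperatures are not attempted; the packaged
cluster table is used for membership bookkeeping only.

## Preprocessing

* **Baseline.** Modified-polyfit: fit a 5th-order polynomial, clip the
  working spectrum to the pointwise minimum of itself and the fit, refit
  until the fit changes by < 10⁻⁶ of the intensity scale (≤ 100 passes).
  Plain least squares over-subtracts under peaks; the iterative clip pulls
  the fit onto the fluorescence background. Negative residuals are kept so
  distances stay unbiased.
* **Smoothing.** Savitzky-Golay, 2nd-order, 11-point window (~6.6 cm⁻¹):
  reproduces quadratics exactly, attenuates a one-point spike by ~79%.
* **Normalization.** Divide by the maximum within 1002 ± 5 cm⁻¹ (the
  phenylalanine band), windowed rather than global so a residual spike
  cannot become the reference. The chain is exactly scale-invariant, and a
  second pass changes intensities only by the smoother's own effect on an
  already-smooth signal (< 2% at sharp band shoulders).

## Synthetic cohorts: what they emulate and what they do not

The generator produces 2330-point spectra on 400-1800 cm⁻¹ for three
classes (default 160/150/42 spectra from 16/21/7 patients). Spectra are
sums of Lorentzian lines from a shared 23-band serum catalog (width 8 cm⁻¹,
amide-III shoulders 25 cm⁻¹, the 1040-1100 envelope 45 cm⁻¹; 1002 cm⁻¹
maximal by construction) with class-specific suppressions: leukemia loses
1654 (completely), 1620, 1603, 1556, 1523 and 1447 cm⁻¹; breast and
cervical lose the low amide-III shoulder and the 938 cm⁻¹ region; cervical
additionally loses 714 cm⁻¹; breast flattens 1040-1100 cm⁻¹. Each
(patient, band) pair draws one log-normal amplitude factor (σ = 0.1),
giving within-class patient substructure. A random positive degree-5
polynomial (~2× the peak scale) models fluorescence; Gaussian noise
(σ = 0.06 of the normalized peak, before smoothing) models shot noise;
Poisson-placed spikes (rate 0.2/spectrum, 1-3 points wide, 5-10× the
signal maximum) model cosmic rays. Everything derives deterministically
from one seed.

Free parameters were calibrated once, when the generator was built: band
amplitudes so that the class hierarchy matches the one reported on real
sera (breast most distinct; cervical and leukemia closer), and the noise
level so that after smoothing the within-class to between-class distance
ratio is ~1:2 — real serum cohorts overlap substantially, and with
near-disjoint classes the Gaussian coupling would leave inter-class bonds
astronomically weak and no single-cluster phase reachable on a linear
temperature grid.

What the generator does **not** model: instrument response and wavenumber
miscalibration, SERS enhancement, physical Raman cross-sections,
concentration-driven covariation between bands, and non-polynomial
fluorescence shapes. Passing the planted-recovery benchmarks therefore
demonstrates the correctness of the clustering machinery on data with the
stated geometry, not clinical performance on real sera.

**Benchmark design.** Cosmic-ray residue that survives the smoother is an
extreme outlier (several units at ~1-2% of spectra); under a Gaussian
coupling such a point correctly never joins any cluster at any practical
temperature, which would make "one cluster at the lowest temperature"
unattainable on a spiked cohort for reasons unrelated to the physics being
tested. The phase-behavior and recovery benchmarks therefore run on
spike-free planted cohorts (30 spectra, 3 × 10, two patients per class),
while spike handling is verified separately: spiked spectra must end as
residual singletons, never inside a natural cluster.

## Numerical choices and degenerate inputs

* Monte Carlo per temperature: 400 sweeps with 100 discarded (benchmarks)
  — enough that the correlation estimator's threshold crossing is stable;
  tests against exact enumeration use 21 000 sweeps.
* Susceptibility uses the population variance; at least two retained
  samples are required.
* Exact-enumeration comparisons use batch means (50 batches) for ⟨δ⟩ and
  ⟨m⟩ and a delete-one-batch jackknife for χ, with a 3-standard-error
  acceptance band.
* Degenerate inputs raise typed errors: all-coincident points (d̄ = 0),
  flat-zero spectra at normalization, empty sweeps, out-of-range K, q < 2,
  non-positive temperatures, zero-lifetime roots in stability ratios.
* PCA on zero-variance data returns zero explained variance with a
  warning rather than failing.

## Known limitations

* The natural-cluster rule, while validated on planted data and on the
  published tree shape, is one of several defensible readings of the
  verbal prescription; the threshold, Jaccard cut, grace period and
  minimum size are all exposed in `TreeConfig`.
* Lineage membership is recorded at birth; clusters that slowly accrete
  members keep their birth roster in reports.
* On cohorts whose classes are separated far beyond the calibrated
  geometry, the ferromagnetic phase may begin below the default `t_min`;
  lower it (or raise the neighbor count) in that regime.
* Runtime scales as (temperatures × sweeps × edges); the full 352-spectrum
  design with a 10⁻³ grid runs in minutes, not seconds.
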