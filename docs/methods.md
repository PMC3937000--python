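# Methods

`genoprof` simulates, end to end, how somatic point mutations accumulating
along a tree's cell lineages become visible to genome profiling (GP) — a
fingerprinting assay that combines single-primer low-stringency PCR
("random PCR") with micro temperature-gradient gel electrophoresis
(μTGGE) — and analyses the resulting genomic-distance matrices. This note
records the model, its assumptions, the default parameters and why they
were chosen, and what the synthetic studies do and do not establish.

## Lineage model

The plant is a trunk with branches attached at configured heights; each
leaf hangs from its branch point on an edge of length `branch_length`.
Following the single-file-of-cells idealization, a physical distance `B`
corresponds to `g' = B / a` cell generations, with unit cell length
`a = 20 µm` by default. Edge generation counts are `ceil(length / a)`, so
any positive distance costs at least one division. This is deliberately an
upper-bound generation model: real meristems are not single files of
cells, so true generation counts per meter are smaller.

Each generation, every base mutates at constant rate `mu_c`
(replication-dependent only; repair-dependent mutation is neglected, as
its rate is assumed much smaller). Along an edge of `g` generations the
simulator draws `Poisson(mu_c · L · g)` substitutions, places them
uniformly, and substitutes to a uniformly chosen different base
(Jukes–Cantor-like; no indels — the GP observables respond to any
substitution, so the simplest substitution model suffices). Back-mutation
is possible; `mutations_from_root` counts events, not Hamming distance.

**Scale.** The default genome is `L = 10 kb` with `mu_c = 5 × 10⁻⁷`
/base/generation. Real tree genomes are 10⁴–10⁵ times larger and real
rates correspondingly smaller; the quantity the observables depend on is
the expected pairwise mutation count `mu_c · L · g`, so the simulation
preserves that product: with branch attach heights 0.5 / 1.4 / 2.3 m and
2 cm leaf stalks, same-branch pairs expect ~10 mutations and
between-branch pairs 235–460, the regime the mutation-rate arithmetic
describes. `5 × 10⁻⁷` sits at the upper end of the replication error
rates reported for DNA polymerases (10⁻⁶–10⁻⁹).

## Measurement model

Random PCR is modelled as one site-finding pass: the primer binds wherever
it aligns to either strand with at most `max_mismatch` Hamming mismatches
(default 6 of 12) and a perfectly matched 3′ anchor (default 3 bases) —
polymerase extension requires a matched 3′ terminus. The experimental
two-round protocol (relaxed then stringent cycles) re-amplifies
first-round products without changing fragment identity, so one pass
captures the fragment set. Every convergent (+,−) site pair whose span
lies in `[min_len, max_len]` (default [500, 1500] bp, around the ~1 kb
band scale) is an amplicon. `select_fragments` models amplification bias
(keep the `n_bands` best-primed products, deterministic tie-breaks); the
pipeline default scores *all* amplified products as feature points
(`n_bands: null`), because a hard selection boundary makes the profile
hypersensitive to mutations in marginal priming sites — a single
rank-flip among candidates replaces a band wholesale, which swamps the
graded melting signal. The "~10 bands" figure of the assay refers to the
strong products; the feature-point extraction scores every visible
transition (gels show more dots than headline bands).

The default primer is Pfm12 (`5'-AGAACGCGCCTG`). The alternative HUNT
(`5'-TGCTGCTGCTGC`) is self-similar with period 3, so its binding sites
arrive in phase-shifted clusters and the amplicon set collapses into a
few nested families covering little of the genome; Pfm12's sites are
effectively independent, giving profiles that sample the genome evenly.
Both primers are available; the choice matters only for profile coverage,
not for any algorithm downstream.

Each fragment becomes one *pre-spiddo*: a raw
(mobility, temperature) point.

* **Mobility** is log-size migration, `1 − log₁₀(len/L_min) /
  log₁₀(L_max/L_min)`, clipped to [0, 1] (defaults L_min = 100,
  L_max = 3000): strictly decreasing in size, 1 at L_min, 0 at L_max.
* **Melting temperature** is the lowest-melting-domain proxy: the minimum
  over all `tm_window`-bp subsequences of the Marmur–Doty GC formula
  `64.9 + 41 (n_GC − 16.4)/w`, minus a constant denaturant offset.
  The window default is 500 bp — melting domains are hundreds of bases,
  and at domain scale a substitution anywhere in a band's governing
  domain shifts its Tm by `41/w ≈ 0.08 °C`, which is what gives the assay
  its stated single-mutation sensitivity over the banded bases. The
  offset (default −20 °C) models Tm depression by the 8 M urea in these
  gels (~2 °C per molar); it cancels in every Tm difference but places
  sample transitions in the same temperature range as the internal
  references, which matters because calibration noise grows with the
  distance between sample points and reference points.

Two internal reference fragments, Ref1 (200 bp, Tm 60.0 °C) and Ref2
(900 bp, Tm 61.4 °C), are co-migrated on every gel. Gel-to-gel
irreproducibility is modelled as one affine transform per axis per gel
(scales and offsets drawn from configured ranges), applied to samples and
references alike, plus i.i.d. Gaussian jitter per point (default
σ = 0.005 on both axes).

## Normalization (spiddos)

Because both references ride on the same gel, the per-axis linear map
sending their observed coordinates to their nominal coordinates undoes
any per-axis affine distortion *exactly*; applying it to every sample
point and dropping the references yields the spiddos. Nominal reference
coordinates come from the package's own mobility/Tm models, so the
simulated and normalized frames coincide. Two-point linear calibration is
the only map two references can determine; flipped gels (negative
recovered scale) and coincident references are errors, not silent fixes.
Residual noise after normalization is the point jitter plus jitter on the
references amplified by the lever arm between a sample point and the
reference pair — the motivation for keeping sample Tm values near 60 °C.

## PaSS and genomic distance

Spiddo correspondence between two profiles is the minimum-total-
Euclidean-displacement one-to-one assignment (Hungarian algorithm), the
automated analogue of superimposing dot patterns by eye. Then

    PaSS = 1 − (1/n) Σᵢ |pᵢ − p′ᵢ| / (|pᵢ| + |p′ᵢ|),     dG = 1 − PaSS

over the matched pairs, with Euclidean norms. Unequal profile sizes leave
extras unmatched and unscored (no penalty by default); a pair with both
points at the origin contributes a perfect match. dG is symmetric, zero
on the diagonal and bounded in [0, 1]; no triangle inequality is claimed.
The denominator makes PaSS origin-dependent; all coordinates live in the
normalized frame where both axes are positive, and dG values are
meaningful relative to one another within a study, not as absolute
divergence estimates. Replicate gels of one sample can be combined in
"mean-spiddos" mode: each replicate is matched to the first and matched
coordinates averaged (the pipeline default uses 3 replicates).

## Clustering

Ward agglomeration is implemented directly as the Lance–Williams
recurrence, in two conventions: `ward.d` (recurrence on the dG values as
given — the default, since dG is not Euclidean) and `ward.d2` (recurrence
on squared distances, square-root heights; equivalent to scipy/R
`ward.D2` on Euclidean input, which is the cross-check used in tests).
Ties in the minimal inter-cluster distance break on the
lexicographically smallest pair of cluster leaf labels, making the
result invariant to input order. Dendrograms export to Newick with
ultrametric branch lengths (node at half its merge height, so leaf-to-
leaf path length equals the cophenetic distance). Planted-topology
recovery cuts the tree into as many clusters as planted branches and
reports the adjusted Rand index (plus a rescaled [0, 1] score
`(ARI+1)/2`); no automatic cluster-count selection is attempted.

## Mutation-rate arithmetic

The quantitative layer: accumulated load `mu(g) = Σ (mu(i) + γ(i))`,
constant-rate form `mu(g) = g · mu_c`; assay sensitivity
`1/(n_bands × band_len)` (10 × 1000 bp → 10⁻⁴/base); generations needed
to reach a load, `g ≥ mu(g)/mu_c` (10⁻⁴/10⁻⁸ → 10⁴); generations
available from geometry, `g' = B/a` (2 m / 20 µm → 10⁵); and the rate
bound `mu_c ≥ mu(g)/g'` (→ 10⁻⁹). The inequality-valued operations
return the bound and its direction explicitly. "Per replication" is
treated as per generation (one replication per division).
`estimate_rate_from_simulation` fits the origin-constrained
least-squares slope of count/L against g (unbiased for Poisson counts)
with a nonparametric bootstrap percentile interval.

## Synthetic studies and what they show

* **Planted-branch recovery** (`experiments.clustering_recovery`): ten
  full pipeline runs on the default 3-branch × 3-leaf tree; Ward
  clustering of the measured dG recovers the planted partition
  (ARI ≥ 0.9) in ≥ 9 of 10 runs.
* **Dose-response** (`experiments.monotone_signal`): 3 independent root
  genomes × 25 two-leaf lineages, separations log-spaced over
  2 000–20 000 generations (expected mutation counts 10–100); each leaf
  measured 20 times under fresh gel distortions; pooled Spearman of mean
  dG against true separation is ≥ 0.7. Independent pairs are used rather
  than pairs within one tree because a single small tree has few edges,
  and the rank statistics of 28 correlated path sums over a handful of
  mutation events are dominated by realization luck rather than by the
  property under test.
* **Normalization stress test**: 100 random positive-scale affine
  distortions are undone to < 10⁻⁹ (float rounding).
* **Rate recovery**: mu_c = 10⁻⁸ recovered within 1.5× in ≥ 95% of 200
  Poisson trials (L = 10⁶, g ∈ 10³–10⁵).

These studies exercise the model's own generative assumptions. Passing
them shows the pipeline is internally consistent and that the
normalization, matching, distance and clustering layers transmit a
mutational signal of realistic size through realistic gel noise. They do
not show that real gels are affinely distorted, that real melting
behaves like windowed GC content, or that real lineages are single files
of cells; on real digitized-gel data (spiddos TSV or a dG matrix) only
the distance and clustering layers apply.

## Numerical and degenerate-input choices

Uniform random genomes at GC 0.5; genome coordinates 0-based half-open;
a primer longer than the genome yields no sites (not an error); fewer
candidate fragments than requested bands returns them all with a logged
warning; PaSS terms with zero denominator contribute zero; exact
duplicate spiddos (possible only in noiseless simulation) are merged;
distance matrices are validated symmetric to 10⁻⁹ on read and
symmetrized; dendrogram heights are monotone by the Ward coefficients;
all stage seeds are spawned from one master seed via `SeedSequence`, so a
(config, seed) pair reproduces every output byte for byte.

## Known limitations

Substitutions only (no indels or rearrangements), haploid genomes, no
developmental model of meristem growth, one primer per profile (no
multi-primer fusion), no gel-image processing, and the Tm/mobility models
are feature-point proxies, not thermodynamics. dG magnitudes from the
simulation (~10⁻⁴–10⁻² here) are smaller than published GP distances,
which reflects the denominator convention and band counts, not the
ordering of distances — every analysis in the package depends on dG only
through comparisons.
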