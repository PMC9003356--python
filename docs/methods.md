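# Methods

`its2dist` estimates pairwise genetic distances for ITS2-like markers under
two views of the same alignment: an independent-site DNA view (GD_DNA) and a
structure-partitioned RNA view (GD_RNA) in which the paired (stem) columns
evolve as coupled dinucleotide sites. The difference between the two, driven
by compensatory base changes (CBCs), is the quantity of interest: when both
nucleotides of a base pair change together, an independent-site model counts
two substitutions where the paired-site view counts one coupled event.

## Sequence-structure records and partitioning

The unit of analysis is a sequence plus its dot-bracket secondary structure
(Vienna format, three lines per record). Structures are inputs — typically
homology-modelled elsewhere — not predicted here. Aligned records are
partitioned by a majority-rule consensus structure: a candidate pair (i, j)
is accepted when the fraction of records pairing those two columns, among
records ungapped at both, reaches the threshold (default 0.75, the field's
standard), with at least two ungapped supporting records; conflicting
(column-sharing or crossing) candidates are removed greedily in decreasing
frequency order with ties broken by the leftmost column. Columns in accepted
pairs are STEM, all others LOOP. Coordinates are 0-based internally and
1-based in reports.

## Substitution models

Every model is a general time-reversible Markov generator Q_ij = s_ij π_j
(symmetric exchangeabilities s, stationary frequencies π), normalised to one
expected substitution event per site per unit time, so branch lengths are in
events per site. Transition probabilities come from an eigendecomposition of
the symmetrised generator D^{1/2} Q D^{-1/2} (reversibility guarantees a real
spectrum), with `scipy.linalg.expm` as a fallback.

Loop models: JC69, K2P, HKY85, REV on {A, C, G, U}.

Stem models operate on dinucleotides. The 7-state family uses the six
pairing states {AU, GU, GC, UA, UG, CG} (canonical plus wobble) and a lumped
mismatch state MM covering the ten remaining dinucleotides:

- **RNA7G** (two-rate preset): rate α on single-nucleotide moves between
  pairing states (AU↔GU, GU↔GC, UA↔UG, UG↔CG) and β on moves between any
  pairing state and MM; double-substitution moves are forbidden. A full CBC
  (AU→GC) is therefore a two-step process through the wobble intermediate,
  matching the accepted biology. One free rate parameter (α/β) after
  normalisation, plus six free frequencies.
- **RNA7A**: fully general reversible 7-state model (20 free
  exchangeabilities).
- **RNA16**: general reversible on all 16 ordered dinucleotides with
  single-nucleotide moves free (47 exchangeabilities) and double moves zero;
  `RNA16REV` (all 119) is available behind configuration.

These constraint sets are declared in `src/its2dist/data/model_presets.yaml`
and are this package's documented parameterisations of the RNA7/RNA16 model
families; alternative constraint sets can be transcribed there without code
changes. An `independent_pair_model` helper lifts any 4-state model to 16
dinucleotide states as a Kronecker sum — the model under which paired-site
and independent-site analyses provably coincide, used for calibration.

Empirically estimated frequencies receive a pseudo-frequency floor of 1e-6
before renormalisation so that states absent from short alignments cannot
produce degenerate likelihoods.

## Pairwise maximum-likelihood distances

For two aligned records, site patterns are tabulated per partition under
complete deletion: a loop column is dropped if either sequence has a gap or
ambiguity there, and a stem pair-column is dropped if any of its four
nucleotides does. GD_DNA maximises lnL(t) = Σ ln(π_x P_xy(t)) over all
usable nucleotide columns (stem columns unfolded to independent sites).
GD_RNA maximises the sum of a loop term and a stem term with separate branch
lengths t_loop and t_stem; because parameters do not cross partitions the
joint optimisation splits into two independent fits.

The mixed distance is reported per site of the partitioned matrix, where a
stem pair-column is one (two-nucleotide) site:

    GD_RNA = (n_loop·t_loop + n_stempairs·t_stem·c/2) / (n_loop + n_stempairs)

with c the expected nucleotide changes per stem-model event (exactly 1 for
the single-substitution presets), so t_stem·c/2 is the expected nucleotide
changes per stem position. Weighting each coupled pair once is the
paired-site reading of the data: a full CBC contributes one substitution to
one site, where GD_DNA counts two changes at two sites. Two consequences
follow by construction and are verified by simulation: when stems and loops
evolve at the same per-position rate, GD_RNA and GD_DNA estimate the same
quantity (their ratio is 1 in expectation); and as the stem/loop rate ratio
grows, the GD ratio falls below 1 — the deviation that motivates using
structure-aware distances once stems evolve a few-fold faster than loops.
We considered the alternative per-nucleotide-position convention (dividing
by n_loop + 2·n_stempairs and counting each pair event's changes in full);
it makes GD_RNA a consistent estimator of the same quantity GD_DNA targets,
so their ratio stays pinned near 1 with a minimum at equal rates, and the
diagnostic contrast between the two views disappears. The per-pair-site
convention is the one that expresses the "count the covarying pair once"
argument as a measurable quantity.

The magnitude of the GD-ratio deviation depends on divergence as well as on
the rate ratio. At moderate divergence (a few to ~10 % per site) and a
threefold stem/loop rate ratio the ratio sits clearly below 1 (about 0.91
in the large-site limit under the default models). At higher divergence the
independent-site distance develops a downward bias of its own — stem
positions are hidden-Markov marginals of the pair process, so DNA models
undercorrect their multiple hits — which partially offsets the pair-site
discount and pulls the ratio back toward or above 1. The decreasing trend
in the rate ratio holds in both regimes; the crossing point below 1 moves
with divergence.

Optimisation is bounded L-BFGS-B over t ∈ [0, 10] (the distance cap) plus
the model's free rate parameters, multistarted from t ∈ {0.01, 0.1, 1.0}
(single start for models with more than five rate parameters, whose
likelihood surfaces are smooth in t and expensive per evaluation).
Frequencies are fixed at their pooled empirical values rather than iterated.
Diagonal-only pattern counts (identical sequences) are handled exactly:
lnL is maximised at t = 0 since P_ii(t) ≤ 1, so the fit short-circuits
there instead of crawling along a numerically flat surface. An estimate
pinned at the cap with the likelihood still increasing is flagged
unconverged (saturation) rather than silently reported.

## Model comparison across state spaces

Likelihoods fitted on 4-, 7- and 16-state stem treatments live on different
sample spaces. Spreading the lumped MM probability uniformly over the ten
mismatch dinucleotides multiplies a 7-state likelihood by 1/10 per MM
observation, placing it on the 16-state space:

    lnL_corrected = lnL + n_MM · ln(1/10).

4-state likelihoods on stem nucleotides are already on the dinucleotide
space by independence. Model fits are ranked by AICc = −2lnL + 2k +
2k(k+1)/(n−k−1) with n the number of usable nucleotide columns
(pair-columns count 2) and k counting substitution parameters, estimated
frequency parameters, and branch lengths (one for pure fits, two for mixed).
The default grid is {HKY85, REV} loop models × {RNA7A, RNA7G, RNA16} stem
models plus the pure DNA models for contrast; combinations whose AICc is
undefined (n ≤ k+1) are retained with AICc = +∞ rather than dropped.

## CBC counting and raw rates

On each consensus pair, a CBC is a change of both partner nucleotides with
pairing (canonical or wobble) maintained on both sides; a hemi-CBC changes
exactly one side with pairing maintained. Changes that end in a mismatch are
neither — compensation means the structure survives. Pairs containing gaps
are unscorable. SRS and SRL are the fractions of variable nucleotide columns
in stems and loops (per-column counting, gapped columns deleted); SRS/SRL is
the threshold statistic: below ~2 the independent-site DNA model remains
safe, around 3 the structure-aware distance is consistently the smaller one.

## Sister-species screening

A genus alignment is screened with the standard barcoding recipe: pairwise
K2P distances under global complete deletion, a neighbor-joining tree, and
bootstrap supports from column resampling (default 1000 replicates). NJ is
implemented directly with deterministic lowest-index tie-breaking; on an
additive matrix it recovers the generating topology and branch lengths
exactly (negative estimates are clamped to zero), and library NJ
implementations serve as independent oracles in the tests. A species is
identified iff its individuals form a clade with support strictly above 50;
the genus passes at a resolution of at least 50 % of assessed
(multi-individual) species; a sister species pair is two identified species
whose clades are adjacent across one internal edge (their leaf union is
itself a split, or the whole leaf set when only two clades remain) with that
edge's support strictly above 50. Saturated (non-finite) K2P entries refuse
tree building with a clear error; degenerate bootstrap resamples are
redrawn with a retry cap.

## Synthetic data generator

The generator emulates the structure of the real analysis inputs: a shared
four-helix consensus structure with 67 base pairs (134 paired positions,
helix lengths 10/15/35/7) and 97 unpaired positions — echoing the field's
reported averages — adenine-biased loops (π_A = 0.34), GC-rich stems with a
2 % stationary mismatch mass, sister divergence t_total = 0.025
substitutions per site (the few-percent scale typical of sister species) and
within-species divergence t_within = 0.005, three individuals per species.
The stem default is RNA7G with α = 4, β = 1: most stem events preserve
pairing, making the compensatory pathway dominant.

Rate bookkeeping: `rate_ratio` is the per-nucleotide-position stem/loop rate
ratio r_S/r_L, normalised so the sequence-wide expected rate is one
substitution per position per unit time (f_L·r_L + f_S·r_S = 1). Loop sites
evolve by P_loop(t·r_L); stem pairs by P_stem(t·r_S·2/c), so each stem
position accrues t·r_S expected changes and the realised SRS/SRL tracks
`rate_ratio`. Endpoint states are sampled directly from P(t), which is
distributionally identical to event-by-event simulation for endpoint data;
realised CBCs are therefore tracked by comparing pair states between the
ancestor and each tip and between the two tips (so no tip-observable CBC is
ever missed), not by counting path events. Under a 7-state stem model a
pair staying in the lumped MM state keeps its current dinucleotide; entry
into MM draws one of the ten mismatches uniformly — consistent with the
uniform-spreading likelihood correction.

Genus simulation places species ancestors on a seeded random ultrametric
species tree (tip depth t_total/2, internal joins stratified uniformly) and
radiates individuals from each species ancestor at t_within/2. One global
seed drives named substreams (ancestor, branches, tips), so every output is
reproducible component by component.

What the generator does **not** emulate: insertions/deletions (alignments
are gap-free; gap handling is exercised by hand-crafted fixtures),
coalescent within-species genealogies, structure heterogeneity among
individuals, alignment error, and base-composition drift along the tree.
Passing tests therefore demonstrate correctness of the estimators under the
generating model and the qualitative stem/loop-rate response — not
robustness to misalignment or indel-rich real data.

## Problem sizes used by the test and acceptance runs

Branch-length and model recovery use sister pairs of 10,000 nucleotide
columns (5,000 loop sites + 2,500 stem pairs) at t_loop = 0.05 and
t_stem = 0.15 over 50 seeds. The rate-ratio sweep runs 30 replicates per
ratio in {0.5, 1, 2, 3, 4} at t_total = 0.3 on a four-fold scaled structure
(924 columns), a divergence high enough that model choice matters while the
Monte-Carlo error of per-ratio means stays near 0.01; the monotone-decrease
claim is assessed by Spearman rank correlation over replicate points, since
the underlying response flattens between ratios 3 and 4 and differences
there fall below Monte-Carlo resolution at any modest replicate count.
Screening end-to-end uses two-species genera at the default study
conditions with 100 bootstrap replicates over 50 seeds. The optimiser's
iteration cap on the 20- and 47-parameter stem models (100–150 L-BFGS-B
iterations in the recovery runs) is a convergence-tolerance choice; it can
only under-fit the over-parameterised competitors, never favour them.

## Known limitations

- The RNA7G/RNA16 constraint sets are this package's declared
  parameterisations of the 7- and 16-state paired model families; published
  implementations of such families differ in their exact constraint sets,
  and the presets file exists precisely so alternatives can be transcribed.
- The likelihood correction assumes the uniform spreading of MM mass; a
  16-state model with strongly non-uniform mismatch frequencies is only
  approximately comparable to a corrected 7-state fit.
- Pairwise (two-taxon) likelihoods only; no tree-wide joint estimation, no
  among-site rate variation (Γ), no pseudoknots.
- GD_RNA's per-pair-site convention is a reporting choice; diagnostics
  (t_loop, t_stem, per-partition lnL) are always emitted so any alternative
  normalisation can be recomputed from the same fit.
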