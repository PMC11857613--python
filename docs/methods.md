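# Methods

`ms2fp` implements a complete metabolite-annotation workflow: MS/MS spectra
are embedded as fixed-grid binned intensity vectors, a multi-label neural
model predicts a condensed molecular fingerprint from the vector, and
database compounds retrieved by precursor m/z under adduct hypotheses are
ranked by the Tanimoto similarity between their fingerprints and the
prediction, optionally fused with an external formula-prediction score.
This note records the model, the parameters that matter, the numerical
conventions, and what the synthetic benchmark does and does not show.

## Spectrum preprocessing

A spectrum's peak intensities are first rescaled so the base peak is 100
(relative intensity).  Spectra with no or more than one precursor mass, or
with fewer than five peaks, are discarded; this quality filter is applied to
the raw (scaled, unrestricted) peak list.  Peaks outside the closed mass
range 100–1010 Da or with scaled intensity below 1 are then removed, the 20
most intense surviving peaks are kept (ties broken toward lower m/z for
determinism), and the survivors are summed into 0.01 Da bins.  The closed
grid has exactly 91,001 bins; an m/z exactly at 1010.0 falls in the last
bin.  Bin indices are computed as `floor((mz − 100)/0.01)` with a 1e−7
round-off guard, which is far below the 5-decimal precision of the data but
prevents boundary peaks from landing one bin low.

Bins populated in fewer than 0.1% of the training spectra are removed;
occupancy exactly at the threshold survives (the removal rule is strictly
"less than").  Positive- and negative-mode spectra share the grid but are
occupancy-filtered separately, so each ionization mode has its own retained
bin set and its own model.

## Fingerprints and condensation

A compound is encoded by the concatenation of five binary substructure
blocks with pinned widths — FP3 (55), FP4 (307), PubChem-width (881), MACCS
(166), Klekota-Roth-width (4860) — 6,269 bits in total.  FP3, FP4 and MACCS
are computed with OpenBabel's pattern definitions after RDKit
canonicalization of the input SMILES, so every spelling of a molecule maps
to identical bits.  The PubChem/CACTVS and Klekota-Roth key sets are large
external pattern libraries that are not bundled with this package; those two
blocks are filled by deterministic hashed substructure fingerprints (Morgan
radius 2 folded to 881 bits, RDKit path fingerprints folded to 4860).  The
hashed blocks preserve the scheme's width and all downstream algebra, and
remain genuine structure-derived substructure encodings, but individual bit
positions in those blocks do not correspond to the published key
definitions; analyses that interpret single PubChem or Klekota-Roth bits
chemically should substitute the published pattern sets.

On a training compound set, columns constant across all compounds are
dropped and groups of identical columns are condensed to one representative
(the lowest original index).  The resulting condensed map is a partition of
the 6,269 indices and defines the model's output space; it is serialized
with every trained model, and candidate fingerprints are projected through
it at annotation time (if a duplicate group disagrees on an unseen molecule,
the representative bit decides and the disagreement is counted).

## Supervised feature selection

Bin selection trains one tiny probe network per candidate bin — a
single-input multilayer perceptron (one hidden layer of 32 units) against
all fingerprint bits — under five-fold cross-validation with folds split on
compound identity, and scores the bin by the micro-averaged F1 of the
held-out predictions; the top 500 bins are kept (ties toward the lower
index).  Probe seeds depend on the fold only, so identical bin columns
receive identical scores.  Fingerprint selection trains one convolutional
probe (32 filters of width 5, a 64-unit dense layer) on the selected bins
and keeps bits whose mean per-fold F1 strictly exceeds 0.8; a bit without
positive examples in a fold scores 0 for that fold.  When no bit passes,
the pipeline proceeds with all bits and logs a warning.  Probe budgets (20
epochs, batch 128, Adam at 0.01) are configuration values; the probes are
deliberately small and their absolute F1 depends on that budget.

## Prediction models

Three architectures share one contract (same build/fit/predict surface,
same serialization): a dense network (512 → 256 → sigmoid outputs), a
convolutional network (two conv blocks of 64 and 32 width-5 filters with
max-pool 2, then a 128-unit dense layer), and a recurrent network (the bin
vector is right-padded and chunked into a 20-step sequence feeding an
LSTM with 128 hidden units, then a 128-unit dense layer).  All layers are
implemented in a compact NumPy engine with manual backpropagation
(`ms2fp.nn`): dense, valid-padding 1-D convolution, max-pooling, LSTM,
Adam with optional decoupled L2 and proximal L1 penalties, and seeded
Glorot initialization.  Training is single-threaded and bit-reproducible
under a fixed seed.

The training objective is one minus a differentiable (soft) Tanimoto
similarity, `1 − Σyp / (Σy + Σp − Σyp)` per sample, which reduces to
`1 − TP/(TP+FP+FN)` on binary predictions; a sample whose target and
prediction are both all-zero scores loss 0.  Binary cross-entropy is
available as an alternative objective.  Predictions are discretized at 0.5
by default; the ranking stage can alternatively consume raw probabilities.

### Training scheme at small sample sizes

At desk scale the training set contains a few dozen distinct compounds in a
bin space of comparable dimension, so the bin→bit linear system is
underdetermined: a network can reach zero training loss by memorizing
compound co-activation patterns without learning the per-bit structure, and
plain mini-batch training does exactly that (near-zero training loss,
near-baseline accuracy on held-out compounds).  The generalizing solution
is sparse — each fingerprint bit depends on a handful of bins — so the
default fit bootstraps it explicitly:

1. a per-bit L1-regularized logistic map (scikit-learn, liblinear, C = 10)
   is fitted on the training partition; the L1 penalty recovers the sparse
   bin support of each bit reliably even from few compounds;
2. each epoch, a fresh batch of synthetic bin vectors (independent
   Bernoulli occupancy at the empirical per-bin rate, scaled by the
   empirical mean nonzero intensity) is labelled by this sparse teacher and
   appended to the real rows (8× the real count by default);
3. the network warms up on the mixed stream under binary cross-entropy
   (60 epochs at Adam 3e−3 for the dense and convolutional models; 350
   epochs at 1e−2, batch 64, for the recurrent model, which converges much
   more slowly), then fine-tunes under the soft-Tanimoto objective
   (25 epochs at 1e−3) with the best validation-loss weights retained.

The validation split always holds out whole compounds (20% of compound
groups), so reported validation similarities measure structure-level
generalization, not replicate memorization.  Inputs are scaled by the
maximum training intensity before entering the network; the scale is stored
with the model.  With `augmentation="none"` the fit is a plain mini-batch
loop with early stopping (patience 15).  At corpus scale (tens of
thousands of compounds) the bootstrap would be unnecessary; it is a
small-sample regularization device, not part of the model.

## Candidate retrieval, fusion, ranking

The neutral monoisotopic mass implied by a query's precursor m/z is
computed under each mode-consistent adduct hypothesis using pinned
monoisotopic shifts (electron mass folded in): [M+H]+ 1.007276,
[M+NH4]+ 18.033823, [M+Na]+ 22.989218, [M−H]− −1.007276, [M+Cl]−
34.969401, [M+FA−H]− 44.998201 Da.  Compounds whose mass lies within
5 ppm (relative to the hypothesis mass) are retrieved; a compound matching
under several adducts appears once with all tags.  Retrieval uses a sorted
mass index and is tested for equality against a brute-force linear scan.

Each candidate's fingerprint, projected into the model's output space, is
compared to the prediction by Tanimoto similarity (binarized by default).
External formula-prediction scores, read from a CSV keyed by challenge and
formula, are min–max normalized within each challenge — a constant or
singleton score list maps to 1.0 so the fused score's upper bound stays
attainable — and fused with the fingerprint score in a 7:3 ratio.
Candidates without a formula score keep their fingerprint score unchanged.
Ranking is by descending overall score with a deterministic secondary sort
on compound id; tied candidates all receive the worst rank of their block,
so ties can never inflate top-k counts.

## Evaluation

Binary comparisons are tallied into TP/FP/FN/TN.  Tanimoto similarity is
TP/(TP+FP+FN) (defined as 1.0 when nothing is positive anywhere); F1 is
2PR/(P+R) with the degenerate conventions TP=FP=FN=0 → 1.0 and
positives-on-one-side-only → 0.0; MCC returns 0 when any marginal is empty.
A variant Tanimoto denominator (FP+FN−TP) is available behind a flag for
comparison only — it can leave the unit interval and is not a similarity;
nothing in the package uses it.  In cross-validation, F1 and Tanimoto are
micro-averaged over all bits of the concatenated held-out predictions,
while MCC is computed per bit and averaged ("mean MCC").  A candidate is a
hit when it shares the first 14 InChIKey characters (the skeleton block)
with the truth, case-sensitively.  Structure-disjoint training removes
every training spectrum whose InChIKey block 1 occurs among the test
compounds.  The random-ranking baseline shuffles each challenge's candidate
list 100 times; its top-k expectation is min(k, N)/N for a list of size N.

## Synthetic benchmark

The generator plants a known ground truth: a per-seed global codebook
assigns each fingerprint bit one characteristic fragment m/z (configurable)
drawn from 100–1010 Da with all codebook peaks in distinct bins; a
compound's spectrum consists of the peaks of its active bits at intensity
100·exp(N(0, σ)), plus Poisson-rate spurious peaks, and exactly one
precursor at mass ± the proton mass.  Compounds have i.i.d. Bernoulli
fingerprints (default mean 10 of 64 bits — chosen so that noiseless spectra
essentially never fall below the 5-peak filter or above the 20-peak cap),
unique InChIKey-like identifiers, and uniform masses in 150–900 Da.  Decoys
sit at a controlled ppm offset from their true compound (default 0.5–10
ppm, so some compete inside the 5 ppm window and some do not), differ by
exactly 4 fingerprint bit flips, and always carry a different InChIKey
skeleton.  Synthetic formula scores give the true formula a higher-mean
distribution (0.9 ± 0.05 vs 0.4 ± 0.15, clipped to [0, 1]), with a
configurable fraction of challenges missing the true formula.

Default study conditions: 50 compounds, 64 fingerprint bits, 4 replicate
spectra per compound, noiseless intensities, 5 decoys per compound.  Under
these conditions each architecture exceeds 0.8 held-out-compound
soft-Tanimoto similarity and the full pipeline (preprocess → select →
train convolutional model → annotate → evaluate) ranks the true compound
first in ≥90% of structure-disjoint challenges.

What the synthetic benchmark does not emulate: chemically realistic
fragmentation (fragment m/z are arbitrary codebook values, not bond
cleavages), correlated fingerprint bits, isotope patterns, adduct
heterogeneity within one dataset, retention time, chimeric spectra, and
instrument-dependent intensity response.  Passing these tests therefore
shows the pipeline's machinery is correct and recoverable under its own
assumptions, not that the trained models reach any particular accuracy on
real spectral libraries.

## Numerical and design conventions

- Peak m/z is written to 5 decimals and intensity to 4 significant figures;
  round-trips through MSP/MGF preserve peaks to that precision.
- The raw precursor-field count of each record is preserved by the parsers
  (never defaulted to 1) so the one-precursor filter is faithful.
- MGF ionization mode comes from the ION MODE/CHARGE fields, never from
  adduct text; MSP accepts NIST- and MoNA-style headers case-insensitively.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; fold assignment deals shuffled compound
  groups round-robin.
- Problem sizes in the test suite (hundreds of spectra, tens of compounds,
  64–800 bins) are the package's desk-scale defaults; every size is a
  configuration value and scales up unchanged.

## Known limitations

- The PubChem and Klekota-Roth blocks are hashed surrogates (see above).
- The LSTM model converges an order of magnitude more slowly than the
  dense and convolutional models at these sizes and reaches a lower
  plateau; its schedule defaults are sized accordingly.
- The condensed map, bin selection, and fingerprint selection are
  mode-specific and travel with the model; applying a model to vectors
  built with any other selection is rejected rather than silently accepted.
- SIRIUS-style formula scores are consumed from file only; the package
  neither runs nor reimplements formula prediction.
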