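# Methods

This note records the models implemented in `phosphodia`, their
assumptions, the parameters that matter, what the synthetic generators do
and do not emulate, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Peptide representation

A modified phosphopeptide is a residue string over the 20 standard amino
acids with a per-position modification map (phospho on S/T/Y, oxidation on
M) and an N-terminal acetyl flag. The compact text dialect replaces a
modified residue by a digit (`1` = oxidized M, `2`/`3`/`4` = phospho
S/T/Y) and prefixes the string with `*` (N-terminal acetyl) or `@` (free
N terminus). The leading symbol is tied to the *N-terminal acetyl state
only*; this is one admissible reading of marker symbols of this kind, and
fixing it makes the token alphabet unambiguous. Validation enforces
residue/modification chemistry and a length window of 7–50 residues
(configurable) at parse time.

Token ids are assigned in a frozen order — 20 amino acids alphabetically,
the four modification digits, `*`, `@`, charge tokens +1..+6, pad — so
that saved model weights remain portable across sessions. The ion model's
input appends the precursor charge; the RT model's input has no charge
token.

## Fragment-ion channel space

The prediction target for one precursor is an `L x 8` matrix (`L` = the
longest peptide in the dataset); row `i` holds the channels b(i)/y(i) ×
fragment charge +1/+2 × {no loss, H3PO4 loss} in a fixed column order.
Two structural rules define the validity mask:

1. only fragment numbers `1..n-1` exist for a peptide of length `n`;
2. a phosphoric-acid (−97.976896 Da) loss channel exists only if the
   fragment (b_i = residues 1..i, y_i = residues n−i+1..n) contains at
   least one phosphosite.

Invalid cells carry the sentinel −1; valid intensities are normalized so
the largest equals 1 (base-peak convention — the natural reading of a
relative-intensity column in library TSVs). The mask is enforced in the
training loss, in prediction post-processing, in the similarity metrics,
and when reading library files (a loss annotation on a phosphate-free
fragment is rejected as malformed).

Choices where the representation is silent:

- +2 fragment channels are *not* masked by precursor charge or fragment
  length; only the two rules above apply. This is configurable downstream
  via library filters.
- A fragment with two or more phosphosites still has a single-loss channel
  only; multi-loss species are unrepresentable in the 8-channel space and
  are not modeled.
- Masses are monoisotopic (pyteomics residue table; proton 1.007276,
  water 18.010565, H3PO4 97.976896; deltas: phospho +79.96633, oxidation
  +15.99491, N-terminal acetyl +42.01057). Cysteine is treated as
  carbamidomethylated (+57.02146) by default, matching the fixed
  modification used in standard phosphoproteome searches; a `MassTable`
  flag disables it. m/z is written to 4 decimals; full precision is kept
  internally.

## Sequence models

Both tasks share a trunk: token embedding → two stacked bidirectional LSTM
layers (hidden 512 per direction at full size) → linear projection to the
model width `d_model` → sinusoidal position encoding → a stack of post-norm
Transformer encoder layers (8 attention heads at full size) → task head.

- **Ion model.** Each amino-acid token embeds to 192 dims; the precursor
  charge embeds to 64 dims and is broadcast-concatenated at *every*
  position (the placement of the charge conditioning was open; broadcasting
  makes every layer charge-aware). The head is a per-position linear map to
  the 8 channels. Loss: MSE over cells valid in the target mask — sentinel
  cells contribute exactly zero gradient (verified by finite differences in
  the tests).
- **RT model.** Tokens embed to 256 dims (no charge). A linear layer
  produces one scalar weight per position; weights are softmax-normalized
  over non-pad positions (normalization of the instance-specific weights
  was open; softmax makes the pooling a proper weighted average and
  guarantees pad positions receive zero weight); the pooled feature maps
  linearly to one scalar on the normalized RT scale. Loss: RMSE. Reported
  predictions are clipped to [0, 1] before rescaling; the loss sees the
  unclipped value. The deployed predictor averages an ensemble of networks
  with Transformer depths 4–8 (reduced configurations use fewer/shallower
  members). Averaging in z or in RT units is identical because the rescale
  is linear.
- **d_model.** The 1024-wide biLSTM output is projected linearly to
  `d_model` = 512 (configurable) before the position encoding and the
  encoder stack; the reconciliation between the recurrent width and the
  Transformer width was an open point and an explicit projection is the
  least surprising choice. The position encoding is added to the projected
  features.
- **RT scale.** Targets are normalized to [0, 1] via a fixed window,
  default min(RT) = −100 and max(RT) = 200 in iRT units, so that models
  trained on different corpora share one output scale.

### Training

Adam, learning rate 1e−3 for first-phase pretraining corpora and 1e−4
otherwise (fine-tuning default), decayed by 0.1 at preset epoch milestones
(default ⌈2/3·E⌉ and ⌈5/6·E⌉ for E epochs, since only "predefined epochs"
is specified). Datasets split 8:1:1 into train/validation/test (9:1 for
pretraining), with the *modified sequence* as the grouping unit so charge
states of one peptide never straddle splits. The returned checkpoint is
the best validation epoch — median per-precursor PCC (maximized) for the
ion task, Δt95% (minimized) for RT — never the last epoch. Transfer
learning initializes from a previous checkpoint and continues at the lower
rate; the fine-tuning stage never touches the pretraining data. An
optional `stop_at_metric` ends training once the validation metric crosses
a threshold. Non-finite losses abort with a diagnostic.

The tensor substrate is a small in-package reverse-mode autodiff over
float64 numpy arrays (`phosphodia._autodiff`) with a fused
whole-sequence LSTM kernel; every primitive's vector-Jacobian product is
finite-difference-checked in the test suite. This keeps the package
runnable on a single CPU with no deep-learning framework.

## Evaluation metrics

Per precursor, PCC and the normalized spectral angle
`SA = 1 − 2·arccos(p̂·p)/π` on L2-normalized intensity vectors, both over
cells valid in the *target* mask; corpus summaries are medians over defined
values (zero-variance or zero-norm spectra are reported missing, not
zero). For RT: median absolute error, OLS R², and
`Δt95% = 2·|z−ẑ|_{95%}` with the 95th percentile fixed to the
nearest-rank (ceil(0.95·n)-th order statistic) so the number is bit-stable.
PCC uses all valid cells, not only nonzero target cells — with max-
normalized spectra the zero cells carry real information about absent
fragments.

## In silico digestion

Tryptic digestion uses `pyteomics.parser.icleave` behind the module
surface, with two rules: `trypsin` (cleave after K/R, suppressed before P;
the default, matching standard search-engine settings) and `trypsin/P`.
Defaults mirror phosphosite-database library construction: peptide length
7–30, no missed cleavage, at most one phosphosite per peptide, precursor
charges {2, 3, 4}. Registered sites are validated against the protein
sequence, converted to peptide-local coordinates, and enumerated as
site combinations up to the per-peptide maximum (unmodified forms are never
emitted). Duplicate modified sequences from paralogous proteins collapse
to one entry; output order is canonical, so the result is independent of
protein order in the FASTA. Initiator methionine is not specially removed.
Peptides containing additional, unregistered S/T/Y keep them unmodified —
only registered sites are phosphorylated.

## Library engineering

Libraries are keyed by (modified sequence, charge); all transformations
are value-semantic (inputs are never mutated) and preserve key uniqueness.

- **Predicted library**: model spectra → peaks above a relative-intensity
  floor (default 0.05), at most 25 fragments per precursor, fragment m/z
  restricted to 200–2000 Da; precursor-level filters (m/z window, length,
  phosphosite count, charge set) drop whole entries and are logged.
  Tie-breaks in the top-N cut follow a fixed channel order so output is
  deterministic.
- **Hybrid merge**: union with the experimental entry winning both the
  spectrum and the iRT on key collisions; idempotent.
- **Focused library** (iterative search): predicted entries are filtered
  to the identifications of the initial search; experimental entries are
  kept whole by default.
- **Decoys**: the reversed sequence (C-terminal residue fixed,
  modifications traveling with their residues, N-terminal acetyl and the
  charge retained) predicted with the same trained models and appended.
  Palindromic reversals that collide with any target key are dropped and
  counted rather than mutated.
- **Entrapment libraries**: concatenation of two species-tagged libraries;
  modified sequences shared across species are dropped from the entrapment
  side; unique-peptide counts per species are recorded for the FDR
  normalization.
- **TSV dialect**: one row per fragment with fixed Spectronaut-compatible
  columns (PrecursorMz, PrecursorCharge, ModifiedPeptide in the bracket
  dialect, StrippedPeptide, iRT, FragmentMz, RelativeIntensity,
  FragmentType, FragmentNumber, FragmentCharge, FragmentLossType,
  ProteinId, Source); read∘write is the identity to 4 decimals.
- **Identification tables**: adapters for a normalized dialect plus
  MaxQuant/Spectronaut column subsets; records require localization
  probability strictly greater than 0.75 (class-I convention; the boundary
  value is excluded); unparseable rows are counted and skipped.
- **iRT calibration**: OLS of observed RT on predicted iRT over shared
  peptides (≥ 3 required), applied to the whole library.

## Error control

- Reverse-decoy FDR: `2·Hits_rev / (Hits_orig + Hits_rev)`.
- Entrapment FDR: false hits are scaled by the main/entrapment
  library-size ratio and by `1/(1−0.01)` to offset the search's own 1%
  error tolerance; `FDR = NormHits_False / (Hits_True + NormHits_False)`.
- FLR on a synthetic ground-truth set: the fraction of identified sites
  not in the truth set; site recovery is reported alongside.
- Two-proteome quantification: intensities are de-normalized upstream;
  a precursor's ratio at a condition is the mean over replicates divided
  by the mean at the control, requiring observation in both (missing
  values are excluded pairwise, never imputed). The relative error is
  `|measured/expected − 1|` (a log-scale error is available behind a
  flag); FQR(t) is the fraction of (precursor, condition) *measurements* —
  not peptides — exceeding t, always reported at t = 0.30 and 0.50;
  replicate CV is `100·SD/mean` per precursor per condition with ≥ 2
  replicates.

## Synthetic data: what it does and does not emulate

The generators provide *structure*, not instrument physics, and they are a
test harness rather than a fragmentation theory:

- Peptides: uniform residue usage with a forced tryptic-like C-terminal
  K/R, lengths 7–30, phosphosite count 1/2/3 with probability
  0.70/0.25/0.05 (the mono-phosphosite majority typical of enrichment
  data), charges 2/3/4 with probability 0.5/0.35/0.15.
- Spectra: a smooth deterministic rule — per-series Gaussian bumps over
  relative fragment position, a precursor-charge gain, a
  cleavage-residue factor, and loss channels at a fixed 0.4 of their
  no-loss partner — plus optional multiplicative lognormal noise
  (multiplicative error being the standard intensity-noise model).
  Masks match the validity rules exactly. Because the rule is dominated
  by fragment *position*, a reversed-sequence decoy produces a spectrum
  similar to its target; the reverse-FDR emulation in the acceptance
  script is therefore conservative (numerically high) compared to real
  data, where fragmentation is strongly sequence-specific. Passing tests
  demonstrate that the models can learn a smooth sequence-to-spectrum map
  and that the machinery is wired correctly — not that real-instrument
  accuracy is achieved.
- Retention times: an additive fixed per-residue coefficient model with
  phospho/oxidation/acetyl offsets and Gaussian noise; the coefficients
  are public so tests recover them by least squares.
- Identification tables: localization probabilities drawn with an exact,
  seed-fixed count below the 0.75 boundary to exercise the class-I filter.
- Two-proteome design: a fixed background species and a spike species
  scaled by 0.25/0.5/1.5/2 across four conditions against a 1:1 control,
  six replicates each, lognormal replicate noise (σ = 0.1 by default,
  which puts the median replicate CV near 10%), optional missingness.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own desk-scale defaults: reduced model
configurations (embeddings 32/16, LSTM hidden 64, 2 encoder layers, 2
heads, d_model 64); 64-precursor overfit runs for learning sanity (3
seeds); a 500-peptide corpus for RT generalization; a 300-precursor corpus
(5% spectrum noise, 0.5-unit RT noise) with an 8:1:1 split for the
acceptance pipeline; 120-entry libraries for the decoy/entrapment search
emulation; 300 precursors × 5 conditions × 6 replicates for the
quantification block. Full-size configurations (192/64 embeddings, hidden
512, 8 encoder layers) are constructible and tested for contracts but not
trained in the suite.

## Known limitations

- The search emulation in the acceptance script matches by precursor m/z
  window + spectral angle; it has no XIC extraction, interference
  correction, or peptide-centric statistical scoring, so its FDR/FLR
  numbers characterize the synthetic conditions, not a real search engine.
- Only b/y ions with single H3PO4 loss are represented; no a/c/x/z ions,
  immonium ions, isotope envelopes, or HPO3 loss.
- Only phospho (S/T/Y), oxidation (M), and N-terminal acetyl are modeled;
  no I/L disambiguation.
- The MaxQuant/Spectronaut id-table dialects are documented column-subset
  adapters, not full parsers of those tools' native outputs.
- Training is single-CPU float64; it is deliberately sized for reduced
  configurations, not for proteome-scale corpora.
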