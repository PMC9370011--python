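# Methods

## Model and assumptions

`scmfold` implements the sequential-collapse picture of folding nucleation:
an unfolded chain first forms one specific non-local contact between two
short hydrophobic segments, closing a loop that subsequently collapses. The
scan treats early contacts as hydrophobicity-only — hydrogen bonds, salt
bridges and disulfides either are weaker or form later, so they do not enter
the early-contact energy. The three terms of the contact free energy (in kT):

* **Hydrophobic gain** `−(h_a + h_b)/c`, where `h_a`, `h_b` are per-window
  sums of the Fauchère–Pliska side-chain octanol/water transfer values and
  `c = 0.45` scale units per kT (each conversion carries an estimated
  ±0.1 kT margin). Glycine is the scale's zero; tryptophan (2.25) its
  maximum.
* **Loop-closure entropy** `ν·ln(n_ij)` with exponent `ν = 3/2`, the
  excluded-volume loop-closure scaling, on the center-to-center separation
  `n_ij`.
* **Side-chain immobilisation** `1.09 kT` per contact residue over both
  segments. The per-residue constant is the upper end of per-residue folding
  entropy estimates; at the default window width 5 this yields the canonical
  10.9 kT. It is generated from `1.09 × 2w`, never hard-coded, so
  non-default widths scale consistently.

Admissible separations are `65 ≤ n_ij ≤ 100` inclusive: below ~65 residues
early loop formation is entropically disfavored in the model; above ~100 a
single primary loop no longer leads to a viable native pathway. The minimal
fluctuating loop (~15 residues) of later folding phases plays no
computational role here and is documented only for orientation.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `width` | 5 | residues | contact window per segment; 4–7 supported (even widths anchor the center left of middle) |
| `min_separation` | 65 | residues | optimal minimal loop `n_op` |
| `max_separation` | 100 | residues | maximum primary loop |
| `cutoff_kt` | 3.0 | kT | report contacts within this margin of the best |
| `sidechain_cost_per_residue` | 1.09 | kT | side-chain entropy per contact residue |
| `loop_exponent` | 1.5 | — | coefficient of ln n_ij |
| `kt_conversion` | 0.45 | scale units/kT | hydrophobicity-to-energy conversion |

## Numerical and design choices

* **Separation definition.** `n_ij` is center-to-center. This is the
  definition under which the published core-p53 contact energies (−8.9,
  −8.2, −7.8 kT at separations 92, 73, 83) emerge from the formula and the
  published window sums.
* **Selection.** The scored grid keeps a candidate only if no better-ranked
  candidate overlaps it in *both* windows (non-maximum suppression), so a
  plateau of frame-shifted variants collapses to its local optimum while
  contacts sharing a single segment stay distinct. Ranking and suppression
  break exact ties deterministically: lower ΔG, then smaller `n_ij`, then
  smaller N-terminal center, then smaller C-terminal center.
* **Sign convention.** Computation carries signed ΔG (negative stable);
  reports print the positive stability magnitude to one decimal, with full
  precision retained in JSON.
* **Populations.** `p_k = exp(s_k)/Σ exp(s_m)` over stability magnitudes,
  computed as a max-shifted softmax so large stabilities cannot overflow.
  Reported percentages round half-away-from-zero to integers.
* **Confidence shifts.** One-at-a-time: each contact's own stability is
  moved by ± its uncertainty with all others at nominal values, and the
  signed change of that contact's fraction is reported in percentage
  points. Joint propagation would not produce the characteristic asymmetric
  intervals. Uncertainties are user-supplied inputs (the package carries the
  published ±0.3/±0.4 kT values for the core-p53 table); no derivation of
  them is attempted.
* **Stability source for populations.** The pipeline can feed the population
  stage either the scanned stabilities or an explicit override list. For the
  core-p53 reference analysis the published four-contact stability table is
  used as the input, because the scan itself does not reproduce the third
  entry of that table: with the published scale values, the VQLWV–YNYMC pair
  at separation 91 evaluates to ≈ −5.1 kT, not −7.8, and falls below the
  3 kT cutoff (the scan instead retains MTEVV–ILTII at −6.2 kT in fourth
  place). The scan reports whatever the formula yields; no printed value is
  ever injected into it.
* **Channel merging.** Contacts are merged transitively along the
  stability-sorted chain when adjacent stabilities differ by at most the
  tolerance. Transitive chaining was chosen over cliques because kinetic
  indistinguishability is a chain property: if A is unresolvable from B and
  B from C, no experiment separates the three.
* **Non-standard residues** (X, U, B, Z) are a hard error by default; a
  `zero` policy assigns h = 0 with a warning. Silent zeros would bias ΔG
  downward, so the warning is unconditional.
* **Numbering.** All user-facing positions are 1-based inclusive in the
  record's offset numbering (the core-p53 fixture reports 94–297); internal
  indices are private.

## Interdiction extensions

The contact scan itself is the model; two interdiction-stage quantities go
beyond it and are flagged as model extensions in every report:

* **Attachment score** for a peptide–segment pairing: the contact formula
  without the loop term, on the rationale that an intermolecular attachment
  closes no loop. It is a ranking heuristic, not a binding constant.
* **Redistribution.** Blocking fraction ε of one channel's nucleation flux
  scales that channel by (1−ε) and reassigns the removed mass to the
  surviving channels in proportion to their baseline Boltzmann weights
  (equivalently, at ε = 1, Boltzmann weighting over the survivors alone).
  ε is a free input — no binding constants are estimated — and proportional
  reassignment is a modeling assumption; whether interdicted molecules
  instead misfold directly is experimentally open. Both assumptions are
  stated in the JSON report itself.

Both interdiction modes (peptide binds the partner segment; peptide masks
the matched segment) are always reported, since which dominates is
undetermined; polymeric-seed interdiction is represented only as the same
assignments carrying a seed flag — no aggregate structure is modeled.

## Synthetic data and what the tests show

The generator draws i.i.d. background sequences from a configurable residue
composition (uniform over the 20 standard residues by default) and
overwrites *planted* hydrophobic segments at chosen positions, so scan
behaviour can be verified against known ground truth: a planted pair of
strongly hydrophobic 5-mers on a polar background at an admissible
separation must always rank first. An independently coded brute-force
double loop (`oracle_scan`, sharing only the scale constants) re-scores
every admissible pair and must agree with the scan exactly.

Real sequences are not i.i.d. — they carry local composition bias and
repeats the generator does not emulate — so passing the synthetic checks
demonstrates correctness of the scoring and selection machinery, not
predictive accuracy on natural proteins. The end-to-end check on the
embedded 204-residue core-p53 domain (landmark segments asserted at load so
a transcription error fails loudly) provides the natural-sequence anchor.

Problem sizes used in the test and acceptance runs: grids on sequences of
120–300 residues (a few thousand window pairs each), 100 random sequences
for the oracle-equivalence sweep, 20 seeds for planted-pair recovery — all
chosen as the smallest sizes that exercise every separation regime of the
scan.

## Limitations

* No structural assessment: whether a predicted contact is native in the 3D
  fold requires a structure and is outside the package.
* No kinetics: channel populations are nucleation-weight fractions, not
  folding rates.
* No aggregation or amyloidogenicity prediction; the secondary-channel
  misfolding mechanism is a hypothesis the package parameterises (via ε)
  rather than validates.
* The window-size default (5) is taken as the model's standard operating
  point; the geometric derivation behind it is rounding-ambiguous and is not
  re-derived here.
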