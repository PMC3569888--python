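# Methods

## Registration model

A β-strand is taken to be a maximal run of residues assigned the extended
state `E`, split at chain breaks; isolated bridges (`B`) are never
strands, while single-residue `E` runs are (native sets contain strands
of length 1). Two strands form a pair when at least one residue of one
lists a residue of the other in the DSSP bridge-partner columns. The
bridged residues of a regular (bulge-free) ladder form one contiguous
block of equal size in each strand; that block length is the common
paired part `PL`, and the overhangs are the terminal extensions
`Et1 = SL1 − PL`, `Et2 = SL2 − PL`, with whole length
`EL = PL + Et1 + Et2`. These definitions entail identities that the test
suite asserts on every dataset: `EL = PL + Et1 + Et2`,
`Et1 − Et2 = SL1 − SL2`, `1 ≤ PL ≤ min(SL1, SL2)`, and
`R ≤ min(Rt1, Rt2)` for the ratios `R = 100·PL/EL`, `Rti = 100·PL/SLi`.

Pairs whose bridged residues are non-contiguous in either strand, or
whose two bridged-residue counts differ, are flagged **β-bulged**. Bulged
pairs are excluded from all summaries by default (configurable): a bulge
locally breaks the one-to-one residue pairing, so a single block length
no longer describes the register. When included, `PL` is the smaller of
the two bridged counts.

Orientation is read from the direction of partner progression along
strand 1 (increasing → parallel, decreasing → antiparallel). A one-rung
ladder carries no progression; there the case of the DSSP ladder label is
used (lowercase letters mark parallel bridges, uppercase antiparallel).
If neither source is available the pair is classified antiparallel — the
majority class in native sheets — with a warning. Non-monotonic
progressions mark the pair bulged and take the majority direction.

Strand 1 of a pair is the strand earlier along the chain (smaller
ordinal); interchain pairs are ordered by `(chain_id, ordinal)` and are
included in statistics by default, tagged `interchain`. Duplicate bridge
links between the same residue pair are collapsed: `PL` counts residues,
not hydrogen bonds.

## Chain filtering

Chains are dropped, with a logged reason, when they contain no `E`
residue (nothing to analyse) or contain the unknown-residue marker `X`
(DSSP's rendering of nonstandard residue names, which indicate covalent
ligands or modified residues). Lowercase amino-acid letters are DSSP's
encoding of disulfide-bonded cysteines; they are normalised to `C` with a
flag and do **not** trigger the nonstandard filter. Beyond these, only
structural validity of the residue table is enforced (strictly increasing
indices, resolvable bridge partners); no attempt is made to judge
"uncertain" structures, for which no operational test exists.

## DSSP dialect

Only the classic fixed-column format is supported (the dialect with BP1,
BP2 and sheet-label columns; residue-table sentinel
`#  RESIDUE AA STRUCTURE BP1 BP2`); mmCIF-flavoured DSSP output is out of
scope. The writer pads the columns the parser does not read, and
`parse ∘ emit` is the identity on all read fields (property-tested). The
BP columns are four characters wide, which caps one file at 9999
residues; the writer refuses overflow and the synthetic generator
transparently splits large datasets over several files.

## Synthetic generator

Each configuration fixes `(SL1, SL2, offset o, orientation)`, where `o`
shifts strand 2's pairing frame against strand 1's; antiparallel
configurations reverse strand 2's sequence before framing, so one overlap
formula `PL = min(SL1, o + SL2) − max(0, o)` covers both orientations.
Configurations render as two `E` runs wired through BP1 with correct
ladder-label case, separated by ≥ 4 coil residues so runs never merge.
Amino acids are drawn uniformly from the 20 standard letters — sequence
content plays no role in any implemented statistic.

Default sampling parameters emulate nonredundant native pair sets:

- **Lengths.** Discretised truncated normals on [1, 25] solved
  numerically so the realised mean/sd equal the targets
  (SL1: 4.99 ± 2.82, SL2: 4.90 ± 2.80). A Gaussian copula with
  correlation 0.85 couples the two lengths; that value reproduces the
  ~30% equal-length share seen in native pairs. The copula's elliptical
  shape thins the far tail of `|SL1 − SL2|` relative to native data — a
  known limitation.
- **Offsets.** A mixture centred on the two terminal-aligned registers
  (`o = 0` and `o = SL1 − SL2`) with two-sided geometric decay of rate
  0.09 away from them, giving ~83% double alignment for equal lengths,
  matching the native share.
- **Orientation.** 70% antiparallel, the field-typical majority; no
  statistic here depends on the mix.
- **Bulges.** Off by default. When enabled, a single interior rung of the
  ladder is deleted, which requires `PL ≥ 3`; one- and two-rung ladders
  cannot host an interior bulge and are left unperturbed.

What passing synthetic tests show — and do not show: they verify the
bookkeeping (parsing, pair wiring, the registration decomposition, the
aggregation) exactly against closed-form ground truth, and they show that
*under native-like length/register distributions* the rule-pass rate
lands where native data lands (~95% > 90%). They do not validate the
generative model itself against real sheets: real data have β-bulges,
bifurcated ladders, heavier length-difference tails, and
sequence-dependent register preferences the generator does not model.
Reproducing the native headline percentages exactly requires the actual
2009-era nonredundant chain set with DSSP output, which is not shipped.

## Numerical choices

- Percents are carried on the 0–100 scale throughout; display rounding is
  half-up to two decimals (`round2`), computation at full precision.
- Standard deviations use the sample (n−1) convention; at the dataset
  sizes involved the population convention is indistinguishable.
- Ratio histograms use right-closed bins `(0, w], …, (100−w, 100]` so
  pairs at exactly 100% (no extensions) are counted once, in the top bin.
- Cumulative curves use `CP(x) = 100 · P(value ≥ x)`; with right-closed
  bins, `CP` at a bin edge equals the complemented histogram cumsum plus
  the probability atom at the edge (tested explicitly).
- Rule thresholds are inclusive (`≥`), making the rule region closed;
  boundary behaviour is probed at ±1e−9 around every face.
- The length-distribution calibration solves a 2-parameter least-squares
  problem for the latent normal's mean/sd; infeasible targets (e.g. mean
  outside [1, 25]) raise before any sampling.
- Empty inputs: the cross-table returns all-zero counts; the variable
  summary raises (`no pairs`), since min/max are undefined.

## Problem sizes

The shipped checks use an exhaustive sweep of all ~3.5k configurations
with `SL1, SL2 ≤ 12` (every valid offset, both orientations), 1,000-pair
end-to-end recovery, 10,000-pair rule-rate summaries and a 100,000-draw
moment-calibration check; together the suite runs in ~10 s and the
acceptance script in ~6 s on one CPU.

## Known limitations

- mmCIF DSSP output and running DSSP itself are out of scope; the package
  consumes DSSP text.
- Bifurcated ladders (a residue bridging twice into the same neighbour)
  surface as bulged pairs rather than as a separate category.
- The interchain/bulge inclusion policies are configurable but the
  defaults (include interchain, exclude bulged) are conventions, not
  facts about any particular published census.
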