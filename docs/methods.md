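# Methods

Scope: what the library computes, the exact parameter values and units it
uses, how the synthetic generators work and where they are realistic, which
numerical choices were made and why, and what the implementation does not
claim to do.

## Data model and conventions

- ΔΔG is stored in kcal/mol with **positive = destabilizing**.  Source
  tables in other conventions are normalized on read through a
  `DialectConfig` (unit: kcal/mol or kJ/mol, 1 kcal = 4.184 kJ; sign:
  destabilizing-positive or stabilizing-positive).
- A mutation is identified by (PDB id, chain, mutation code), e.g.
  `1ABC`, `A`, `V31A`; positions in codes are 1-based.
- A `VariantPair` holds wild-type sequence, mutant sequence, the single
  differing 0-based position, and the target ΔΔG; construction enforces the
  exactly-one-substitution invariant.  `pair.reversed()` swaps the
  sequences and negates the target.

## Curation pipeline (five steps)

1. **Split by condition availability.**  Records with both pH and
   temperature go to Group I; the rest to Group II.
2. **Core selection.**  Per unique mutation id, the Group-I record closest
   to standard conditions (pH 7.0, 25 °C) wins, with distance
   `sqrt(((pH−7)/0.5)² + ((T−25)/10)²)` — each axis scaled by its window
   half-width so the two conditions are commensurate.  Ties break first on
   smaller |pH−7|, then on input order (first wins).  Both choices are
   arbitrary but deterministic and documented.
3. **Additional samples.**  Remaining Group-I records within the *closed*
   window (|ΔpH| ≤ 0.5 and |ΔT| ≤ 10 °C) **of the core record's own
   conditions** join the core; Group-II records join only when their
   mutation id has no Group-I measurement at all.
4. **Averaging.**  All selected records per id are averaged
   (arithmetic mean); the averaged record inherits the core's conditions.
5. **Consistency filter.**  Ids whose members contain both a strictly
   positive and a strictly negative value are dropped ("opposite signs";
   zeros are sign-neutral).  Otherwise, ids whose members have sample
   variance (ddof = 1) **computed in kJ/mol** exceeding 5 (kJ/mol)² are
   dropped ("variance").  The comparison is strictly greater-than, so a set
   whose variance equals the threshold exactly is kept; the unit suite
   pins this boundary.

Post-processing: a per-wild-type-sequence cap of 70 records (uniform
random without replacement, seeded); reverse augmentation (training splits
only — output is exactly 2n, originals first); a homology filter that
removes training records whose chain sequence has **both** identity > 30 %
**and** E-value < 0.05 against any test sequence (conjunction — a
high-identity short local hit with a poor E-value survives, which is the
conservative reading for removing only confident homologs).

## Embeddings and heads

A backbone maps a length-N sequence to an (N+2)×D matrix: row 0 is a
whole-sequence (CLS) representation, rows 1…N per-residue representations,
row N+1 an end-of-sequence token.  `mutation_row(emb, pos)` returns row
`pos+1` for 0-based sequence position `pos`.

`MockBackbone` makes each residue row a deterministic function of
(seed, residue identity, position context) via seeded generators, the CLS
row the mean of the residue rows, and applies an optional trainable linear
map (identity-initialized `proj`, zero `bias`).  It has the exact interface
a transformer protein language model would present; `EsmBackbone` is an
adapter stub that raises a clear ImportError when its optional dependencies
are absent (no GPU/torch stack ships in this environment).

Five head designs (the only admissible (source, merge) combinations):
position×{concatenation, outer product, linear}, CLS×linear, and
(CLS + position)×linear.  The linear merge is
`w_wt ⊙ e_wt + w_mt ⊙ e_mt` with weights initialized to all-ones.  Each
head is one hidden tanh layer (`hidden_width`, default 128) and a scalar
output.  The outer product is guarded by `outer_cap` (default 256) because
its feature width is D².

**Antisymmetric tying.**  With `w_mt = −w_wt` (single trainable vector) and
hidden/output biases frozen at zero, the network input is odd under
(wt ↔ mt), tanh is odd, and the output is a linear map of odd features —
so `predict(a,b) = −predict(b,a)` holds *exactly* (to rounding), not
approximately.  This requires the linear merge; requesting it with other
merges is an error.

**Ensemble.**  Five heads trained independently with seeds
`seed+1 … seed+5`; the prediction is their arithmetic mean.

## Training

Per-example (batch size 1) MSE with Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8), 3 epochs, and a piecewise-linear schedule: 0 at step 0, peak at
30 % of total steps, 0 at the final step.  The default peak learning rate
is 1e-5 (appropriate for fine-tuning a large backbone).  For the small
NumPy heads trained here on the mock backbone, the worked examples and the
recovery test use **1e-2** — with D ≤ 16 parameters per head, 1e-5 cannot
traverse the loss landscape in 3 epochs; this value was fixed before the
recovery experiment was run, not tuned to it.  Data order is reshuffled
each epoch from the run seed; training is bitwise reproducible.
Forward/backward passes are hand-derived NumPy (no deep-learning framework
is available in the target environment); gradients flow into the backbone's
`proj`/`bias` unless `freeze_backbone` is set.

## Evaluation

Pearson r (scipy), RMSE and MAE, reported separately on direct and
reversed variants (`evaluate_symmetric`).  Constant predictions yield
r = NaN with an explicit warning rather than an arbitrary number.
`AntisymmetrizedModel` wraps any model as `(m(a,b) − m(b,a))/2`, which
makes the two sides of the symmetric evaluation agree exactly — a useful
oracle and a cheap post-hoc symmetrization.  Cross-validation folds:
single-linkage clusters at identity > 30 % and E-value < 0.05, assigned
greedily heaviest-cluster-first to the currently lightest fold (seeded
shuffle breaks ties), so no two folds share a cluster.

## Structure stratification

Interchain contacts: any heavy-atom pair across chains within 4.5 Å
(k-d trees; an O(n²) scan is the test oracle).  A chain is "oligomeric"
when strictly more than 30 % of its residues are interface residues —
exactly 30 % is not.  Ligand contact uses the same cutoff against HETATM
groups (heme test subsets use codes HEM/HEC/BLA).  Burial and secondary
structure come from classic-format DSSP text: relative ASA = ACC divided
by the residue's maximum ASA (Tien et al. 2013 theoretical values),
clipped to [0, 1]; buried means rel. ASA < 0.25; the 8-state DSSP alphabet
collapses to helix {H,G,I}, strand {E,B}, coil otherwise.

## Synthetic generators: realism and limits

- **Mutation tables** are built from named scenarios (single core,
  multi-replicate averaging, out-of-window rejection, sign conflict, high
  variance, Group-II-only ids, Group-II duplicates) with configurable
  fractions, and emit a manifest stating every id's expected fate and
  expected mean — so the curation pipeline can be graded against the
  generator's *intent*, not against itself.  Realistic: heterogeneous
  conditions, replicate scatter, multi-source round-robin.  Not realistic:
  ΔΔG magnitudes are drawn from simple distributions with no
  thermodynamic structure, and sequences are uniform random.
- **Toy structures** place Cα-only chains on a 6 Å grid (no accidental
  contacts), then plant contact pairs at 4.4 Å, boundary pairs at
  4.4/4.6 Å around the 4.5 Å cutoff, and a HEM iron 3 Å from one residue.
  They exercise the geometry exactly but are not protein-like.
- **Recoverable datasets** draw random single mutations and set the target
  to a fixed linear function of (wt − mt) embedding rows, optionally plus
  noise.  This gives a closed-form OLS oracle and a known ceiling for the
  trainer; it says nothing about real ΔΔG learnability.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2³¹.
- The variance filter computes in kJ/mol space (matching the 5 (kJ/mol)²
  threshold) even though records are stored in kcal/mol.
- The learning-rate schedule is evaluated at `step+1` inside the loop so
  the very first update uses a nonzero rate and the final update uses the
  final-step value.
- Checkpoints are single `.npz` archives with a JSON metadata block;
  loading reproduces predictions bitwise.

## Limitations

- No real protein language model ships with the package; headline
  literature-scale accuracies require fine-tuning a large transformer on
  experimental datasets with GPU hardware and are out of scope here.
- The trainer supports batch size 1 only (matching the per-example
  protocol); there is no minibatching or parallelism.
- The naive identity backend does all-vs-all global alignment (quadratic);
  the BLAST backend requires external binaries.
- DSSP parsing covers the classic fixed-column format only, and structure
  reading takes the first model / highest-occupancy altloc of a PDB file.
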