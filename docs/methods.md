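# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `plifscreen`. It states no empirical result
that the test suite or the acceptance script does not itself compute.

## 1. Data curation and binarization

Bioactivity records are filtered the way high-quality ChEMBL curation is
usually done for binary classifiers: confidence strictly greater than 7,
binding ("B") assays, *Homo sapiens*, measure in {IC50, Ki, Kd}, and an
admissible relation. Censored records are interpreted through their
bound: ">" records are admissible only when the bound is at or above the
activity threshold and are always labeled inactive; "<" records are
admissible only when the bound is at or below the threshold and are
labeled by the bound. Every filter can be switched off individually;
each rejected record carries exactly one reason (the first failing
filter), which keeps reject reports unambiguous.

Binarization is *strictly below* 2 µM: a value of exactly 2 µM is
inactive. The threshold is a config parameter (`activity_threshold_um`).

Structures are standardized with RDKit's MolStandardize (largest organic
fragment → neutralize → canonical tautomer) and keyed by InChIKey.
Duplicates by key are merged keeping the minimum value — the most potent
measurement wins. This open-source standardization stands in for
commercial protonation/minimization tooling; the divergence is
intentional and confined to `standardize_smiles`.

Class balancing samples the inactive shortfall from a pool without
replacement under a seed, and refuses with an explicit shortfall message
when the pool is too small.

## 2. Feature blocks

Three blocks, column order frozen:

- **physchem** — the full RDKit 2D descriptor panel (210 descriptors,
  frozen by literal name list in `_descriptor_panel.py` so feature order
  cannot drift). Non-finite values are mapped to 0 so the assembled
  matrix has no missing entries.
- **morgan** — 1024-bit, radius-2 circular fingerprints.
- **residue_contacts** — the six key pocket residue bits of the robust
  PLIF (LEU70, VAL75, LEU78, LEU129, ASP156, LEU157).

## 3. Robust PLIFs

A residue bit is set iff the residue is contacted, by any interaction
type, in ≥ `min_poses` (4) of the `top_n` (5) highest-scoring poses.
Pose ranking is by descending score with ties broken by ascending pose
index; tables with fewer than `min_poses` poses are a hard error (the
fingerprint is undefined; no prorated threshold is attempted).

The fingerprint is residue-level binary: all interaction types collapse
into one bit. Typed contacts are preserved upstream in the pose-contact
tables for SAR inspection.

Tanimoto similarity is |A∩B|/|A∪B| over on-bits, optionally restricted
to a residue subset; an empty restricted union is defined as similarity
0.0 (no shared evidence). The percentile cutoff uses NumPy's linear
interpolation convention, and the pass rule is *strictly above* the
cutoff, matching the ">80th percentile" selection (equivalently >0.83
similarity on the original calibration data). In the pipeline the cutoff
is derived from the screening library's own similarity distribution at
the configured percentile unless an absolute `sim_cutoff` is given —
an absolute 0.83 is only meaningful for PLIFs produced by the same
docking backend as the reference.

The built-in geometric detector is deliberately minimal (apolar-carbon
pairs ≤ 4.0 Å → hydrophobic; donor–acceptor heavy atoms ≤ 3.5 Å with
donor angle ≥ 120° → hydrogen bond; thresholds configurable). It exists
so the package runs without any external backend; PLIP/ProLIF-style
contact tables are ingested through the CSV schema and are the expected
production route. Water bridges, metal coordination, π-stacking
geometry are out of scope for the built-in detector.

The packaged reference fingerprint is a **synthetic stand-in** for the
5HX6 co-crystal ligand PLIF (the real one requires licensed docking
runs); it ships as an editable CSV so a real reference can be dropped
in without code changes.

## 4. Signature mining

All residue subsets of sizes `min_size`–`max_size` over the key-residue
panel are enumerated (size, then lexicographic order; 57 subsets for 6
residues, sizes 2–6). A subset's score is the fraction of actives whose
fingerprint carries *all* subset bits, likewise for inactives; the ratio
uses an explicit +∞ sentinel when no inactive matches, ranking above all
finite ratios. Selection maximizes ratio among rules with coverage ≥
`min_coverage` (default 0.5, chosen so a 61%-coverage winner qualifies);
ties prefer higher coverage, then **larger** subsets, then
lexicographically smaller residue tuples. The larger-subset preference
matters: when several nested subsets match exactly the same compounds,
the most specific (largest) description of the signature is returned.

"Largest difference of contacts" is implemented as the frequency
*ratio*, not the absolute difference, because the headline statistic of
the underlying analysis is a fold change ("2.5× more frequent");
absolute-difference selection can be obtained by ranking the rules table
externally.

Ligand efficiency is score / heavy-atom count — the field's standard
size correction; the divisor is config-overridable. Enrichment curves
report precision for actives among compounds strictly above each score
percentile; an empty selection reports NaN, never 0. The ×100
"% enrichment" formatting happens only at the CLI.

## 5. QSAR ensemble

`EnsembleForestClassifier` follows the scikit-learn estimator contract.
Defaults: 100 members, 700 trees, bag fraction 0.9 **without**
replacement (a flag switches to with-replacement), vote threshold
strictly above 50% — an exact 50/50 tie is inactive. Within-forest
randomness is delegated to scikit-learn's RandomForest but pinned by
member seeds drawn from the top-level `random_state`, so identical seeds
give bit-identical vote fractions.

Hyperparameter search evaluates every (tree count, feature-block
combination) pair — 70 on the full default grid — by stratified k-fold
CV accuracy of a single forest (stratification keeps both classes in
every fold; folds are seeded and shared across configurations so the
comparison is paired). Ties prefer fewer trees, then fewer feature
columns.

Train/test splitting is plain seeded random sampling with
`floor(n · test_fraction)` test rows (624 rows at 0.3 → 437/187), and it
refuses splits that leave a class absent from training.

## 6. Applicability domains

**RDN (QSAR route).** The underlying metric is under-specified in its
original form, so the package documents its own interpretation: the
reliability of a query is the kernel-weighted mass of *correct*
out-of-fold training predictions in its neighborhood,

    r(q) = Σ_i correct_i · exp(−d(q,i)² / 2h²),  d = 1 − Tanimoto(morgan),

with bandwidth h = 0.25 (contributions decay sharply past ~0.5 Tanimoto
distance). The score is a sum, not an average: adding a nearby correct
training compound can never lower it, and a query with no kernel support
scores exactly 0. The numeric scale therefore differs from the original
0.03 cutoff; only the precision/coverage trade-off is comparable, which
is what `ad_curve` reports. Acceptance in the pipeline is scale-free:
the top `ad_coverage` fraction (default 0.3, matching the published
coverage compromise) of library predictions by reliability is accepted.
The AD interface is a plain estimator (`fit`/`score_samples`) so
alternative domains can be swapped in.

**MCS (docking route).** Over-extrapolation of the contact rules is
controlled by the size (heavy atoms) of the largest maximum common
substructure between a query and a reference inhibitor set. Matching is
connected, bond-order-sensitive, ring-atoms-match-ring-atoms, with a
per-pair timeout (default 5 s) after which the result is flagged as a
lower bound. No absolute size threshold is imposed; candidates are
*ranked* by MCS anchor size, because the original selection was rank-
based ("top 50 by largest MCS").

**Consensus.** Tier 1 = docking candidates ∩ accepted QSAR actives, in
input order; backfill = docking-only candidates by descending MCS
anchor, ties by larger PLIF similarity, then input order. The original
backfill was driven by vendor availability, which is not modelable; the
deterministic MCS ranking is this package's reproducible substitute.

## 7. The synthetic world

The generator emulates the *statistical* structure the funnel consumes,
not docking physics:

- **Structures** come from a fragment-decoration grammar (6 asymmetric
  heteroaromatic cores × 12 × 12 substituents × 8 tails = 6,912
  combinations), all parseable, mutually distinct by InChIKey, and
  stable under standardization — so deduplication bookkeeping is exact.
- **Contacts.** Each compound is a signature *carrier* with class
  probability `p_contact_active` = 0.61 (actives) or
  `p_contact_inactive` = 0.25 (inactives) — the observed active/inactive
  contrast, ratio 2.44. Carriers have all planted-signature residues on;
  non-carriers have them off. Non-signature residues are independent
  Bernoulli(`background_p` = 0.15). Because every subset of the planted
  signature then matches exactly the carrier set, subset ratios tie
  exactly and the larger-subset tie-break recovers the full planted
  signature — the property the recovery tests rely on.
- **Poses.** Per-pose contacts are the profile with independent flip
  noise (default 0 — the noiseless stated world; robustness tests raise
  it explicitly, and `analytic_pass_probability` gives the closed-form
  binomial pass probability under noise). Pose scores are Gaussian per
  class (60 ± 5 actives, 55 ± 5 inactives: overlapping distributions,
  reflecting that scores separate classes poorly). 10 poses by default
  (the real runs used 50; 10 keeps tests fast without changing the
  top-5 aggregation logic).
- **Library.** Exactly `round(library_size · hit_fraction)` compounds
  (default 50 of 1000) carry the signature profile at seeded random
  positions; the hidden truth table is emitted separately and used only
  for evaluation.
- **AD scenario.** Two dense learnable clusters (actives around one
  binary prototype, inactives around another, 5% bit flips) plus a
  sparse third region carrying *random* labels — so cross-validated
  correctness is poor exactly where density is low, which is the regime
  an applicability domain is for.
- **Assembly fixture.** Four source tables with the published subset
  sizes (248 curated + 72 + 118 labeled records; a 277-compound inactive
  pool) arranged to binarize to 312/126 and balance to 624.

What a green test on this world does **not** establish: anything about
real docking geometry, real chemistry–activity relationships, or the
transferability of the 0.83 similarity cutoff across docking backends.
The synthetic world validates the *machinery* — aggregation rules,
selection logic, error control, bookkeeping — against known truth.

## 8. Numerical conventions and degenerate inputs

- Exact 2 µM → inactive; exact 0.83 similarity → fails; exact 50% vote →
  inactive; QED exactly at the threshold → dropped. All boundaries are
  strict, matching the source conventions ("below", ">", ">50%").
- Undefined quantities (precision with no predicted actives, enrichment
  of an empty selection) are reported as None/NaN, never 0.
- Percentiles use linear interpolation throughout (NumPy default), and
  the same convention is used by the independent oracles in the tests.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; generators are pure functions of
  (config, seed).

## 9. Known limitations

- The built-in contact detector is a teaching-grade stand-in; production
  use should ingest PLIP/ProLIF contact tables.
- The RDN reliability scale is implementation-defined; cutoffs are not
  portable across feature spaces or bandwidths (use quantile-based
  acceptance, as the pipeline does).
- MCS with timeouts is a lower bound on large inputs; flagged rows
  should be re-run with a larger budget if ranking near the cut matters.
- The QSAR model on the synthetic world learns mostly from the residue
  block (the only label-linked block there); its test accuracy is not a
  statement about real-data performance.
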