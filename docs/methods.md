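# Methods

## The prediction model

The core assumption is the similarity principle as it manifests in curated
bioactivity data: compounds active against one protein target cluster into
congeneric series, so a new molecule's nearest structural neighbours are
informative about its targets.  The engine never models the protein; a
target is represented purely by its ensemble of annotated ligands.

For a query *q* and ensemble *T*, each registered fingerprint type *i*
contributes its maximum query-to-ensemble Tanimoto, Tc_i^max.  Using the
maximum (rather than, say, the mean) makes the score a multi-view
nearest-neighbour statistic: one sufficiently similar ensemble member is
enough for that view.  A single fingerprint's high similarity can be a
hashing artefact; requiring at least `n_min_fp` types to clear their own
calibrated significance thresholds is the consensus that gives the method
its robustness.  The score

SC = (1/N_fp) · Σ over qualifying *i* of Tc_i^max,  N_fp = panel size,

is bounded by [0, 1]; since the normalizer is a constant, any other choice
of constant produces the identical ranking (a unit test proves this), so
the normalization is purely cosmetic and SC = 1 has the convenient reading
"every fingerprint found an identical compound".  Ties are broken by the
number of qualifying fingerprints, then lexicographic target id, making
rankings fully deterministic.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `m_percent` | 95 | percentile of random-pair Tc defining significance; raising it trades recall for precision |
| `n_min_fp` | 4 | minimum qualifying fingerprint types for a target to be reported |
| `min_ensemble_size` | 10 | smallest ligand ensemble considered a searchable target |
| `n_pairs` | 10⁵ | calibration sample size (dimensionless counts; desk-scale default, recorded with its seed in the threshold table) |
| `ph` | 7.4 | pH for dominant-microspecies assignment |

`m_percent` and `n_min_fp` are deliberately configuration, not constants:
they are the two dials a user should log with every run, and every result
object records them.  Thresholds are only valid for the panel and molecular
representation they were calibrated on; the threshold table carries the
registry digest and the search refuses a mismatch.

## Percentile convention

The threshold is the smallest observed Tc value t with
fraction(Tc ≤ t) ≥ m/100 — the empirical lower-value percentile with no
interpolation.  This makes the post-hoc guarantee exact: the fraction of
calibration pairs strictly above t is at most (100−m)% plus the tie mass at
t, which is asserted against a sort-based oracle in the tests.  Pairs are
drawn uniformly with replacement over unordered distinct pairs.

## Structure standardization and protonation

Standardization uses RDKit's MolStandardize: sanitize (with a cleanup
retry on valence errors), metal disconnection, normalization rules, largest
fragment by heavy-atom count (ties broken lexicographically on canonical
SMILES), neutralization, and stereochemistry recalculation.  The pipeline
is idempotent.  Stereoisomer groups that collapse to one stereo-stripped
canonical SMILES are reduced to a single representative drawn with a seeded
RNG, because an unseeded random pick would make library builds
irreproducible.

The dominant microspecies at pH 7.4 is assigned by a bundled SMARTS→pKa
table (`data/pka_rules.yaml`): acids with pKa < pH are deprotonated, bases
with conjugate-acid pKa > pH protonated, acid and base rules act
independently (zwitterions fall out naturally), and each atom is modified
at most once with earlier (stronger) rules shadowing later ones.  The table
covers the ionizable groups that dominate drug-like chemistry —
sulfonic/phosphonic/carboxylic acids, tetrazoles, imides, sulfonamides,
phenols, thiols, guanidines, amidines, aliphatic amines — plus groups
listed only to document why they stay neutral at 7.4 (pyridines, anilines,
imidazoles).  This is a deterministic rule engine, not a pKa predictor: it
ignores electronic effects of substituents and treats multi-site ionization
as independent events (e.g. piperazine is doubly protonated although its
second real pKa is ~5.6).  For threshold calibration and consensus ranking
these approximations are benign — both query and database pass through the
same rules — but individual microspecies should not be quoted as chemistry.

## The fingerprint panel

The default registry holds 13 types.  Circular (radius-1 Morgan with
connectivity and with feature invariants), atom-pair, topological-torsion,
SMARTS-pattern and branched/linear hashed-path fingerprints come from
RDKit; the linear-fragment FP2 comes from Open Babel.  MACCS uses RDKit's
166-key implementation (the vector's unused bit 0 is shifted away).  Three
key-based types — `pubchem`, `klekota_roth`, `substructure` — load
package-authored, *reduced* SMARTS key sets (files suffixed `_synthetic`)
that emulate the flavour of the element/ring-count, bioactivity-substructure
and functional-group families at ~60–110 keys each; they are not the
original 881/4860/307-key definitions.  `graph` and `hybridization` are
hand-rolled hashed linear-path fingerprints (paths of 1–7 atoms, CRC32 into
1024 bits) whose atom invariant is the element only, respectively the
hybridization state, with bond orders and formal charges masked — `graph`
is therefore charge-blind by construction, which the pH-sensitivity tests
exploit as a negative control.  Which types are pH-sensitive is a measured
property of this panel (7 of 13 on the synthetic library), not an assumption
carried over from any other implementation.

Because thresholds are calibrated per registered panel and the registry
digest accompanies every artefact, swapping any provider merely changes the
calibration, never the algorithm.

Two empty fingerprints have Tanimoto 0, not 1: absence of features is never
evidence of similarity.  Bulk similarity uses uint64-packed bit matrices
and `numpy.bitwise_count`; a set-based scalar implementation is kept as the
reference and the two are cross-checked in the tests.

## Synthetic data: what it does and does not show

The generator emulates the one structural property the method relies on:
per-target congeneric series.  Each synthetic target is one of ~20 bundled
drug-like scaffolds decorated at a marked attachment point with substituents
from a shared 40-fragment alphabet; activity values are lognormal in nM
(median ≈ 90 nM, σ_log ≈ 1.5), positive and right-skewed like real Ki/IC50
data.  Planted rule violations are clones of clean records mutated in
exactly one field, so filter reports can be checked against ground truth.

Study-scale defaults are 20 targets × 30 analogs with a 20% hold-out and
10⁵ calibration pairs — large enough for stable percentiles and accuracy
estimates, small enough for a laptop.  Passing tests on this data shows the
machinery is correct and that clustered chemistry is recovered almost
perfectly (hold-out p1 ≈ 96–98%).  It does not show real-world accuracy:
real libraries have overlapping chemotypes, promiscuous ligands, activity
cliffs and heterogeneous series sizes, none of which the generator models.
On real data the reported accuracy is bounded by how many of a query's true
targets survive curation at all.

## Numerical and degenerate-input choices

- Fragment-strip ties (equal heavy atoms): lexicographically smallest
  canonical SMILES.
- Dedup ties (equal activity values): first record in input order.
- Threshold comparison is ≥ everywhere, including the quadrant boundary.
- Queries with an empty ranked list count as misses in p1/p5.
- Unparseable molecules are recorded per record/row (never silently
  dropped); an unfingerprintable query raises with the failing type named.
- Zero surviving targets yields an empty database with a provenance
  warning, not an error.
- All RNG consumers (series generation, pair sampling, hold-out split,
  enantiomer pick, single-annotation draw) take explicit seeds and are
  bit-reproducible.

## Known limitations

- The pKa rule table matches no specific microspecies predictor
  molecule-for-molecule; borderline groups (imidazole at 7.0, phosphonate
  second ionization) sit close to 7.4 and are resolved by fiat.
- Reduced key sets give the three emulated key-based types different
  discrimination (and different pH-sensitivity) than their full-size
  namesakes; thresholds absorb the difference but per-type numbers are not
  comparable across implementations.
- The embedded JSON store is built for desk-scale libraries (10²–10⁴
  molecules); a production deployment over millions of records would need a
  real database backend, which is out of scope here.
- No applicability-domain or activity-cliff detection: a confident SC on a
  query far from all ensembles, or near a cliff, is still just a
  similarity statement.
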