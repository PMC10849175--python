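# Methods

## The SGED table model

An SGED file is an ordinary CSV/TSV table whose first column stores one
*group* of site coordinates per row, written inside square brackets with
semicolons as the only separator: `[14]`, `[A:ARG14;A:ARG21]`.  Three
coordinate referentials are distinguished syntactically:

| form        | referential                          | example    |
|-------------|--------------------------------------|------------|
| `14`        | 1-based alignment/sequence position  | `[14]`     |
| `A:ARG14`   | chain : residue-name residue-number (+ optional insertion code) | `[A:GLY35A]` |
| `geneB:12`  | labelled position (concatenated alignments) | `[geneB:12]` |

Positions are 1-based throughout (the codeml site table that feeds the
worked example numbers its reference sequence from 1).  Chain identifiers
may be longer than one character (mmCIF).  Residue names are restricted to
1–3 letters, which keeps the structure-residue grammar disjoint from the
`label:digits` form.

Design choices that matter for interoperability:

* attribute values are stored and re-emitted as the **exact strings** read
  from the file — a probability `0.71` never becomes `0.710`; consumers
  parse numbers lazily;
* missing data is the literal token `NA`; an empty group `[]` is a hard
  error, not an empty record;
* group strings are never quoted: brackets make them unambiguous even in
  CSV because commas cannot appear inside them;
* comment lines (`#`) are retained as table metadata and re-emitted first;
  the default output dialect is TSV, reading auto-detects (tab beats
  comma in the header line);
* `group` keeps only the `Group` column (combining rows into one group is
  a coordinate operation; carrying row-wise attributes over to a single
  row would be ill-defined), `ungroup` copies attributes to every derived
  row.

`merge` joins two tables on element-wise group equality; duplicate keys
are an error unless a many-to-many join is requested explicitly, and
column-name collisions are suffixed `_2` deterministically.

## Coordinate indices

A coordinate index is an injective partial map from source to target
coordinates, serialized as a two-column TSV with `# name: value` metadata
lines, `NA` marking unmapped sources.  Builders:

* **alignment index** — column → ungapped position of a chosen reference
  sequence; reference gaps map to `NA`.  Mapped targets are exactly
  `1..n` in increasing column order.
* **concatenation index** — super-alignment column → `name:local` labelled
  position, offsets being cumulative lengths.
* **structure index** — every alignment sequence is globally aligned
  against the resolved-residue sequence of every polymer chain of every
  candidate structure; the best pair defines the mapping
  column → sequence position → chain residue.

Pairwise alignment is Biopython's `PairwiseAligner` in global mode with a
BLOSUM62 substitution table, affine gaps (`gap_extend = gap_open / 2`
unless given) and **end gaps penalised**; characters outside the matrix
alphabet are scored as `X`.  Among co-optimal alignments the aligner's
first traceback is used, which is deterministic.  "Best match" ranks by
raw score with coverage (number of aligned residue pairs) as tie-break,
then input order; coverage as the secondary criterion favours mappings
that lose the least data.  With `exclude_incomplete`, chains whose
observed residue numbering has internal gaps are removed from candidacy —
the simplest observable notion of an incomplete model.

Chain sequences are derived from the residues actually present in the
coordinate file (unknown residues become `X`), not from the declared
full-length sequence, because the mapping must target residues that exist
in 3D.

## Structure model and statistics

Structures are read with gemmi (PDB and mmCIF).  Only the first model of
multi-model files is kept; hydrogens and waters are dropped; alternate
locations resolve to the highest-occupancy conformer (ties: first
encountered).  Residues whose chemical component is not an amino acid are
flagged hetero and excluded from residue lists and sampling pools by
default.

* **Cα distances** — mean/min/max Euclidean distance over all unordered
  residue pairs of a group (Å).  Undefined for singletons (an error); a
  group member without a Cα atom is an error naming the residue.
* **Cluster count** — single-linkage hierarchical clustering
  (`scipy.cluster.hierarchy`) of the pairwise distance matrix, cut at a
  distance threshold; equivalently the number of connected components of
  the graph joining pairs at distance ≤ threshold.  Cα–Cα distances by
  default (consistent with the distance statistic); a flag switches to
  minimal inter-atomic distance.  Singletons count as one cluster.
* **Relative solvent accessibility** — two backends.  The *external*
  backend wraps the DSSP program (via Bio.PDB) and also returns the DSSP
  secondary-structure class.  The *internal* backend is biotite's
  Shrake–Rupley rolling-probe surface computation, probe radius 1.4 Å,
  ProtOr united-atom radii (element radii as fallback for atoms outside
  that set), with no secondary structure.  RSA is the accessible area
  divided by the residue's theoretical maximum area from Tien et al. 2013
  (PLoS ONE 8:e80635), capped at 1.0; group summaries report percent.
  The two backends differ in absolute normalisation (DSSP uses its own
  algorithm and reference areas) but rank residues concordantly; analyses
  that compare a group against a null sampled under the *same* backend are
  insensitive to the choice.  The backend used is recorded in an output
  comment.
* **Residue depth** — optional wrapper around the MSMS program; a missing
  executable raises a documented feature-unavailable error rather than
  crashing.

## Randomization tests

Given a table of test groups and a pool of candidate sites, each replicate
redraws a group of the same size uniformly without replacement within the
group; sites may recur across replicates and across test groups.  The
empirical upper-tail p-value is `(#{S_sim ≥ S_obs} + 1) / (N + 1)` — ties
count as extreme, the add-one correction treats the observed group as one
more replicate, so `1/(N+1) ≤ p ≤ 1` and the null distribution of p is
uniform on that grid (verified by a Kolmogorov–Smirnov check in the test
suite).  The lower tail mirrors with ≤.

**Conditional sampling** matches each replicate member to one specific
test site: a candidate is eligible for test value *v* when its covariate
lies in `[v − t, v + t]` (threshold *t*; *t* = 0 degenerates to exact
matching, which covers categorical covariates).  Matching site-wise rather
than on the group mean makes the "no eligible candidate" error
well-defined per site.  Test sites themselves stay in the pool unless
`exclude_test_sites` removes them.

For a skewed covariate the mean of the eligible window differs from *v*,
biasing the replicate-mean covariate.  The **bias correction** implemented
here is iterative window recentering: the window is shifted by the signed
discrepancy between its candidate mean and *v*, at most 10 times or until
the discrepancy falls below *t*/100, and the draw is then uniform over the
final window.  This recentering scheme is this package's own construction
(the literature describes bias corrections for conditional resampling
without a reproducible algorithm); its effect — replicate means centred on
the observed group mean within Monte-Carlo error on an exponential pool —
is validated by simulation in the test suite.

Randomness comes from a single `numpy.random.default_rng` seeded by the
spec (fixed default, always overridable); replicate tables embed the seed
and replicate count as comments, and identical specs reproduce
byte-identical output.

## Synthetic fixtures

The fixture generators produce deterministic, analytically known inputs:

* *extended line* — Cα atoms every 3.8 Å on a line, so distances are
  `|i − j| × 3.8` and cluster counts at thresholds 3.0/4.0 Å are n/1;
* *helix* — ideal α-helix Cα geometry (2.3 Å radius, 1.5 Å rise, 100°
  twist);
* *random globule* — a self-avoiding 3.8 Å random walk confined to a
  sphere of radius ≈ 0.95·3.8·n^⅓, decorated with N/C/O/Cβ atoms, giving
  compact folds with a realistic buried-to-exposed RSA gradient;
* *shell-buried* — one residue enclosed by a Fibonacci-sphere shell
  (RSA ≈ 0 at the centre);
* gapped alignments with planted column→position maps, and codeml-style
  site-model output whose site tables are fully specified by the caller.

These fixtures emulate the *geometry and bookkeeping* of real data — they
are not energetically plausible proteins, carry no real secondary
structure, and their RSA distribution is narrower than in crystal
structures.  Tests passing on them demonstrate correctness of the
algorithms (parsing, mapping, distances, sampling, p-values), not
biological conclusions about any particular protein.

## Acceptance run

`scripts/acceptance.py` executes the complete pipeline on a synthetic
130-residue globule whose sequence carries the worked example's seven
candidate residues at their published positions, with 10,000 replicates
per randomization run (the published analysis size; a few seconds on one
CPU).  All reported numbers are computed at run time from the seed given
on the command line.  Reproducing the published lysozyme statistics
themselves (22.06 Å, 51.27 %, p = 0.0304/0.0444/0.2674) additionally
requires downloading PDB entry 134L and, for the RSA value, the external
DSSP backend; the corresponding acceptance tests state this explicitly
when those resources are absent.

## Known limitations

* No codon-aware mapping, profile alignment, or structure–structure
  alignment; one reference sequence per index.
* Secondary structure is never computed internally (DSSP only).
* Conditional sampling handles a single continuous (or, at threshold 0,
  categorical) covariate; multivariate conditioning is out of scope.
* SGED tables are held in memory; files too large for that are out of
  scope.
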