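# Methods

## Identity as string equality

The system never asks a database to understand chemistry. Identity is
decided entirely at registration time by serializing a molecule into
seven text layers and hashing them; the store only ever compares
strings on indexed columns. This is what makes duplicate checks and
layer-subset queries uniformly fast and portable across SQL backends,
and it is also the core design commitment: anything the hash does not
encode (conformation below the rounding resolution, atom numbering,
input serialization) cannot distinguish two molecules, and anything it
does encode (tautomeric state, stereochemistry, SGroup data, the escape
text) always does.

### Layer construction

A working copy of the input is normalized before serialization:
hydrogens that carry no information are removed (stereogenic ones and
isotopes are kept), atom-map numbers are cleared, and enhanced stereo
groups are canonicalized. From that copy:

- `FORMULA` — Hill-order molecular formula (net charge appears as a
  suffix, e.g. `CH6N+`).
- `CANONICAL_SMILES` — canonical CXSMILES carrying atom labels,
  enhanced stereo groups and atropisomer bonds, but never coordinates:
  2D identity must not depend on depiction.
- `TAUTOMER_HASH` / `NO_STEREO_TAUTOMER_HASH` — the heteroatom-tautomer
  hash delegated to RDKit's MolHash (v1 or v2, recorded in the database
  configuration so every database is self-describing about which
  variant produced its contents). The version in use here is sensitive
  to atom/bond enumeration order for a small class of amide-like
  systems, so the hash is computed on a molecule rebuilt from its
  canonical serialization; this restores the guarantee that equivalent
  input serializations produce byte-identical layers.
- `NO_STEREO_SMILES` — canonical SMILES after removing every stereo
  annotation (atom parities, double-bond configuration, stereo groups).
- `SGROUP_DATA` — DAT-SGroup field/value records as a JSON object:
  field names map to sorted lists of record values, keys sorted, no
  whitespace, `{}` when absent. Grouping by field with sorted values
  makes the layer independent of the order SGroups appear in a mol
  block. Which fields participate is configurable; by default all DAT
  fields do. Polymer-type SGroups are a *filter* concern, not a hash
  concern.
- `ESCAPE` — caller text, stored verbatim. It lets a workflow force
  distinctions the structure does not carry (batch, supplier,
  protonation context) without touching the chemistry.

The combined digest is SHA1 over the UTF-8 encoding of
`NAME:value` items joined by single newlines in the fixed layer order
(`FORMULA`, `CANONICAL_SMILES`, `TAUTOMER_HASH`, `NO_STEREO_SMILES`,
`NO_STEREO_TAUTOMER_HASH`, `SGROUP_DATA`, `ESCAPE`). The serialization
is documented precisely so digests are reproducible, but they are not
interchangeable with other layered-hash implementations that combine
layers differently. SHA1's cryptographic weaknesses are irrelevant
here: the digest is a uniqueness key over trusted inputs, not a
security boundary, and layer columns are stored individually anyway.

## Conformer hashing

A conformer hash is built in four steps: round every Cartesian
coordinate to `digits` decimals (default 3, i.e. 0.001 Å — finer than
any meaningful geometric difference between stored poses, coarse
enough to absorb format round-trips), render each atom as fixed-point
`"x,y,z"`, sort the atom strings lexicographically, and SHA256 the
semicolon-joined result. Sorting removes atom-order dependence; nothing
removes pose dependence, by design.

Numeric formatting choices that make the strings byte-stable:
fixed-point only (no exponent notation, no leading `+`), round-half-even
as applied to the decimal expansion of the IEEE double, and negative
zero normalized to positive zero (otherwise `-0.000` and `0.000` would
hash differently for coordinates that are equal after rounding).
Hydrogens are not special-cased: every atom present in the input
participates, and callers wanting heavy-atom-only identity strip
hydrogens first.

`canonicalize_orientation` provides opt-in rigid-motion invariance:
translate the centroid to the origin, rotate onto the principal axes of
the coordinate covariance ordered by descending eigenvalue, sign each
of the first two axes so its largest-magnitude projection is positive,
and take the third axis as the cross product (right-handed frame). For
asymmetric conformers any rigid transform then maps to the same
canonical pose to ~1e-12 Å, far below the rounding resolution. The
convention is one of many valid ones; determinism is the only
requirement. Degenerate inputs (single atom, coincident atoms) are
translated only; near-degenerate inertia tensors (eigenvalue ties) are
handled deterministically but canonical-pose recovery is not guaranteed
for them, which is acceptable because identity falls back to the pose
as submitted.

A hash can still flip when a coordinate sits within numerical noise of
a rounding boundary. The test generators therefore either snap
coordinates onto the rounding grid (maximal distance from every
boundary) for perturbation-stability checks, or reject conformers whose
canonicalized coordinates fall within 0.1 grid units of a boundary for
transform-recovery checks — a margin ten orders of magnitude above the
noise of an orthonormal rotation.

## Standardization pipeline

Steps are named, ordered, and of two kinds: standardizers may return a
modified molecule; filters return their input unchanged or reject it.
The pipeline stops at the first rejection, and the database stores both
the configured pipeline and, per molecule, the list of steps actually
applied plus the rejecting step — so any registered entry can be
audited years later.

Built-in decisions worth recording:

- *Largest fragment*: heavy-atom count, then total atom count, then
  lexicographically smallest canonical SMILES. A fully deterministic
  tie-break matters more than which tie-break is chosen.
- *Neutralization* delegates to RDKit's Uncharger with canonical atom
  ordering; simple protonation changes only, zwitterions whose charges
  cannot be independently removed stay intact.
- *Charge parent* = neutralized largest organic fragment, "organic"
  meaning "contains carbon", falling back to the plain largest fragment
  for inorganic inputs.
- *Overlapping atoms*: default threshold 1e-4 Å — effectively "same
  point"; the comparison is strict so atoms exactly at the threshold
  pass. Molecules without coordinates pass vacuously.
- *Polymer filter* rejects SGroup types SRU, MON, COP, CRO, GRA, MOD,
  MER, ANY.
- The default pipeline for a new database is `["sanitize"]`: the least
  opinionated configuration that still guarantees hashable molecules.
  Heavier policies (charge-parent registration for assay datasets) are
  one config entry away.

User steps register under fresh names and become addressable from the
JSON pipeline configuration exactly like built-ins.

## Storage

SQLite, append-only, schema shipped as versioned DDL text. Each layer
occupies its own indexed column (layer-subset queries are index
lookups), alongside the unique combined digest. The original submission
is stored byte-identically, the standardized structure as a v3000 mol
block, and conformer coordinates at full input precision — only the
hash is rounded, so retrieval returns exactly what was measured.
molregnos are a monotone sequence from 1; conf_ids count per molecule
from 1. Conformer uniqueness is enforced per (molregno, conf_hash)
because distinct molecules could in principle share coordinates;
hash-based conformer search remains global. A small backend registry
keeps the SQL in the portable core dialect so a client/server backend
can implement the same contract; the embedded backend is the default
and the one the test suite exercises.

## Experiment tables

Metadata (how to reproduce an experiment) and data (its results) live
in separate per-type tables named `<type>_metadata` / `<type>_data`,
linked by random (v4) UUID keys; data rows reference molregno and
optionally conf_id. Column kinds are `number`, `text` and `json` — the
JSON-only shape fits almost any experiment, the fully-columned shape
trades flexibility for compactness and fast filtering, and both are
the same machinery, which is what the schema-duality test pins down.
`conf_id` is nullable everywhere so 2D and conformer-linked experiments
share one shape. Result batches are validated completely before
anything is written. Callers may supply their own UUIDs for
reproducible pipelines.

## Synthetic test data

The generators produce: curated tautomer, stereoisomer and salt pairs
(the identity cases the layers must separate or unite); random acyclic
C/N/O/S molecules with occasional carbonyls (valence-capped random
trees, sanitized, deduplicated — structurally varied and cheap at any
count); equivalent alternative SMILES via random atom renumbering; and
random point-cloud conformers in an 8 Å box. Everything is a pure
function of explicit seeds.

What this corpus does not emulate: ring-rich or macrocyclic chemistry,
organometallics, charged polymer SGroups, chemically realistic 3D
geometries (random points exercise the hash contract, which depends on
coordinates alone — a handful of distance-geometry-embedded structures
cover the end-to-end 3D path), or adversarial near-boundary coordinates
beyond the margins described above. Passing tests demonstrate the
identity semantics and storage contracts, not robustness across the
breadth of real compound collections.

## Problem sizes

The verification script and tests use 500 molecules (each submitted
twice) for duplicate detection, 100 random conformers for the hash
invariances, 25 boundary-safe conformers for orientation recovery,
20 fixed cases for digest cross-checks, and 10–30 molecules elsewhere —
sizes at which every property is exercised many times over while the
whole suite stays interactive.

## Known limitations

- Identity is exactly as fine as the layers: two depictions differing
  only in properties no layer encodes (e.g. isotopically identical
  atom maps, 2D coordinates) are duplicates, always.
- The tautomer layers inherit the strengths and blind spots of the
  delegated heteroatom-tautomer hash; its internals are an external
  contract, selected by version tag, not reimplemented here.
- No substructure or similarity search: string equality is the only
  query primitive. Chemically aware search belongs to database
  cartridges outside this package's scope.
- No update or delete: the registry is append-only by design.
- The PostgreSQL-dialect backend is a seam, not a shipped
  implementation; only the embedded SQLite backend is provided.
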