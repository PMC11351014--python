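# molregistry

A lightweight chemical registration system for computational
workflows: stable integer identifiers (*molregnos*) for 2D molecular
structures, per-molecule conformer identifiers for 3D poses, and
companion tables that keep experimental results queryable together
with the structures that produced them.

Most registration systems are GUI applications built for bench
chemists registering one compound at a time, and most bake in a single,
fixed notion of "these two compounds are the same". Neither fits a
computational group that processes thousands of virtual molecules and
needs to distinguish — or deliberately *not* distinguish — tautomers,
stereoisomers, salt forms and docking poses depending on the project.
molregistry is a Python library plus a small CLI, backed by an embedded
SQLite database, with a configurable definition of chemical identity.

## The identity model

Duplicate detection never searches chemistry; it compares strings. Each
molecule is reduced to seven text **layers**:

| layer | content |
|---|---|
| `FORMULA` | molecular formula (Hill order) |
| `CANONICAL_SMILES` | canonical CXSMILES incl. enhanced stereo |
| `TAUTOMER_HASH` | tautomer-invariant serialization (HetAtom tautomer hash v1/v2), stereo-aware |
| `NO_STEREO_SMILES` | canonical CXSMILES, all stereo removed |
| `NO_STEREO_TAUTOMER_HASH` | tautomer-invariant serialization, stereo removed |
| `SGROUP_DATA` | canonical JSON of selected DAT-SGroup fields (`{}` if none) |
| `ESCAPE` | free-text discriminator supplied by the caller |

The seven layers are combined into a single SHA1 digest (UTF-8 of the
`NAME:value` lines joined by newlines, in the fixed order above), so a
registration check is one indexed string comparison. Queries may select
any layer subset: matching on `{TAUTOMER_HASH}` finds registered
tautomers of the query, `{NO_STEREO_SMILES}` finds stereoisomers, and
the full set means "exact duplicate". Digests from this serialization
are stable but deliberately not interchangeable with other layered-hash
implementations.

3D conformers get their own identity: round each coordinate to a fixed
number of decimals (default 3), write each atom as `"x,y,z"`, sort the
strings lexicographically, join with semicolons, and take the SHA256.
This is invariant to atom order but *not* to translation or rotation —
intentionally, so pre-aligned poses (docking results, crystal
structures) stay distinct. An optional `canonicalize_orientation`
standardization step provides orientation-free identity when wanted.

Before hashing, every submission runs through an ordered, configurable
standardization pipeline (sanitization, fragment removal,
neutralization, charge-parent reduction, overlap and polymer filters,
plus user-registered steps); the pipeline and the steps applied to each
molecule are stored in the database itself.

## Worked example

```python
from molregistry import Registry, TAUTOMER_HASH

reg = Registry.init("demo.db")
reg.register("CCO").molregno          # -> 1
r = reg.register("OCC")               # same molecule, different SMILES
(r.status, r.molregno)                # -> ('duplicate', 1)

reg.register("O=c1cccc[nH]1").molregno  # 2-pyridone      -> 2
reg.register("Oc1ccccn1").molregno      # its tautomer    -> 3

reg.query("O=c1cccc[nH]1")                          # -> [2]
reg.query("O=c1cccc[nH]1", layers={TAUTOMER_HASH})  # -> [2, 3]

reg.retrieve([2], mode="hashes")[2]
# FORMULA           C5H5NO
# CANONICAL_SMILES  O=c1cccc[nH]1
# TAUTOMER_HASH     [O]:[C]1:[C]:[C]:[C]:[C]:[N]:1_5_0
# FULL_HASH         626e8a4b8fc57284db5e345cb184dfe5ca7971b5
```

Ethanol registered twice under two spellings occupies one row; the
tautomer pair occupies two rows (they are different compounds at full
precision) but is united when the query relaxes identity to the
tautomer layer. The same flows are available from the shell:

```bash
molregistry init --dbfile demo.db
molregistry register --dbfile demo.db --smiles CCO     # prints 1
molregistry query --dbfile demo.db --smiles OCC        # prints 1
```

Experimental data attaches through `ExperimentStore`: one metadata
table and one data table per experiment type, linked by UUID keys, with
every result row carrying the molregno (and optionally conf_id) it was
measured on.

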