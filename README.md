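# mavekit

A minimum-information toolkit for **multiplexed assays of variant effect
(MAVEs)** — saturation-mutagenesis experiments that score thousands of
variants of a target sequence in a single multiplexed functional assay.

MAVE datasets are only reusable if the metadata describing each stage of the
experiment — variant library generation, delivery into a model system,
functional separation, sequencing-based quantification, and score
calculation — is recorded consistently, and if the variants themselves are
represented unambiguously. `mavekit` implements the machinery that makes
that possible:

- **Structured metadata** for one MAVE experiment, validated against a
  controlled vocabulary (project scope, library generation, library
  integration/expression, assay type, sequencing method, phenotype/disease
  relevance) and a table of reporting rules with three severities
  (must → error, should → warning, encourage → info). The document model is
  also emitted as a JSON Schema (Draft 2020-12) whose hard constraints match
  the error-level rules.
- **Computed sequence identifiers**: `sha512t24u(S) = base64url(SHA-512(S)[0:24])`,
  the GA4GH refget/VRS digest, so any full target sequence has a stable
  32-character global identifier.
- **MAVE-HGVS parsing** — a strict, machine-parsable HGVS subset for
  variants on contiguous target sequences (substitution, deletion,
  duplication, insertion, delins, protein synonymous, multi-edit), with
  canonical formatting and sequence application.
- **VRS-style alleles**: 0-based inter-residue locations plus a replacement
  state, with *fully justified* normalization — every representation of an
  indel inside a repeat collapses to the one allele spanning the whole
  ambiguity interval, so normalized-allele equality is semantic equality and
  the digest of the canonical serialization is a global variant identifier.
- **Target-to-reference mapping** through an ungapped anchor (position +
  strand): the homologous allele on a versioned reference accession, tagged
  with the `homologous_to` relation and an emitted `g.` HGVS string
  (3'-shifted for indels).
- **Score/count table validation** (MaveDB-style CSV) against the target and
  the data-sharing recommendations (share raw counts; report scores prior to
  normalization/imputation), plus saturation-coverage measurement.
- **A deterministic fixture generator** that simulates the whole pipeline —
  saturation library, latent effects, logistic bin sorting, multinomial
  sequencing counts, log-ratio scores, compliant metadata — so every feature
  is testable without downloading anything.

## Worked example

Generate a synthetic standard-compliant dataset and validate it:

```sh
$ mavekit make-fixture demo --seed 7 --length 12
target  demo/target.fasta
scores  demo/scores.csv
counts  demo/counts.csv
metadata        demo/metadata.json

$ mavekit digest demo/target.fasta
synthetic_target_7      12      cLRiNOrnKAAjJGwRnhtLXpFVfODBQpNw

$ mavekit validate-meta demo/metadata.json
no findings
```

`digest` prints each record's label, length, and sha512t24u identifier —
the same digest any GA4GH refget implementation would compute for that
sequence. `validate-meta` exits 0 because the generated document satisfies
every reporting rule; ablate any guarded field and it names the violated
rule and its JSON Pointer path, exiting 1.

The scores CSV is a saturation library (3 variants per nucleotide position)
with one score per variant; `latentClass`/`latentEffect` columns expose the
simulation's ground truth:

```
hgvs_nt,hgvs_pro,score,latentClass,latentEffect
c.1T>A,,-2.1146547491244023,deleterious,-2.1277059444583992
c.1T>C,,0.14082983585159756,null,0.12538255030549525
```

Deleterious variants (latent effect near −2) sort into low bins and score
near −2; null variants score near 0.

Map a target variant to its homologous reference allele:

```sh
$ mavekit map-variant c.2G>A demo/target.fasta --anchor 101 --accession NM_000546.6
{
  "targetAllele":    {"location": {"sequenceId": "cLRiNOrn…", "start": 1, "end": 2}, "state": "A"},
  "referenceAllele": {"location": {"sequenceId": "NM_000546.6", "start": 101, "end": 102}, "state": "A"},
  "relation": "homologous_to",
  "referenceHgvs": "NM_000546.6:g.102G>A"
}
```

Target position 2 (interbase `[1, 2)`) lands at reference position
`anchor + 1 = 102`; the emitted HGVS uses 1-based closed coordinates on the
versioned accession.

The same operations are available as a library:

```python
from mavekit import TargetSequence, parse_variant, to_allele, normalize

t = TargetSequence("toy", "CAAAT")
a = to_allele(parse_variant("c.2del"), t)      # delete one A of the run
n = normalize(a, t.residues)
# n spans the whole A-run: location [1, 4), state "AA"
```

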