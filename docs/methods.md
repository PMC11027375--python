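# Methods

This note records the models, conventions, and design decisions behind
`mavekit`, in the order a reader meets them: sequence identity, variant
representation, allele normalization and mapping, the metadata rule system,
table validation, and the synthetic-data generator.

## Sequence identity (seqid)

Targets are stored as the exact residues assayed. The computed identifier is
**sha512t24u**: the base64url encoding, without padding, of the first 24
bytes of the SHA-512 digest of the ASCII sequence bytes — 24 bytes encode to
exactly 32 characters over `[A-Za-z0-9_-]`, with no `=` padding by
construction. Digests must be case-stable, so residues are uppercased on
ingest, and RNA input is stored as DNA (`U → T`) so that the identifier does
not depend on transcription state. The U→T convention is a toolkit decision:
no external mandate fixes how RNA targets should be normalized before
digesting, and a single nucleotide alphabet keeps digest identity simple.
The digest is exposed bare (canonical) and in a `SQ.`-prefixed CURIE-like
form for use inside identifiers.

Reference anchoring requires a **versioned** accession: `parse_accession`
splits a mandatory trailing `.N` and classifies the resource by prefix
(`NM_`/`NP_`/`NC_`/… → RefSeq, `ENS…[GTPE]` + 11 digits → Ensembl, the
UniProtKB accession regex → UniProt, anything else → other). A missing
version raises `MissingVersionError`; the metadata validator converts that
signal into the `VERSIONED_ACCESSION_REQUIRED` error. Unversioned
identifiers are not stable and therefore never accepted silently.

## Variant grammar (mavehgvs)

The parser covers the MAVE-HGVS subset appropriate for contiguous assayed
targets: plain positive integer positions only. Intronic/UTR offsets
(`c.78+1G>A`, `c.-12A>G`, `c.*5A>G`), uncertain `(…)` positions, and
prefixes other than `c/n/g/p` are grammar errors that report the offending
token's offset. Supported productions: substitution, deletion, duplication,
insertion (between adjacent positions only), delins, protein synonymous
(`p.Arg5=`, `p.=`), and the bracketed multi-edit form `c.[1A>G;5del]`.

Conventions:

- Protein residues use three-letter codes in canonical output; one-letter
  input is accepted and normalized on parse.
- Multi-edit lists must be position-sorted and non-overlapping; edits whose
  closed spans touch (including equal-position pairs) are rejected as
  authoring errors rather than disambiguated.
- `apply_variant` applies edits right-to-left so every coordinate refers to
  the unedited target, checks stated reference residues against the target
  (raising a mismatch error naming expected vs observed), and enforces the
  length-change law per edit kind (substitution 0, deletion −(end−start+1),
  insertion +|alt|, duplication +(end−start+1), delins |alt|−(end−start+1)).
- `enumerate_saturation` yields the full single-substitution library in
  deterministic order (position-major, alphabetical alternate): 3L variants
  for a DNA target of length L; 19N for a protein target of length N,
  drawing alternates from the 20 standard amino acids. A stop (`*`) residue
  in a protein target would admit 20 alternates at that position; generated
  targets never contain stops, so the 19N law holds throughout the test
  corpus.

## Alleles: interbase coordinates, normalization, mapping (alleles)

A `SimpleAllele` is a 0-based half-open (inter-residue) location plus a
replacement state; interbase coordinates make insertion points unambiguous
(the empty interval `[p, p)`). Conversion from 1-based closed variant
coordinates is fixed: substitution at p → `[p−1, p)`; deletion p_q →
`[p−1, q)` with empty state; insertion between p and p+1 → `[p, p)`;
duplication p_q → an insertion of the unit at `[q, q)`; delins → `[p−1, q)`.
Multi-edit variants must be decomposed first — one allele per edit.

**Normalization is fully justified** (both-ends expansion), matching
VRS/VOCA behavior rather than left- or right-shuffling: representation
independence is the property that matters. The algorithm: (1) trim residues
shared between the reference span and the state from both ends (prefix
first, then suffix); (2) if the trimmed allele still has both reference and
state it is a substitution/delins and is returned trimmed; (3) a pure
deletion is rolled left (`[s,e) ≡ [s−1,e−1)` iff `seq[s−1] == seq[e−1]`) and
right to find the maximal ambiguity interval, and re-expressed spanning that
whole interval with the flanking repeat residues included in both reference
span and state; a pure insertion rolls its unit analogously (rotating the
unit as it moves). Identity alleles (reference and state equal) reduce to an
empty allele at the trim point — the trim-only result. The operation is
idempotent, and the test suite verifies canonicality against a brute-force
oracle that enumerates, for each fuzzed indel, every (location, state) pair
whose application yields the same edited sequence.

**Allele identifiers** are the sha512t24u digest of the fixed ASCII
serialization `sequenceId|start|end|state` of the *normalized* allele.
Identifier stability depends on that exact join, so it is part of the
contract. `allele_identifier` takes the sequence as an optional argument to
perform the normalization; without it the allele is assumed normalized.

**Mapping** uses an ungapped alignment model — an anchor position plus a
strand. A block/CIGAR alignment is out of scope for this version; ungapped
anchoring covers cloned-segment targets, which are the common case. Plus
strand: reference interbase start = (anchor − 1) + target start, state
unchanged. Minus strand: reference start = (anchor − 1) + (target length −
target end), state reverse-complemented (protein alleles cannot map to the
minus strand). The mapped variant carries the `homologous_to` relation and
an emitted reference-side `g.` HGVS string. For HGVS emission the normalized
full-span allele is reduced to a minimal edit by trimming the maximal common
*prefix* first — which realizes the HGVS 3'-rule (right-shifted indels) —
then formatted as substitution, del, ins, or delins in 1-based closed
coordinates. The reference-side allele's sequence-identifier slot carries
the versioned accession string rather than a sha512t24u digest, because the
full reference sequence is never available offline; this mirrors the
general VRS practice of allowing multiple sequence-identifier namespaces.
`project_from_reference` inverts the mapping exactly on both strands.

## Metadata model and rule system (vocabulary)

The document model is deliberately **lenient**: `MetadataDocument` wraps the
camelCase JSON as-is (unknown fields preserved), because the validator's
contract is to accept incomplete or invalid documents and return findings,
never to raise. Typed descriptor classes (`ModelSystem`,
`LibraryDescriptor`, `AssayDescriptor`, …) exist for programmatic
construction and serialize into the same JSON shape.

Rule severities mirror modal language: *must/essential* → **error**
(`TARGET_SEQUENCE_REQUIRED`, `VERSIONED_ACCESSION_REQUIRED`,
`MODEL_SYSTEM_TAXON`, `LIBRARY_GENERATION_MODE`, `ASSAY_READOUT_TERM`,
`SEQUENCING_METHOD_TERM`); *should/recommend* → **warning**
(`RAW_READS_DEPOSITION`, `RAW_READ_FILE_DESCRIPTIONS`,
`DISEASE_TERM_SOURCE`, `SOFTWARE_VERSIONS`, `CALIBRATION_VARIANT_SOURCE`,
`RAW_COUNTS_SHARED`, `PRENORMALIZED_SCORES_SHARED`, `CUSTOM_TERM`);
*encourage/ideally* → **info** (`GENE_DISEASE_ENTITY`, `CODE_ARCHIVE_DOI`,
`ENV_VARIABLES_DOCUMENTED`, `REFERENCE_IDENTICAL_ALLELE`, `UNKNOWN_FIELD`).
Findings carry a stable rule id, a JSON Pointer path that resolves in the
input document, and a message; they sort by (severity, path) and the
validator is deterministic and idempotent.

CURIE validation is syntactic plus a prefix allowlist only (`NCBITaxon` for
taxa, `CLO` for cell lines, `MONDO`/`OMIM` for diseases) — no live ontology
lookup, so everything runs offline. The bundled registry is a seeded
skeleton of the vocabulary categories with a shortlist of leaf terms per
category; terms outside the shortlist are allowed and reported as
`CUSTOM_TERM` warnings, since the categories are fixed but the leaf set is
extensible. Registry files are versioned JSON and can be swapped via
`--registry` on every CLI command.

`emit_schema` produces a JSON Schema in the Draft 2020-12 dialect whose
hard constraints coincide exactly with the error-severity rules (required
sections, non-empty target residues, versioned-accession pattern,
`NCBITaxon:\d+` pattern, generation-mode enum, non-empty readout terms,
required sequencing method term). Warning- and info-level recommendations
are deliberately not encoded, so schema acceptance ⇔ zero error findings;
the per-category term shortlists are embedded as `$defs` enums for tooling
without restricting custom terms. The schema validates against the 2020-12
meta-schema and is byte-stable for a given registry.

## Tables (tables)

Score CSVs follow the MaveDB convention: `hgvs_nt` and/or `hgvs_pro` plus
`score`; every other column is preserved as an extra. The dialect is
comma-separated UTF-8, with `NA` and the empty cell both read as *missing*
score (never zero). Duplicate variant strings and missing required columns
are hard errors at read time. Count files need a variant column and at
least one sample column; every non-variant column is treated as a sample,
and counts must be non-negative integers.

`validate_scoreset` reports per-record errors (grammar, bounds, reference
mismatch — multi-edit variants validated by decomposition) and set-level
warnings: absent counts (`RAW_COUNTS_SHARED`), normalized/imputed scores
without a declared raw sibling (`PRENORMALIZED_SCORES_SHARED`), and
score/count variant-set disagreement (`SCORE_COUNT_CONSISTENCY`).
`hgvs_pro` records are checked against a protein sibling target when one is
supplied, otherwise syntax-only with a warning. `saturation_completeness`
is the fraction of the full single-substitution library with a record —
monotone under record addition by construction.

## Synthetic data (fixtures)

The generator emulates the canonical MAVE pipeline well enough to exercise
every validator and round-trip path; it is non-normative (a reporting
standard prescribes what to record, not how to simulate) and its parameters
are all surfaced on `FixtureSpec`:

- `target_length` (default 30) and `molecule_type` (dna): a pseudo-random
  target; the library is its full saturation set (90 variants at default).
- Effect model: each variant is null with probability `null_fraction`
  (default 0.5, latent effect 0) or deleterious (effect
  `deleterious_mean_shift`, default −2.0), plus Gaussian noise
  (`noise_sd`, default 0.1). The defaults give a clearly bimodal map at a
  realistic signal-to-noise for a well-powered screen.
- Sorting: a read from variant *i* lands in bin `b ~ Binomial(nBins−1, σ(effect_i))`
  with `nBins = 4` bins, so the logit of the mean normalized bin equals the
  latent effect. Per-variant totals are `Poisson(depth_per_variant)`
  (default 2000), split multinomially across bins.
- Score: the empirical logit of the mean normalized bin with a half-count
  pseudocount — approximately the latent effect, so the mean score
  separation between null and deleterious classes estimates |shift|. The
  acceptance run recovers the specified −2.0 shift to well within ±10%
  over 20 seeds (observed ≈ 2.005).

What the generator does **not** emulate: read-level sequencing error,
variant-calling artifacts, bottlenecking/jackpotting during library
delivery, epistasis between edits, or real assay-specific score
distributions. Passing tests therefore demonstrate that the machinery —
representation, validation, round-trips, mapping — is correct, not that any
biological conclusion holds on real data.

Determinism: one integer seed keys everything; per-stage substreams are
spawned as `SeedSequence([seed, stage])` so adding stages never perturbs
earlier outputs, and identical seeds give byte-identical FASTA/CSV/JSON
files. The compliant metadata preset uses synthetic placeholder identifiers
(e.g. `NM_900001.2`, `SRR000000`) and is illustrative, not a replica of any
published record. `ablate` produces, per rule id, a copy of the preset with
exactly the guarded field corrupted — the basis of the validator coverage
matrix (each error rule's ablation triggers exactly that rule).

## Numerical and interface choices

- Problem sizes in the default test and acceptance runs (10,000 grammar
  round-trips, 500 normalization equivalence classes on ≤30-residue
  windows, 500 mapping pairs, 20 generator seeds) were chosen to make the
  statistical checks stable at three significant figures while keeping the
  whole suite under ten seconds.
- `lift_to_reference` takes the target length as an explicit third argument:
  the minus-strand arithmetic needs it and the link object deliberately
  stores only the anchor, strand, and optional reference window.
- CLI exit codes: 0 pass, 1 findings at/above `--fail-on`, 2 usage/parse
  error. Reports go to stdout, diagnostics to stderr.

## Known limitations

- Ungapped anchoring only; targets that align to a reference with indels
  need a block alignment model that this version does not provide.
- No codon-level mapping between nucleotide and protein variants, and no
  score computation from counts (enrichment/regression) — scoring pipelines
  are upstream tools whose *description* this toolkit validates.
- The bundled vocabulary is a shortlist skeleton; real deployments should
  load their community registry file.
- Reference-side HGVS is emitted, never parsed; clinical HGVS constructs
  (genomic offsets, rearrangements, mosaicism) are out of scope.
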