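# Methods

## Variant identity and normalization

All comparisons in the toolkit reduce to exact matching of the canonical key
*(chrom, pos, ref, alt)*.  Normalization is therefore the load-bearing step:

* a leading `chr` prefix is stripped case-insensitively and the remainder
  kept verbatim (`1`, `X`, `MT`), so call sets from GRCh37- and hg19-style
  pipelines compare equal;
* positions are VCF-native 1-based everywhere; no half-open conversion
  exists anywhere in the code base;
* alleles are uppercased on ingest, making soft-masked (lowercase) alleles
  equivalent;
* multi-allelic ALT fields are split into one key per alternate allele.
  Splitting is the stricter reading of the exact-match rule: a germline
  `A→T` at a site must match a somatic `A→T` call even when the somatic
  record also lists `A→G`;
* symbolic, breakend, missing (`.`, `*`) and non-ACGT alternates are dropped
  with a counted warning; in SNV mode (the default) indels and MNVs are
  dropped and counted as well;
* duplicate keys deduplicate silently (the count is logged).  Leak counting
  is over *distinct* keys: the match rule is defined at the variant level,
  and duplicated submission lines must not double-count one leaked
  polymorphism.

FILTER handling defaults to ingesting every data line — submissions are
final call sets, already filtered by their authors — with `pass_only` as an
opt-in.

The filtering path works on raw text lines rather than parsed-and-reserialized
records: header lines and retained data lines must survive byte-for-byte so a
filtered submission is diffable against the original, and parse errors must
name the offending 1-based line number.  Record-object VCF APIs guarantee
neither, so the scanner here reads CHROM/POS/REF/ALT/FILTER itself (genotype
columns are ignored); the test suite cross-checks key extraction against an
independent VCF reader.

## The encrypted germline store

Threat model: the server performing leak checks is public-facing and must
never hold recoverable germline genotypes; an attacker who obtains the store
file and its passphrase still only obtains *hashes* of variant keys.  Hashes
of common variants can in principle be matched against hashes of known
variants — a dictionary attack inherent to any unsalted scheme — so the
encryption layer is the second line of defence, and the store is treated as
a credential-protected artifact, not as public data.

Digests are deliberately **unsalted**: stores built independently, by
different parties or at different times, must agree on the digest of the same
variant, otherwise cross-checks between stores and sessions would be
impossible.  Per-store salting would also add nothing against the dictionary
attack above once the store is decrypted.

Construction (see the byte layout in `crypto_store.py`):

* key derivation: PBKDF2-HMAC-SHA256, 16-byte random salt, 200 000
  iterations by default (a format parameter recorded in the header, so tests
  and interactive use may lower it);
* encryption: AES-256 (default) or Blowfish in CTR mode over the sorted
  concatenation of digests.  Sorting makes the plaintext canonical given
  identical salt/IV; salt and IV are drawn fresh per build, so two builds of
  the same set differ as files while decrypting to identical digest sets;
* authentication: encrypt-then-MAC with HMAC-SHA256 over header and
  ciphertext, plus an 8-byte passphrase verifier derived from the MAC key.
  The verifier lets a wrong passphrase be reported as a credentials failure,
  distinct from ciphertext corruption, and neither case ever yields a
  partial digest set;
* the decrypted digest set lives only in process memory; no code path
  writes it out.

The cipher primitives are implemented in-package (encryption direction only —
CTR needs nothing else) and are pinned by reference test vectors: FIPS-197
appendix C and NIST SP800-38A for AES, the Schneier/SSLeay vector set for
Blowfish.  The AES S-box is generated from its GF(2⁸) definition at import;
Blowfish's P/S constants (the first 8336 hex digits of π) are computed from
Machin's formula on first use and spot-checked against published values.
This store format is a clean specification: files are not interchangeable
with any other tool's format.

## Scoring

Precision is the fraction of submitted calls that are true somatic SNVs,
recall the fraction of true somatic SNVs recovered, F₁ their harmonic mean.
Specificity is deliberately absent: against a whole genome of true-negative
positions it is uninformative.  Zero conventions, chosen so cohort
statistics remain total: precision := 0 for an empty prediction set and
F₁ := 0 when precision + recall = 0.

`classify_calls` partitions predictions into true positives, germline leaks
and other false positives.  A key present in both truth sets counts once, as
a true positive, and is flagged ambiguous; the synthetic generator never
creates such keys (truth sets are position-disjoint by construction), so the
flag exists to surface malformed real inputs.  `leak_count` itself is the
plain intersection of predictions with the germline truth set, so it is
identical whether computed here or through the encrypted store (a
cross-module test asserts this).

## Cohort statistics

* Medians use the mean-of-central-pair convention (numpy's default).
* Spearman ρ is the Pearson correlation of mid-ranks with average ranks on
  ties, delegated to `scipy.stats.spearmanr`; the test suite checks it
  against a from-first-principles mid-rank Pearson oracle on short, heavily
  tied vectors.  Only ρ is reported — no significance testing.  A constant
  input vector raises an explicit undefined-correlation error; in per-tumour
  summaries that case is reported as missing rather than as a number.
* Best-per-team selection: highest F₁ per (tumour, team); ties broken by
  fewest leaks, then lexicographically smallest submission ID.  The ordering
  is total, so the selection is reproducible; the tie-break favouring fewer
  leaks reflects the privacy goal.
* Administrator baseline submissions stay in all statistics by default and
  are excludable by flag.
* Recurrence counts, per distinct leaked variant, the number of submissions
  containing it.

## Synthetic data generator

The generator emulates, at the *variant* level, a spike-in benchmark design:
truth germline and somatic sets whose locations are exactly known, and
caller outputs with controlled error structure.

* **Truth sets** — positions uniform without replacement over an
  `n_chroms × chrom_length` genome (defaults 22 × 1 Mb), so germline and
  somatic sets are position-disjoint by construction; substitution types
  uniform over the 12 ordered ref→alt pairs.  Requesting more spike-ins than
  sites raises a capacity error.  Defaults of 5000 germline and 4000 somatic
  spike-ins put a submission's size in the thousands of calls, the scale of
  a whole-genome benchmark at desk size.
* **Callers** — each somatic truth key is emitted with probability
  `sensitivity` (default 0.9), each germline key with probability
  `leak_rate`, and a Poisson(`fp_rate`) number of novel false calls is
  placed at positions untouched by either truth set (collisions are
  resampled), keeping the TP/leak/other-FP partition exact.  The default
  `leak_rate` of 0.001 leaks a handful of the 5000 germline variants,
  the regime where leakage is rare but nonzero.  `leak_rate` is a
  variant-level proxy for the mechanism that drives leakage in real tumours
  (normal-cell contamination inflating germline signal in tumour reads);
  read-level contamination, coverage structure, subclonality and VAF
  modelling are explicitly not simulated — passing tests show the *pipeline*
  is correct, not that any particular real caller leaks at any particular
  rate.
* **Cohorts** — a grid of caller profiles runs against shared per-tumour
  truth sets and every submission is scored end-to-end, yielding the table
  the cohort statistics consume.  A grid in which leakier callers are also
  less sensitive reproduces the expected negative F₁-vs-leak-count
  correlation by construction; the acceptance checks assert its sign, not
  its magnitude.

Reproducibility: one numpy `default_rng` stream per (seed, caller_seed) with
a fixed draw order — somatic recovery, germline leakage, novel-FP count,
novel-FP placement — so outputs are bit-identical across platforms.

## Problem sizes and numerical choices

Test and acceptance runs use genomes of 10⁵–10⁷ sites, truth sets of 10²–10³
variants per tumour (5000 germline for the parameter-recovery check, which
uses 200 replicate callers and a 3-standard-error band), and a few hundred
random store fixtures per property — sizes chosen so the full stack,
including the pure-Python cipher path, exercises every branch while the
suite stays interactive.  Stores built in tests use a reduced PBKDF2
iteration count, which the format records per file; the 200 000-iteration
default applies to real use.

## Known limitations

* Exact matching only: no allele-frequency-aware or position-only modes, no
  liftover between genome builds, no indel/SV leakage.
* The store's dictionary-attack exposure for common variants is inherent to
  unsalted comparability (discussed above).
* `serve_session` is an in-process API; any network transport,
  authentication and rate limiting are the hosting layer's responsibility.
* Whole-genome scoring only — no BED-masked region restriction.
* The published cohort statistics of the original 259-submission challenge
  can be recomputed with `cohort_analysis` from the challenge's leaderboard
  table, but that table is third-party data and is not redistributed with
  the package.
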