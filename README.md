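# leakguard

Somatic single-nucleotide variant (SNV) call sets are often shared openly
because tumour-specific mutations are not, by themselves, identifying.  But
somatic callers are imperfect: inherited **germline** polymorphisms slip into
somatic prediction sets — *germline leakage* — and as few as 30–80 independent
SNPs can suffice to re-identify a person.  `leakguard` is a toolkit for data
providers, benchmarking-challenge operators and pipeline developers who need
to **quantify and remove germline leakage** from somatic SNV VCFs before
publication, including on public-facing servers that must never hold the
germline genotypes themselves.

## What it does

A variant is identified by its exact key *(chromosome, position, REF, ALT)*;
a predicted somatic call is a **leak** iff its key exactly matches a germline
truth call.  The toolkit has two modes:

* **Server mode (privacy-preserving).**  Each germline key is serialized as
  `chrom:pos:ref:alt`, hashed (SHA-512 default, MD5 optional), and the digest
  set is encrypted (AES-256 default, Blowfish optional; CTR mode with
  PBKDF2-derived keys and an HMAC integrity tag) into a *store* file.  The
  store can sit on any server: submissions are hashed in memory and compared
  against the decrypted digest set, and only the **count** of matches is ever
  reported.  Decrypted material never touches disk.
* **Local mode.**  With plaintext germline access, the leaked keys themselves
  are listed and a filtered VCF is written in which non-leak lines are
  byte-identical to the input.

Around the filter sits the benchmarking apparatus: per-submission scoring
with precision P = TP/(TP+FP), recall R = TP/(TP+FN) and
F₁ = 2PR/(P+R); cohort statistics (per-tumour leak medians and ranges,
Spearman ρ of F₁ vs leak count, best-submission-per-team selection, leaked
variant recurrence); and a synthetic spike-in generator that emulates a
tumour/normal truth design plus callers with controlled sensitivity,
false-positive rate and leak rate, so the whole stack is testable without
any external data.

## Worked example

Simulate a tumour with 1000 germline and 800 somatic spike-ins and one
caller (92% sensitivity, 1% germline leak rate), then screen and clean its
submission:

```sh
$ export LEAKGUARD_PASSPHRASE=demo-pass
$ leakguard build-store --germline germline.vcf --out germline.store
wrote germline.store: 1000 sha512 digests, aes encrypted

$ leakguard count --store germline.store --somatic submission.vcf
submission.vcf: 16 germline leak(s) in 780 distinct calls

$ leakguard filter --germline germline.vcf --somatic submission.vcf \
      --out clean.vcf --list-leaks leaks.tsv
removed 16 leak(s); filtered VCF written to clean.vcf

$ leakguard count --store germline.store --somatic clean.vcf
clean.vcf: 0 germline leak(s) in 764 distinct calls
```

The caller emitted 780 distinct calls of which 16 exactly matched germline
spike-ins; after filtering, a recount through the encrypted store confirms
zero residual leakage.  Scoring the same submission
(`leakguard evaluate …`) prints the full metric set:

```json
{
  "tp": 728, "fp": 52, "fn": 72,
  "precision": 0.9333, "recall": 0.91, "f1": 0.9215,
  "leak_count": 16,
  "leak_fraction_of_calls": 0.0205,
  "leak_fraction_of_fp": 0.3077
}
```

i.e. the 16 leaks are ~31% of this caller's false positives — leakage and
overall accuracy are tightly linked, which is exactly what the cohort
statistics (`leakguard cohort --table submissions.tsv`) measure at scale via
the Spearman correlation of F₁ against leak count.

`leakguard simulate --outdir fixtures/` writes truth VCFs, submission VCFs
and a cohort table for a configurable grid of caller profiles (YAML), and
`leakguard count --max-leaks N` exits with code 3 when a submission exceeds
an acceptable leakage threshold, for use in automated upload gates.

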