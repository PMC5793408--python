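import random

import pytest

from leakguard.vcf_io import VariantKey, VariantSet

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##source=test-fixture\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)

_CHROMS = [str(c) for c in range(1, 23)] + ["X", "Y", "MT"]
_BASES = "ACGT"


def vcf_text(rows, header: str = VCF_HEADER) -> str:
    """Render VCF text from (chrom, pos, ref, alt[, filter]) tuples."""
    lines = [header.rstrip("\n")]
    for row in rows:
        chrom, pos, ref, alt = row[:4]
        filt = row[4] if len(row) > 4 else "PASS"
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.")
    return "\n".join(lines) + "\n"


def write_vcf_file(path, rows, header: str = VCF_HEADER):
    path.write_text(vcf_text(rows, header))
    return path


def random_keys(rng: random.Random, n: int) -> set:
    """n distinct random SNV keys (distinct (chrom, pos) sites)."""
    keys: dict = {}
    while len(keys) < n:
        site = (rng.choice(_CHROMS), rng.randint(1, 500_000))
        if site in keys:
            continue
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        keys[site] = VariantKey(site[0], site[1], ref, alt)
    return set(keys.values())


def keys_to_rows(keys):
    from leakguard.vcf_io import variant_sort_key

    return [(k.chrom, k.pos, k.ref, k.alt) for k in sorted(keys, key=variant_sort_key)]


@pytest.fixture
def rng():
    return random.Random(20180131)


@pytest.fixture
def small_germline_somatic(rng, tmp_path):
    """A 5-key germline set and a 7-key somatic set sharing exactly 2 keys,
    both written as VCF files; returns (germline_set, somatic_set, g_path, s_path)."""
    germline = random_keys(rng, 5)
    shared = set(random.Random(7).sample(sorted(germline, key=str), 2))
    somatic_only = random_keys(random.Random(99), 5) - germline
    somatic = shared | set(list(somatic_only)[:5])
    g_path = write_vcf_file(tmp_path / "germline.vcf", keys_to_rows(germline))
    s_path = write_vcf_file(tmp_path / "somatic.vcf", keys_to_rows(somatic))
    return (
        VariantSet(frozenset(germline), "germline"),
        VariantSet(frozenset(somatic), "somatic"),
        g_path,
        s_path,
    )
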