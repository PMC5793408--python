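"""Reading, normalizing and filtering variant records in VCF text.

Every module in the toolkit identifies a single-nucleotide variant (SNV) by
the same canonical key: normalized chromosome label, 1-based position,
reference allele and alternate allele.  Matching between germline and somatic
call sets is exact on all four fields, so normalization has to be identical on
both sides:

* a leading ``chr`` prefix is stripped (case-insensitively) so that calls from
  GRCh37- and hg19-style pipelines compare equal;
* alleles are uppercased, making soft-masked (lowercase) alleles equivalent;
* coordinates stay VCF-native 1-based throughout.

The filtering path (:func:`write_filtered_vcf`) deliberately works at the text
line level: header lines and every retained data line are passed through
byte-for-byte, so a filtered submission differs from the original only by the
removed records.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .errors import InvalidKeyError, VcfParseError

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "VariantSet",
    "ReadCounts",
    "read_variant_keys",
    "read_variant_keys_counted",
    "write_filtered_vcf",
    "variant_sort_key",
]

_NUCLEOTIDES = frozenset("ACGT")

VcfSource = Union[str, Path, IO[str], IO[bytes]]


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Canonical identity of one variant: (chrom, pos, ref, alt).

    ``chrom`` carries no ``chr`` prefix, ``pos`` is 1-based, alleles are
    uppercase strings over A/C/G/T.  Instances are immutable and hashable so
    call sets are plain Python sets of keys.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvalidKeyError("chromosome label must be non-empty")
        if self.chrom.lower().startswith("chr"):
            raise InvalidKeyError(
                f"chromosome {self.chrom!r} not normalized (chr prefix present)"
            )
        if not isinstance(self.pos, int) or self.pos < 1:
            raise InvalidKeyError(f"position must be a positive integer, got {self.pos!r}")
        for allele in (self.ref, self.alt):
            if not allele or not _NUCLEOTIDES.issuperset(allele):
                raise InvalidKeyError(f"allele {allele!r} is not a string over A/C/G/T")
        if self.ref == self.alt:
            raise InvalidKeyError(f"ref and alt are identical ({self.ref!r})")

    @classmethod
    def from_fields(cls, chrom: str, pos: Union[int, str], ref: str, alt: str) -> "VariantKey":
        """Build a key from raw VCF fields, applying canonical normalization."""
        return cls(normalize_chrom(chrom), int(pos), ref.strip().upper(), alt.strip().upper())

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` (any case) and surrounding whitespace."""
    chrom = chrom.strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


def variant_sort_key(key: VariantKey) -> tuple:
    """Genome order: numeric chromosomes first (1..22), then X/Y/MT etc. lexically."""
    if key.chrom.isdigit():
        chrom_rank: tuple = (0, int(key.chrom), "")
    else:
        chrom_rank = (1, 0, key.chrom)
    return (*chrom_rank, key.pos, key.ref, key.alt)


@dataclass(frozen=True)
class VariantSet:
    """A deduplicated collection of :class:`VariantKey` with a provenance label."""

    keys: frozenset
    source_label: str = ""

    @classmethod
    def from_keys(cls, keys: Iterable[VariantKey], source_label: str = "") -> "VariantSet":
        return cls(frozenset(keys), source_label)

    def __len__(self) -> int:
        return len(self.keys)

    def __iter__(self) -> Iterator[VariantKey]:
        return iter(self.keys)

    def __contains__(self, key: object) -> bool:
        return key in self.keys

    def sorted_keys(self) -> list:
        return sorted(self.keys, key=variant_sort_key)


@dataclass
class ReadCounts:
    """Bookkeeping of what a VCF scan kept and dropped."""

    data_lines: int = 0
    kept_keys: int = 0
    non_snv_skipped: int = 0
    symbolic_skipped: int = 0
    filter_skipped: int = 0
    duplicate_keys: int = 0

    @property
    def skipped_records(self) -> int:
        return self.non_snv_skipped + self.symbolic_skipped + self.filter_skipped


def _open_lines(source: VcfSource) -> Iterator[bytes]:
    """Yield raw lines (bytes, newline included) from a path or open stream.

    Paths ending in ``.gz`` — or whose first two bytes are the gzip magic —
    are transparently decompressed.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path, "rb") as raw:
            magic = raw.read(2)
            raw.seek(0)
            if magic == b"\x1f\x8b":
                with gzip.open(raw) as gz:
                    yield from gz
            else:
                yield from raw
        return
    # open stream: accept text or binary
    first = source.read(0)
    if isinstance(first, str):
        for line in source:
            yield line.encode("utf-8")
    else:
        yield from source


def _is_symbolic_alt(alt: str) -> bool:
    """Symbolic (<DEL>), breakend ([, ]), missing (., *) or non-ACGT alleles."""
    if not alt or alt in {".", "*"}:
        return True
    if alt.startswith("<") or "[" in alt or "]" in alt:
        return True
    return not _NUCLEOTIDES.issuperset(alt.upper())


def _split_data_line(line: str, lineno: int) -> list:
    fields = line.rstrip("\r\n").split("\t")
    if len(fields) < 5:
        # tolerate whitespace-delimited minimal fixtures
        fields = line.split()
    if len(fields) < 5:
        raise VcfParseError(
            f"line {lineno}: expected at least CHROM POS ID REF ALT, got {len(fields)} field(s)"
        )
    return fields


def _keys_from_fields(fields: list, lineno: int, counts: ReadCounts) -> list:
    """Canonical keys for one data line; multi-allelic ALT is split per allele.

    Symbolic/breakend alternates are dropped (counted); malformed CHROM/POS/REF
    raise :class:`VcfParseError` naming the line.
    """
    chrom_raw, pos_raw, _id, ref_raw = fields[0], fields[1], fields[2], fields[3]
    chrom = normalize_chrom(chrom_raw)
    if not chrom:
        raise VcfParseError(f"line {lineno}: empty CHROM field")
    try:
        pos = int(pos_raw)
    except ValueError:
        raise VcfParseError(f"line {lineno}: POS {pos_raw!r} is not an integer") from None
    if pos < 1:
        raise VcfParseError(f"line {lineno}: POS must be >= 1, got {pos}")
    ref = ref_raw.strip().upper()
    if not ref or not _NUCLEOTIDES.issuperset(ref):
        raise VcfParseError(f"line {lineno}: REF allele {ref_raw!r} is not over A/C/G/T")
    keys = []
    for alt_raw in fields[4].split(","):
        alt = alt_raw.strip().upper()
        if _is_symbolic_alt(alt):
            counts.symbolic_skipped += 1
            logger.warning("line %d: dropping symbolic/unsupported ALT %r", lineno, alt_raw)
            continue
        if alt == ref:
            raise VcfParseError(f"line {lineno}: ALT allele equals REF ({ref!r})")
        keys.append(VariantKey(chrom, pos, ref, alt))
    return keys


def _line_passes_filter(fields: list) -> bool:
    filt = fields[6].strip() if len(fields) > 6 else "."
    return filt in ("PASS", ".", "")


def read_variant_keys_counted(
    source: VcfSource, snv_only: bool = True, pass_only: bool = False,
    source_label: str = "",
) -> tuple:
    """Scan a VCF and return ``(VariantSet, ReadCounts)``.

    Multi-allelic records contribute one key per alternate allele; duplicate
    keys are deduplicated (counted).  With ``snv_only`` (the default), records
    whose REF/ALT are not both single bases are dropped and counted; with
    ``pass_only``, records whose FILTER is neither ``PASS`` nor ``.`` are
    dropped first.  An input that is empty after the header yields an empty
    set, not an error.
    """
    counts = ReadCounts()
    keys: set = set()
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.decode("utf-8", errors="replace")
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        counts.data_lines += 1
        fields = _split_data_line(line, lineno)
        if pass_only and not _line_passes_filter(fields):
            counts.filter_skipped += 1
            continue
        for key in _keys_from_fields(fields, lineno, counts):
            if snv_only and not key.is_snv:
                counts.non_snv_skipped += 1
                continue
            if key in keys:
                counts.duplicate_keys += 1
            else:
                keys.add(key)
    counts.kept_keys = len(keys)
    if counts.skipped_records or counts.duplicate_keys:
        logger.info(
            "%s: kept %d keys from %d data lines "
            "(non-SNV %d, symbolic %d, FILTER %d, duplicates %d)",
            source_label or "vcf", counts.kept_keys, counts.data_lines,
            counts.non_snv_skipped, counts.symbolic_skipped,
            counts.filter_skipped, counts.duplicate_keys,
        )
    return VariantSet(frozenset(keys), source_label), counts


def read_variant_keys(
    source: VcfSource, snv_only: bool = True, pass_only: bool = False,
    source_label: str = "",
) -> VariantSet:
    """Read the deduplicated set of canonical variant keys from a VCF."""
    variant_set, _ = read_variant_keys_counted(
        source, snv_only=snv_only, pass_only=pass_only, source_label=source_label
    )
    return variant_set


def write_filtered_vcf(source: VcfSource, leaks: Iterable[VariantKey], out: Union[str, Path]) -> int:
    """Copy a VCF, omitting every data line that carries a leaked key.

    Header lines and retained data lines are written byte-for-byte.  A data
    line is omitted iff at least one of its canonical keys (after
    multi-allelic splitting) is in ``leaks``.  Returns the number of data
    lines written.  An ``out`` path ending in ``.gz`` is gzip-compressed.
    """
    leak_set = frozenset(leaks)
    out = Path(out)
    counts = ReadCounts()  # symbolic drops during key extraction are not line drops here
    written = 0

    opener = gzip.open if out.suffix == ".gz" else open
    with opener(out, "wb") as sink:
        for lineno, raw in enumerate(_open_lines(source), start=1):
            line = raw.decode("utf-8", errors="replace")
            if line.startswith("#") or not line.strip():
                sink.write(raw)
                continue
            fields = _split_data_line(line, lineno)
            line_keys = _keys_from_fields(fields, lineno, counts)
            if leak_set and any(k in leak_set for k in line_keys):
                continue
            sink.write(raw)
            written += 1
    return written
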