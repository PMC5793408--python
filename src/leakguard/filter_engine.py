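"""Counting, locating and stripping germline leaks from somatic call sets.

A *leak* is a predicted somatic SNV that exactly matches a germline variant
at chromosome, position, reference allele and alternate allele.  Two modes:

* **server mode** (:func:`count_leaks`, :class:`FilterSession`) compares
  hashed somatic keys against an encrypted store's digests and reports only
  the number of matches — never positions or alleles, preserving the privacy
  purpose of the hashed store;
* **local mode** (:func:`locate_leaks`, :func:`filter_submission`) has
  plaintext germline access and can therefore list the leaked keys and write
  a filtered submission VCF.

Leak counting is over *distinct* canonical keys: duplicate submission lines
would otherwise double-count a single leaked polymorphism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

from . import vcf_io
from .crypto_store import GermlineStore, hash_key, load_store, serialize_key
from .errors import ConfigurationError, SessionClosedError, UnknownTumourError
from .vcf_io import VariantKey, VariantSet, VcfSource

logger = logging.getLogger(__name__)

__all__ = [
    "LeakReport",
    "count_leaks",
    "locate_leaks",
    "filter_submission",
    "serve_session",
    "FilterSession",
]


@dataclass(frozen=True)
class LeakReport:
    """Outcome of screening one submission against one germline truth set."""

    submission_label: str
    total_calls: int
    leak_count: int
    leak_keys: frozenset = frozenset()  # populated only in local mode
    skipped_records: int = 0
    threshold: Optional[int] = None
    rejected: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.leak_count <= self.total_calls:
            raise ValueError(
                f"leak_count {self.leak_count} outside [0, total_calls={self.total_calls}]"
            )

    def sorted_leaks(self) -> list:
        return sorted(self.leak_keys, key=vcf_io.variant_sort_key)


def _apply_threshold(report: LeakReport, threshold: Optional[int]) -> LeakReport:
    if threshold is None:
        return report
    rejected = report.leak_count > threshold
    if rejected:
        logger.warning(
            "%s: %d leaks exceed threshold %d -> submission rejected",
            report.submission_label, report.leak_count, threshold,
        )
    return LeakReport(
        submission_label=report.submission_label,
        total_calls=report.total_calls,
        leak_count=report.leak_count,
        leak_keys=report.leak_keys,
        skipped_records=report.skipped_records,
        threshold=threshold,
        rejected=rejected,
    )


def count_leaks(
    somatic: VariantSet,
    store: GermlineStore,
    hash_protocol: Optional[str] = None,
    skipped_records: int = 0,
    threshold: Optional[int] = None,
) -> LeakReport:
    """Server-mode leak count: hashed somatic keys vs the store's digests.

    ``hash_protocol``, if given, must agree with the store header — a
    mismatch would silently count zero leaks, so it is refused.
    """
    if hash_protocol is not None and hash_protocol.lower() != store.header.hash_protocol:
        raise ConfigurationError(
            f"hash protocol {hash_protocol!r} does not match store protocol "
            f"{store.header.hash_protocol!r}"
        )
    protocol = store.header.hash_protocol
    n_leaks = sum(1 for k in somatic if hash_key(serialize_key(k), protocol) in store.digests)
    report = LeakReport(
        submission_label=somatic.source_label,
        total_calls=len(somatic),
        leak_count=n_leaks,
        skipped_records=skipped_records,
    )
    return _apply_threshold(report, threshold)


def count_leaks_vcf(
    somatic_vcf: VcfSource,
    store: GermlineStore,
    threshold: Optional[int] = None,
    label: str = "",
) -> LeakReport:
    """Read a somatic submission VCF and count leaks against a loaded store."""
    somatic, counts = vcf_io.read_variant_keys_counted(
        somatic_vcf, source_label=label or str(somatic_vcf)
    )
    return count_leaks(
        somatic, store, skipped_records=counts.skipped_records, threshold=threshold
    )


def locate_leaks(
    somatic_vcf: VcfSource,
    germline_vcf: VcfSource,
    threshold: Optional[int] = None,
) -> LeakReport:
    """Local-mode leak listing: plaintext intersection of the two call sets."""
    somatic, counts = vcf_io.read_variant_keys_counted(
        somatic_vcf, source_label=str(somatic_vcf)
    )
    germline = vcf_io.read_variant_keys(germline_vcf, source_label=str(germline_vcf))
    leaks = somatic.keys & germline.keys
    report = LeakReport(
        submission_label=somatic.source_label,
        total_calls=len(somatic),
        leak_count=len(leaks),
        leak_keys=frozenset(leaks),
        skipped_records=counts.skipped_records,
    )
    return _apply_threshold(report, threshold)


def filter_submission(
    somatic_vcf: Union[str, Path],
    germline_vcf: Union[str, Path],
    out_vcf: Union[str, Path],
    threshold: Optional[int] = None,
) -> LeakReport:
    """Write a copy of the submission with every leaking record removed.

    Non-leak lines are passed through byte-identically; re-running
    :func:`locate_leaks` on the output yields zero leaks.
    """
    report = locate_leaks(somatic_vcf, germline_vcf, threshold=threshold)
    vcf_io.write_filtered_vcf(somatic_vcf, report.leak_keys, out_vcf)
    return report


class FilterSession:
    """In-process multi-tumour screening session over encrypted stores.

    Decrypted digest sets are held in memory for the session lifetime only;
    :meth:`close` drops them and refuses further requests.  The hosting layer
    (e.g. a challenge submission server) may wrap this in whatever transport
    it likes — no network code lives here.
    """

    def __init__(self, stores: Mapping[str, GermlineStore]):
        self._stores: Optional[dict] = dict(stores)

    @property
    def tumour_labels(self) -> list:
        self._ensure_open()
        return sorted(self._stores)  # type: ignore[arg-type]

    def _ensure_open(self) -> None:
        if self._stores is None:
            raise SessionClosedError("session is closed")

    def count(
        self, tumour_label: str, somatic_vcf: VcfSource, threshold: Optional[int] = None
    ) -> LeakReport:
        self._ensure_open()
        try:
            store = self._stores[tumour_label]  # type: ignore[index]
        except KeyError:
            raise UnknownTumourError(
                f"no store loaded for tumour {tumour_label!r}; "
                f"known: {sorted(self._stores)}"  # type: ignore[arg-type]
            ) from None
        return count_leaks_vcf(somatic_vcf, store, threshold=threshold, label=tumour_label)

    def close(self) -> None:
        self._stores = None

    def __enter__(self) -> "FilterSession":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def serve_session(
    store_paths: Mapping[str, Union[str, Path]],
    passphrase_source: Union[str, Callable[[str], str]],
) -> FilterSession:
    """Load every labelled store (eagerly, so failures surface now) and open a session.

    ``passphrase_source`` is either the passphrase itself or a callable
    ``label -> passphrase``, so per-tumour credentials are possible.
    """
    provider = passphrase_source if callable(passphrase_source) else (lambda _label: passphrase_source)
    stores = {label: load_store(path, provider(label)) for label, path in store_paths.items()}
    return FilterSession(stores)
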