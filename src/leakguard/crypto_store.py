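"""The encrypted store of hashed germline variant keys.

The privacy model: a germline call set must be usable for leak counting on a
public-facing server without the genotypes themselves ever being present
there.  Each variant key is serialized to its canonical ``chrom:pos:ref:alt``
string, digested with an unsalted cryptographic hash (so digests are
comparable across independently built stores), and the *set of digests* is
encrypted under a passphrase before it touches disk.  Leak counting later
happens purely on in-memory digests; the decrypted payload is never written
out by any operation here.

Hash protocols: SHA-512 (default) or MD5.  Ciphers: AES-256 (default) or
Blowfish, both in CTR mode with encrypt-then-MAC (HMAC-SHA256).  The
passphrase is stretched with PBKDF2-HMAC-SHA256; salt, iteration count and IV
travel in the plaintext header.

On-disk layout (all integers big-endian)::

    magic      4 bytes  b"GLF1"
    version    1 byte   (currently 1)
    hash_id    1 byte   (1 = SHA512, 2 = MD5)
    cipher_id  1 byte   (1 = AES, 2 = Blowfish)
    kdf_iter   4 bytes
    salt_len   1 byte, salt
    iv_len     1 byte, iv            (cipher block size)
    verifier   8 bytes               (HMAC of a fixed tag; detects a wrong
                                      passphrase before any decryption)
    count      8 bytes               (number of digests)
    ct_len     8 bytes, ciphertext   (the sorted digest concatenation, CTR)
    mac        32 bytes              (HMAC-SHA256 over header || ciphertext)

A wrong passphrase fails the verifier check and raises
:class:`BadPassphraseError`; any byte damage to header or ciphertext fails
the MAC and raises :class:`StoreIntegrityError`.  Neither ever yields a
partial digest set.
"""

from __future__ import annotations

import hashlib
import hmac as hmac_mod
import os
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from ._ciphers import AES, Blowfish, ctr_transform
from .errors import (
    BadPassphraseError,
    ConfigurationError,
    InvalidKeyError,
    StoreFormatError,
    StoreIntegrityError,
)
from .vcf_io import VariantKey, VariantSet

__all__ = [
    "HASH_PROTOCOLS",
    "CIPHERS",
    "StoreHeader",
    "GermlineStore",
    "serialize_key",
    "hash_key",
    "digest_set",
    "build_store",
    "load_store",
]

MAGIC = b"GLF1"
VERSION = 1
DEFAULT_KDF_ITERATIONS = 200_000

# name -> (wire id, digest size)
HASH_PROTOCOLS = {"sha512": (1, 64), "md5": (2, 16)}
# name -> (wire id, key size, block size)
CIPHERS = {"aes": (1, 32, 16), "blowfish": (2, 32, 8)}

_VERIFIER_TAG = b"GLF1-passphrase-check"
_MAC_LEN = 32
_VERIFIER_LEN = 8


def _canonical_protocol(name: str, table: dict, what: str) -> str:
    lowered = name.strip().lower()
    if lowered not in table:
        raise ConfigurationError(
            f"unsupported {what} {name!r}; choose one of {sorted(table)}"
        )
    return lowered


def serialize_key(key: VariantKey) -> str:
    """Canonical serialization ``chrom:pos:ref:alt`` of one variant key.

    Single-colon delimiters, no whitespace, base-10 position.  The form is
    injective over valid keys: colons cannot occur in a normalized chromosome
    label's role-free fields, so distinct keys give distinct strings.
    """
    if not isinstance(key, VariantKey):
        raise InvalidKeyError(f"expected VariantKey, got {type(key).__name__}")
    return f"{key.chrom}:{key.pos}:{key.ref}:{key.alt}"


def hash_key(canonical: str, protocol: str = "sha512") -> bytes:
    """Unsalted digest of the canonical string's UTF-8 bytes."""
    protocol = _canonical_protocol(protocol, HASH_PROTOCOLS, "hash protocol")
    if protocol == "sha512":
        return hashlib.sha512(canonical.encode("utf-8")).digest()
    return hashlib.md5(canonical.encode("utf-8")).digest()


def digest_set(variants: VariantSet, protocol: str = "sha512") -> frozenset:
    """Digests of every key in a variant set."""
    return frozenset(hash_key(serialize_key(k), protocol) for k in variants)


@dataclass(frozen=True)
class StoreHeader:
    """Plaintext metadata of one store file."""

    hash_protocol: str
    cipher: str
    kdf_iterations: int
    kdf_salt: bytes
    iv: bytes
    digest_count: int
    version: int = VERSION

    @property
    def digest_size(self) -> int:
        return HASH_PROTOCOLS[self.hash_protocol][1]


@dataclass(frozen=True)
class GermlineStore:
    """Decrypted digest set plus its header; exists only in memory."""

    digests: frozenset
    header: StoreHeader

    def __len__(self) -> int:
        return len(self.digests)

    def __contains__(self, digest: object) -> bool:
        return digest in self.digests


def _derive_keys(passphrase: str, salt: bytes, iterations: int, cipher: str) -> tuple:
    key_len = CIPHERS[cipher][1]
    material = hashlib.pbkdf2_hmac(
        "sha256", passphrase.encode("utf-8"), salt, iterations, dklen=key_len + 32
    )
    return material[:key_len], material[key_len:]


def _make_cipher(cipher: str, key: bytes):
    return AES(key) if cipher == "aes" else Blowfish(key)


def _pack_header(header: StoreHeader, verifier: bytes) -> bytes:
    hash_id = HASH_PROTOCOLS[header.hash_protocol][0]
    cipher_id = CIPHERS[header.cipher][0]
    return b"".join(
        [
            MAGIC,
            struct.pack(">BBBI", header.version, hash_id, cipher_id, header.kdf_iterations),
            struct.pack(">B", len(header.kdf_salt)), header.kdf_salt,
            struct.pack(">B", len(header.iv)), header.iv,
            verifier,
            struct.pack(">Q", header.digest_count),
        ]
    )


def build_store(
    germline: VariantSet,
    passphrase: str,
    hash_protocol: str = "sha512",
    cipher: str = "aes",
    out: Union[str, Path, None] = None,
    kdf_iterations: int = DEFAULT_KDF_ITERATIONS,
    seed_material: bytes | None = None,
) -> StoreHeader:
    """Hash a germline variant set and write the encrypted store file.

    The payload is the sorted concatenation of per-key digests, CTR-encrypted
    under a PBKDF2-derived key.  Salt and IV are drawn fresh (from
    ``seed_material`` only when reproducible files are explicitly wanted, e.g.
    in tests), so two builds of the same set produce different bytes that
    decrypt to the same digest set.
    """
    if not passphrase:
        raise ConfigurationError("passphrase must be non-empty")
    if out is None:
        raise ConfigurationError("an output path is required")
    hash_protocol = _canonical_protocol(hash_protocol, HASH_PROTOCOLS, "hash protocol")
    cipher = _canonical_protocol(cipher, CIPHERS, "cipher")
    if kdf_iterations < 1:
        raise ConfigurationError("kdf_iterations must be positive")

    block = CIPHERS[cipher][2]
    if seed_material is not None:
        stretch = hashlib.sha512(b"glf-seed" + seed_material).digest()
        salt, iv = stretch[:16], stretch[16:16 + block]
    else:
        salt, iv = os.urandom(16), os.urandom(block)

    digests = sorted(digest_set(germline, hash_protocol))
    header = StoreHeader(
        hash_protocol=hash_protocol, cipher=cipher, kdf_iterations=kdf_iterations,
        kdf_salt=salt, iv=iv, digest_count=len(digests),
    )
    enc_key, mac_key = _derive_keys(passphrase, salt, kdf_iterations, cipher)
    verifier = hmac_mod.new(mac_key, _VERIFIER_TAG, hashlib.sha256).digest()[:_VERIFIER_LEN]
    ciphertext = ctr_transform(_make_cipher(cipher, enc_key), iv, b"".join(digests))

    head = _pack_header(header, verifier)
    body = struct.pack(">Q", len(ciphertext)) + ciphertext
    mac = hmac_mod.new(mac_key, head + body, hashlib.sha256).digest()
    Path(out).write_bytes(head + body + mac)
    return header


class _Reader:
    def __init__(self, blob: bytes):
        self.blob = blob
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.blob):
            raise StoreIntegrityError("store file is truncated")
        chunk = self.blob[self.pos:self.pos + n]
        self.pos += n
        return chunk


def load_store(path: Union[str, Path], passphrase: str) -> GermlineStore:
    """Decrypt a store file in memory and return its digest set.

    Raises :class:`BadPassphraseError` on a wrong passphrase,
    :class:`StoreIntegrityError` on truncation or tampering, and
    :class:`StoreFormatError` if the file is not a store at all.  Decrypted
    bytes are never written anywhere.
    """
    blob = Path(path).read_bytes()
    r = _Reader(blob)
    if len(blob) < 4 or r.take(4) != MAGIC:
        raise StoreFormatError(f"{path}: not a germline store (bad magic)")
    version, hash_id, cipher_id, iterations = struct.unpack(">BBBI", r.take(7))
    if version != VERSION:
        raise StoreFormatError(f"{path}: unsupported store version {version}")
    try:
        hash_protocol = next(k for k, v in HASH_PROTOCOLS.items() if v[0] == hash_id)
        cipher = next(k for k, v in CIPHERS.items() if v[0] == cipher_id)
    except StopIteration:
        raise StoreFormatError(f"{path}: unknown protocol ids ({hash_id}, {cipher_id})") from None
    salt = r.take(struct.unpack(">B", r.take(1))[0])
    iv = r.take(struct.unpack(">B", r.take(1))[0])
    verifier = r.take(_VERIFIER_LEN)
    (digest_count,) = struct.unpack(">Q", r.take(8))
    (ct_len,) = struct.unpack(">Q", r.take(8))
    ciphertext = r.take(ct_len)
    mac = r.take(_MAC_LEN)
    if r.pos != len(blob):
        raise StoreIntegrityError(f"{path}: trailing bytes after MAC")

    enc_key, mac_key = _derive_keys(passphrase, salt, iterations, cipher)
    expect_verifier = hmac_mod.new(mac_key, _VERIFIER_TAG, hashlib.sha256).digest()[:_VERIFIER_LEN]
    if not hmac_mod.compare_digest(verifier, expect_verifier):
        raise BadPassphraseError(f"{path}: passphrase does not match this store")
    if not hmac_mod.compare_digest(
        mac, hmac_mod.new(mac_key, blob[: len(blob) - _MAC_LEN], hashlib.sha256).digest()
    ):
        raise StoreIntegrityError(f"{path}: authentication failed (file corrupted)")

    digest_size = HASH_PROTOCOLS[hash_protocol][1]
    if ct_len != digest_count * digest_size:
        raise StoreIntegrityError(
            f"{path}: payload length {ct_len} inconsistent with digest count {digest_count}"
        )
    plain = ctr_transform(_make_cipher(cipher, enc_key), iv, ciphertext)
    digests = frozenset(plain[i:i + digest_size] for i in range(0, len(plain), digest_size))
    if len(digests) != digest_count:
        raise StoreIntegrityError(f"{path}: duplicate digests in payload")
    header = StoreHeader(
        hash_protocol=hash_protocol, cipher=cipher, kdf_iterations=iterations,
        kdf_salt=salt, iv=iv, digest_count=digest_count, version=version,
    )
    return GermlineStore(digests=digests, header=header)
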