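"""Block-cipher primitives used by the encrypted germline store.

Both ciphers expose only block *encryption*, which is all counter (CTR) mode
needs for encryption and decryption alike.  They are validated against the
published reference test vectors in the test suite.
"""

from .aes import AES
from .blowfish import Blowfish

__all__ = ["AES", "Blowfish", "ctr_transform"]


def ctr_transform(cipher, iv: bytes, data: bytes) -> bytes:
    """Encrypt/decrypt ``data`` with ``cipher`` in CTR mode (self-inverse).

    The keystream block for index ``i`` is ``E(iv + i mod 2**(8*B))`` where the
    counter block is the big-endian integer reading of ``iv`` and ``B`` is the
    cipher's block size.
    """
    block = cipher.block_size
    if len(iv) != block:
        raise ValueError(f"iv must be {block} bytes for this cipher, got {len(iv)}")
    counter = int.from_bytes(iv, "big")
    mask = (1 << (8 * block)) - 1
    out = bytearray()
    for off in range(0, len(data), block):
        keystream = cipher.encrypt_block(counter.to_bytes(block, "big"))
        chunk = data[off:off + block]
        out += bytes(a ^ b for a, b in zip(chunk, keystream))
        counter = (counter + 1) & mask
    return bytes(out)
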