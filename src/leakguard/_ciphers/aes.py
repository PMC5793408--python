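"""AES block encryption (Rijndael with a 128-bit block), key sizes 128/192/256.

The S-box is derived at import time from its algebraic definition (the
multiplicative inverse in GF(2^8) modulo x^8+x^4+x^3+x+1, followed by the
affine transform), rather than being pasted in as a table of constants.
Only the forward (encryption) direction is implemented; the store uses the
cipher in CTR mode, which never needs block decryption.
"""

from __future__ import annotations

__all__ = ["AES"]


def _build_sbox() -> bytes:
    # GF(2^8) exponentials of the generator 3 give every non-zero element;
    # inverses follow from exp/log tables.
    exp = [0] * 256
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        x ^= (x << 1) ^ (0x11B if x & 0x80 else 0)
        x &= 0xFF
    sbox = [0] * 256
    for value in range(256):
        inv = 0 if value == 0 else exp[(255 - log[value]) % 255]
        # affine transform: bit-rotate xor with 0x63
        result = inv
        for shift in (1, 2, 3, 4):
            result ^= ((inv << shift) | (inv >> (8 - shift))) & 0xFF
        sbox[value] = result ^ 0x63
    return bytes(sbox)


_SBOX = _build_sbox()
assert _SBOX[0x00] == 0x63 and _SBOX[0x53] == 0xED  # FIPS-197 spot checks

_XTIME = bytes(((v << 1) ^ 0x1B if v & 0x80 else v << 1) & 0xFF for v in range(256))

_RCON = [0x01]
while len(_RCON) < 14:
    _RCON.append(_XTIME[_RCON[-1]])


class AES:
    """AES block cipher, encryption direction only."""

    block_size = 16

    def __init__(self, key: bytes):
        if len(key) not in (16, 24, 32):
            raise ValueError(f"AES key must be 16, 24 or 32 bytes, got {len(key)}")
        self._round_keys = self._expand_key(key)
        self._rounds = len(self._round_keys) - 1

    @staticmethod
    def _expand_key(key: bytes) -> list:
        nk = len(key) // 4
        rounds = nk + 6
        words = [list(key[4 * i:4 * i + 4]) for i in range(nk)]
        for i in range(nk, 4 * (rounds + 1)):
            temp = list(words[i - 1])
            if i % nk == 0:
                temp = temp[1:] + temp[:1]
                temp = [_SBOX[b] for b in temp]
                temp[0] ^= _RCON[i // nk - 1]
            elif nk > 6 and i % nk == 4:
                temp = [_SBOX[b] for b in temp]
            words.append([a ^ b for a, b in zip(words[i - nk], temp)])
        # group into 16-byte round keys, flattened column-major state order
        return [
            [b for word in words[4 * r:4 * r + 4] for b in word]
            for r in range(rounds + 1)
        ]

    def encrypt_block(self, block: bytes) -> bytes:
        if len(block) != 16:
            raise ValueError("AES operates on 16-byte blocks")
        s = [b ^ k for b, k in zip(block, self._round_keys[0])]
        for rnd in range(1, self._rounds):
            s = [_SBOX[b] for b in s]
            s = _shift_rows(s)
            s = _mix_columns(s)
            s = [b ^ k for b, k in zip(s, self._round_keys[rnd])]
        s = [_SBOX[b] for b in s]
        s = _shift_rows(s)
        s = [b ^ k for b, k in zip(s, self._round_keys[self._rounds])]
        return bytes(s)


def _shift_rows(s: list) -> list:
    # state is column-major: byte (row r, col c) sits at index 4*c + r
    return [
        s[0], s[5], s[10], s[15],
        s[4], s[9], s[14], s[3],
        s[8], s[13], s[2], s[7],
        s[12], s[1], s[6], s[11],
    ]


def _mix_columns(s: list) -> list:
    out = [0] * 16
    for c in range(0, 16, 4):
        a0, a1, a2, a3 = s[c], s[c + 1], s[c + 2], s[c + 3]
        t = a0 ^ a1 ^ a2 ^ a3
        out[c] = a0 ^ t ^ _XTIME[a0 ^ a1]
        out[c + 1] = a1 ^ t ^ _XTIME[a1 ^ a2]
        out[c + 2] = a2 ^ t ^ _XTIME[a2 ^ a3]
        out[c + 3] = a3 ^ t ^ _XTIME[a3 ^ a0]
    return out
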