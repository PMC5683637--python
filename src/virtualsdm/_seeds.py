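"""Deterministic seed derivation.

Every factor cell of the experiment gets its own substream seed derived by
hashing the master seed together with the factor levels, so cells are
independently reproducible and insensitive to execution order.
"""

import hashlib


def derive_seed(*parts) -> int:
    """Hash arbitrary labels into a 31-bit seed.

    Stable across processes and platforms (blake2b of the ``|``-joined
    string representations).
    """
    key = "|".join(str(p) for p in parts)
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
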