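"""Shared helpers: seed derivation and checksums."""
from __future__ import annotations

import hashlib
from pathlib import Path


def derive_seed(master, *parts):
    """Derive a stable 31-bit sub-seed from a master seed and a label path.

    Hash-based (splittable) so sub-streams are independent of the order
    in which they are drawn: regenerating one module, or processing
    proteins in a different order, never perturbs the others.
    """
    token = ":".join([str(int(master))] + [str(p) for p in parts])
    digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sha256_file(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path):
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
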