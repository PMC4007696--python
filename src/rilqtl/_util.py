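"""Shared helpers: provenance headers on output files, config hashing."""

from __future__ import annotations

import hashlib
import json


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_comments(seed, cfg_hash: str) -> list[str]:
    from . import __version__

    return [f"rilqtl v{__version__}", f"seed={seed}", f"config_hash={cfg_hash}"]


def write_csv_with_header(df, path, seed, cfg_hash: str, **to_csv_kwargs) -> None:
    """Write a CSV preceded by '#' provenance comment lines."""
    with open(path, "w") as fh:
        for c in provenance_comments(seed, cfg_hash):
            fh.write(f"# {c}\n")
        df.to_csv(fh, index=False, **to_csv_kwargs)
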