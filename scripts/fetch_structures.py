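#!/usr/bin/env python
"""Download the deposited PDB entries the crystal-structure tests use.

Places lowercase ``<id>.pdb`` files under ``data/structures/``.  Requires
network access to files.rcsb.org; the entries themselves are not
redistributable inside this repository.

    python scripts/fetch_structures.py [6rb2 3n8g 1t5t 4h1w]
"""

import sys
import urllib.request
from pathlib import Path

DEFAULT_ENTRIES = ("3n8g", "6rb2", "1t5t", "4h1w")
URL = "https://files.rcsb.org/download/{}.pdb"
DEST = Path(__file__).resolve().parent.parent / "data" / "structures"


def fetch(entry_id: str) -> Path:
    entry_id = entry_id.lower()
    DEST.mkdir(parents=True, exist_ok=True)
    target = DEST / f"{entry_id}.pdb"
    if target.exists():
        print(f"{target} already present")
        return target
    url = URL.format(entry_id.upper())
    print(f"fetching {url} -> {target}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        target.write_bytes(resp.read())
    return target


if __name__ == "__main__":
    entries = sys.argv[1:] or DEFAULT_ENTRIES
    for entry in entries:
        fetch(entry)
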