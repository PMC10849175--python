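"""Convenience download of PDB entries by accession (integration example).

Used by the worked lysozyme example, which needs the experimental
structure 134L from the RCSB archive.  Network access is required; the
rest of the package works fully offline.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request

from .core import SgedError

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_pdb(pdb_id: str, dest_dir: str = ".", timeout: float = 30.0) -> str:
    """Download ``<pdb_id>.pdb`` into ``dest_dir`` and return its path.

    Raises :class:`SgedError` when the entry cannot be retrieved (no
    network, unknown accession).
    """
    pdb_id = pdb_id.upper()
    dest = os.path.join(dest_dir, f"{pdb_id.lower()}.pdb")
    if os.path.exists(dest):
        return dest
    url = RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise SgedError(f"could not download PDB entry {pdb_id}: {exc}") from exc
    with open(dest, "wb") as fh:
        fh.write(data)
    return dest
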