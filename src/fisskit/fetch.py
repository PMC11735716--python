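"""Optional accession download with a local cache.

Coordinate sets are fetched from the wwPDB once and cached under the user
cache directory; all tests run on packaged synthetic fixtures and never
require the network.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request

from .errors import FetchError

__all__ = ["fetch_structure", "default_cache_dir"]

_URL = "https://files.rcsb.org/download/{acc}.{ext}"


def default_cache_dir() -> str:
    base = os.environ.get("XDG_CACHE_HOME", os.path.expanduser("~/.cache"))
    return os.path.join(base, "fisskit")


def fetch_structure(
    accession: str, fmt: str = "cif", cache_dir: str | None = None,
    timeout: float = 15.0,
) -> str:
    """Return the local path of an accession, downloading it if needed."""
    if fmt not in ("cif", "pdb"):
        raise FetchError(f"unsupported format {fmt!r}")
    acc = accession.lower()
    cache_dir = cache_dir or default_cache_dir()
    os.makedirs(cache_dir, exist_ok=True)
    path = os.path.join(cache_dir, f"{acc}.{fmt}")
    if os.path.exists(path) and os.path.getsize(path) > 0:
        return path
    url = _URL.format(acc=acc.upper(), ext=fmt)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(
            f"cannot download {accession} from {url}: {exc}. "
            f"Place the file manually at {path} to proceed offline."
        ) from exc
    with open(path, "wb") as fh:
        fh.write(data)
    return path
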