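"""Shared I/O helpers: gzip-transparent text streams, atomic writes, read ids."""

from __future__ import annotations

import gzip
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import IO, Iterator


def open_text(path: str | os.PathLike, mode: str = "rt") -> IO[str]:
    """Open plain or gzip text by suffix sniffing (.gz)."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@contextmanager
def atomic_write(path: str | os.PathLike, mode: str = "wt") -> Iterator[IO[str]]:
    """Write to a temp file in the target directory, rename on success.

    A failed write never leaves a partial file at *path*.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        opener = gzip.open if path.name.endswith(".gz") else open
        with opener(tmp, mode) as handle:
            yield handle
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def fragment_id(read_id: str) -> str:
    """Fragment-level id: first whitespace token with a /1 or /2 suffix removed."""
    rid = read_id.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid
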