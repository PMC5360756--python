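"""Small reporting helpers shared across modules.

Percentages in composition tables are rounded to 2 decimals; marker
fractions and densities to 1 decimal. Values are kept unrounded
internally and rounded only at the reporting boundary.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from typing import IO, Iterator


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """Percentage ``100 * part / whole`` rounded to *ndigits* decimals."""
    if whole == 0:
        raise ValueError("percentage of a zero total is undefined")
    return round(100.0 * part / whole, ndigits)


def provenance_header(subcommand: str) -> str:
    from clovermark import __version__

    return f"# clovermark {__version__} {subcommand}"


@contextmanager
def atomic_write(path: str | os.PathLike) -> Iterator[IO[str]]:
    """Write to a temp file in the target directory, rename on success.

    Guarantees the output path is never left partially written.
    """
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".clovermark.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise
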