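"""Packaged amino-acid substitution matrices.

PAM250 (Dayhoff log-odds) drives the biochemical-similarity admission and
threshold in the surface-motif matcher; BLOSUM30 scores motif conservation
across the chains of a cluster. Both ship as plain-text files whose sha256
is pinned here so a corrupted install fails loudly rather than silently
changing scores.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib import resources

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_CHECKSUMS = {
    "PAM250.txt": "dbffe75e660f9cf7e8a61acbecebbf253dfc48449e11d7f2cab05ad955b44f81",
    "BLOSUM30.txt": "63286d5cba61f5745cc10fd1534c001b8cc4235b1f99afc1ba3f07c4fd8b7148",
}


class MatrixIntegrityError(RuntimeError):
    """A packaged matrix file does not match its pinned checksum."""


def _read_matrix(filename: str) -> dict[tuple[str, str], int]:
    data = resources.files(__package__).joinpath("data", filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _CHECKSUMS[filename]
    if digest != expected:
        raise MatrixIntegrityError(
            f"{filename}: sha256 {digest} != expected {expected}"
        )
    lines = [
        ln for ln in data.decode().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split()
    matrix: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        fields = line.split()
        row = fields[0]
        for col, value in zip(header, fields[1:]):
            matrix[(row, col)] = int(value)
    return matrix


@lru_cache(maxsize=None)
def pam250() -> dict[tuple[str, str], int]:
    """The 20x20 PAM250 log-odds matrix as a symmetric dict."""
    return _read_matrix("PAM250.txt")


@lru_cache(maxsize=None)
def blosum30() -> dict[tuple[str, str], int]:
    """The 20x20 BLOSUM30 log-odds matrix as a symmetric dict."""
    return _read_matrix("BLOSUM30.txt")


def score(matrix: dict[tuple[str, str], int], a: str, b: str) -> int:
    """Look up a substitution score; 'X' scores 0 against anything.

    Raises ValueError for characters outside the 20-letter alphabet + X.
    """
    a, b = a.upper(), b.upper()
    for c in (a, b):
        if c != "X" and c not in AMINO_ACIDS:
            raise ValueError(f"not an amino-acid code: {c!r}")
    if a == "X" or b == "X":
        return 0
    return matrix[(a, b)]
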