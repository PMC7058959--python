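"""Haplotype matrices and the ms text dialect used throughout the package.

A :class:`HaplotypeMatrix` holds 0/1 haplotypes (rows) by segregating sites
(columns) on a locus of length L bp.  Rows are ordered population A first,
then population B; within a population, consecutive blocks of k rows form
one individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeMatrix", "MsParseError", "write_ms", "read_ms"]


class MsParseError(ValueError):
    """Malformed ms input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class HaplotypeMatrix:
    """0/1 haplotypes x segregating sites with positions on [0, L)."""

    data: np.ndarray  # shape (n_haplotypes, n_sites), uint8
    positions: np.ndarray  # bp coordinates, strictly increasing
    pop_sizes: tuple[int, ...]  # haplotype counts per population, in row order
    k: int = 2  # haplotypes per individual (row-block size)
    L: float = 1_000_000.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (haplotypes x sites)")
        if self.data.shape[1] != self.positions.size:
            raise ValueError("positions length must equal the number of sites")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if sum(self.pop_sizes) != self.data.shape[0]:
            raise ValueError("pop_sizes must sum to the number of haplotype rows")

    @property
    def n_haplotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def pop(self, index: int) -> np.ndarray:
        """Row-slice of one population's haplotypes."""
        start = sum(self.pop_sizes[:index])
        return self.data[start : start + self.pop_sizes[index]]

    def pop_slice(self, index: int) -> slice:
        start = sum(self.pop_sizes[:index])
        return slice(start, start + self.pop_sizes[index])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.pop_sizes == other.pop_sizes
            and self.k == other.k
            and self.L == other.L
            and np.array_equal(self.data, other.data)
            and np.allclose(self.positions, other.positions, rtol=0, atol=1e-6 * self.L)
        )


def write_ms(matrix: HaplotypeMatrix, sink) -> None:
    """Write one record in the `segsites:/positions:` ms dialect.

    Positions are printed as fractions of L with 6 decimals; the header
    comment records haplotype counts per population, ploidy and L so that
    :func:`read_ms` can rebuild the matrix.
    """
    pops = ",".join(str(c) for c in matrix.pop_sizes)
    sink.write(
        f"# polysweep ms nhap={matrix.n_haplotypes} pops={pops} "
        f"k={matrix.k} L={matrix.L:g}\n"
    )
    sink.write("//\n")
    sink.write(f"segsites: {matrix.n_sites}\n")
    if matrix.n_sites:
        fracs = " ".join(f"{p / matrix.L:.6f}" for p in matrix.positions)
        sink.write(f"positions: {fracs}\n")
        for row in matrix.data:
            sink.write("".join("1" if x else "0" for x in row) + "\n")


def read_ms(source) -> HaplotypeMatrix:
    """Parse one ms record written by :func:`write_ms`."""
    lines = source.read().splitlines()
    pop_sizes: tuple[int, ...] | None = None
    k = 2
    L = 1_000_000.0
    i = 0
    n = len(lines)

    def fail(msg: str, lineno: int):
        raise MsParseError(msg, lineno + 1)

    # header comments
    while i < n and (lines[i].startswith("#") or not lines[i].strip()):
        if "polysweep ms" in lines[i]:
            for tok in lines[i].split():
                if tok.startswith("pops="):
                    pop_sizes = tuple(int(c) for c in tok[5:].split(","))
                elif tok.startswith("k="):
                    k = int(tok[2:])
                elif tok.startswith("L="):
                    L = float(tok[2:])
        i += 1
    if i < n and lines[i].strip() == "//":
        i += 1
    if i >= n or not lines[i].startswith("segsites:"):
        fail("expected 'segsites: S'", min(i, n - 1))
    try:
        S = int(lines[i].split(":", 1)[1])
    except ValueError:
        fail("unparseable segsites count", i)
    i += 1
    if S == 0:
        positions = np.empty(0)
        nhap = sum(pop_sizes) if pop_sizes else 0
        data = np.zeros((nhap, 0), dtype=np.uint8)
        return HaplotypeMatrix(data, positions, pop_sizes or (0,), k=k, L=L)
    if i >= n or not lines[i].startswith("positions:"):
        fail("expected 'positions:' line", min(i, n - 1))
    try:
        fracs = np.array([float(x) for x in lines[i].split(":", 1)[1].split()])
    except ValueError:
        fail("unparseable position", i)
    if fracs.size != S:
        fail(f"expected {S} positions, found {fracs.size}", i)
    i += 1
    rows = []
    while i < n and lines[i].strip():
        row = lines[i].strip()
        if len(row) != S or set(row) - {"0", "1"}:
            fail("haplotype row must be a 0/1 string of length segsites", i)
        rows.append([int(c) for c in row])
        i += 1
    if not rows:
        fail("no haplotype rows", n - 1)
    data = np.asarray(rows, dtype=np.uint8)
    if pop_sizes is None:
        pop_sizes = (data.shape[0],)
    return HaplotypeMatrix(data, fracs * L, pop_sizes, k=k, L=L)
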