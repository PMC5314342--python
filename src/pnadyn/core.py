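"""Domain types for strands, duplexes and Watson-Crick bookkeeping.

A peptide nucleic acid (PNA) strand is written N-terminus to C-terminus;
an RNA strand 5' to 3'.  In an antiparallel PNA:RNA duplex, position ``i``
counted from the PNA N-terminus pairs position ``i`` counted from the RNA
3' end.  Pair indexing is 0-based from the PNA N-terminus everywhere;
reports label pairs "PNAbase:RNAbase".

Each coarse-grained monomer carries four sites: one backbone bead and a
three-site triplet spanning the aromatic base plane (its centroid is the
base center, its normal the base-plane normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "NucleobaseSpec",
    "NUCLEOBASES",
    "StrandTopology",
    "DuplexTopology",
    "Conformation",
    "Trajectory",
    "build_duplex",
    "build_strand",
    "half_hbond_total",
    "counterion_count",
    "revcomp",
    "SITES_PER_MONOMER",
]

#: backbone bead + base-plane triplet
SITES_PER_MONOMER = 4


@dataclass(frozen=True)
class NucleobaseSpec:
    """A nucleobase code, its Watson-Crick partner and the canonical
    H-bond count of the pair (3 for G:C, 2 for A:T and A:U)."""

    code: str
    wc_partner: str
    hbond_count: int

    def __post_init__(self) -> None:
        if self.code not in "ACGTU":
            raise ValueError(f"invalid base code {self.code!r}")
        if self.hbond_count not in (2, 3):
            raise ValueError("hbond_count must be 2 or 3")


NUCLEOBASES: dict[str, NucleobaseSpec] = {
    "A": NucleobaseSpec("A", "T", 2),
    "T": NucleobaseSpec("T", "A", 2),
    "U": NucleobaseSpec("U", "A", 2),
    "G": NucleobaseSpec("G", "C", 3),
    "C": NucleobaseSpec("C", "G", 3),
}

StrandKind = Literal["pna", "gamma_pna", "rna"]


def _check_sequence(seq: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    for i, b in enumerate(seq):
        if b not in NUCLEOBASES:
            raise ValueError(f"invalid base code {b!r} at position {i}")
    return seq


def _complementary(a: str, b: str) -> bool:
    # T and U are interchangeable as partners of A
    pa = NUCLEOBASES[a].wc_partner
    return pa == b or (pa == "T" and b == "U") or (pa == "A" and b in "TU")


def revcomp(seq: str, *, rna: bool = False) -> str:
    """Reverse complement of a base string (T by default, U if ``rna``)."""
    seq = _check_sequence(seq)
    comp = []
    for b in reversed(seq):
        p = NUCLEOBASES[b].wc_partner
        if rna and p == "T":
            p = "U"
        comp.append(p)
    return "".join(comp)


@dataclass(frozen=True)
class StrandTopology:
    """Coarse-grained topology of one strand.

    Sites are numbered contiguously, ``SITES_PER_MONOMER`` per monomer and
    monomer-major, starting at ``site_offset`` (nonzero for the second
    strand of a duplex).  Within a monomer: backbone bead first, then the
    base-plane triplet.
    """

    kind: StrandKind
    sequence: str
    site_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence))
        if self.kind not in ("pna", "gamma_pna", "rna"):
            raise ValueError(f"unknown strand kind {self.kind!r}")
        if self.kind == "rna":
            # normalize T -> U on the RNA strand
            object.__setattr__(
                self, "sequence", self.sequence.replace("T", "U")
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_sites(self) -> int:
        return SITES_PER_MONOMER * self.length

    @property
    def termini(self) -> tuple[str, str]:
        return ("5'", "3'") if self.kind == "rna" else ("N-term", "C-term")

    @property
    def formal_charge_per_monomer(self) -> np.ndarray:
        """RNA carries one negative phosphodiester charge per linkage
        (length - 1 in total, assigned to monomers 1..n-1); PNA backbones
        are neutral."""
        q = np.zeros(self.length, dtype=int)
        if self.kind == "rna":
            q[1:] = -1
        return q

    def backbone_site(self, monomer: int) -> int:
        return self.site_offset + SITES_PER_MONOMER * monomer

    def plane_triplet(self, monomer: int) -> tuple[int, int, int]:
        b = self.site_offset + SITES_PER_MONOMER * monomer
        return (b + 1, b + 2, b + 3)

    def monomer_sites(self, monomer: int) -> tuple[int, ...]:
        b = self.site_offset + SITES_PER_MONOMER * monomer
        return tuple(range(b, b + SITES_PER_MONOMER))


@dataclass(frozen=True)
class DuplexTopology:
    """Antiparallel PNA:RNA duplex.

    ``pair_map`` lists ``(index_a, index_b)`` with ``index_a`` counted from
    the PNA N-terminus and ``index_b`` from the RNA 5' end; antiparallel
    order means pair ``i`` joins PNA monomer ``i`` with RNA monomer
    ``L - 1 - i``.
    """

    strand_a: StrandTopology
    strand_b: StrandTopology
    pair_map: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        seen_a = set()
        seen_b = set()
        for ia, ib in self.pair_map:
            if ia in seen_a or ib in seen_b:
                raise ValueError("pair_map is not a bijection")
            seen_a.add(ia)
            seen_b.add(ib)
            a = self.strand_a.sequence[ia]
            b = self.strand_b.sequence[ib]
            if not _complementary(a, b):
                raise ValueError(
                    f"non-complementary pair at position {ia}: {a}:{b}"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pair_map)

    @property
    def n_sites(self) -> int:
        return self.strand_a.n_sites + self.strand_b.n_sites

    def pair_label(self, i: int) -> str:
        ia, ib = self.pair_map[i]
        return f"{self.strand_a.sequence[ia]}:{self.strand_b.sequence[ib]}"

    def pair_labels(self) -> list[str]:
        return [self.pair_label(i) for i in range(self.n_pairs)]

    def pair_hbond_count(self, i: int) -> int:
        ia, _ = self.pair_map[i]
        return NUCLEOBASES[self.strand_a.sequence[ia]].hbond_count

    def strands(self) -> Iterator[StrandTopology]:
        yield self.strand_a
        yield self.strand_b


@dataclass
class Conformation:
    """Per-site coordinates in nm, optionally with an orthorhombic box."""

    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_sites, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.coordinates.copy(),
                            None if self.box is None else self.box.copy())


@dataclass
class Trajectory:
    """Time-ordered conformations with a stored-frame spacing ``dt`` (ps),
    a temperature label (K) and the seed that generated it.  ``energies``,
    when logged, holds (kinetic, potential) kJ/mol per stored frame."""

    frames: list[Conformation]
    dt: float
    temperature: float
    seed: int = 0
    energies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one frame")
        n = self.frames[0].n_sites
        for f in self.frames:
            if f.n_sites != n:
                raise ValueError("frames do not share a topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_sites, 3) array."""
        return np.stack([f.coordinates for f in self.frames])


def build_strand(seq: str, kind: StrandKind = "pna",
                 site_offset: int = 0) -> StrandTopology:
    return StrandTopology(kind=kind, sequence=seq, site_offset=site_offset)


def build_duplex(pna_seq: str, rna_seq: str) -> DuplexTopology:
    """Build an antiparallel PNA:RNA duplex from sequences.

    ``pna_seq`` is given N-terminus to C-terminus, ``rna_seq`` 5' to 3'.
    T in the RNA string is accepted and normalized to U.  Raises on length
    mismatch or any non-complementary pair (position reported).
    """
    pna = build_strand(pna_seq, "pna")
    rna = build_strand(rna_seq, "rna", site_offset=pna.n_sites)
    if pna.length != rna.length:
        raise ValueError(
            f"length mismatch: PNA {pna.length} vs RNA {rna.length}"
        )
    n = pna.length
    pair_map = tuple((i, n - 1 - i) for i in range(n))
    return DuplexTopology(strand_a=pna, strand_b=rna, pair_map=pair_map)


def half_hbond_total(duplex: DuplexTopology,
                     half: Literal["first", "second"]) -> int:
    """Total canonical Watson-Crick H-bonds in one half of an even-length
    duplex, halves split at the midpoint counted from the PNA N-terminus."""
    n = duplex.n_pairs
    if n % 2 != 0:
        raise ValueError("half_hbond_total requires an even-length duplex")
    if half == "first":
        idx = range(0, n // 2)
    elif half == "second":
        idx = range(n // 2, n)
    else:
        raise ValueError(f"half must be 'first' or 'second', got {half!r}")
    return sum(duplex.pair_hbond_count(i) for i in idx)


def counterion_count(obj: DuplexTopology | StrandTopology) -> int:
    """Number of monovalent cations needed to neutralize the formal charge
    of a strand or duplex (an RNA n-mer carries n-1 phosphodiester
    charges; PNA backbones are neutral)."""
    strands: Sequence[StrandTopology]
    if isinstance(obj, DuplexTopology):
        strands = [obj.strand_a, obj.strand_b]
    else:
        strands = [obj]
    total = sum(int(s.formal_charge_per_monomer.sum()) for s in strands)
    return -total
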