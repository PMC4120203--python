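"""In-silico restriction digestion and map / FASTA plumbing.

A restriction enzyme recognises a short nucleotide sequence (typically 4–8 bp)
and cuts the DNA at every occurrence.  Digesting a known sequence in silico
yields its ordered restriction-fragment sizes, the same representation an
optical restriction map (ORM) provides for a genome.  The conventions here
(cut placed immediately before the first base of each occurrence; occurrences
scanned left-to-right allowing overlaps; case-insensitive; ``N`` never
matches) are applied identically to the genome and to every contig, so only
fragment-size consistency between the two digests matters, never the exact
intra-site cut offset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from Bio import SeqIO

_VALID_SEQ = re.compile(r"^[ACGTN]+$")
_VALID_SITE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme, identified by its recognition sequence.

    Parameters
    ----------
    recognition:
        Recognition site, uppercase A/C/G/T, length >= 1.  A typical optical
        mapping enzyme uses a 4–8 bp site; 4-mers cut a random sequence about
        every ``4**4 = 256`` bp.
    """

    recognition: str

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        if not site or not _VALID_SITE.match(site):
            raise ValueError(
                f"invalid recognition sequence {self.recognition!r}: "
                "must be a non-empty string over A/C/G/T"
            )
        object.__setattr__(self, "recognition", site)

    def __len__(self) -> int:
        return len(self.recognition)

    def cut_positions(self, seq: str) -> list[int]:
        """0-based offsets at which this enzyme cuts ``seq``.

        The cut is placed immediately before the first base of each
        recognition-site occurrence.  Occurrences are scanned left-to-right
        and may overlap (the search restarts one base after each found start),
        so e.g. ``ACAC`` occurs twice in ``ACACAC``.
        """
        seq = _check_sequence(seq)
        site = self.recognition
        cuts: list[int] = []
        pos = seq.find(site)
        while pos != -1:
            cuts.append(pos)
            pos = seq.find(site, pos + 1)
        return cuts


def _check_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains invalid characters: {bad}")
    return seq


def digest_sequence(seq: str, enzyme: Enzyme) -> list[int]:
    """Ordered restriction-fragment sizes of ``seq`` under ``enzyme``.

    Fragment sizes are the distances between consecutive cut points plus the
    leading and trailing pieces; their sum always equals ``len(seq)``.
    Zero-length fragments are never emitted: a site starting at the first
    base contributes no leading fragment.
    """
    seq = _check_sequence(seq)
    boundaries = [c for c in enzyme.cut_positions(seq) if c != 0]
    edges = [0, *boundaries, len(seq)]
    return [b - a for a, b in zip(edges, edges[1:])]


@dataclass
class ORMap:
    """An optical restriction map: ordered fragment sizes with tolerances.

    Attributes
    ----------
    sizes:
        Ordered fragment sizes ``o_1..o_m`` in bp, all >= 1.
    stds:
        Optional per-fragment size tolerance (standard deviation, bp) used by
        the scorer; ``None`` means "use the scorer's global default".
    """

    sizes: np.ndarray
    stds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.ndim != 1 or self.sizes.size == 0:
            raise ValueError("ORMap needs a non-empty 1-d list of fragment sizes")
        if (self.sizes < 1).any():
            raise ValueError("all ORM fragment sizes must be >= 1 bp")
        if self.stds is not None:
            self.stds = np.asarray(self.stds, dtype=np.float64)
            if self.stds.shape != self.sizes.shape:
                raise ValueError("stds must have one entry per fragment")
            if (self.stds < 0).any():
                raise ValueError("stds must be non-negative")

    @property
    def m(self) -> int:
        return int(self.sizes.size)

    @property
    def total_bp(self) -> int:
        return int(self.sizes.sum())

    @classmethod
    def from_sequence(
        cls, seq: str, enzyme: Enzyme, stds: np.ndarray | None = None
    ) -> "ORMap":
        return cls(np.asarray(digest_sequence(seq, enzyme)), stds)


@dataclass
class ContigDigest:
    """Ordered restriction-fragment sizes of one contig."""

    contig_id: str
    sizes: np.ndarray

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.ndim != 1 or self.sizes.size == 0:
            raise ValueError(f"contig {self.contig_id!r}: empty fragment list")
        if (self.sizes < 1).any():
            raise ValueError(f"contig {self.contig_id!r}: fragment sizes must be >= 1")

    @property
    def n(self) -> int:
        return int(self.sizes.size)

    @property
    def total_bp(self) -> int:
        return int(self.sizes.sum())

    @classmethod
    def from_sequence(cls, contig_id: str, seq: str, enzyme: Enzyme) -> "ContigDigest":
        return cls(contig_id, np.asarray(digest_sequence(seq, enzyme)))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)`` pairs.

    Rejects empty files and duplicate record ids.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
    for rid, seq in records:
        if not seq:
            raise ValueError(f"FASTA record {rid!r} has an empty sequence")
    return records


def read_map(path: str | Path) -> ORMap:
    """Read a plain-text fragment-size map.

    Format: whitespace/newline-separated positive integers, optionally with a
    second column of per-fragment stds (every data line then has exactly two
    fields), and an optional ``# std <value>`` header line setting a global
    tolerance for all fragments.
    """
    path = Path(path)
    rows: list[list[str]] = []
    global_std: float | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].split()
                if len(fields) == 2 and fields[0].lower() == "std":
                    global_std = float(fields[1])
                continue
            rows.append(line.split())
    if not rows:
        raise ValueError(f"no fragment sizes found in {path}")
    paired = all(len(r) == 2 for r in rows)
    if paired:
        sizes = [_parse_size(r[0], path) for r in rows]
        stds: np.ndarray | None = np.array([float(r[1]) for r in rows])
    else:
        sizes = [_parse_size(tok, path) for r in rows for tok in r]
        stds = None
    if stds is None and global_std is not None:
        stds = np.full(len(sizes), global_std, dtype=np.float64)
    return ORMap(np.asarray(sizes), stds)


def _parse_size(tok: str, path: Path) -> int:
    try:
        size = int(tok)
    except ValueError as exc:
        raise ValueError(f"{path}: invalid fragment size {tok!r}") from exc
    if size < 1:
        raise ValueError(f"{path}: fragment sizes must be >= 1, got {size}")
    return size


def write_map(orm: ORMap, path: str | Path) -> None:
    """Write a map in the format :func:`read_map` accepts (round-trip safe)."""
    with open(path, "w") as fh:
        if orm.stds is None:
            for s in orm.sizes:
                fh.write(f"{int(s)}\n")
        else:
            for s, sd in zip(orm.sizes, orm.stds):
                fh.write(f"{int(s)}\t{float(sd):g}\n")
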