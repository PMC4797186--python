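"""DNA sequence container and FASTA I/O.

Sequences are plain strings over the alphabet {A, C, G, T, N}, upper-cased
on construction.  N marks masked or ambiguous positions; every windowed
operation in this package drops windows that touch an N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
#: letter -> integer code (A=0, C=1, G=2, T=3); N and anything unexpected -> -1
LETTER_CODE = {a: i for i, a in enumerate(ALPHABET)}

_VALID = set(ALPHABET) | {"N"}


@dataclass(frozen=True)
class Sequence:
    """An identified DNA string over {A, C, G, T, N}.

    Residues are upper-cased on construction; any character outside the
    five permitted symbols raises ``ValueError``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid symbols {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def l(self) -> int:
        """Sequence length (number of residues)."""
        return len(self.residues)

    def codes(self) -> np.ndarray:
        """Residues as an int8 array: A=0, C=1, G=2, T=3, N=-1."""
        arr = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        out = np.full(arr.shape, -1, dtype=np.int8)
        for letter, code in LETTER_CODE.items():
            out[arr == ord(letter)] = code
        return out


def read_fasta(path: str | Path) -> List[Sequence]:
    """Read a (multi-record) FASTA file into a list of sequences.

    Record ids must be unique; a duplicate raises ``ValueError``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seqs = [Sequence(rec.id, str(rec.seq)) for rec in records]
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids in {path}: {dupes}")
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    """Write sequences to a FASTA file."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
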