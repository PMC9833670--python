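"""Multiple-alignment container over the DNA alphabet {A,C,G,T,-,N}.

Sequences are stored as a uint8 code matrix (A=0, C=1, G=2, T=3, gap=4,
N=5) for vectorised column arithmetic; FASTA I/O goes through Biopython.
"""

from __future__ import annotations

import io
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

ALPHABET = "ACGT-N"
A, C, G, T, GAP, N = range(6)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i


class Alignment:
    """Equal-length sequences keyed by unique taxon labels."""

    def __init__(self, labels: list[str], codes: np.ndarray):
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate sequence labels")
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2 or codes.shape[0] != len(labels):
            raise ValidationError("code matrix shape does not match labels")
        if codes.size and codes.max() > N:
            raise ValidationError("character outside alphabet ACGT-N")
        self.labels = list(labels)
        self.codes = codes
        self._row = {lab: i for i, lab in enumerate(labels)}

    # -- construction -------------------------------------------------

    @classmethod
    def from_dict(cls, seqs: Mapping[str, str]) -> "Alignment":
        labels = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise ValidationError(f"ragged alignment: row lengths {sorted(lengths)}")
        rows = []
        for lab in labels:
            arr = _CODE[np.frombuffer(seqs[lab].encode(), dtype=np.uint8)]
            if (arr == 255).any():
                bad = seqs[lab][int(np.argmax(arr == 255))]
                raise ValidationError(f"invalid character {bad!r} in sequence {lab}")
            rows.append(arr)
        codes = np.vstack(rows) if rows else np.empty((0, 0), dtype=np.uint8)
        return cls(labels, codes)

    @classmethod
    def from_fasta(cls, path_or_handle) -> "Alignment":
        records = list(SeqIO.parse(path_or_handle, "fasta"))
        return cls.from_dict({r.id: str(r.seq) for r in records})

    # -- accessors ----------------------------------------------------

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.codes[self._row[label]]

    def sequence(self, label: str) -> str:
        return "".join(ALPHABET[c] for c in self.row(label))

    def __contains__(self, label: str) -> bool:
        return label in self._row

    def __len__(self) -> int:
        return len(self.labels)

    # -- output -------------------------------------------------------

    def to_fasta(self, path_or_handle) -> None:
        records = [
            SeqRecord(Seq(self.sequence(lab)), id=lab, description="")
            for lab in self.labels
        ]
        SeqIO.write(records, path_or_handle, "fasta")

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue()
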