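"""Sequence records, FASTA IO, translation and ORF finding.

Coordinate convention for the whole package: 1-based, inclusive on both
ends, matching the residue numbering used in the transporter literature
(e.g. "A47", "position 173-176"). Conversion to Python's 0-based slices
is private to each function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
#: 20 standard amino acids, plus X (unknown) and * (stop marker from translation)
IUPAC_PROTEIN = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_CODON_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
_STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)

IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class ParseError(ValueError):
    """Raised for malformed or empty sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA or protein sequence over the IUPAC alphabets."""

    id: str
    residues: str
    alphabet: str = "protein"  # {"dna", "protein"}
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = IUPAC_DNA if self.alphabet == "dna" else IUPAC_PROTEIN
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.alphabet} character(s) "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval with a strand, on some sequence."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def _infer_alphabet(residues: str) -> str:
    return "dna" if set(residues) <= IUPAC_DNA else "protein"


def read_fasta(path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into SequenceRecords.

    Residues are uppercased; order is preserved. Gap characters are
    rejected: plain records must be ungapped (use
    :func:`slc6kit.align.MultipleAlignment.from_fasta` for alignments).
    If ``alphabet`` is None it is inferred per record (a sequence whose
    letters all fall in the IUPAC DNA code set is taken as DNA).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if "-" in residues:
            raise ParseError(f"record {rec.id!r}: gap characters in plain FASTA")
        alph = alphabet or _infer_alphabet(residues)
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=residues,
                    alphabet=alph,
                    description=rec.description,
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write SequenceRecords as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _translate_codon(codon: str) -> str:
    if codon in _STOP_CODONS:
        return "*"
    aa = _CODON_TABLE.forward_table.get(codon)
    if aa is None:
        # degenerate codon: translate to the single amino acid all of its
        # expansions agree on, else X (the cloned-library context makes Ns
        # plausible, so this is not an error)
        expansions = [IUPAC_EXPANSION.get(b) for b in codon]
        if any(e is None for e in expansions):
            return "X"
        aas = {
            _translate_codon("".join(c)) for c in itertools.product(*expansions)
        }
        return aas.pop() if len(aas) == 1 else "X"
    return aa


def translate(
    dna: SequenceRecord, frame: int = 1, to_first_stop: bool = False
) -> SequenceRecord:
    """Translate a DNA record in frame 1, 2 or 3 (standard genetic code).

    Stops are emitted as '*'; with ``to_first_stop`` the product ends just
    before the first stop. Degenerate codons whose expansions disagree
    translate to X.
    """
    if dna.alphabet != "dna":
        raise ValueError("translate expects a DNA record")
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    seq = dna.residues[frame - 1 :]
    aas = []
    for i in range(0, len(seq) - 2, 3):
        aa = _translate_codon(seq[i : i + 3])
        if aa == "*" and to_first_stop:
            break
        aas.append(aa)
    if not aas:
        raise ValueError(f"record {dna.id!r}: nothing to translate in frame {frame}")
    return SequenceRecord(
        id=dna.id,
        residues="".join(aas),
        alphabet="protein",
        description=f"{dna.description} [translation frame {frame}]".strip(),
    )


_DNA_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def reverse_complement(dna: SequenceRecord) -> SequenceRecord:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, N<->N)."""
    if dna.alphabet != "dna":
        raise ValueError("reverse_complement expects a DNA record")
    rc = dna.residues.translate(_DNA_COMPLEMENT)[::-1]
    return SequenceRecord(
        id=dna.id, residues=rc, alphabet="dna", description=dna.description
    )


def _orfs_on_strand(seq: str):
    """Yield (start0, end0_exclusive, n_aa) for every ATG..stop ORF, where
    coordinates are 0-based on the given strand and include the stop codon."""
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in _STOP_CODONS:
                for s in starts:
                    yield s, i + 3, (i - s) // 3
                starts = []


def find_longest_orf(dna: SequenceRecord):
    """Locate the longest ATG..stop ORF over all six frames.

    Returns ``(Interval, protein SequenceRecord)`` where the interval is in
    forward-strand coordinates and includes the stop codon, or ``(None,
    None)`` when no complete ORF exists. Ties prefer the + strand, then the
    smallest start coordinate.
    """
    if dna.alphabet != "dna":
        raise ValueError("find_longest_orf expects a DNA record")
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    n = len(dna)
    candidates = []  # (n_aa, strand_rank, fwd_start, interval, s0, strand)
    for strand, seq in (("+", dna.residues), ("-", reverse_complement(dna).residues)):
        for s0, e0, n_aa in _orfs_on_strand(seq):
            if n_aa == 0:
                continue
            if strand == "+":
                iv = Interval(s0 + 1, e0, "+")
            else:
                iv = Interval(n - e0 + 1, n - s0, "-")
            candidates.append((-n_aa, 0 if strand == "+" else 1, iv.start, iv, s0, seq))
    if not candidates:
        return None, None
    candidates.sort(key=lambda c: c[:3])
    _, _, _, iv, s0, seq = candidates[0]
    orf_seq = seq[s0 : s0 + (len(iv) - 3)]  # stop codon excluded from product
    protein = SequenceRecord(
        id=dna.id,
        residues="".join(
            _translate_codon(orf_seq[i : i + 3]) for i in range(0, len(orf_seq), 3)
        ),
        alphabet="protein",
        description=f"{dna.description} [ORF {iv.start}-{iv.end} ({iv.strand})]".strip(),
    )
    return iv, protein
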