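"""Degenerate-primer matching and in-silico PCR amplicon prediction.

Primer bases are IUPAC codes (R, N, ...), each standing for a set of
concrete bases; a primer base matches a template base iff the template
base is in the code's expansion. The 3'-terminal ``anchor_3prime`` bases
must match exactly (polymerase extension is intolerant of 3' mismatches).
Coordinates follow the strand-specific RT-PCR convention: a hit is
reported at the 1-based forward-template coordinate of the primer's
5'-terminal base, on either strand, so the length of a product of a
forward hit at f and a reverse hit at r is simply r - f + 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .seqio import IUPAC_EXPANSION, SequenceRecord, reverse_complement


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str  # 5'->3'
    role: str  # {"forward", "reverse"}

    def __post_init__(self) -> None:
        if len(self.seq) < 10:
            raise ValueError(f"primer {self.name!r}: shorter than 10 nt")
        bad = set(self.seq) - set(IUPAC_EXPANSION)
        if bad:
            raise ValueError(f"primer {self.name!r}: invalid codes {sorted(bad)}")
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: role must be forward/reverse")

    @property
    def degeneracy(self) -> int:
        n = 1
        for b in self.seq:
            n *= len(IUPAC_EXPANSION[b])
        return n


@dataclass(frozen=True)
class PrimerHit:
    primer: Primer
    pos_5prime: int  # forward-template coordinate of the primer's 5' base
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    fwd: PrimerHit
    rev: PrimerHit

    def __post_init__(self) -> None:
        if self.fwd.strand != "+" or self.rev.strand != "-":
            raise ValueError("amplicon needs a + forward hit and a - reverse hit")
        if self.length <= 0:
            raise ValueError("non-positive amplicon length")

    @property
    def length(self) -> int:
        return self.rev.pos_5prime - self.fwd.pos_5prime + 1


def load_primers(path=None) -> dict:
    """Load primers from a 3-column TSV (name, seq, role); default is the
    bundled fixture of the published cloning / RT-PCR primers."""
    if path is None:
        text = resources.files("slc6kit.data").joinpath("primers.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    primers = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, seq, role = line.split("\t")
        primers[name] = Primer(name=name, seq=seq.upper(), role=role)
    return primers


def _base_matches(primer_base: str, template_base: str) -> bool:
    # a degenerate template base is covered only when every base it could
    # be is allowed by the primer code (conservative: N in the template
    # never satisfies an A in the primer)
    if template_base in "ACGT":
        return template_base in IUPAC_EXPANSION[primer_base]
    return set(IUPAC_EXPANSION[template_base]) <= set(
        IUPAC_EXPANSION[primer_base]
    )


def iupac_match(
    primer: Primer,
    template: SequenceRecord,
    max_mismatch: int = 0,
    anchor_3prime: int = 3,
) -> list[PrimerHit]:
    """All annealing sites of a degenerate primer on both template strands.

    Degenerate *template* bases count as mismatches unless the primer code
    covers them (conservative: an N in the template never satisfies an A in
    the primer). Hits are sorted by position; minus-strand positions are
    the forward-template coordinate of the primer's 5' base.
    """
    k = len(primer.seq)
    n = len(template)
    if k > n:
        raise ValueError(
            f"primer {primer.name!r} ({k} nt) longer than template ({n} nt)"
        )
    hits = []
    fwd = template.residues
    for s in range(n - k + 1):
        window = fwd[s : s + k]
        mm = sum(
            not _base_matches(p, t) for p, t in zip(primer.seq, window)
        )
        if mm > max_mismatch:
            continue
        if anchor_3prime > 0 and any(
            not _base_matches(p, t)
            for p, t in zip(primer.seq[-anchor_3prime:], window[-anchor_3prime:])
        ):
            continue
        hits.append(PrimerHit(primer, s + 1, "+", mm))
    # minus strand: primer anneals to the reverse complement; its footprint
    # on the forward template is the revcomp of the primer, 5' base at the
    # rightmost footprint coordinate
    rc = reverse_complement(
        SequenceRecord(id="p", residues=primer.seq, alphabet="dna")
    ).residues
    for s in range(n - k + 1):
        window = fwd[s : s + k]
        # rc[i] corresponds to primer base k-1-i; compare in primer space
        mm = sum(not _base_matches(p, t) for p, t in zip(rc, window))
        if mm > max_mismatch:
            continue
        # primer 3' end sits at the left edge of the footprint
        if anchor_3prime > 0 and any(
            not _base_matches(p, t)
            for p, t in zip(rc[:anchor_3prime], window[:anchor_3prime])
        ):
            continue
        hits.append(PrimerHit(primer, s + k, "-", mm))
    hits.sort(key=lambda h: (h.pos_5prime, h.strand))
    return hits


def predict_amplicons(
    fwd: Primer,
    rev: Primer,
    template: SequenceRecord,
    max_len: int = 5000,
    max_mismatch: int = 0,
    anchor_3prime: int = 3,
) -> list[Amplicon]:
    """All products of a forward/reverse primer pair, sorted by length.

    A product pairs a +-strand hit of the forward primer with a --strand
    hit of the reverse primer downstream of it, with
    0 < length <= ``max_len``.
    """
    fwd_hits = [
        h for h in iupac_match(fwd, template, max_mismatch, anchor_3prime)
        if h.strand == "+"
    ]
    rev_hits = [
        h for h in iupac_match(rev, template, max_mismatch, anchor_3prime)
        if h.strand == "-"
    ]
    out = []
    for fh in fwd_hits:
        for rh in rev_hits:
            length = rh.pos_5prime - fh.pos_5prime + 1
            if 0 < length <= max_len:
                out.append(Amplicon(fwd=fh, rev=rh))
    out.sort(key=lambda a: (a.length, a.fwd.pos_5prime))
    return out


def amplicon_length_from_coords(fwd_pos: int, rev_pos: int) -> int:
    """Product length from the 5'-base coordinates of the two primers.

    This is the pure coordinate arithmetic behind primer names like
    For_293/Rev_684: both coordinates refer to 5' bases on the forward
    template, so the product spans rev_pos - fwd_pos + 1 nucleotides
    (293, 684 -> 392 bp).
    """
    if rev_pos < fwd_pos:
        raise ValueError(
            f"reverse 5' coordinate {rev_pos} upstream of forward {fwd_pos}"
        )
    return rev_pos - fwd_pos + 1


def primer_coordinate_from_name(name: str) -> int:
    """Parse the 5'-base cDNA coordinate encoded in For_#/Rev_# names."""
    try:
        return int(name.rsplit("_", 1)[1])
    except (IndexError, ValueError):
        raise ValueError(f"primer name {name!r} does not encode a coordinate")
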