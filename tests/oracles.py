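"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation paths they
check: alignment scores come from enumerating every gapped alignment,
primer hits from expanding every concrete realization of a degenerate
primer, ORFs from an exhaustive start/stop scan, and so on.
"""

from __future__ import annotations

import itertools

# --- alignment: enumerate every global alignment of a, b -------------------


def _alignment_score(cols, score_fn, gap_open, gap_extend):
    total = 0.0
    prev = None  # which row was gapped in the previous column
    for x, y in cols:
        if x == "-":
            total -= gap_open if prev != "a" else gap_extend
            prev = "a"
        elif y == "-":
            total -= gap_open if prev != "b" else gap_extend
            prev = "b"
        else:
            total += score_fn(x, y)
            prev = None
    return total


def enumerate_alignments(a: str, b: str):
    """Yield every gapped global alignment (no double-gap columns) as a
    list of (x, y) columns."""
    if not a and not b:
        yield []
        return
    if a and b:
        for rest in enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest
    if a:
        for rest in enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest


def best_alignment_score(a, b, score_fn, gap_open, gap_extend):
    """Optimal affine-gap score by exhaustive enumeration (gap of length k
    costs open + (k-1)*extend)."""
    return max(
        _alignment_score(cols, score_fn, gap_open, gap_extend)
        for cols in enumerate_alignments(a, b)
    )


# --- ORF scan --------------------------------------------------------------

STOPS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_plain(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def all_orfs(dna: str):
    """Every ATG..stop ORF over six frames as
    (n_aa, strand_rank, fwd_start, fwd_end, strand)."""
    n = len(dna)
    out = []
    for strand, seq in (("+", dna), ("-", revcomp_plain(dna))):
        for start in range(n - 2):
            if seq[start : start + 3] != "ATG":
                continue
            for stop in range(start + 3, n - 2, 3):
                codon = seq[stop : stop + 3]
                if codon in STOPS:
                    n_aa = (stop - start) // 3
                    if strand == "+":
                        s, e = start + 1, stop + 3
                    else:
                        s, e = n - (stop + 3) + 1, n - start
                    out.append((n_aa, 0 if strand == "+" else 1, s, e, strand))
                    break
    return out


def longest_orf(dna: str):
    orfs = [o for o in all_orfs(dna) if o[0] > 0]
    if not orfs:
        return None
    return min(orfs, key=lambda o: (-o[0], o[1], o[2]))


# --- degenerate primer expansion -------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand_primer(seq: str):
    return ["".join(p) for p in itertools.product(*(IUPAC[b] for b in seq))]


def primer_hits_bruteforce(primer_seq, template, max_mismatch, anchor):
    """(pos_5prime, strand, mismatches) hits by expanding every concrete
    primer and taking, per window, the best concrete realization."""
    k = len(primer_seq)
    concretes = expand_primer(primer_seq)
    hits = []
    for s in range(len(template) - k + 1):
        window = template[s : s + k]
        best = None
        for c in concretes:
            mm = sum(x != y for x, y in zip(c, window))
            anchor_ok = c[-anchor:] == window[-anchor:] if anchor else True
            if anchor_ok and (best is None or mm < best):
                best = mm
        if best is not None and best <= max_mismatch:
            hits.append((s + 1, "+", best))
    rc_concretes = [revcomp_plain(c) for c in concretes]
    for s in range(len(template) - k + 1):
        window = template[s : s + k]
        best = None
        for c in rc_concretes:
            mm = sum(x != y for x, y in zip(c, window))
            anchor_ok = c[:anchor] == window[:anchor] if anchor else True
            if anchor_ok and (best is None or mm < best):
                best = mm
        if best is not None and best <= max_mismatch:
            hits.append((s + k, "-", best))
    return sorted(hits)


# --- ion-dependence rule table ---------------------------------------------


def ion_call_oracle(na1_statuses, cl_statuses):
    """Independent statement of the classification rules."""
    if all(s in ("identical", "similar") for s in na1_statuses):
        na = "dependent"
    else:
        na = "undetermined"
    if "unaligned" in cl_statuses:
        cl = "undetermined"
    elif all(s == "identical" for s in cl_statuses):
        cl = "dependent"
    else:
        cl = "independent_candidate"
    return na, cl


# --- average residue masses (independent table) ----------------------------

AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER = 18.0153


def mass_oracle(protein: str) -> float:
    return sum(AVERAGE_RESIDUE_MASS[a] for a in protein) + WATER
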