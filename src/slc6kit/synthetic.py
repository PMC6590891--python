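"""Synthetic data generators with known ground truth.

Every downstream stage of the characterization pipeline is testable
offline against constructions from this module:

* protein families evolved on a (random or supplied) tree under a
  Poisson substitution process with planted invariant columns — the
  conservation structure that binding-site projection and the pocket
  report assume;
* membrane proteins with planted TM segments, sequons and cysteines —
  the 12-TM architecture the hydropathy annotator is pointed at;
* DNA templates with embedded, possibly degenerate-matching, primer
  sites — the strand-specific RT-PCR design.

Generators are pure functions of their seed (bit-identical reruns) and
return a truth record sufficient for exact recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .insilico_pcr import Primer
from .phylo import SupportedTree
from .seqio import IUPAC_EXPANSION, Interval, SequenceRecord, reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Narrow composition alphabets for the membrane-protein generator, chosen
# so the hydropathy contrast at TM boundaries is sharp: TM cores are
# strongly hydrophobic with low within-set KD variance (I 4.5, V 4.2,
# L 3.8) and loops mildly hydrophilic with near-zero variance (S -0.8,
# T -0.7). Both sets sit inside the KD >= 1.8 / KD <= -0.4 envelopes.
TM_ALPHABET = "IVL"
LOOP_ALPHABET = "ST"
#: keep planted sequons/cysteines this far from any TM boundary so they
#: cannot perturb boundary windows of the hydropathy caller
BOUNDARY_GUARD = 10


def random_tree(
    n_taxa: int, seed: int = 0, length_scale: float = 0.1
) -> SupportedTree:
    """Random bifurcating topology by uniform coalescent-style joins, with
    exponential branch lengths (mean ``length_scale``, expected
    substitutions/site). Deterministic per seed."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(
        [f"T{i + 1}" for i in range(n_taxa)]
    )
    lineages = [dendropy.Node(taxon=t) for t in tns]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = dendropy.Node()
        for child in (lineages[i], lineages[j]):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(length_scale))
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=lineages[0])
    tree.is_rooted = True
    return SupportedTree(tree)


@dataclass(frozen=True)
class FamilyConfig:
    n_taxa: int = 8
    tree: SupportedTree | None = None  # random_tree(n_taxa, seed) if None
    root_seq: str | None = None
    length: int = 300
    invariant_columns: frozenset = frozenset()
    seed: int = 0
    length_scale: float = 0.1

    def __post_init__(self) -> None:
        L = len(self.root_seq) if self.root_seq else self.length
        bad = [c for c in self.invariant_columns if not 1 <= c <= L]
        if bad:
            raise ValueError(f"invariant columns out of range: {sorted(bad)}")


@dataclass(frozen=True)
class FamilyTruth:
    tree: SupportedTree
    root_seq: str
    invariant_columns: frozenset
    leaf_ids: tuple


def simulate_family(config: FamilyConfig):
    """Evolve a protein family on a tree.

    Substitution events per site per branch are Poisson(branch length);
    each event replaces the residue with a uniform draw from the other 19
    amino acids. Planted invariant columns are never substituted. Returns
    ``(records, FamilyTruth)`` with leaves in taxon order.
    """
    rng = np.random.default_rng(config.seed)
    st = config.tree or random_tree(config.n_taxa, config.seed, config.length_scale)
    if config.root_seq:
        root = np.array([AA20.index(a) for a in config.root_seq], dtype=np.int64)
    else:
        root = rng.integers(0, 20, size=config.length)
    L = len(root)
    mutable = np.array(
        [i for i in range(L) if (i + 1) not in config.invariant_columns],
        dtype=np.int64,
    )
    seqs: dict[int, np.ndarray] = {id(st.tree.seed_node): root}
    records = []
    for node in st.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_seq = seqs[id(node.parent_node)]
        seq = parent_seq.copy()
        b = node.edge.length or 0.0
        if b > 0 and len(mutable):
            k = rng.poisson(b, size=len(mutable))
            for site_idx in np.nonzero(k)[0]:
                site = mutable[site_idx]
                for _ in range(int(k[site_idx])):
                    # uniform over the 19 non-current residues
                    step = int(rng.integers(1, 20))
                    seq[site] = (seq[site] + step) % 20
        seqs[id(node)] = seq
        if node.is_leaf():
            records.append(
                SequenceRecord(
                    id=node.taxon.label,
                    residues="".join(AA20[i] for i in seq),
                    alphabet="protein",
                )
            )
    truth = FamilyTruth(
        tree=st,
        root_seq="".join(AA20[i] for i in root),
        invariant_columns=frozenset(config.invariant_columns),
        leaf_ids=tuple(r.id for r in records),
    )
    return records, truth


@dataclass(frozen=True)
class MembraneProteinSpec:
    n_tm: int = 12
    tm_len: int = 25
    loop_lens: tuple | None = None  # n_tm + 1 entries; default all 25
    sequon_positions: tuple = ()  # 1-based N positions, inside loops
    cys_positions: tuple = ()  # 1-based, inside loops
    seed: int = 0

    def resolved_loop_lens(self) -> tuple:
        if self.loop_lens is not None:
            if len(self.loop_lens) != self.n_tm + 1:
                raise ValueError(
                    f"need {self.n_tm + 1} loop lengths, got {len(self.loop_lens)}"
                )
            return tuple(self.loop_lens)
        return tuple([25] * (self.n_tm + 1))


@dataclass(frozen=True)
class MembraneTruth:
    tm_intervals: tuple
    loop_intervals: tuple
    sequons: tuple  # 3-residue Intervals
    cysteines: tuple
    length: int


def default_membrane_spec(seed: int = 0) -> MembraneProteinSpec:
    """The study-like architecture: 12 TM helices with a large loop between
    TM3 and TM4 (the extracellular EL2 analogue) carrying two sequons and a
    three-cysteine cluster."""
    n_tm, tm_len = 12, 25
    loop_lens = tuple(61 if k == 3 else 25 for k in range(n_tm + 1))
    # locate the enlarged loop between TM3 and TM4 (loop index 3)
    pos = sum(loop_lens[:3]) + 3 * tm_len
    loop3 = (pos + 1, pos + loop_lens[3])
    mid = (loop3[0] + loop3[1]) // 2
    return MembraneProteinSpec(
        n_tm=n_tm,
        tm_len=tm_len,
        loop_lens=loop_lens,
        sequon_positions=(mid - 5, mid + 4),
        cys_positions=(mid - 10, mid + 9, mid + 10),
        seed=seed,
    )


def make_membrane_protein(spec: MembraneProteinSpec):
    """Generate a membrane protein with planted TM/loop architecture.

    Loops and TM segments tile the sequence (loop0, TM1, loop1, ..., TMn,
    loopn). Sequons (spliced as N-G-[S/T]) and cysteines must fall inside
    loops; a decoration inside a TM region is an error, and decorations
    are kept ``BOUNDARY_GUARD`` residues clear of TM boundaries so the
    planted hydropathy architecture is preserved exactly.
    """
    rng = np.random.default_rng(spec.seed)
    loop_lens = spec.resolved_loop_lens()
    if spec.n_tm < 1 or spec.tm_len < 1 or any(l < 1 for l in loop_lens):
        raise ValueError("regions must have positive length")
    chunks = []
    tm_intervals = []
    loop_intervals = []
    pos = 0
    for k in range(spec.n_tm):
        loop_intervals.append(Interval(pos + 1, pos + loop_lens[k]))
        chunks.append(
            "".join(rng.choice(list(LOOP_ALPHABET), size=loop_lens[k]))
        )
        pos += loop_lens[k]
        tm_intervals.append(Interval(pos + 1, pos + spec.tm_len))
        chunks.append("".join(rng.choice(list(TM_ALPHABET), size=spec.tm_len)))
        pos += spec.tm_len
    loop_intervals.append(Interval(pos + 1, pos + loop_lens[-1]))
    chunks.append("".join(rng.choice(list(LOOP_ALPHABET), size=loop_lens[-1])))
    pos += loop_lens[-1]
    seq = list("".join(chunks))
    length = len(seq)

    def _in_tm(p: int) -> bool:
        return any(iv.contains(p) for iv in tm_intervals)

    def _check_guard(p: int, what: str) -> None:
        for iv in tm_intervals:
            if abs(p - iv.start) < BOUNDARY_GUARD or abs(p - iv.end) < BOUNDARY_GUARD:
                raise ValueError(
                    f"{what} at {p} within {BOUNDARY_GUARD} residues of a TM "
                    "boundary; it would perturb the planted hydropathy "
                    "architecture"
                )

    sequons = []
    for p in spec.sequon_positions:
        if p < 1 or p + 2 > length:
            raise ValueError(f"sequon at {p} outside sequence")
        if any(_in_tm(q) for q in (p, p + 1, p + 2)):
            raise ValueError(f"sequon requested inside a TM region (position {p})")
        _check_guard(p, "sequon")
        _check_guard(p + 2, "sequon")
        seq[p - 1] = "N"
        seq[p] = "G"
        seq[p + 1] = str(rng.choice(["S", "T"]))
        sequons.append(Interval(p, p + 2))
    for p in spec.cys_positions:
        if p < 1 or p > length:
            raise ValueError(f"cysteine at {p} outside sequence")
        if _in_tm(p):
            raise ValueError(f"cysteine requested inside a TM region (position {p})")
        _check_guard(p, "cysteine")
        seq[p - 1] = "C"
    record = SequenceRecord(
        id=f"synthetic_membrane_{spec.seed}",
        residues="".join(seq),
        alphabet="protein",
        description=f"synthetic {spec.n_tm}-TM membrane protein",
    )
    truth = MembraneTruth(
        tm_intervals=tuple(tm_intervals),
        loop_intervals=tuple(loop_intervals),
        sequons=tuple(sequons),
        cysteines=tuple(spec.cys_positions),
        length=length,
    )
    return record, truth


@dataclass(frozen=True)
class PlantedPrimer:
    primer: Primer
    pos_5prime: int
    strand: str
    realized: str  # concrete footprint on the forward template


def make_template_with_primers(length: int, inserts, seed: int = 0):
    """Random ACGT template with primer sites spliced in.

    ``inserts`` is a list of ``(Primer, pos_5prime, strand)``; degenerate
    primer bases are resolved uniformly at random and the concrete
    realization recorded in the truth, so downstream mismatch counts are
    exact. Footprints must not overlap.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    footprints = []
    truth = []
    for primer, pos, strand in inserts:
        k = len(primer.seq)
        if strand == "+":
            lo, hi = pos, pos + k - 1
        elif strand == "-":
            lo, hi = pos - k + 1, pos
        else:
            raise ValueError(f"bad strand {strand!r}")
        if lo < 1 or hi > length:
            raise ValueError(f"primer {primer.name!r} footprint outside template")
        for plo, phi in footprints:
            if lo <= phi and plo <= hi:
                raise ValueError("overlapping primer footprints")
        footprints.append((lo, hi))
        concrete = "".join(
            str(rng.choice(list(IUPAC_EXPANSION[b]))) for b in primer.seq
        )
        on_plus = concrete
        if strand == "-":
            on_plus = reverse_complement(
                SequenceRecord(id="p", residues=concrete, alphabet="dna")
            ).residues
        seq[lo - 1 : hi] = list(on_plus)
        truth.append(PlantedPrimer(primer, pos, strand, on_plus))
    record = SequenceRecord(
        id=f"synthetic_template_{seed}",
        residues="".join(seq),
        alphabet="dna",
        description="synthetic PCR template with planted primer sites",
    )
    return record, truth
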