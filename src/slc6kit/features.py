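"""Membrane-protein feature annotation.

Kyte-Doolittle hydropathy profiles, transmembrane (TM) segment calling,
topology labelling, N-glycosylation sequons (N-X-[S/T], X != P), cysteine
inventories and average molecular mass. This is the classic desk
characterization applied to a newly cloned SLC6 transporter: 12 TM helices,
intracellular N/C termini, a large extracellular loop (EL2) carrying
sequons and a cysteine cluster.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.ProtParamData import kd as KD_SCALE

from .seqio import Interval, SequenceRecord

_SEQUON_RE = re.compile(r"(?=(N[^P][ST]))")


@dataclass(frozen=True)
class HydropathyProfile:
    """Sliding-window mean Kyte-Doolittle hydropathy.

    ``scores[k]`` is the unweighted mean over the window centred at protein
    position ``positions[k]``; centres run from ceil(w/2) to L - floor(w/2)
    (1-based), so there are L - w + 1 scores.
    """

    window: int
    scores: np.ndarray
    length: int  # protein length the profile was computed on

    @property
    def positions(self) -> np.ndarray:
        first = self.window // 2 + 1
        return np.arange(first, first + len(self.scores))

    def score_at(self, pos: int) -> float:
        first = self.window // 2 + 1
        return float(self.scores[pos - first])


@dataclass(frozen=True)
class TMSegment:
    interval: Interval
    mean_score: float


@dataclass(frozen=True)
class Topology:
    n_term_side: str
    c_term_side: str
    loops: tuple  # ((Interval, side), ...) in N->C order; zero-length loops omitted
    largest_out_loop: Interval | None


@dataclass(frozen=True)
class TMAnnotation:
    """Full feature annotation of one membrane protein."""

    record_id: str
    profile: HydropathyProfile
    segments: tuple
    topology: Topology
    sequons: tuple
    cysteines: tuple
    mass_da: float | None

    def to_rows(self) -> list[dict]:
        rows = []
        for i, seg in enumerate(self.segments, 1):
            rows.append(
                dict(type="TM", name=f"TM{i}", start=seg.interval.start,
                     end=seg.interval.end, detail=f"mean_kd={seg.mean_score:.3f}")
            )
        for iv, side in self.topology.loops:
            rows.append(dict(type="loop", name=side, start=iv.start, end=iv.end,
                             detail=f"side={side}"))
        for iv in self.sequons:
            rows.append(dict(type="sequon", name="N-X-[ST]", start=iv.start,
                             end=iv.end, detail=""))
        for pos in self.cysteines:
            rows.append(dict(type="cysteine", name="C", start=pos, end=pos,
                             detail=""))
        if self.mass_da is not None:
            rows.append(dict(type="mass", name="average_mass_da", start=1,
                             end=self.profile.length,
                             detail=f"{self.mass_da:.1f}"))
        return rows

    def to_json(self) -> str:
        return json.dumps(
            dict(
                record_id=self.record_id,
                window=self.profile.window,
                n_tm=len(self.segments),
                segments=[[s.interval.start, s.interval.end, s.mean_score]
                          for s in self.segments],
                n_term_side=self.topology.n_term_side,
                c_term_side=self.topology.c_term_side,
                sequons=[[iv.start, iv.end] for iv in self.sequons],
                cysteines=list(self.cysteines),
                mass_da=self.mass_da,
            ),
            indent=2,
        )


def kd_profile(protein: SequenceRecord, window: int = 19) -> HydropathyProfile:
    """Sliding unweighted mean of Kyte-Doolittle residue hydropathies.

    X residues score 0. ``window`` must be odd and no longer than the
    sequence.
    """
    if protein.alphabet != "protein":
        raise ValueError("kd_profile expects a protein record")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    L = len(protein)
    if window > L:
        raise ValueError(f"window {window} longer than sequence ({L})")
    vals = np.array([KD_SCALE.get(aa, 0.0) for aa in protein.residues])
    kernel = np.ones(window) / window
    scores = np.convolve(vals, kernel, mode="valid")
    return HydropathyProfile(window=window, scores=scores, length=L)


def call_tm_segments(
    profile: HydropathyProfile,
    threshold: float = 1.6,
    min_tm_len: int = 10,
    merge_gap: int = 5,
) -> list[TMSegment]:
    """Call TM segments as maximal runs of window centres above threshold.

    Runs separated by fewer than ``merge_gap`` below-threshold positions are
    merged; merged runs shorter than ``min_tm_len`` are discarded. Segment
    intervals are reported in protein coordinates (window-centre positions)
    with the mean profile score over the run.
    """
    above = profile.scores >= threshold
    positions = profile.positions
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    segments = []
    for s, e in merged:
        if e - s + 1 < min_tm_len:
            continue
        segments.append(
            TMSegment(
                interval=Interval(int(positions[s]), int(positions[e])),
                mean_score=float(profile.scores[s : e + 1].mean()),
            )
        )
    return segments


def assign_topology(
    segments, length: int, n_term_side: str = "in"
) -> Topology:
    """Label inter-segment loops, alternating sides from the N terminus.

    With an even number of TM crossings the C terminus returns to the
    N-terminal side (the 12-TM SLC6 architecture: both termini "in", with
    the large extracellular loop EL2 between TM3 and TM4). The largest
    "out" loop strictly between two segments is reported as the EL2
    analogue.
    """
    if n_term_side not in ("in", "out"):
        raise ValueError(f"n_term_side must be 'in' or 'out', got {n_term_side!r}")
    other = {"in": "out", "out": "in"}
    if not segments:
        return Topology(n_term_side, n_term_side,
                        ((Interval(1, length), n_term_side),), None)
    loops = []
    side = n_term_side
    if segments[0].interval.start > 1:
        loops.append((Interval(1, segments[0].interval.start - 1), side))
    for prev, nxt in zip(segments, segments[1:]):
        side = other[side]
        if nxt.interval.start > prev.interval.end + 1:
            loops.append(
                (Interval(prev.interval.end + 1, nxt.interval.start - 1), side)
            )
    c_side = other[side]  # side after crossing the last segment
    if segments[-1].interval.end < length:
        loops.append((Interval(segments[-1].interval.end + 1, length), c_side))
    inner = [
        (iv, s)
        for iv, s in loops
        if s == "out"
        and iv.start > segments[0].interval.start
        and iv.end < segments[-1].interval.end
    ]
    largest_out = max(inner, key=lambda t: len(t[0]))[0] if inner else None
    return Topology(n_term_side, c_side, tuple(loops), largest_out)


def find_sequons(
    protein: SequenceRecord, region: Interval | None = None
) -> list[Interval]:
    """All N-X-[S/T] sequons with X != P, as 3-residue intervals.

    Overlapping matches are all reported. With ``region`` only motifs
    lying entirely inside the region are returned.
    """
    if protein.alphabet != "protein":
        raise ValueError("find_sequons expects a protein record")
    out = []
    for m in _SEQUON_RE.finditer(protein.residues):
        start = m.start() + 1
        iv = Interval(start, start + 2)
        if region is None or (region.contains(iv.start) and region.contains(iv.end)):
            out.append(iv)
    return out


def average_mass(protein: SequenceRecord) -> float:
    """Average (not monoisotopic) molecular mass in Da, including one water."""
    if protein.alphabet != "protein":
        raise ValueError("average_mass expects a protein record")
    if "X" in protein.residues or "*" in protein.residues:
        raise ValueError(
            f"record {protein.id!r}: mass undefined for ambiguous residues"
        )
    return float(molecular_weight(protein.residues, seq_type="protein"))


def cysteines_in_region(
    protein: SequenceRecord, region: Interval | None = None
) -> list[int]:
    """1-based positions of cysteines, optionally restricted to a region."""
    if protein.alphabet != "protein":
        raise ValueError("cysteines_in_region expects a protein record")
    return [
        i + 1
        for i, aa in enumerate(protein.residues)
        if aa == "C" and (region is None or region.contains(i + 1))
    ]


def annotate(
    protein: SequenceRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_tm_len: int = 10,
    merge_gap: int = 5,
    n_term_side: str = "in",
) -> TMAnnotation:
    """One-call feature annotation: profile, TM segments, topology, sequons
    in the largest extracellular loop context, cysteines and mass."""
    profile = kd_profile(protein, window)
    segments = tuple(call_tm_segments(profile, threshold, min_tm_len, merge_gap))
    topology = assign_topology(segments, len(protein), n_term_side)
    sequons = tuple(find_sequons(protein))
    cys = tuple(cysteines_in_region(protein))
    try:
        mass = average_mass(protein)
    except ValueError:
        mass = None
    return TMAnnotation(
        record_id=protein.id,
        profile=profile,
        segments=segments,
        topology=topology,
        sequons=sequons,
        cysteines=cys,
        mass_da=mass,
    )
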