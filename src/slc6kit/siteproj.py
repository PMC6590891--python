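"""Template binding-site projection and ion-dependence classification.

SLC6 transporters couple substrate translocation to Na+ (and usually Cl-)
gradients. The two sodium coordination sites of the LeuT fold (Na1, Na2)
and the chloride site characterized in SERT are small sets of residue
positions on the structural templates. Projecting those template positions
through a pairwise alignment onto a query sequence, and scoring each
projected residue as identical / similar (BLOSUM62 > 0) / divergent /
unaligned, supports a deterministic prediction of whether the query is a
Na+-dependent and/or Cl--dependent transporter:

* Na+ dependence is called when every Na1 residue is conserved
  (identical or similar); Na1 is the functionally indispensable site.
* Cl- dependence is called when all four SERT chloride-site residues are
  identical (the pattern of the Cl--dependent transporters SLC6A18 and
  SLC6A20); one or more non-identical residues marks the query as a
  chloride-independence candidate (the SLC6A15/17/19 pattern). A
  threonine at the SERT-S336-equivalent position is specifically flagged:
  that is the LeuT (T254) configuration believed to exclude chloride
  binding in the prokaryotic, chloride-independent transporters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .align import PairwiseAlignment, SubstitutionMatrix, MultipleAlignment, default_matrix
from .seqio import SequenceRecord

UNALIGNED = "unaligned"
STATUSES = ("identical", "similar", "divergent", UNALIGNED)


@dataclass(frozen=True)
class TemplateSiteSet:
    """Named residue-position sets on one structural template."""

    template_id: str
    sites: dict  # site_name -> tuple of (template_pos, expected_residue)

    def __post_init__(self) -> None:
        for name, entries in self.sites.items():
            positions = [p for p, _ in entries]
            if positions != sorted(positions):
                raise ValueError(f"site {name!r}: positions not ascending")
            for _, res in entries:
                if res not in "ACDEFGHIKLMNPQRSTVWY":
                    raise ValueError(f"site {name!r}: bad residue {res!r}")

    def validate_against(self, template: SequenceRecord) -> None:
        """Check the template sequence carries the expected residue at every
        site position — catches a mis-numbered template at load time."""
        for name, entries in self.sites.items():
            for pos, res in entries:
                if pos > len(template):
                    raise ValueError(
                        f"site {name!r} position {pos} beyond template "
                        f"{template.id!r} (length {len(template)})"
                    )
                actual = template.residues[pos - 1]
                if actual != res:
                    raise ValueError(
                        f"template {template.id!r} has {actual} at {pos}, "
                        f"expected {res} for site {name!r}"
                    )


@dataclass(frozen=True)
class SiteEntry:
    site_name: str
    template_pos: int
    template_res: str
    query_pos: int | None  # None = unaligned
    query_res: str | None
    status: str


@dataclass(frozen=True)
class SiteProjection:
    template_id: str
    query_id: str
    entries: tuple

    def by_site(self, site_name: str) -> list[SiteEntry]:
        return [e for e in self.entries if e.site_name == site_name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


@dataclass(frozen=True)
class IonDependenceCall:
    na1_identical: int
    na1_size: int
    na2_identical: int
    na2_size: int
    cl_conserved: int
    cl_size: int
    na_call: str  # {dependent, undetermined}
    cl_call: str  # {dependent, independent_candidate, undetermined}
    rationale: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def load_sitesets(path=None) -> dict:
    """Load bundled (or external) binding-site fixtures.

    Returns ``{template_id: TemplateSiteSet}``. The bundled file carries
    the LeuT Na1/Na2 sites, the SERT Cl site, and a provisional LeuT
    substrate-pocket set.
    """
    if path is None:
        source = resources.files("slc6kit.data").joinpath("binding_sites.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    by_template: dict[str, dict] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("template_id"):
            continue
        template_id, site_name, pos, res = line.split("\t")
        by_template.setdefault(template_id, {}).setdefault(site_name, []).append(
            (int(pos), res)
        )
    return {
        tid: TemplateSiteSet(
            template_id=tid,
            sites={name: tuple(v) for name, v in sites.items()},
        )
        for tid, sites in by_template.items()
    }


def map_positions(aln: PairwiseAlignment, template_positions) -> list[int | None]:
    """Map 1-based template (sequence A) positions to query (sequence B)
    positions by walking alignment columns with two residue counters. A
    template position aligned against a gap maps to None."""
    a_len = len(aln.a_aln.replace("-", ""))
    wanted = sorted(set(template_positions))
    for p in wanted:
        if p < 1 or p > a_len:
            raise ValueError(f"template position {p} out of range 1..{a_len}")
    mapping: dict[int, int | None] = {}
    ti = qi = 0
    for x, y in zip(aln.a_aln, aln.b_aln):
        if x != "-":
            ti += 1
        if y != "-":
            qi += 1
        if x != "-" and ti in mapping:
            continue
        if x != "-" and ti in wanted and ti not in mapping:
            mapping[ti] = qi if y != "-" else None
    return [mapping[p] for p in template_positions]


def project_sites(
    siteset: TemplateSiteSet,
    aln: PairwiseAlignment,
    matrix: SubstitutionMatrix | None = None,
) -> SiteProjection:
    """Project every site residue of the template (sequence A of ``aln``)
    onto the query (sequence B) with a conservation status per entry."""
    matrix = matrix or default_matrix()
    a_seq, b_seq = aln.degapped()
    entries = []
    for site_name, site in siteset.sites.items():
        positions = [p for p, _ in site]
        mapped = map_positions(aln, positions)
        for (pos, t_res), q_pos in zip(site, mapped):
            actual = a_seq[pos - 1]
            if actual != t_res:
                raise ValueError(
                    f"template residue mismatch at {pos}: sequence has "
                    f"{actual}, siteset expects {t_res}"
                )
            if q_pos is None:
                entries.append(
                    SiteEntry(site_name, pos, t_res, None, None, UNALIGNED)
                )
                continue
            q_res = b_seq[q_pos - 1]
            if q_res == t_res:
                status = "identical"
            elif matrix.score(t_res, q_res) > 0:
                status = "similar"
            else:
                status = "divergent"
            entries.append(SiteEntry(site_name, pos, t_res, q_pos, q_res, status))
    return SiteProjection(
        template_id=siteset.template_id, query_id=aln.b_id, entries=tuple(entries)
    )


def classify_ion_dependence(
    projection: SiteProjection,
    na1_site: str = "Na1",
    na2_site: str = "Na2",
    cl_site: str = "Cl",
    cl_projection: SiteProjection | None = None,
) -> IonDependenceCall:
    """Deterministic ion-dependence call from projection statuses.

    The chloride site may live on a different template (SERT) than the
    sodium sites (LeuT); pass its projection as ``cl_projection`` (defaults
    to the same projection).
    """
    cl_projection = cl_projection or projection
    na1 = projection.by_site(na1_site)
    na2 = projection.by_site(na2_site)
    cl = cl_projection.by_site(cl_site)
    for name, group in ((na1_site, na1), (na2_site, na2), (cl_site, cl)):
        if not group:
            raise ValueError(f"projection has no entries for site {name!r}")

    na1_ident = sum(e.status == "identical" for e in na1)
    na2_ident = sum(e.status == "identical" for e in na2)
    cl_ident = sum(e.status == "identical" for e in cl)

    if all(e.status in ("identical", "similar") for e in na1):
        na_call = "dependent"
        na_note = (
            f"all {len(na1)} Na1 residues conserved "
            f"({na1_ident} identical); Na2 {na2_ident}/{len(na2)} identical"
        )
    else:
        na_call = "undetermined"
        na_note = "Na1 site not fully conserved or not fully aligned"

    if any(e.status == UNALIGNED for e in cl):
        cl_call = "undetermined"
        cl_note = "chloride-site residues unaligned"
    elif cl_ident == len(cl):
        cl_call = "dependent"
        cl_note = "all chloride-site residues identical (SLC6A18/A20 pattern)"
    else:
        cl_call = "independent_candidate"
        cl_note = (
            f"{len(cl) - cl_ident} non-identical chloride-site residue(s) "
            "(SLC6A15/17/19 pattern)"
        )
        thr = [
            e for e in cl
            if e.template_res == "S" and e.query_res == "T"
        ]
        if thr:
            pos_list = ", ".join(
                f"query {e.query_pos} (template S{e.template_pos})" for e in thr
            )
            cl_note += (
                f"; threonine at the SERT-S336-equivalent position ({pos_list}),"
                " the LeuT-like configuration thought to exclude Cl- binding"
            )
    return IonDependenceCall(
        na1_identical=na1_ident, na1_size=len(na1),
        na2_identical=na2_ident, na2_size=len(na2),
        cl_conserved=cl_ident, cl_size=len(cl),
        na_call=na_call, cl_call=cl_call,
        rationale=f"Na+: {na_note}. Cl-: {cl_note}.",
    )


def pocket_conservation_report(
    siteset: TemplateSiteSet,
    msa: MultipleAlignment,
    site_name: str = "pocket",
    consensus: dict | None = None,
) -> pd.DataFrame:
    """Per-sequence agreement with the consensus at substrate-pocket columns.

    The template row of the MSA anchors the pocket positions to alignment
    columns. The consensus residue per column is the modal residue over all
    rows (ties broken alphabetically) unless supplied. Returns a tidy frame
    with one row per (sequence, pocket column): the pocket columns ranked
    by conservation plus a per-sequence match count is derivable by the
    caller via groupby; a summary ``n_match`` column per sequence is
    included for convenience.
    """
    if siteset.template_id not in msa.ids:
        raise ValueError(f"template row {siteset.template_id!r} absent from MSA")
    site = siteset.sites.get(site_name)
    if site is None:
        raise ValueError(f"siteset has no site {site_name!r}")
    trow = msa.row(siteset.template_id)
    # template residue index -> alignment column
    col_of: dict[int, int] = {}
    ti = 0
    for j, ch in enumerate(trow):
        if ch != "-":
            ti += 1
            col_of[ti] = j
    records = []
    col_conservation = {}
    for pos, t_res in site:
        if pos not in col_of:
            raise ValueError(f"pocket position {pos} beyond template row")
        j = col_of[pos]
        column = msa.column(j)
        if trow[j] != t_res:
            raise ValueError(
                f"template residue mismatch at pocket position {pos}: "
                f"alignment has {trow[j]}, siteset expects {t_res}"
            )
        if consensus is not None and pos in consensus:
            cons = consensus[pos]
        else:
            residues = [c for c in column if c != "-"]
            counts = {}
            for c in residues:
                counts[c] = counts.get(c, 0) + 1
            cons = min(sorted(counts), key=lambda c: -counts[c])
        n_agree = sum(c == cons for c in column)
        col_conservation[pos] = n_agree / msa.n_rows
        for rid, res in zip(msa.ids, column):
            records.append(
                dict(seq_id=rid, template_pos=pos, template_res=t_res,
                     consensus=cons, residue=res, match=res == cons)
            )
    df = pd.DataFrame(records)
    df["column_conservation"] = df["template_pos"].map(col_conservation)
    df["conservation_rank"] = (
        df["template_pos"]
        .map({p: r + 1 for r, p in enumerate(
            sorted(col_conservation, key=lambda p: (-col_conservation[p], p))
        )})
    )
    n_match = df.groupby("seq_id", sort=False)["match"].sum()
    df["n_match"] = df["seq_id"].map(n_match)
    return df
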