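"""End-to-end characterization: annotate -> align -> project -> tree -> pcr.

Each stage writes one report file; a stage whose inputs are absent is
skipped with a logged warning, and any stage failure is recorded in the
manifest while the remaining stages still run. Reports are deterministic
given the same inputs, config and seed, and every report carries the
effective config for provenance (schema version 1).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import align as al
from . import features as ft
from . import insilico_pcr as pcr
from . import phylo
from . import siteproj as sp
from .config import PipelineConfig
from .seqio import read_fasta

SCHEMA_VERSION = 1
log = logging.getLogger("slc6kit")


def _config_header(config: PipelineConfig) -> str:
    items = " ".join(f"{k}={v}" for k, v in sorted(config.to_dict().items()))
    return f"# slc6kit report schema={SCHEMA_VERSION} {items}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        df.to_csv(fh, sep="\t", index=False)


def _write_json(payload: dict, path: Path, config: PipelineConfig) -> None:
    payload = dict(payload)
    payload["schema"] = SCHEMA_VERSION
    payload["config"] = config.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_characterization(
    query_fasta,
    out_dir,
    config: PipelineConfig | None = None,
    templates_fasta=None,
    siteset_path=None,
    family_fasta=None,
    labels_path=None,
    template_dna_fasta=None,
    fwd_primer: str | None = None,
    rev_primer: str | None = None,
) -> dict:
    """Run every applicable stage; return the manifest (also written as
    ``manifest.json``). Stages with missing optional inputs are skipped."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = al.SubstitutionMatrix.load(config.matrix)
    manifest: dict = {"stages": {}, "outputs": []}

    def record(stage: str, status: str, message: str = "", output: str | None = None):
        manifest["stages"][stage] = {"status": status, "message": message}
        if output:
            manifest["outputs"].append(output)
        if status == "error":
            log.error("%s: %s", stage, message)
        elif status == "skipped":
            log.warning("%s skipped: %s", stage, message)

    query = read_fasta(query_fasta, alphabet="protein")[0]

    # --- feature annotation -------------------------------------------------
    try:
        ann = ft.annotate(
            query,
            window=config.window,
            threshold=config.threshold,
            min_tm_len=config.min_tm_len,
            merge_gap=config.merge_gap,
            n_term_side=config.n_term_side,
        )
        _write_tsv(pd.DataFrame(ann.to_rows()), out / "features.tsv", config)
        record("annotate", "ok", output="features.tsv")
    except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
        record("annotate", "error", str(exc))

    # --- homology statistics ------------------------------------------------
    templates = []
    if templates_fasta:
        try:
            templates = read_fasta(templates_fasta, alphabet="protein")
            rows = []
            alignments = {}
            for t in templates:
                pa = al.global_align(t, query, matrix, config.gap_open,
                                     config.gap_extend)
                alignments[t.id] = pa
                stats = al.similarity_stats(pa, matrix, config.denominator)
                rows.append(dict(
                    template=t.id, query=query.id, score=pa.score,
                    pct_identity=round(stats.pct_identity, 2),
                    pct_similarity=round(stats.pct_similarity, 2),
                    n_columns_scored=stats.n_columns_scored,
                ))
            _write_tsv(pd.DataFrame(rows), out / "similarity.tsv", config)
            record("align", "ok", output="similarity.tsv")
        except Exception as exc:
            alignments = {}
            record("align", "error", str(exc))
    else:
        alignments = {}
        record("align", "skipped", "no template sequences supplied")

    # --- binding-site projection -------------------------------------------
    if templates and (siteset_path or True):
        try:
            sitesets = sp.load_sitesets(siteset_path)
            usable = [t for t in templates if t.id in sitesets]
            if not usable:
                record("project", "skipped",
                       "no template matches a siteset id")
            else:
                frames = []
                projections = {}
                for t in usable:
                    proj = sp.project_sites(sitesets[t.id], alignments[t.id],
                                            matrix)
                    projections[t.id] = proj
                    frames.append(proj.to_frame().assign(template=t.id))
                _write_tsv(pd.concat(frames, ignore_index=True),
                           out / "site_projection.tsv", config)
                na_proj = next(
                    (p for p in projections.values()
                     if p.by_site("Na1") and p.by_site("Na2")), None)
                cl_proj = next(
                    (p for p in projections.values() if p.by_site("Cl")), None)
                if na_proj and cl_proj:
                    call = sp.classify_ion_dependence(
                        na_proj, cl_projection=cl_proj)
                    _write_json(call.__dict__, out / "ion_dependence.json",
                                config)
                    record("project", "ok", output="site_projection.tsv")
                    manifest["outputs"].append("ion_dependence.json")
                else:
                    record("project", "ok",
                           "projection written; Na/Cl sitesets incomplete, "
                           "no ion-dependence call", "site_projection.tsv")
        except Exception as exc:
            record("project", "error", str(exc))
    else:
        record("project", "skipped", "no templates for site projection")

    # --- phylogenetic placement ---------------------------------------------
    if family_fasta:
        try:
            family = read_fasta(family_fasta, alphabet="protein")
            if len(family) < 3:
                record("tree", "skipped",
                       f"family has {len(family)} sequences; need >= 3")
            else:
                seqs = family if any(s.id == query.id for s in family) \
                    else [query] + family
                msa = al.progressive_msa(seqs, matrix, config.gap_open,
                                         config.gap_extend)
                msa = al.trim_termini(msa, config.min_occupancy)
                st = phylo.bootstrap_support(
                    msa, n_reps=config.bootstrap_reps, seed=config.seed,
                    model=config.distance_model)
                payload = {}
                if labels_path:
                    labels = phylo.read_label_map(labels_path)
                    outgroup = [t for t, l in labels.items()
                                if l == "outgroup" and t in msa.ids]
                    if outgroup:
                        st = phylo.root_by_outgroup(st, outgroup)
                    assign = phylo.cluster_assignment(st, labels)
                    payload = dict(
                        query=assign.query, cluster=assign.label,
                        sister_taxa=list(assign.sister_taxa),
                        is_nested=assign.is_nested,
                    )
                (out / "tree.nwk").write_text(st.newick() + "\n")
                manifest["outputs"].append("tree.nwk")
                if payload:
                    _write_json(payload, out / "assignment.json", config)
                    manifest["outputs"].append("assignment.json")
                record("tree", "ok")
        except Exception as exc:
            record("tree", "error", str(exc))
    else:
        record("tree", "skipped", "no family sequences supplied")

    # --- in-silico PCR -------------------------------------------------------
    if template_dna_fasta and fwd_primer and rev_primer:
        try:
            template = read_fasta(template_dna_fasta, alphabet="dna")[0]
            primers = pcr.load_primers()
            fwd = primers.get(fwd_primer) or pcr.Primer(fwd_primer, fwd_primer,
                                                        "forward")
            rev = primers.get(rev_primer) or pcr.Primer(rev_primer, rev_primer,
                                                        "reverse")
            amps = pcr.predict_amplicons(
                fwd, rev, template, config.max_amplicon_len,
                config.max_mismatch, config.anchor_3prime)
            rows = [dict(
                fwd=a.fwd.primer.name, fwd_pos=a.fwd.pos_5prime,
                fwd_mismatches=a.fwd.mismatches,
                rev=a.rev.primer.name, rev_pos=a.rev.pos_5prime,
                rev_mismatches=a.rev.mismatches, length_bp=a.length,
            ) for a in amps]
            _write_tsv(pd.DataFrame(
                rows, columns=["fwd", "fwd_pos", "fwd_mismatches", "rev",
                               "rev_pos", "rev_mismatches", "length_bp"]),
                out / "amplicons.tsv", config)
            record("pcr", "ok", output="amplicons.tsv")
        except Exception as exc:
            record("pcr", "error", str(exc))
    else:
        record("pcr", "skipped", "no DNA template / primer pair supplied")

    manifest["ok"] = not any(
        s["status"] == "error" for s in manifest["stages"].values()
    )
    _write_json(manifest, out / "manifest.json", config)
    return manifest
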