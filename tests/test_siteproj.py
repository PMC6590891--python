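import itertools

import pytest

from oracles import ion_call_oracle
from slc6kit.align import PairwiseAlignment, global_align, progressive_msa
from slc6kit.seqio import SequenceRecord
from slc6kit.siteproj import (
    SiteEntry,
    SiteProjection,
    TemplateSiteSet,
    classify_ion_dependence,
    load_sitesets,
    map_positions,
    pocket_conservation_report,
    project_sites,
)
from slc6kit.synthetic import FamilyConfig, simulate_family

TEMPLATE = SequenceRecord("tmpl", "MAGNVTWYLKDSERFHCQIP")
SITESET = TemplateSiteSet(
    "tmpl",
    {
        "Na1": ((2, "A"), (4, "N")),
        "Na2": ((5, "V"), (7, "W")),
        "Cl": ((8, "Y"), (12, "S")),
    },
)


def make_projection(statuses_by_site):
    """Build a SiteProjection carrying given statuses (for rule testing)."""
    entries = []
    qpos = 0
    for site, statuses in statuses_by_site.items():
        for k, status in enumerate(statuses):
            qpos += 1
            entries.append(SiteEntry(
                site_name=site, template_pos=qpos, template_res="A",
                query_pos=None if status == "unaligned" else qpos,
                query_res=None if status == "unaligned" else
                ("A" if status == "identical" else
                 "S" if status == "similar" else "W"),
                status=status,
            ))
    return SiteProjection("tmpl", "query", tuple(entries))


class TestMapPositions:
    def test_identity_alignment_maps_to_self(self):
        pa = global_align(TEMPLATE, SequenceRecord("q", TEMPLATE.residues))
        positions = list(range(1, len(TEMPLATE) + 1))
        assert map_positions(pa, positions) == positions

    def test_hand_walked_gapped_columns(self):
        # template ABD vs query ACD aligned as AB-D / A-CD
        pa = PairwiseAlignment("t", "q", "AW-E", "A-YE", 0.0, 10, 0.5)
        assert map_positions(pa, [1, 2, 3]) == [1, None, 3]

    def test_out_of_range_rejected(self):
        pa = PairwiseAlignment("t", "q", "AW", "AY", 0.0, 10, 0.5)
        with pytest.raises(ValueError):
            map_positions(pa, [3])

    def test_order_preserving_and_injective(self, rng):
        from conftest import random_protein

        a = random_protein(rng, 60, rec_id="a")
        b = random_protein(rng, 50, rec_id="b")
        pa = global_align(a, b)
        mapped = map_positions(pa, list(range(1, 61)))
        aligned = [m for m in mapped if m is not None]
        assert aligned == sorted(aligned)
        assert len(set(aligned)) == len(aligned)


class TestProjectSites:
    def test_template_onto_itself_is_all_identical(self):
        for siteset in (SITESET, *load_sitesets().values()):
            if siteset.template_id == "tmpl":
                template = TEMPLATE
            else:
                continue  # structural templates need their real sequences
            pa = global_align(template,
                              SequenceRecord("q", template.residues))
            proj = project_sites(siteset, pa)
            assert all(e.status == "identical" for e in proj.entries)

    def test_statuses_follow_blosum_rule(self, blosum62):
        # query differs at N4->Q (similar, BLOSUM62 +0? N/Q = 0 -> divergent
        # is wrong; N->H scores +1 -> similar) and W7->P (divergent)
        query = SequenceRecord("q", "MAGHVTPYLKDSERFHCQIP")
        pa = global_align(TEMPLATE, query)
        proj = project_sites(SITESET, pa)
        by_pos = {e.template_pos: e for e in proj.entries}
        assert by_pos[2].status == "identical"
        assert by_pos[4].status == "similar"  # N vs H: +1
        assert by_pos[7].status == "divergent"  # W vs P: -4
        assert blosum62.score("N", "H") > 0 > blosum62.score("W", "P")

    def test_template_residue_mismatch_detected(self):
        bad = TemplateSiteSet("tmpl", {"Na1": ((2, "G"),)})
        pa = global_align(TEMPLATE, SequenceRecord("q", TEMPLATE.residues))
        with pytest.raises(ValueError, match="mismatch"):
            project_sites(bad, pa)

    def test_bundled_fixtures_well_formed(self):
        sitesets = load_sitesets()
        assert set(sitesets) == {"LeuT", "SERT"}
        assert len(sitesets["LeuT"].sites["Na1"]) == 4
        assert len(sitesets["LeuT"].sites["Na2"]) == 5
        assert len(sitesets["SERT"].sites["Cl"]) == 4
        assert dict(sitesets["LeuT"].sites["Na1"]) == {
            22: "A", 24: "G", 27: "N", 254: "T"
        }
        assert dict(sitesets["SERT"].sites["Cl"]) == {
            121: "Y", 336: "S", 368: "N", 372: "S"
        }

    def test_planted_invariant_sites_identical_at_every_leaf(self):
        invariant = frozenset({5, 12, 20, 33, 47})
        records, truth = simulate_family(
            FamilyConfig(n_taxa=6, length=60, invariant_columns=invariant,
                         seed=11, length_scale=0.12)
        )
        template = SequenceRecord("template", truth.root_seq)
        siteset = TemplateSiteSet("template", {
            "planted": tuple(
                (p, truth.root_seq[p - 1]) for p in sorted(invariant)
            )
        })
        for leaf in records:
            proj = project_sites(siteset, global_align(template, leaf))
            assert all(e.status == "identical" for e in proj.entries)
            assert [e.query_pos for e in proj.entries] == sorted(invariant)


class TestIonDependenceRules:
    def test_sert_self_projection_is_chloride_dependent(self):
        proj = make_projection({
            "Na1": ["identical"] * 4,
            "Na2": ["identical"] * 5,
            "Cl": ["identical"] * 4,
        })
        call = classify_ion_dependence(proj)
        assert call.na_call == "dependent"
        assert call.cl_call == "dependent"

    def test_divergent_na1_undetermined(self):
        proj = make_projection({
            "Na1": ["identical", "divergent", "identical"],
            "Na2": ["identical"],
            "Cl": ["identical"],
        })
        assert classify_ion_dependence(proj).na_call == "undetermined"

    def test_rule_table_exhaustive(self):
        statuses = ("identical", "similar", "divergent", "unaligned")
        for na1 in itertools.product(statuses, repeat=2):
            for cl in itertools.product(statuses, repeat=2):
                proj = make_projection({
                    "Na1": list(na1), "Na2": ["identical"], "Cl": list(cl),
                })
                call = classify_ion_dependence(proj)
                na_ref, cl_ref = ion_call_oracle(na1, cl)
                assert (call.na_call, call.cl_call) == (na_ref, cl_ref)
                assert call.cl_conserved == sum(
                    s == "identical" for s in cl
                )

    def test_call_invariant_under_entry_permutation(self):
        proj = make_projection({
            "Na1": ["identical", "similar", "divergent"],
            "Na2": ["identical", "unaligned"],
            "Cl": ["identical", "similar", "identical"],
        })
        base = classify_ion_dependence(proj)
        for perm in itertools.permutations(proj.entries):
            call = classify_ion_dependence(
                SiteProjection("tmpl", "query", tuple(perm))
            )
            assert (call.na_call, call.cl_call, call.cl_conserved) == (
                base.na_call, base.cl_call, base.cl_conserved
            )

    def test_threonine_at_sert_s336_equivalent_flagged(self):
        entries = (
            SiteEntry("Na1", 1, "A", 1, "A", "identical"),
            SiteEntry("Na2", 2, "A", 2, "A", "identical"),
            SiteEntry("Cl", 121, "Y", 72, "Y", "identical"),
            SiteEntry("Cl", 336, "S", 309, "T", "similar"),
            SiteEntry("Cl", 368, "N", 341, "N", "identical"),
            SiteEntry("Cl", 372, "S", 354, "S", "identical"),
        )
        call = classify_ion_dependence(SiteProjection("SERT", "q", entries))
        assert call.cl_call == "independent_candidate"
        assert call.cl_conserved == 3
        assert "S336" in call.rationale or "threonine" in call.rationale

    def test_missing_site_group_errors(self):
        proj = make_projection({"Na1": ["identical"], "Na2": ["identical"]})
        with pytest.raises(ValueError, match="Cl"):
            classify_ion_dependence(proj)


class TestPocketReport:
    def test_identical_sequences_all_match(self, blosum62):
        recs = [SequenceRecord(s, TEMPLATE.residues)
                for s in ("tmpl", "a", "b")]
        msa = progressive_msa(recs, blosum62)
        pocket = TemplateSiteSet("tmpl", {
            "pocket": ((2, "A"), (5, "V"), (12, "S"))
        })
        df = pocket_conservation_report(pocket, msa)
        assert (df.groupby("seq_id")["match"].sum() == 3).all()
        assert (df["column_conservation"] == 1.0).all()

    def test_planted_invariant_pocket_columns(self, blosum62):
        invariant = frozenset({7, 19, 31})
        records, truth = simulate_family(
            FamilyConfig(n_taxa=5, length=40, invariant_columns=invariant,
                         seed=3, length_scale=0.15)
        )
        template = SequenceRecord("template", truth.root_seq)
        msa = progressive_msa([template] + records, blosum62)
        pocket = TemplateSiteSet("template", {
            "pocket": tuple(
                (p, truth.root_seq[p - 1]) for p in sorted(invariant)
            )
        })
        df = pocket_conservation_report(pocket, msa)
        n = len(invariant)
        assert (df.groupby("seq_id")["match"].sum() == n).all()

    def test_template_row_absent_errors(self, blosum62):
        msa = progressive_msa(
            [SequenceRecord("a", "MKVL"), SequenceRecord("b", "MKVI")],
            blosum62,
        )
        pocket = TemplateSiteSet("tmpl", {"pocket": ((1, "M"),)})
        with pytest.raises(ValueError, match="absent"):
            pocket_conservation_report(pocket, msa)
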