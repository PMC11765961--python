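import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntenylocus.annotation_io import write_gff3
from syntenylocus.gc_pcr import PrimerPair, gc_content, gc_sliding
from syntenylocus.simulate import (
    PanelSpec,
    generate_gc_cds,
    generate_panel,
    generate_transcript_variant,
    plant_domains,
    plant_primer_sites,
    random_protein,
)
from syntenylocus.synteny import learn_pattern
from syntenylocus.transcripts import map_exons


def gff3_text(ann):
    buf = io.StringIO()
    write_gff3(ann, buf)
    return buf.getvalue()


class TestGeneratePanel:
    def test_single_species_no_decoys_is_exactly_the_planted_triplet(self):
        panel, truth = generate_panel(
            PanelSpec(n_species=1, n_decoys_per_scaffold=0, seed=3)
        )
        (ann,) = panel
        order = ann.ordered_genes(ann.seq_ids[0])
        assert [g.symbol for g in order] == ["AKAP17A", "ASMT", "ASMTL"]
        target = order[1]
        akap, asmtl = order[0], order[2]
        assert akap.strand == target.strand
        assert asmtl.strand != target.strand
        loc = truth.target_locus["species01"]
        assert (loc.start, loc.end) == (target.start, target.end)

    def test_same_seed_gives_byte_identical_gff3(self):
        spec = PanelSpec(n_species=4, seed=11)
        p1, _ = generate_panel(spec)
        p2, _ = generate_panel(spec)
        for a, b in zip(p1, p2):
            assert gff3_text(a) == gff3_text(b)

    def test_different_seeds_differ(self):
        a, _ = generate_panel(PanelSpec(n_species=1, seed=1))
        b, _ = generate_panel(PanelSpec(n_species=1, seed=2))
        assert gff3_text(a[0]) != gff3_text(b[0])

    def test_closed_loop_consensus_recovers_planted_pattern(self, small_panel):
        panel, truth = small_panel
        pattern = learn_pattern(panel, truth.target_symbol)
        assert {
            (c.anchor_symbol, c.relative_orientation) for c in pattern.constraints
        } == {("AKAP17A", "same"), ("ASMTL", "opposite")}
        assert all(c.support == 1.0 for c in pattern.constraints)
        # supports match the generator's bookkeeping
        for con in pattern.constraints:
            satisfied = [
                sp
                for sp, table in truth.constraint_satisfaction.items()
                if table[con.anchor_symbol]
            ]
            assert sorted(con.supporting_species) == sorted(satisfied)

    def test_ablation_removes_anchor_for_that_species_only(self):
        panel, truth = generate_panel(
            PanelSpec(
                n_species=3,
                seed=5,
                constraint_ablation={"species02": ["AKAP17A"]},
            )
        )
        by_species = {a.species: a for a in panel}
        assert by_species["species01"].has_symbol("AKAP17A")
        assert not by_species["species02"].has_symbol("AKAP17A")
        assert by_species["species02"].has_symbol("ASMTL")
        assert truth.constraint_satisfaction["species02"]["AKAP17A"] is False
        assert truth.constraint_satisfaction["species02"]["ASMTL"] is True

    def test_unplaceable_arrangement_is_an_error(self):
        with pytest.raises(ValueError, match="does not fit"):
            generate_panel(PanelSpec(n_species=1, scaffold_length_bp=10_000, seed=0))

    def test_ground_truth_json_round_trip(self, small_panel):
        from syntenylocus.simulate import GroundTruth

        _, truth = small_panel
        back = GroundTruth.from_json(truth.to_json())
        assert back.target_symbol == truth.target_symbol
        assert back.target_locus == truth.target_locus
        assert back.constraint_satisfaction == truth.constraint_satisfaction


class TestGenerateGcCds:
    @given(
        length=st.integers(min_value=50, max_value=2000),
        gc=st.floats(min_value=0.0, max_value=1.0),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_composition_is_exact_up_to_rounding(self, length, gc, seed):
        seq = generate_gc_cds(length, gc, seed=seed)
        assert len(seq) == length
        n_gc = sum(1 for c in seq if c in "GC")
        assert n_gc == round(length * gc)

    def test_extremes(self):
        assert set(generate_gc_cds(100, 1.0, seed=0)) <= {"G", "C"}
        assert set(generate_gc_cds(100, 0.0, seed=0)) <= {"A", "T"}

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_gc_cds(0, 0.5)
        with pytest.raises(ValueError):
            generate_gc_cds(10, 1.5)

    def test_window_gc_variance_matches_hypergeometric(self):
        # fixed composition + shuffle = sampling windows without replacement,
        # so per-window GC counts are hypergeometric
        length, gc, window = 10_000, 0.6474, 100
        counts = []
        for seed in range(60):
            seq = generate_gc_cds(length, gc, seed=seed)
            counts.extend(
                round(v * window / 100) for _, v in gc_sliding(seq, window, window)
            )
        K = round(length * gc)
        expected_var = (
            window * (K / length) * (1 - K / length) * (length - window) / (length - 1)
        )
        observed = np.var(counts)
        assert observed == pytest.approx(expected_var, rel=0.15)


class TestGenerateTranscriptVariant:
    def test_no_drop_no_error_is_identity(self):
        exons = ["ACGTACGTAC", "GGGGCCCCAA", "TTTTAAAACC"]
        query, truth = generate_transcript_variant(exons, [])
        assert query == "".join(exons)
        assert truth["n_substitutions"] == 0

    def test_drop_all_is_an_error(self):
        with pytest.raises(ValueError, match="all exons"):
            generate_transcript_variant(["ACGTACGTAC"], [1])

    def test_out_of_range_drop_is_an_error(self):
        with pytest.raises(ValueError, match="out-of-range"):
            generate_transcript_variant(["ACGTACGTAC"] * 2, [3])

    def test_error_rate_yields_expected_identity(self):
        rng = np.random.default_rng(77)
        exons = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(6)]
        identities = []
        for seed in range(40):
            query, _ = generate_transcript_variant(
                exons, [], error_rate=0.01, seed=seed
            )
            smap = map_exons(query, exons)
            identities.extend(r.identity for r in smap.exon_records)
        assert np.mean(identities) == pytest.approx(0.99, abs=0.005)


class TestPlantDomains:
    def test_planted_consensus_recovered_by_scan(self, profiles):
        from syntenylocus.domains import scan

        maf = profiles["Maf"]
        protein, truth = plant_domains(400, [(maf.consensus, 120)], seed=4)
        (hit,) = scan(protein, maf)
        planted = truth["planted"][0]
        assert (hit.start, hit.end) == (planted["start"], planted["end"])

    def test_overlapping_plants_are_an_error(self, profiles):
        maf = profiles["Maf"]
        with pytest.raises(ValueError, match="overlap"):
            plant_domains(400, [(maf.consensus, 100), (maf.consensus, 110)])

    def test_plant_off_the_end_is_an_error(self, profiles):
        maf = profiles["Maf"]
        with pytest.raises(ValueError, match="exceeds"):
            plant_domains(100, [(maf.consensus, 90)])

    def test_determinism(self):
        assert random_protein(50, seed=9) == random_protein(50, seed=9)
        a, _ = plant_domains(100, [("WWWWWWWWWWWW", 10)], seed=1)
        b, _ = plant_domains(100, [("WWWWWWWWWWWW", 10)], seed=1)
        assert a == b


class TestPlantPrimerSites:
    def test_gc_of_template_near_target(self):
        pair = PrimerPair("p", "CCCCAGTTCCCGCACAC", "CAGAAGCTCAGCATCGCTCT")
        template, _ = plant_primer_sites(pair, 1214, 2000, gc_target=0.6474, seed=1)
        assert gc_content(template) == pytest.approx(64.74, abs=1.5)

    def test_too_short_product_is_an_error(self):
        pair = PrimerPair("p", "CCCCAGTTCCCGCACAC", "CAGAAGCTCAGCATCGCTCT")
        with pytest.raises(ValueError, match="shorter"):
            plant_primer_sites(pair, 20, 1000)
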