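import pytest

from syntenylocus.models import AnnotationSet, GeneRecord, Strand
from syntenylocus.simulate import (
    PanelSpec,
    default_asmt_pattern,
    generate_panel,
    mirror_annotation,
)
from syntenylocus.synteny import (
    ANY,
    OPPOSITE,
    SAME,
    AnchorsNotFoundError,
    NoConsensusError,
    build_consensus,
    extract_context,
    learn_pattern,
    localize,
)


def _scaffold(*genes, species="t", seq_id="chr1"):
    """genes: (symbol, start, end, strand)"""
    ann = AnnotationSet(species=species)
    for i, (sym, start, end, strand) in enumerate(genes):
        ann.add_gene(
            GeneRecord(
                gene_id=f"{species}_g{i}", symbol=sym, seq_id=seq_id,
                start=start, end=end, strand=Strand.parse(strand),
            )
        )
    return ann


class TestExtractContext:
    def test_toy_triplet_ranks_and_orientations(self):
        ann = _scaffold(
            ("A", 100, 200, "+"), ("T", 300, 400, "+"), ("P", 500, 600, "-")
        )
        (ctx,) = extract_context(ann, "T", k=1)
        by_rank = {n.rank: n for n in ctx.neighbors}
        assert set(by_rank) == {-1, 1}
        assert by_rank[-1].gene.symbol == "A"
        assert by_rank[-1].relative_orientation == SAME
        assert by_rank[1].gene.symbol == "P"
        assert by_rank[1].relative_orientation == OPPOSITE
        assert by_rank[-1].gap_bp == 99

    def test_human_like_arrangement_shows_adjacent_same_strand_akap17a(self):
        # AKAP17A immediately adjacent to ASMT, same orientation, with the
        # paralog ASMTL on the other side in opposite orientation
        ann = _scaffold(
            ("P2RY8", 1_000, 5_000, "-"),
            ("AKAP17A", 10_000, 20_000, "+"),
            ("ASMT", 25_000, 70_000, "+"),
            ("ASMTL", 75_000, 95_000, "-"),
        )
        (ctx,) = extract_context(ann, "ASMT", k=2)
        akap = ctx.neighbor_by_symbol("AKAP17A")
        asmtl = ctx.neighbor_by_symbol("ASMTL")
        assert abs(akap.rank) == 1 and akap.relative_orientation == SAME
        assert abs(asmtl.rank) == 1 and asmtl.relative_orientation == OPPOSITE

    def test_absent_symbol_gives_empty_list(self):
        ann = _scaffold(("A", 1, 10, "+"))
        assert extract_context(ann, "NOPE", k=1) == []

    def test_single_gene_scaffold_gives_empty_neighbors(self):
        ann = _scaffold(("T", 1, 10, "+"))
        (ctx,) = extract_context(ann, "T", k=3)
        assert ctx.neighbors == ()

    def test_agrees_with_brute_force_neighbor_scan(self, small_panel):
        panel, truth = small_panel
        for ann in panel:
            for k in (1, 2, 3):
                (ctx,) = extract_context(ann, truth.target_symbol, k=k)
                order = ann.ordered_genes(ctx.focal.seq_id)
                i = [g.gene_id for g in order].index(ctx.focal.gene_id)
                expected = {
                    order[j].gene_id: j - i
                    for j in range(len(order))
                    if j != i and abs(j - i) <= k
                }
                got = {n.gene.gene_id: n.rank for n in ctx.neighbors}
                assert got == expected
                for n in ctx.neighbors:
                    assert (n.relative_orientation == SAME) == (
                        n.gene.strand == ctx.focal.strand
                    )


class TestBuildConsensus:
    def test_planted_panel_recovers_both_constraints_at_full_support(self, small_panel):
        panel, truth = small_panel
        pattern = learn_pattern(panel, truth.target_symbol)
        by_symbol = {c.anchor_symbol: c for c in pattern.constraints}
        assert set(by_symbol) == {"AKAP17A", "ASMTL"}
        assert by_symbol["AKAP17A"].relative_orientation == SAME
        assert by_symbol["ASMTL"].relative_orientation == OPPOSITE
        assert by_symbol["AKAP17A"].support == 1.0
        assert by_symbol["ASMTL"].support == 1.0

    def test_single_species_panel_is_that_context_verbatim(self):
        ann = _scaffold(
            ("A", 100, 200, "+"), ("T", 300, 400, "+"), ("P", 500, 600, "-")
        )
        (ctx,) = extract_context(ann, "T", k=1)
        pattern = build_consensus({"t": ctx}, target_symbol="T", min_support=1.0, k=1)
        got = {(c.anchor_symbol, c.relative_orientation, c.support) for c in pattern.constraints}
        assert got == {("A", SAME, 1.0), ("P", OPPOSITE, 1.0)}

    def test_no_consensus_error_names_best_support(self):
        a = _scaffold(("X", 1, 10, "+"), ("T", 20, 30, "+"), species="s1")
        b = _scaffold(("Y", 1, 10, "+"), ("T", 20, 30, "+"), species="s2")
        ctxs = {
            "s1": extract_context(a, "T", k=1)[0],
            "s2": extract_context(b, "T", k=1)[0],
        }
        with pytest.raises(NoConsensusError, match="0.5"):
            build_consensus(ctxs, target_symbol="T", min_support=0.8, k=1)

    def test_orientation_tie_yields_any(self):
        a = _scaffold(("A", 1, 10, "+"), ("T", 20, 30, "+"), species="s1")
        b = _scaffold(("A", 1, 10, "-"), ("T", 20, 30, "+"), species="s2")
        ctxs = {
            "s1": extract_context(a, "T", k=1)[0],
            "s2": extract_context(b, "T", k=1)[0],
        }
        pattern = build_consensus(ctxs, target_symbol="T", min_support=1.0, k=1)
        (con,) = pattern.constraints
        assert con.relative_orientation == ANY and con.support == 1.0

    def test_species_input_order_does_not_matter(self, small_panel):
        panel, truth = small_panel
        fwd = learn_pattern(panel, truth.target_symbol)
        rev = learn_pattern(list(reversed(panel)), truth.target_symbol)
        assert fwd == rev


class TestLocalize:
    def test_misannotated_target_is_top_prediction(self):
        pattern = default_asmt_pattern()
        qpanel, qtruth = generate_panel(
            PanelSpec(n_species=1, misannotate_target=True, seed=5)
        )
        preds = localize(qpanel[0], pattern)
        top = preds[0]
        loc = qtruth.target_locus["species01"]
        assert top.candidate_symbol == loc.symbol
        assert (top.start, top.end, top.strand.value) == (loc.start, loc.end, loc.strand)
        assert top.score == 2 and top.rank == 1

    def test_annotated_target_self_consistency_full_score(self):
        pattern = default_asmt_pattern()
        qpanel, _ = generate_panel(
            PanelSpec(n_species=1, misannotate_target=False, seed=6)
        )
        preds = localize(qpanel[0], pattern)
        assert preds[0].candidate_symbol == "ASMT"
        assert preds[0].score == len(pattern.constraints)
        assert all(p.score <= len(pattern.constraints) for p in preds)

    def test_missing_all_anchors_is_an_error(self):
        pattern = default_asmt_pattern()
        ann = _scaffold(("X", 1, 10, "+"), ("Y", 20, 30, "+"))
        with pytest.raises(AnchorsNotFoundError, match="AKAP17A"):
            localize(ann, pattern)

    def test_empty_slot_between_anchors_predicts_interval_and_strand(self):
        # AKAP17A(+) then a gap, then ASMTL(-): the slot should be reported
        # with strand + (same as AKAP17A, opposite of ASMTL)
        pattern = default_asmt_pattern()
        ann = _scaffold(("AKAP17A", 1_000, 2_000, "+"), ("ASMTL", 9_000, 10_000, "-"))
        preds = localize(ann, pattern)
        slots = [p for p in preds if p.candidate_gene_id is None]
        assert slots, "expected an empty-slot prediction"
        slot = slots[0]
        assert (slot.start, slot.end) == (2_001, 8_999)
        assert slot.strand is Strand.FORWARD
        assert slot.score == 2

    def test_recovery_degrades_monotonically_with_ablation(self):
        pattern = default_asmt_pattern()
        top1 = {0: 0, 1: 0, 2: 0}
        n = 40
        for seed in range(n):
            for n_ablate in (0, 1):
                ablate = ["AKAP17A", "ASMTL"][:n_ablate]
                qpanel, qtruth = generate_panel(
                    PanelSpec(
                        n_species=1,
                        misannotate_target=True,
                        seed=1000 + seed,
                        constraint_ablation={"species01": ablate},
                    )
                )
                preds = localize(qpanel[0], pattern)
                loc = qtruth.target_locus["species01"]
                if preds and preds[0].candidate_symbol == loc.symbol:
                    top1[n_ablate] += 1
        assert top1[0] == n
        assert top1[1] <= top1[0]

    def test_predictions_are_rank_sorted_and_deterministic(self, small_panel):
        panel, truth = small_panel
        pattern = learn_pattern(panel, truth.target_symbol)
        preds = localize(panel[0], pattern)
        assert [p.rank for p in preds] == list(range(1, len(preds) + 1))
        scores = [p.score for p in preds]
        assert scores == sorted(scores, reverse=True)
        assert preds == localize(panel[0], pattern)


class TestStrandFlipInvariance:
    def test_mirrored_scaffold_same_supports_and_top_prediction(self):
        pattern = default_asmt_pattern()
        for seed in range(10):
            spec = PanelSpec(n_species=3, misannotate_target=True, seed=700 + seed)
            panel, truth = generate_panel(spec)
            mirrored = [mirror_annotation(a, spec.scaffold_length_bp) for a in panel]
            # relative orientations (hence supports) survive mirroring
            pat_m = learn_pattern(
                {a.species: a for a in mirrored},
                "LOC900000001",
                min_support=1.0,
            )
            assert {(c.anchor_symbol, c.relative_orientation, c.support)
                    for c in pat_m.constraints} == {
                ("AKAP17A", SAME, 1.0), ("ASMTL", OPPOSITE, 1.0),
            }
            for ann, mann in zip(panel, mirrored):
                top = localize(ann, pattern)[0]
                top_m = localize(mann, pattern)[0]
                assert top.candidate_gene_id == top_m.candidate_gene_id
                assert top.score == top_m.score
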