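"""Guide scanning, edit prediction, consequence calls and manifest checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bescan.edits import (
    ABE,
    CBE,
    ControlGuideRecord,
    EditError,
    EditPrediction,
    EditorSpec,
    Guide,
    annotate_guides,
    classify_consequence,
    predict_edits,
    rank_control_guides,
    scan_guides,
    validate_manifest,
)
from bescan.gene_model import GeneModel, reverse_complement

from _oracles import brute_force_consequence
from conftest import random_small_gene


def bare_model(seq: str) -> GeneModel:
    """Contig-only carrier for scanning tests (no gene structure)."""
    return GeneModel(
        gene_id="scan", contig_id="c", contig_seq=seq, strand="+",
        exons=[], cds=[], protein="X",
    )


class TestScanGuides:
    def test_plus_strand_ngn_site(self):
        guides = scan_guides(bare_model("ACGTACGTACGTACGTACGTTGC"), CBE)
        plus = [g for g in guides if g.strand == "+"]
        assert len(plus) == 1
        assert plus[0].contig_start == 0
        assert plus[0].pam == "TGC"
        assert plus[0].protospacer == "ACGTACGTACGTACGTACGT"

    def test_pam_middle_base_must_be_g(self):
        guides = scan_guides(bare_model("ACGTACGTACGTACGTACGTTCC"), CBE)
        assert [g for g in guides if g.strand == "+"] == []

    def test_minus_strand_protospacer_is_reverse_complement(self):
        # put a CCN 5' of a 20-mer: its revcomp is an NGG PAM on the minus strand
        core = "ACGTACGTACGTACGTACGT"
        contig = "CCA" + core + "TTT"
        guides = scan_guides(bare_model(contig), CBE)
        minus = [g for g in guides if g.strand == "-" and g.contig_start == 3]
        assert len(minus) == 1
        assert minus[0].protospacer == reverse_complement(core)
        assert minus[0].pam == reverse_complement("CCA")

    def test_region_outside_contig_errors(self):
        with pytest.raises(EditError, match="region"):
            scan_guides(bare_model("ACGT" * 10), CBE, region=(0, 100))

    def test_deterministic_order(self):
        model = bare_model("AGGA" * 30)
        guides = scan_guides(model, ABE)
        keys = [(g.contig_start, g.strand) for g in guides]
        assert keys == sorted(keys, key=lambda t: (t[0], t[1] != "+"))


class TestPredictEdits:
    PROTO = "GGGACCTGGGGGGGGGGGGG"  # window 4..8 = A C C T G

    def guide(self):
        contig = self.PROTO + "AGG"
        return Guide("g1", self.PROTO, "AGG", 0, "+"), contig

    def test_cbe_combined_edits_window_cytosines(self):
        g, contig = self.guide()
        pred = predict_edits(g, CBE, contig_seq=contig)
        assert [(p, c) for p, c, _, _ in pred.edited_positions] == [(5, 4), (6, 5)]
        assert all(ref == "C" and alt == "T" for _, _, ref, alt in pred.edited_positions)

    def test_abe_combined_edits_window_adenines(self):
        g, contig = self.guide()
        pred = predict_edits(g, ABE, contig_seq=contig)
        assert [(p, c) for p, c, _, _ in pred.edited_positions] == [(4, 3)]

    def test_no_editable_base_gives_no_edit(self):
        proto = "GGGGGTTGGG" + "G" * 10  # window bases GGTTG: no C
        g = Guide("g2", proto, "AGG", 0, "+")
        pred = classify_consequence(
            predict_edits(g, CBE, contig_seq=proto + "AGG"),
            bare_model(proto + "AGG"),
        )
        assert pred.consequence == "no_edit"
        assert pred.edited_positions == []

    def test_individual_mode_one_prediction_per_base(self):
        g, contig = self.guide()
        preds = predict_edits(g, CBE, contig_seq=contig, mode="individual")
        assert len(preds) == 2
        assert all(len(p.edited_positions) == 1 for p in preds)

    def test_reference_mismatch_names_first_position(self):
        g, contig = self.guide()
        bad = "T" + contig[1:]
        with pytest.raises(EditError, match="position 1"):
            predict_edits(g, CBE, contig_seq=bad)

    def test_non_targeting_guides_predict_nothing(self):
        g = Guide("nt1", self.PROTO, "AGG", None, "+", category="non_targeting")
        pred = predict_edits(g, CBE)
        assert pred.edited_positions == []

    def test_minus_strand_edit_lands_complemented(self):
        # minus-strand CBE edit converts G->A on the contig plus strand
        contig = "CCT" + "A" * 5 + "G" + "A" * 14 + "TTT"
        proto = reverse_complement(contig[3:23])
        g = Guide("gm", proto, reverse_complement(contig[0:3]), 3, "-")
        pred = predict_edits(g, CBE, contig_seq=contig)
        # protospacer position p maps to contig position 3 + 20 - p
        for p, cpos, ref, alt in pred.edited_positions:
            assert cpos == 3 + 20 - p
            assert (ref, alt) == ("G", "A")


class TestClassifyConsequence:
    def edit(self, model, cpos, ref, alt, guide_id="g"):
        return classify_consequence(
            EditPrediction(guide_id, "CBE", [(1, cpos, ref, alt)]), model
        )

    def test_missense_gca_to_gta(self, single_exon_model):
        # codon 2 GCA, C->T at its 2nd base -> GTA: A2V
        pred = self.edit(single_exon_model, 7, "C", "T")
        assert pred.consequence == "missense"
        assert pred.protein_changes == [(2, "A", "V")]
        assert not pred.installs_proline

    def test_nonsense_caa_to_taa(self):
        m = GeneModel(gene_id="g", contig_id="c", contig_seq="ATGCAATAA",
                      strand="+", exons=[(0, 9)], cds=[(0, 9)])
        pred = self.edit(m, 3, "C", "T")
        assert pred.consequence == "nonsense"
        assert pred.protein_changes == [(2, "Q", "*")]

    def test_splice_acceptor_outranks_bystander_synonymous(self, two_exon_model):
        # ABE edit at the intron-terminal AG adenine (pos 15) plus a
        # synonymous bystander (GCA codon 2 -> GCG at pos 7)
        pred = classify_consequence(
            EditPrediction("g", "ABE", [(1, 7, "A", "G"), (2, 15, "A", "G")]),
            two_exon_model,
        )
        assert pred.consequence == "splice_acceptor"
        assert pred.protein_changes == []
        assert pred.splice_residue == 3  # first residue of exon 2

    def test_splice_donor_flank_residue(self, two_exon_model):
        pred = classify_consequence(
            EditPrediction("g", "CBE", [(1, 9, "T", "C")]), two_exon_model
        )
        assert pred.consequence == "splice_donor"
        assert pred.splice_residue == 2  # last residue of exon 1

    def test_synonymous_lists_affected_codon_without_change(self, two_exon_model):
        pred = classify_consequence(
            EditPrediction("g", "ABE", [(1, 7, "A", "G")]), two_exon_model
        )
        assert pred.consequence == "synonymous"
        assert pred.protein_changes == [(2, "A", "A")]

    def test_installs_proline_via_minus_strand_abe(self):
        # CTT (L) -> CCT (P) by T->C on the plus strand
        m = GeneModel(gene_id="g", contig_id="c", contig_seq="ATGCTTTAA",
                      strand="+", exons=[(0, 9)], cds=[(0, 9)])
        pred = self.edit(m, 4, "T", "C")
        assert pred.consequence == "missense"
        assert pred.protein_changes == [(2, "L", "P")]
        assert pred.installs_proline

    def test_stop_loss_and_start_loss(self):
        m = GeneModel(gene_id="g", contig_id="c", contig_seq="ATGGCATGA",
                      strand="+", exons=[(0, 9)], cds=[(0, 9)])
        stop = classify_consequence(
            EditPrediction("g", "ABE", [(1, 8, "A", "G")]), m
        )
        assert stop.consequence == "stop_loss"
        start = classify_consequence(
            EditPrediction("g", "ABE", [(1, 0, "A", "G")]), m
        )
        assert start.consequence == "start_loss"

    def test_edit_outside_footprint_is_no_edit(self, single_exon_model):
        pred = self.edit(single_exon_model, 0, "C", "T")
        assert pred.consequence == "no_edit"

    def test_promoter_edit(self):
        m = GeneModel(gene_id="g", contig_id="c", contig_seq="CCCATGGCATAA",
                      strand="+", exons=[(3, 12)], cds=[(3, 12)],
                      promoter=(0, 3))
        pred = self.edit(m, 1, "C", "T")
        assert pred.consequence == "promoter"
        assert pred.protein_changes == []


class TestRankControlGuides:
    def rec(self, gid, d, a, c, gene="G1"):
        return ControlGuideRecord(gid, gene, d, a, c)

    def test_metric_is_product_of_disruption_and_score_sum(self):
        assert self.rec("g", 0.5, 0.3, 0.2).metric == pytest.approx(0.25)

    def test_top_three_by_metric_descending(self):
        ms = [0.25, 0.10, 0.40, 0.30, 0.05]
        recs = [self.rec(f"g{i}", m, 1.0, 0.0) for i, m in enumerate(ms)]
        top = rank_control_guides(recs, per_gene_top_k=3)
        assert [r.metric for r in top] == [0.40, 0.30, 0.25]

    def test_all_zero_scores_rank_last_with_id_ties(self):
        recs = [self.rec("b", 0, 0, 0), self.rec("a", 0, 0, 0),
                self.rec("c", 0.5, 1, 1)]
        top = rank_control_guides(recs, per_gene_top_k=3)
        assert [r.guide_id for r in top] == ["c", "a", "b"]

    def test_negative_disruption_score_errors(self):
        with pytest.raises(EditError, match="negative"):
            rank_control_guides([self.rec("g", -0.1, 1, 1)])

    def test_per_gene_selection(self):
        recs = [self.rec(f"g{i}", 0.1 * i, 1, 0, gene="A") for i in range(5)]
        recs += [self.rec(f"h{i}", 0.1 * i, 1, 0, gene="B") for i in range(2)]
        top = rank_control_guides(recs)
        assert sum(r.gene_id == "A" for r in top) == 3
        assert sum(r.gene_id == "B" for r in top) == 2


class TestValidateManifest:
    COUNTS = {
        "targeting": 3107,
        "non_targeting": 57,
        "intergenic": 168,
        "essential_stop_control": 307,
        "nonessential_stop_control": 87,
    }

    def test_reproduces_library_composition(self):
        manifest = []
        i = 0
        for category, n in self.COUNTS.items():
            for _ in range(n):
                manifest.append(
                    Guide(f"g{i:05d}", "A" * 20, "AGA", None, "+", category)
                )
                i += 1
        report = validate_manifest(manifest)
        assert report["category_counts"] == self.COUNTS
        assert report["n_guides"] == 3726
        assert report["invalid_pam"] == []

    def test_duplicate_guide_id_errors(self):
        g = Guide("dup", "A" * 20, "AGA", None, "+", "targeting")
        with pytest.raises(EditError, match="duplicate"):
            validate_manifest([g, g])

    def test_invalid_pam_listed_for_targeting(self):
        g = Guide("g1", "A" * 20, "ACA", None, "+", "targeting")
        report = validate_manifest([g])
        assert report["invalid_pam"] == ["g1"]


# ---------------------------------------------------------------------------
# properties


@settings(max_examples=60)
@given(st.integers(0, 10_000))
def test_consequences_match_brute_force_oracle(seed):
    """Combined-mode consequence calls agree with full-CDS re-translation."""
    rng = np.random.default_rng(seed)
    model = random_small_gene(rng)
    editor = ABE if seed % 2 else CBE
    guides = scan_guides(model, editor)
    if not guides:
        return
    for g in rng.choice(len(guides), size=min(5, len(guides)), replace=False):
        guide = guides[int(g)]
        pred = classify_consequence(
            predict_edits(guide, editor, contig_seq=model.contig_seq), model
        )
        consequence, changes, proline = brute_force_consequence(model, guide, editor)
        assert pred.consequence == consequence
        assert pred.protein_changes == changes
        assert pred.installs_proline == proline


def _flip_model(model: GeneModel) -> GeneModel:
    n = len(model.contig_seq)
    flip = lambda iv: (n - iv[1], n - iv[0])
    return GeneModel(
        gene_id=model.gene_id,
        contig_id=model.contig_id,
        contig_seq=reverse_complement(model.contig_seq),
        strand="-" if model.strand == "+" else "+",
        exons=sorted(flip(e) for e in model.exons),
        cds=sorted(flip(c) for c in model.cds),
        promoter=None if model.promoter is None else flip(model.promoter),
    )


@pytest.mark.parametrize("seed", [3, 17, 91])
@pytest.mark.parametrize("editor", [ABE, CBE])
def test_strand_symmetry(seed, editor):
    """Reverse-complementing the contig leaves all consequences unchanged."""
    model = random_small_gene(np.random.default_rng(seed))
    flipped = _flip_model(model)
    assert flipped.protein == model.protein

    def calls(m):
        out = {}
        for g in scan_guides(m, editor):
            pred = classify_consequence(
                predict_edits(g, editor, contig_seq=m.contig_seq), m
            )
            # key a guide by its strand-invariant protospacer content
            out[(g.protospacer, g.pam)] = (
                pred.consequence,
                tuple(pred.protein_changes),
            )
        return out

    a, b = calls(model), calls(flipped)
    assert a == b


def test_window_widening_never_loses_residue_coverage():
    """Residues reachable by edits grow monotonically with window width."""
    model = random_small_gene(np.random.default_rng(5))

    def covered(window):
        """Residues whose codon contains an editable window base."""
        editor = EditorSpec("CBE", "C", "T", window=window)
        residues = set()
        for g in scan_guides(model, editor):
            pred = predict_edits(g, editor, contig_seq=model.contig_seq)
            for _, cpos, _, _ in pred.edited_positions:
                idx = model.cds_index(cpos)
                if idx is not None:
                    residues.add(idx // 3 + 1)
        return residues

    narrow, default, wide = covered((5, 7)), covered((4, 8)), covered((3, 9))
    assert narrow <= default <= wide
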