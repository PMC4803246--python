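"""Tests for variant impact scoring against the motif model."""

import pytest

from vdrescan.genemodel import parse_cvariant
from vdrescan.impact import assess_variant, best_hit_over_locus, study_report
from vdrescan.motif import MotifHit, scan
from vdrescan.simulate import (
    GeneFixtureConfig,
    default_pwm,
    simulate_gene_fixture,
)

from conftest import brute_force_scan


def _hit(start, raw, strand=1, L=15):
    return MotifHit("s", start, strand, raw, 50.0, "A" * L)


class TestBestHitOverLocus:
    def test_no_overlap_returns_none(self):
        assert best_hit_over_locus([_hit(0, 5.0)], (100, 110)) is None

    def test_highest_raw_score_wins(self):
        hits = [_hit(10, 11.2), _hit(12, 12.5)]
        assert best_hit_over_locus(hits, (14, 18)).raw_score == 12.5

    def test_tie_breaks_on_start_then_strand(self):
        hits = [_hit(20, 9.0), _hit(10, 9.0)]
        assert best_hit_over_locus(hits, (5, 40)).start == 10
        hits = [_hit(10, 9.0, strand=-1), _hit(10, 9.0, strand=1)]
        assert best_hit_over_locus(hits, (5, 40)).strand == 1

    def test_boundary_overlap_is_half_open(self):
        # hit [10, 25) does not overlap locus [25, 30)
        assert best_hit_over_locus([_hit(10, 9.0)], (25, 30)) is None
        assert best_hit_over_locus([_hit(10, 9.0)], (24, 30)) is not None


@pytest.fixture(scope="module")
def fixture():
    return simulate_gene_fixture(seed=11)


class TestAssessVariant:
    def test_identity_snv_changes_nothing(self, fixture):
        pwm, seq, model = fixture.pwm, fixture.sequence, fixture.model
        pos = model.exon(2)[0] - 1062  # inside the strongest intron-1 element
        base = seq[pos]
        v = parse_cvariant(f"c.42-1062{base}>{base}")
        res = assess_variant(pwm, seq, model, v, threshold=80.0)
        assert res.pct_change == 0.0
        assert res.category == "none"

    def test_variant_far_from_hits_has_no_impact(self, fixture):
        pwm, seq, model = fixture.pwm, fixture.sequence, fixture.model
        base = seq[model.translation_start - 1053]
        alt = "T" if base != "T" else "A"
        res = assess_variant(
            pwm, seq, model, parse_cvariant(f"c.1-1053{base}>{alt}"), threshold=80.0
        )
        assert res.category == "none"
        assert res.pct_change == 0.0

    def test_snv_effect_bounded_by_column_spread(self, fixture):
        """An SNV can shift a hit's raw score by at most the largest
        weight spread of any single column."""
        pwm, seq, model = fixture.pwm, fixture.sequence, fixture.model
        e2 = model.exon(2)[0]
        spread = float((pwm.weights.max(axis=0) - pwm.weights.min(axis=0)).max())
        wt_hits = scan(pwm, seq, 80.0)
        strongest = max(wt_hits, key=lambda h: h.raw_score)
        for offset in (0, 7, 14):
            pos = strongest.start + offset
            base = seq[pos]
            alt = "A" if base != "A" else "C"
            v = parse_cvariant(f"c.42-{e2 - pos}{base}>{alt}")
            res = assess_variant(pwm, seq, model, v, threshold=80.0)
            assert res.wt_best is not None and res.mut_best is not None
            delta = abs(res.wt_best.raw_score - res.mut_best.raw_score)
            assert delta <= spread + 1e-9

    def test_pad_invariance(self, fixture):
        """Enlarging the scan window beyond the minimum never changes
        the assessment."""
        pwm, seq, model = fixture.pwm, fixture.sequence, fixture.model
        for text in fixture.variants:
            v = parse_cvariant(text)
            base = assess_variant(pwm, seq, model, v, threshold=80.0)
            for pad in (40, 75, 200):
                res = assess_variant(
                    pwm, seq, model, v, window_pad=pad, threshold=80.0
                )
                assert res.category == base.category
                assert res.pct_change == pytest.approx(base.pct_change)
                if base.wt_best is not None:
                    assert res.wt_best.start == base.wt_best.start
                    assert res.wt_best.raw_score == pytest.approx(
                        base.wt_best.raw_score
                    )

    def test_matches_two_allele_full_rescan_oracle(self, fixture):
        """The windowed implementation agrees with a naive full-sequence
        rescan of both alleles (independent per-window summation)."""
        from vdrescan.genemodel import apply_variant, c_to_contig
        from vdrescan.genemodel import variant_length_change

        pwm, seq, model = fixture.pwm, fixture.sequence, fixture.model
        for text in fixture.variants:
            v = parse_cvariant(text)
            res = assess_variant(pwm, seq, model, v, threshold=80.0)
            locus = c_to_contig(model, v)
            delta = variant_length_change(v)
            mut_locus = (locus[0], locus[1] + max(delta, 0))
            mut = apply_variant(seq, model, v)

            def best(raw_list, loc):
                L = pwm.length
                cands = [
                    (raw, start)
                    for start, strand, raw in raw_list
                    if start < loc[1] and start + L > loc[0]
                ]
                return max(cands)[0] if cands else None

            wt_best = best(brute_force_scan(pwm, seq), locus)
            mut_best = best(brute_force_scan(pwm, mut), mut_locus)
            assert res.wt_best.raw_score == pytest.approx(wt_best, abs=1e-9)
            if res.mut_best is not None:
                assert res.mut_best.raw_score == pytest.approx(mut_best, abs=1e-9)
            if res.pct_change is not None and wt_best > 0:
                assert res.pct_change == pytest.approx(
                    100.0 * (wt_best - mut_best) / wt_best, abs=1e-6
                )

    def test_duplication_inside_planted_motif(self):
        """A 4-base duplication inside a strong planted site reduces the
        best score; the reduction matches an independent re-scan."""
        pwm = default_pwm()
        cfg = GeneFixtureConfig()
        fixture = simulate_gene_fixture(cfg, seed=29)
        v = next(t for t in fixture.variants if "dup" in t and len(t) > 20)
        res = assess_variant(
            pwm, fixture.sequence, fixture.model, parse_cvariant(v), threshold=80.0
        )
        assert res.category == "disrupts"
        assert res.pct_change > 0


class TestStudyReport:
    def test_inventory_only_with_zero_variants(self, fixture):
        tables = study_report(
            fixture.pwm, fixture.sequence, fixture.model, [], threshold=80.0
        )
        assert len(tables.impacts) == 0
        assert len(tables.inventory) == 5

    def test_inventory_matches_truth_record(self, fixture):
        tables = study_report(
            fixture.pwm, fixture.sequence, fixture.model, [],
            threshold=fixture.truth["threshold"],
        )
        planted = {(p["position"], p["strand"]) for p in fixture.truth["plants"]}
        found = {
            (int(r.start), int(r.strand)) for r in tables.inventory.itertuples()
        }
        assert found == planted

    def test_variant_categories_match_truth(self, fixture):
        variants = [parse_cvariant(v["text"]) for v in fixture.truth["variants"]]
        tables = study_report(
            fixture.pwm, fixture.sequence, fixture.model, variants,
            threshold=fixture.truth["threshold"],
        )
        expected = {v["text"]: v["expected_category"] for v in
                    fixture.truth["variants"]}
        for row in tables.impacts.itertuples():
            assert row.category == expected[row.variant]

    def test_edge_snv_disrupts_strongest_intron1_element(self, fixture):
        """An SNV on the last base of the strongest intron-1 element (the
        known-polymorphism analog) still registers as disruptive."""
        snv = fixture.variants[-1]
        res = assess_variant(
            fixture.pwm, fixture.sequence, fixture.model, parse_cvariant(snv),
            threshold=80.0,
        )
        strongest = max(
            (p for p in fixture.truth["plants"] if p["name"].startswith("intron1")),
            key=lambda p: p["raw_score"],
        )
        assert res.wt_best.start == strongest["position"]
        assert res.category == "disrupts"
        assert res.pct_change > 0
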