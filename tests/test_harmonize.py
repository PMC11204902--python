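import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from prscad.data_io import ScoreSet, ScoreVariant
from prscad.harmonize import (
    COMPLEMENT,
    LDReference,
    align_weight,
    classify_alleles,
    find_proxy,
    harmonize_scoreset,
)
from prscad.scoring import compute_prs
from prscad.synthetic import (
    SimulationConfig,
    emit_score_file,
    ld_reference_from_truth,
    simulate_panel,
)

from conftest import make_panel


class TestClassifyAlleles:
    @pytest.mark.parametrize("effect,other,ref,alt,expected", [
        ("A", "G", "G", "A", "exact"),
        ("G", "A", "G", "A", "switched"),
        ("A", "G", "C", "T", "flipped"),            # complement (T,C) == (alt,ref)
        ("G", "A", "C", "T", "flipped_switched"),
        ("A", "T", "A", "T", "ambiguous_dropped"),  # palindromic pair
        ("C", "G", "A", "T", "ambiguous_dropped"),
        ("A", "G", "C", "A", "dropped"),
    ])
    def test_classification_table(self, effect, other, ref, alt, expected):
        assert classify_alleles(effect, other, ref, alt) == expected

    def test_complement_oracle_on_all_non_palindromic_pairs(self):
        # flipped iff complementing both alleles yields (alt, ref)
        bases = "ACGT"
        for e in bases:
            for o in bases:
                if e == o or {e, o} in ({"A", "T"}, {"C", "G"}):
                    continue
                ref, alt = COMPLEMENT[o], COMPLEMENT[e]
                if {ref, alt} == {e, o}:  # would be a direct match instead
                    continue
                assert classify_alleles(e, o, ref, alt) == "flipped"

    def test_invalid_allele_error(self):
        with pytest.raises(ValueError):
            classify_alleles("A", "N", "A", "G")

    _alleles = st.sampled_from("ACGT")

    @given(_alleles, _alleles, _alleles, _alleles)
    @settings(derandomize=True, deadline=None)
    def test_swapping_score_alleles_toggles_switch_status(self, e, o, r, a):
        """Swapping effect/other in the score maps exact<->switched and
        flipped<->flipped_switched, and leaves unresolvable pairs as-is."""
        assume(e != o and r != a)
        toggle = {"exact": "switched", "switched": "exact",
                  "flipped": "flipped_switched", "flipped_switched": "flipped",
                  "ambiguous_dropped": "ambiguous_dropped", "dropped": "dropped"}
        assert classify_alleles(o, e, r, a) == toggle[classify_alleles(e, o, r, a)]


class TestAlignWeight:
    @pytest.mark.parametrize("w,action,expected", [
        (0.3, "switched", -0.3),
        (0.3, "exact", 0.3),
        (0.3, "flipped", 0.3),
        (-0.2, "flipped_switched", 0.2),
    ])
    def test_sign_rules(self, w, action, expected):
        assert align_weight(w, action) == expected

    def test_dropped_action_is_contract_violation(self):
        with pytest.raises(ValueError):
            align_weight(0.3, "dropped")


class TestFindProxy:
    @staticmethod
    def panel_with_pairs():
        dosage = np.tile([0.0, 1.0, 2.0], (4, 1)).T  # 3 samples x 4 identical cols
        return make_panel(dosage, pairs=[("G", "A")] * 4, pos_start=100_000,
                          pos_step=10_000)

    def sv(self, pos=105_000):
        return ScoreVariant(variant_id="rsX", chrom="1", pos=pos,
                            effect_allele="A", other_allele="G", weight=0.4)

    def test_argmax_r2_wins(self):
        panel = self.panel_with_pairs()
        pairs = {(("1", 105_000), ("1", 100_000)): 0.85,
                 (("1", 105_000), ("1", 110_000)): 0.95}
        out = find_proxy(self.sv(), panel, LDReference(pairs=pairs))
        assert out.action == "proxied"
        assert out.panel_variant_key == ("1", 110_000)
        assert out.proxy_r2 == 0.95
        assert out.aligned_weight == 0.4  # effect A == alt A: exact orientation

    def test_below_threshold_dropped(self):
        panel = self.panel_with_pairs()
        pairs = {(("1", 105_000), ("1", 100_000)): 0.6}
        out = find_proxy(self.sv(), panel, LDReference(pairs=pairs))
        assert out.action == "dropped"
        assert out.reason == "no_proxy"

    def test_tie_broken_by_distance(self):
        panel = self.panel_with_pairs()
        sv = self.sv(pos=111_000)  # 1 kb from 110000, 9 kb from 120000
        pairs = {(("1", 111_000), ("1", 110_000)): 0.9,
                 (("1", 111_000), ("1", 120_000)): 0.9}
        out = find_proxy(sv, panel, LDReference(pairs=pairs))
        assert out.panel_variant_key == ("1", 110_000)

    def test_no_ld_data_reason(self):
        panel = self.panel_with_pairs()
        out = find_proxy(self.sv(), panel, LDReference(pairs={}))
        assert out.action == "dropped"
        assert out.reason == "no_ld_data"

    def test_r2_threshold_strict(self):
        panel = self.panel_with_pairs()
        pairs = {(("1", 105_000), ("1", 100_000)): 0.8}  # not > 0.8
        out = find_proxy(self.sv(), panel, LDReference(pairs=pairs))
        assert out.action == "dropped"


class TestHarmonizeScoreset:
    def test_fully_aligned_scoreset_all_exact(self, small_panel):
        meta = small_panel.variant_meta
        variants = [
            ScoreVariant(variant_id=row["id"], chrom=row["chrom"], pos=int(row["pos"]),
                         effect_allele=row["alt"], other_allele=row["ref"], weight=0.1)
            for _, row in meta.iloc[:10].iterrows()
        ]
        hs = harmonize_scoreset(ScoreSet(pgs_id="T", variants=variants), small_panel)
        assert hs.action_counts() == {"exact": 10}
        assert hs.n_dropped == 0

    def test_all_switched_negates_weights(self):
        cfg = SimulationConfig(n_samples=80, n_variants=120, n_causal=12, seed=5)
        panel, truth = simulate_panel(cfg)
        ss, _ = emit_score_file(truth, panel, {"allele_switch": 1.0}, seed=9)
        hs = harmonize_scoreset(ss, panel)
        assert hs.action_counts() == {"switched": 12}
        aligned = np.array([o.aligned_weight for _, o in hs.used()])
        assert np.array_equal(aligned, truth.causal_weights)

    def test_planted_exact_proxies_none_dropped(self):
        cfg = SimulationConfig(n_samples=80, n_variants=200, n_causal=20, seed=6)
        panel, truth = simulate_panel(cfg)
        ss, panel = emit_score_file(truth, panel, {"drop_with_proxy": 0.1}, seed=9)
        hs = harmonize_scoreset(ss, panel, ld_ref=ld_reference_from_truth(truth))
        counts = hs.action_counts()
        assert counts.get("proxied", 0) == 2
        assert hs.n_dropped == 0

    def test_idempotence_on_aligned_weights(self, small_panel):
        meta = small_panel.variant_meta
        w = np.linspace(-0.5, 0.5, 8)
        variants = [
            ScoreVariant(variant_id=row["id"], chrom=row["chrom"], pos=int(row["pos"]),
                         effect_allele=row["alt"], other_allele=row["ref"],
                         weight=float(w[k]))
            for k, (_, row) in enumerate(meta.iloc[:8].iterrows())
        ]
        hs = harmonize_scoreset(ScoreSet(pgs_id="T", variants=variants), small_panel)
        aligned = np.array([o.aligned_weight for _, o in hs.used()])
        assert np.array_equal(aligned, w)

    def test_determinism(self):
        cfg = SimulationConfig(n_samples=60, n_variants=150, n_causal=15, seed=8)
        panel, truth = simulate_panel(cfg)
        ss, panel = emit_score_file(
            truth, panel, {"allele_switch": 0.3, "strand_flip": 0.2}, seed=4)
        hs1 = harmonize_scoreset(ss, panel)
        hs2 = harmonize_scoreset(ss, panel)
        assert [(o.action, o.panel_variant_key, o.aligned_weight)
                for _, o in hs1.entries] == \
               [(o.action, o.panel_variant_key, o.aligned_weight)
                for _, o in hs2.entries]

    def test_orientation_invariance_of_prs_contrasts(self):
        """A score file and its fully allele-swapped copy yield PRS vectors
        differing only by a per-sample constant."""
        cfg = SimulationConfig(n_samples=70, n_variants=100, n_causal=10, seed=21)
        panel, truth = simulate_panel(cfg)
        ss, _ = emit_score_file(truth, panel, None, seed=1)
        swapped = ScoreSet(pgs_id="SW", variants=[
            ScoreVariant(variant_id=v.variant_id, chrom=v.chrom, pos=v.pos,
                         effect_allele=v.other_allele, other_allele=v.effect_allele,
                         weight=-v.weight)
            for v in ss.variants
        ])
        prs_a = compute_prs(harmonize_scoreset(ss, panel), panel).values
        prs_b = compute_prs(harmonize_scoreset(swapped, panel), panel).values
        diff = prs_a - prs_b
        assert np.ptp(diff) <= 1e-12 * max(1.0, np.abs(prs_a).max())
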