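"""Motif scanning and per-sequence feature calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from _oracles import naive_active_site, naive_cbk1_docking, naive_cbk1_phospho
from rniikit import (
    ACTIVE_SITE,
    CBK1_DOCKING,
    CBK1_PHOSPHO,
    AlignedFamily,
    AnnotationConfig,
    DomainSpec,
    MotifError,
    SideCondition,
    annotate_family,
    build_column_map,
    call_active_site,
    call_nls,
    cbk1_phospho_motif,
    parse_motif,
    scan_motif,
)

random_seq = st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=40)


class TestScanMotif:
    def test_phospho_hit_with_basic_in_central_position(self):
        hits = scan_motif("HAAKAS", CBK1_PHOSPHO)
        assert [(h.start, h.matched) for h in hits] == [(1, "HAAKAS")]

    def test_phospho_rejected_without_central_basic(self):
        assert scan_motif("HAAAAS", CBK1_PHOSPHO) == []

    def test_phospho_any_mode_accepts_outer_basic(self):
        motif = cbk1_phospho_motif("any")
        assert scan_motif("HKAAAS", CBK1_PHOSPHO) == []
        assert [h.start for h in scan_motif("HKAAAS", motif)] == [1]

    def test_docking_hit(self):
        hits = scan_motif("AYAFA", CBK1_DOCKING)
        assert [(h.start, h.matched) for h in hits] == [(2, "YAF")]

    def test_ambiguity_character_never_matches(self):
        assert scan_motif("HXAKAS", CBK1_PHOSPHO) == []
        # X fails even a wildcard position
        assert scan_motif("YXF", CBK1_DOCKING) == []

    def test_overlapping_hits_all_reported(self):
        # two docking windows sharing the central F
        hits = scan_motif("YAFAF", CBK1_DOCKING)
        assert [h.start for h in hits] == [1, 3]

    @given(seq=random_seq)
    def test_matches_naive_oracle_on_random_strings(self, seq):
        assert [h.start for h in scan_motif(seq, CBK1_PHOSPHO)] == (
            naive_cbk1_phospho(seq)
        )
        assert [h.start for h in scan_motif(seq, CBK1_DOCKING)] == (
            naive_cbk1_docking(seq)
        )
        assert [h.start for h in scan_motif(seq, ACTIVE_SITE)] == (
            naive_active_site(seq)
        )

    @given(seq=random_seq, suffix=st.text(alphabet="ACDG", max_size=5))
    def test_hit_count_monotone_under_extension(self, seq, suffix):
        before = len(scan_motif(seq, CBK1_DOCKING))
        after = len(scan_motif(seq + suffix, CBK1_DOCKING))
        assert after >= before

    def test_side_condition_must_sit_on_wildcards(self):
        with pytest.raises(MotifError, match="wildcard"):
            parse_motif(
                "bad", "Hxxxx[ST]",
                SideCondition(positions=(1,), residues=frozenset("KR")),
            )


def active_site_family():
    # anchor a1 carries DxxxxxDxDD at residue 3
    return AlignedFamily([
        ("a1", "AADPAQSLDLDDAA"),
        ("a2", "AADPAQSLELDDAA"),  # E at non-catalytic position: still active
        ("a3", "AANPAQSLDLDDAA"),  # N at first catalytic D: inactive
        ("a4", "AADPAQSLDL-DAA"),  # gap at a catalytic column: inactive
    ])


class TestCallActiveSite:
    def test_signature_depends_on_three_catalytic_columns(self):
        calls = {c.seq_id: c for c in call_active_site(active_site_family(), "a1", 3)}
        assert calls["a1"].is_active_signature
        assert calls["a2"].is_active_signature  # Dss1-like DxxxxxELDD
        assert not calls["a3"].is_active_signature
        assert not calls["a4"].is_active_signature
        assert calls["a1"].residues_at_catalytic_columns == "DDD"
        assert calls["a2"].signature_window == "DPAQSLELDD"

    def test_misanchored_call_is_a_hard_error(self):
        with pytest.raises(MotifError, match="does not match"):
            call_active_site(active_site_family(), "a3", 3)
        with pytest.raises(MotifError, match="does not match"):
            call_active_site(active_site_family(), "a1", 2)

    def test_randomising_non_catalytic_columns_never_changes_calls(self):
        rng = np.random.default_rng(42)
        base = active_site_family()
        cmap = build_column_map(base, "a1")
        cat_cols = {cmap.column(3 + p - 1) for p in (1, 9, 10)}
        expected = [c.is_active_signature for c in call_active_site(base, "a1", 3)]
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(25):
            rows = []
            for seq_id, row in base:
                chars = list(row)
                for col in range(1, base.n_columns + 1):
                    if col not in cat_cols and chars[col - 1] != "-":
                        chars[col - 1] = str(rng.choice(letters))
                rows.append((seq_id, "".join(chars)))
            # keep the anchor row intact so anchoring still succeeds
            rows[0] = ("a1", base["a1"])
            fam = AlignedFamily(rows)
            got = [c.is_active_signature for c in call_active_site(fam, "a1", 3)]
            assert got == expected


class TestCallNLS:
    def make(self, window):
        fam = AlignedFamily([("r", "AAA" + window + "AAA")])
        cmap = build_column_map(fam, "r")
        spec = DomainSpec("NLS", 4, 3 + len(window))
        return fam, cmap, spec

    def test_basic_rich_window_called(self):
        fam, cmap, spec = self.make("KKRKA")
        (call,) = call_nls(fam, cmap, spec, min_basic=4)
        assert call.has_nls and call.basic_count == 4
        assert call.window_sequence == "KKRKA"

    def test_alanine_window_negative(self):
        fam, cmap, spec = self.make("AAAAA")
        (call,) = call_nls(fam, cmap, spec, min_basic=4)
        assert not call.has_nls and call.basic_count == 0

    def test_threshold_is_strict(self):
        fam, cmap, spec = self.make("KKRAA")
        (call,) = call_nls(fam, cmap, spec, min_basic=4)
        assert call.basic_count == 3 and not call.has_nls


class TestAnnotateFamily:
    def test_recovers_planted_truth_at_zero_rates(self, frozen_sim):
        fam, truth = frozen_sim
        bp = truth.config.blueprint
        ref = fam.ids[0]
        cmap = build_column_map(fam, ref)
        cfg = AnnotationConfig(
            anchor_id=ref,
            anchor_motif_start=bp.active_site_start,
            nterm=bp.nterm,
            nls=bp.nls_window,
        )
        features, hits = annotate_family(fam, cmap, cfg)
        merged = features.set_index("id")
        truth_t = truth.features.set_index("id")
        assert merged.equals(truth_t.loc[merged.index])
        # per-hit detail agrees with the planted motif starts
        phospho = hits[(hits["motif"] == "cbk1_phospho") & (hits["id"] == ref)]
        assert sorted(phospho["start"]) == truth.phospho_starts

    def test_single_active_anchor_family(self):
        fam = AlignedFamily([("only", "AADPAQSLDLDDAA")])
        cmap = build_column_map(fam, "only")
        cfg = AnnotationConfig(
            anchor_id="only", anchor_motif_start=3,
            nterm=DomainSpec("Nterm", 1, 2), nls=DomainSpec("NLS", 1, 2),
        )
        features, _ = annotate_family(fam, cmap, cfg)
        row = features.iloc[0]
        assert bool(row["active_site"]) and not bool(row["nls"])

    def test_region_shorter_than_motif_counts_zero(self):
        fam = AlignedFamily([("only", "HAKASDPAQSLDLDDAA" + "A")])
        # anchor motif at residue 6
        cmap = build_column_map(fam, "only")
        cfg = AnnotationConfig(
            anchor_id="only", anchor_motif_start=6,
            nterm=DomainSpec("Nterm", 1, 3), nls=DomainSpec("NLS", 1, 3),
        )
        features, _ = annotate_family(fam, cmap, cfg)
        assert int(features.iloc[0]["cbk1_phospho_count"]) == 0
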