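"""Fragmentation and duplex-MFE scanning."""

import numpy as np
import pytest
from conftest import oracle_duplex_mfe, pair_code, random_duplex_instance
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from iugrnet.hybridization import (
    EnergyModel,
    TranscriptRegion,
    duplex_mfe,
    fragment_sequence,
    load_energy_model,
    reverse_complement_rna,
    scan_target,
    predict_targets,
)


class TestFragmentation:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (1000, [(0, 1000)]),
            (2000, [(0, 2000)]),
            (2001, [(0, 2000), (1950, 2001)]),
            (3950, [(0, 2000), (1950, 3950)]),
            (4500, [(0, 2000), (1950, 3950), (3900, 4500)]),
        ],
    )
    def test_step_1950_rule(self, length, expected):
        frags = fragment_sequence("A" * length)
        assert [(f.start, f.end) for f in frags] == expected

    def test_overlap_must_be_smaller_than_fragment(self):
        with pytest.raises(ValueError):
            fragment_sequence("A" * 100, fragment_len=50, overlap=50)

    @pytest.mark.parametrize("length", [1, 17, 1949, 1951, 6000, 12345])
    def test_cover_and_overlap_invariants(self, length):
        frags = fragment_sequence("A" * length)
        self._check_invariants(frags, length)

    @given(
        length=st.integers(1, 12000),
        fragment_len=st.integers(2, 3000),
        overlap=st.integers(0, 2999),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_cover_invariants_hold_for_any_geometry(
        self, length, fragment_len, overlap
    ):
        assume(overlap < fragment_len)
        frags = fragment_sequence(
            "A" * length, fragment_len=fragment_len, overlap=overlap
        )
        assert frags[0].start == 0 and frags[-1].end == length
        step = fragment_len - overlap
        for a, b in zip(frags, frags[1:]):
            assert b.start == a.start + step
            assert a.end - a.start == fragment_len
        covered = set()
        for f in frags:
            covered.update(range(f.start, f.end))
        assert covered == set(range(length))

    @staticmethod
    def _check_invariants(frags, length):
        assert frags[0].start == 0
        assert frags[-1].end == length
        for a, b in zip(frags, frags[1:]):
            assert b.start == a.start + 1950
            assert a.end - b.start == 50  # 50-nt overlap between neighbors
        covered = set()
        for f in frags:
            covered.update(range(f.start, f.end))
        assert covered == set(range(length))


class TestDuplexMFE:
    def test_matches_enumeration_oracle(self, model):
        rng = np.random.default_rng(20)
        n_structured = 0
        for _ in range(150):
            mir, win = random_duplex_instance(rng)
            expected = oracle_duplex_mfe(mir, win, model)
            got = duplex_mfe(mir, win, model)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert got.mfe == pytest.approx(expected, abs=1e-6)
                n_structured += 1
        assert n_structured >= 50

    def test_full_complement_equals_stack_sum(self, model):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        site = reverse_complement_rna(mir)
        hit = duplex_mfe(mir, site, model)
        expected = model.duplex_init
        for k in range(len(mir) - 1):
            p = pair_code(mir[k], site[len(site) - 1 - k])
            q = pair_code(mir[k + 1], site[len(site) - 2 - k])
            expected += model.stack[p, q]
        assert hit.mfe == pytest.approx(expected)
        assert hit.pairing.count("(") == len(mir)
        # seed positions 2-7 paired by construction
        assert set(hit.pairing[1:7]) == {"("}

    def test_unsatisfiable_seed_returns_none(self, model):
        assert duplex_mfe("AAAAAAAAAAAA", "C" * 25, model) is None

    def test_input_validation(self, model):
        with pytest.raises(ValueError, match="non-RNA"):
            duplex_mfe("ACGUX", "ACGU" * 5, model)
        with pytest.raises(ValueError, match="helix"):
            duplex_mfe("ACGUAC", "ACGU" * 5, model)  # 6 nt < helix end

    def test_self_window_rarely_stable(self, model):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGU"))
        weak = 0
        for _ in range(60):
            mir = "".join(rng.choice(bases, 22))
            hit = duplex_mfe(mir, mir, model)
            if hit is None or hit.mfe >= -25.0:
                weak += 1
        assert weak >= 57  # >= 95% of random self-comparisons below threshold

    def test_window_extension_monotone(self, model):
        rng = np.random.default_rng(9)
        for _ in range(40):
            mir, win = random_duplex_instance(rng)
            ext = win + "".join(np.random.default_rng(1).choice(list("ACGU"), 8))
            base = duplex_mfe(mir, win, model)
            wide = duplex_mfe(mir, ext, model)
            if base is not None:
                assert wide is not None and wide.mfe <= base.mfe + 1e-9

    def test_wobble_in_helix_configurable(self, model):
        mir = "AGGGGGGAAAAAAAAAAAAA"
        # seed complement with one G:U wobble at miRNA position 4
        site = reverse_complement_rna(mir)
        pos = len(site) - 1 - 3  # base paired with miRNA index 3
        site = site[:pos] + "U" + site[pos + 1 :]
        strict = EnergyModel(
            stacks={
                f"{p}.{q}": model.stack[i, j]
                for i, p in enumerate(("AU", "UA", "CG", "GC", "GU", "UG"))
                for j, q in enumerate(("AU", "UA", "CG", "GC", "GU", "UG"))
            },
            bulge={g: model.bulge[g] for g in range(1, model.max_bulge + 1)},
            internal={g: model.internal[g] for g in range(2, model.max_internal + 1)},
            duplex_init=model.duplex_init,
            wobble_in_helix=False,
        )
        assert duplex_mfe(mir, site, model) is not None
        relaxed = duplex_mfe(mir, site, model).mfe
        out = duplex_mfe(mir, site, strict)
        assert out is None or out.mfe > relaxed


class TestScan:
    def test_planted_sites_recovered_at_recorded_offsets(self, model, small_bundle):
        truth = small_bundle.truth
        sites = {(s["mirna_id"], s["gene_id"]): s for s in truth.planted_sites}
        for (mirna, gene), site in list(sites.items())[:4]:
            hit = scan_target(
                mirna,
                truth.mirna_sequences[mirna],
                small_bundle.gene_regions[gene],
                model,
            )
            assert hit is not None
            assert hit.mfe < -25.0
            assert hit.region == site["region"]
            assert hit.target_start == site["offset"]

    def test_threshold_is_strict(self, model):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        region = TranscriptRegion("G1", "3UTR", "A" * 40 + reverse_complement_rna(mir) + "A" * 40)
        best = scan_target("m", mir, [region], model, mfe_threshold=-100.0)
        assert best is None  # nothing below -100
        found = scan_target("m", mir, [region], model, mfe_threshold=-25.0)
        assert found is not None
        at_value = scan_target("m", mir, [region], model, mfe_threshold=found.mfe)
        assert at_value is None  # MFE == threshold is not reported
        just_above = scan_target("m", mir, [region], model, mfe_threshold=found.mfe + 1e-6)
        assert just_above is not None

    def test_site_in_overlap_scored_once_and_identically(self, model):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGU"))
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        site = reverse_complement_rna(mir)
        # place the site fully inside the 50-nt overlap [1950, 2000)
        seq = "".join(rng.choice(bases, 2400))
        seq = seq[:1960] + site + seq[1960 + len(site) :]
        region = TranscriptRegion("G1", "3UTR", seq)
        frags = fragment_sequence(seq)
        w0 = seq[frags[0].start : frags[0].end]
        w1 = seq[frags[1].start : frags[1].end]
        h0 = duplex_mfe(mir, w0, model)
        h1 = duplex_mfe(mir, w1, model)
        assert h0.mfe == pytest.approx(h1.mfe)
        assert frags[0].start + h0.target_start == frags[1].start + h1.target_start
        best = scan_target("m", mir, [region], model)
        assert best.target_start == 1960

    def test_missing_gene_sequence_rejected(self, model):
        with pytest.raises(ValueError, match="no sequence"):
            scan_target("m", "UGAGGUAGUAGGUUGUAUAGUU", [], model)

    def test_pass_structure_scans_only_opposite_directions(self, model):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        site = reverse_complement_rna(mir)
        regions = {
            "Gup": [TranscriptRegion("Gup", "3UTR", "A" * 30 + site + "A" * 30)],
            "Gdown": [TranscriptRegion("Gdown", "3UTR", "A" * 30 + site + "A" * 30)],
        }
        hits = predict_targets(
            [("m1", mir, "up")],
            regions,
            {"Gup": "up", "Gdown": "down"},
            model,
        )
        assert list(hits["gene_id"]) == ["Gdown"]  # up-miRNA never scans up-genes
        empty = predict_targets([], regions, {"Gup": "up"}, model)
        assert len(empty) == 0
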