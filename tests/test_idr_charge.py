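"""Charge descriptors, kappa, diagram of states and KKE/D repeat detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snoridr import (
    charge_features,
    detect_kke_repeats,
    diagram_of_states,
    extract_idrs,
    kappa,
    proteome_scan,
    windowed_ncpr,
)
from snoridr.idr_charge import _delta, delta_max
from snoridr.synthetic_sequences import KKED_X9_PEPTIDE, SYNTHETIC_CBF5_LIKE_IDR

aa_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


class TestChargeFeatures:
    def test_kke_d_peptide(self):
        f = charge_features(KKED_X9_PEPTIDE)
        assert f.fcr == pytest.approx(1.0)
        assert f.ncpr == pytest.approx(10 / 28)
        assert f.ncpd == 10

    def test_uncharged_sequence(self):
        f = charge_features("GGGGGG")
        assert f.fcr == 0.0 and f.ncpr == 0.0

    def test_symmetric_pair(self):
        f = charge_features("KE")
        assert f.fcr == 1.0 and f.ncpr == 0.0 and f.ncpd == 0

    def test_histidine_configurable(self):
        assert charge_features("HHHH").fcr == 0.0
        assert charge_features("HHHH", his_charge=1.0).fcr == 1.0

    def test_unknown_residue_rejected_x_tolerated(self, caplog):
        with pytest.raises(ValueError, match="unknown residue"):
            charge_features("KKEB")
        with caplog.at_level("WARNING"):
            f = charge_features("KXE")
        assert f.fcr == pytest.approx(2 / 3)

    @given(seq=aa_text)
    @settings(max_examples=60, deadline=None)
    def test_ncpr_bounded_by_fcr_and_ncpd_exact(self, seq):
        f = charge_features(seq)
        assert abs(f.ncpr) <= f.fcr + 1e-12
        manual = sum(+1 if a in "KR" else -1 if a in "DE" else 0 for a in seq)
        assert f.ncpd == manual


class TestWindowedNcpr:
    def test_all_lysine(self):
        assert windowed_ncpr("KKKKK", 5).tolist() == [1.0]

    def test_mixed(self):
        assert windowed_ncpr("KEKEK", 5)[0] == pytest.approx(0.2)

    def test_profile_length(self):
        assert windowed_ncpr("KEKEKEDDKK", 5).size == 10 - 5 + 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            windowed_ncpr("KE", 5)


class TestKappa:
    def test_fully_segregated_is_one(self):
        assert kappa("EEEEEEKKKKKK").kappa == pytest.approx(1.0)

    def test_perfectly_alternating_is_near_zero(self):
        assert kappa("EKEKEKEKEKEK").kappa < 0.01

    def test_cbf5_like_domain_in_reported_band(self):
        # KKE/D-class domains show moderate segregation (blocks of + and -)
        k = kappa(SYNTHETIC_CBF5_LIKE_IDR).kappa
        assert 0.1 <= k <= 0.4

    def test_undefined_cases_have_reasons(self):
        assert kappa("KKK").reason == "too_short"
        assert kappa("GGGGGGG").reason == "no_charges"
        assert kappa("KKKKKKK").reason == "single_charge_sign"

    def test_interleaving_monotonically_lowers_kappa(self):
        # progressive shuffles from full segregation toward alternation
        series = [
            "EEEEEEKKKKKK",
            "EEEEEKEKKKKK",
            "EEEEEKKEKKKK",
            "KEKKKEKEKEEE",
            "KKKKEEKKEEEE",
            "EEKEKEKEKKEK",
            "EKEKEKEKEKEK",
        ]
        values = [kappa(s).kappa for s in series]
        assert all(a > b for a, b in zip(values, values[1:]))

    @given(seq=st.text(alphabet="KRDEGSA", min_size=6, max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_reversal_and_charge_swap_invariance(self, seq):
        k = kappa(seq).kappa
        if math.isnan(k):
            return
        swapped = seq.translate(str.maketrans("KRDE", "DEKR"))
        assert kappa(seq[::-1]).kappa == pytest.approx(k, abs=1e-9)
        assert kappa(swapped).kappa == pytest.approx(k, abs=1e-9)

    @given(seq=st.text(alphabet="KRDEGSAQN", min_size=6, max_size=50))
    @settings(max_examples=40, deadline=None)
    def test_kappa_in_unit_interval_when_defined(self, seq):
        k = kappa(seq).kappa
        assert math.isnan(k) or 0.0 <= k <= 1.0

    def test_delta_max_dominates_segregated_arrangement(self):
        # the canonical construction always contains the plain segregated
        # block arrangement
        for n_pos, n_neg, n_neu in [(4, 4, 0), (3, 2, 5), (6, 1, 3)]:
            for g in (5, 6):
                seg = np.array([1.0] * n_pos + [0.0] * n_neu + [-1.0] * n_neg)
                assert delta_max(n_pos, n_neg, n_neu, g) >= _delta(seg, g) - 1e-12


class TestDiagramOfStates:
    def test_printed_peptide_is_positive_strong_polyelectrolyte(self):
        f = charge_features(KKED_X9_PEPTIDE)
        assert diagram_of_states(f) == "positive strong polyelectrolyte"

    @pytest.mark.parametrize(
        "fcr,ncpr,label",
        [
            (0.1, 0.05, "weak"),
            (0.30, 0.0, "boundary"),
            (0.4, 0.0, "strong polyampholyte"),
            (0.5, -0.4, "negative strong polyelectrolyte"),
        ],
    )
    def test_region_labels(self, fcr, ncpr, label):
        from snoridr.idr_charge import ChargeFeatures

        f = ChargeFeatures(length=100, fplus=(fcr + ncpr) / 2, fminus=(fcr - ncpr) / 2,
                           fcr=fcr, ncpr=ncpr, ncpd=int(round(ncpr * 100)))
        assert diagram_of_states(f) == label

    def test_canonical_boundary_flag(self):
        from snoridr.idr_charge import ChargeFeatures

        f = ChargeFeatures(length=100, fplus=0.36, fminus=0.04, fcr=0.40, ncpr=0.32, ncpd=32)
        assert diagram_of_states(f) == "positive strong polyelectrolyte"
        assert diagram_of_states(f, ncpr_boundary=0.35) == "strong polyampholyte"


class TestExtractIdrs:
    SEQS = {"P1": "A" * 100, "P2": "C" * 50}

    def test_strictly_longer_than_cutoff(self):
        dis = pd.DataFrame({"protein_id": ["P1", "P1", "P2"],
                            "start": [1, 1, 1], "end": [30, 31, 50]})
        out = extract_idrs(dis, self.SEQS)
        assert [(i.protein_id, len(i.sequence)) for i in out] == [("P1", 31), ("P2", 50)]

    def test_empty_table(self):
        out = extract_idrs(pd.DataFrame(columns=["protein_id", "start", "end"]), self.SEQS)
        assert out == []

    def test_bad_coordinates_rejected(self):
        dis = pd.DataFrame({"protein_id": ["P2"], "start": [10], "end": [80]})
        with pytest.raises(ValueError, match="outside protein"):
            extract_idrs(dis, self.SEQS)

    def test_missing_protein_skipped_with_warning(self, caplog):
        dis = pd.DataFrame({"protein_id": ["P9"], "start": [1], "end": [40]})
        with caplog.at_level("WARNING"):
            assert extract_idrs(dis, self.SEQS) == []
        assert "absent from FASTA" in caplog.text


class TestKkeDetector:
    def test_printed_peptide_has_nine_doublets(self):
        segs = detect_kke_repeats(KKED_X9_PEPTIDE)
        assert len(segs) == 1
        assert segs[0].n_doublets == 9
        assert (segs[0].start, segs[0].end) == (1, 26)

    def test_spacer_composition_reported(self):
        (seg,) = detect_kke_repeats(KKED_X9_PEPTIDE)
        assert seg.spacer_composition == {"E": 4, "D": 4}

    def test_non_polar_spacer_breaks_chain(self):
        assert detect_kke_repeats("KKAKK") == []

    def test_adjacent_doublets_do_not_chain(self):
        assert detect_kke_repeats("KKKK") == []
        assert detect_kke_repeats("KKKK", min_doublets=2) == []

    def test_greedy_triple_lysine_is_one_doublet(self):
        # KKK holds a single doublet; the stray K breaks the chain to the
        # next doublet, so only the downstream KKEKKEKK run qualifies
        segs = detect_kke_repeats("KKKEKKEKKEKK", min_doublets=3)
        assert len(segs) == 1 and segs[0].n_doublets == 3
        assert (segs[0].start, segs[0].end) == (5, 12)

    def test_long_spacer_breaks_chain(self):
        assert detect_kke_repeats("KKEEEEKKEKKEKK", min_doublets=4) == []
        segs = detect_kke_repeats("KKEEEEKKEKKEKK", min_doublets=3)
        assert len(segs) == 1 and segs[0].n_doublets == 3


@pytest.fixture(scope="module")
def scan():
    from snoridr import SimulationConfig, gen_proteome

    cfg = SimulationConfig(seed=31)
    records, disorder, abundance = gen_proteome(cfg)
    seqs = {r.id: str(r.seq) for r in records}
    return cfg, disorder, proteome_scan(seqs, disorder, abundance)


class TestProteomeScan:

    def test_planted_segments_flagged(self, scan):
        cfg, disorder, table = scan
        flagged = table[table["n_kke_segments"] > 0]
        assert set(flagged["protein_id"]) == set(disorder[disorder["is_kke"]]["protein_id"])
        assert (flagged["kke_doublets"] == cfg.kke_doublets).all()

    def test_missing_abundance_retained_as_na(self):
        seqs = {"P1": "K" * 20 + "E" * 20}
        dis = pd.DataFrame({"protein_id": ["P1"], "start": [1], "end": [40]})
        table = proteome_scan(seqs, dis, abundance=pd.DataFrame({"protein_id": [], "abundance": []}))
        assert len(table) == 1 and math.isnan(table["abundance"].iloc[0])

    def test_input_order_invariance(self, scan):
        from snoridr import SimulationConfig, gen_proteome

        cfg = SimulationConfig(seed=31)
        records, disorder, abundance = gen_proteome(cfg)
        seqs = {r.id: str(r.seq) for r in records}
        shuffled = disorder.sample(frac=1.0, random_state=4).reset_index(drop=True)
        pd.testing.assert_frame_equal(scan[2], proteome_scan(seqs, shuffled, abundance))
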