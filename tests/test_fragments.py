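"""Fragment generation, peak annotation, and couplet localization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligophos.fragments import (
    PeakList,
    SiteModification,
    annotate,
    generate_fragments,
    localize,
)
from oligophos.masscalc import (
    ElementTable,
    InvalidHypothesisError,
    ModComposition,
    peptide_neutral_mass,
)
from oligophos.synthetic_data import ENDOGENOUS_PEPTIDE, SimConfig, make_spectrum

PHOSPHO = ModComposition(n_phos=1)
TRIPHOS_FE = ModComposition(n_phos=3, n_fe=1)


def peaklist_from_ions(ions, spectrum_id="exact"):
    mz = np.array([i.mz for i in ions])
    return PeakList(spectrum_id, 500.0, 2, mz, np.ones_like(mz))


class TestGenerateFragments:
    def test_b1_y1_of_dipeptide(self):
        ions = {i.label: i.mz for i in generate_fragments("AK")}
        assert ions["b1(1+)"] == pytest.approx(72.0444, abs=1e-3)
        assert ions["y1(1+)"] == pytest.approx(147.1128, abs=1e-3)

    def test_only_fragments_spanning_site_shift(self):
        plain = {i.label: i.mz for i in generate_fragments("AS")}
        modded = {
            i.label: i.mz
            for i in generate_fragments("AS", (SiteModification(2, PHOSPHO),))
        }
        assert modded["b1(1+)"] == pytest.approx(plain["b1(1+)"], abs=1e-9)
        assert modded["y1(1+)"] == pytest.approx(
            plain["y1(1+)"] + PHOSPHO.delta_mass, abs=1e-9
        )

    def test_empty_series_empty_result(self):
        assert generate_fragments("PEPTIDE", series=()) == []

    def test_c_z_relationships(self):
        t = ElementTable
        ions = {i.label: i.mz for i in generate_fragments("GASK", series="bycz")}
        assert ions["c2(1+)"] == pytest.approx(ions["b2(1+)"] + t.NH3, abs=1e-9)
        assert ions["z2(1+)"] == pytest.approx(
            ions["y2(1+)"] - t.NH3 + t.masses["H"], abs=1e-9
        )

    def test_site_out_of_range_rejected(self):
        with pytest.raises(InvalidHypothesisError):
            generate_fragments("AS", (SiteModification(5, PHOSPHO),))

    def test_phospho_site_policy(self):
        with pytest.raises(InvalidHypothesisError):
            generate_fragments("AK", (SiteModification(1, PHOSPHO),))

    def test_neutral_losses_only_from_phospho_fragments(self):
        ions = generate_fragments(
            "ASAK", (SiteModification(2, ModComposition(n_phos=2)),), losses=True
        )
        for ion in ions:
            if ion.n_hpo3_loss or ion.n_h3po4_loss:
                spans = ion.index >= 2 if ion.series == "b" else ion.index >= 3
                assert spans
                assert ion.n_hpo3_loss + ion.n_h3po4_loss <= 2
        # b1 never has losses, b3 does
        labels = {i.label for i in ions}
        assert "b3-1xHPO3(1+)" in labels
        assert not any(lbl.startswith("b1-") for lbl in labels)

    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=12),
        site_frac=st.floats(0, 1),
        n_phos=st.integers(0, 4),
    )
    @settings(max_examples=100, derandomize=True)
    def test_by_pair_mass_conservation(self, seq, site_frac, n_phos):
        """b_i + y_(n-i) singly charged ions sum to M + 2 protons."""
        sty = [k + 1 for k, aa in enumerate(seq) if aa in "STY"]
        mods = ()
        comp = ModComposition(n_phos=n_phos, n_fe=1 if n_phos >= 2 else 0)
        if sty and n_phos:
            site = sty[int(site_frac * (len(sty) - 1))]
            mods = (SiteModification(site, comp),)
        total = peptide_neutral_mass(seq, tuple(m.comp for m in mods))
        ions = {(i.series, i.index): i.mz for i in generate_fragments(seq, mods)}
        n = len(seq)
        for i in range(1, n):
            assert ions[("b", i)] + ions[("y", n - i)] == pytest.approx(
                total + 2 * ElementTable.PROTON, abs=1e-6
            )


class TestAnnotate:
    def test_exact_peaks_fully_matched(self):
        theo = generate_fragments("PEPTIDEK")
        df = annotate(peaklist_from_ions(theo), theo)
        assert df["matched"].all()
        assert df.attrs["match_fraction"] == 1.0

    def test_empty_peaklist_matches_nothing(self):
        theo = generate_fragments("PEPTIDEK")
        empty = PeakList("empty", 500.0, 2, np.array([]), np.array([]))
        df = annotate(empty, theo)
        assert not df["matched"].any()

    def test_removing_peaks_never_increases_matches(self):
        cfg = SimConfig(seed=5)
        peaks, _ = make_spectrum(cfg)
        theo = generate_fragments(
            ENDOGENOUS_PEPTIDE, (SiteModification(15, TRIPHOS_FE),)
        )
        full = int(annotate(peaks, theo)["matched"].sum())
        for keep in (0.8, 0.5, 0.2, 0.0):
            k = int(len(peaks) * keep)
            sub = PeakList("sub", peaks.precursor_mz, 2,
                           peaks.mz[:k], peaks.intensity[:k])
            assert int(annotate(sub, theo)["matched"].sum()) <= full

    def test_match_fraction_tracks_fragment_efficiency(self):
        """Mean matched fraction across 100 synthetic spectra ~ efficiency."""
        fractions = []
        theo = generate_fragments(
            ENDOGENOUS_PEPTIDE, (SiteModification(15, TRIPHOS_FE),)
        )
        for seed in range(100):
            cfg = SimConfig(seed=seed, fragment_efficiency=0.7,
                            fragment_ppm_sigma=5.0)
            peaks, _ = make_spectrum(cfg)
            df = annotate(peaks, theo, tol_ppm=10.0)
            fractions.append(df.attrs["match_fraction"])
        assert 0.6 <= float(np.mean(fractions)) <= 0.8

    def test_shared_peak_flagged(self):
        theo = generate_fragments("AGGK")  # b2/y2 not isobaric, craft a clash
        mz = np.array([theo[0].mz])
        peaks = PeakList("one", 200.0, 1, mz, np.array([1.0]))
        clash = [theo[0], theo[0]]
        df = annotate(peaks, clash)
        assert df["shared"].all()


class TestLocalize:
    def test_single_candidate_complete_ladder_unambiguous(self):
        seq = "AAASAAK"
        theo = generate_fragments(seq, (SiteModification(4, PHOSPHO),))
        res = localize(seq, [4], PHOSPHO, peaklist_from_ions(theo))
        assert res.status == "unambiguous" and res.best_site == 4

    def test_planted_site_recovered_among_competitors(self):
        seq = "AATASAAK"  # candidates T3 and S5
        comp = ModComposition(n_phos=3)
        theo = generate_fragments(seq, (SiteModification(5, comp),))
        res = localize(seq, [3, 5], comp, peaklist_from_ions(theo))
        assert res.status == "unambiguous" and res.best_site == 5

    def test_nterminal_only_ions_are_ambiguous(self):
        seq = "AATASAAK"
        comp = ModComposition(n_phos=3)
        theo = [
            i for i in generate_fragments(seq, (SiteModification(5, comp),))
            if i.series == "b" and i.index < 3
        ]
        res = localize(seq, [3, 5], comp, peaklist_from_ions(theo))
        assert res.status == "ambiguous" and res.best_site is None

    def test_no_phosphate_unsupported(self):
        peaks = PeakList("x", 500.0, 2, np.array([100.0]), np.array([1.0]))
        res = localize("AAS", [3], ModComposition(n_ox=1), peaks)
        assert res.status == "unsupported"

    def test_recovery_rate_on_synthetic_spectra(self):
        """>=95% unambiguous-correct and zero unambiguous-wrong (200 spectra)."""
        seq = ENDOGENOUS_PEPTIDE
        candidates = [6, 11, 15]  # T6, S11, T15
        comp = ModComposition(n_phos=3, n_fe=1)
        correct = wrong = 0
        n_spectra = 200
        for seed in range(n_spectra):
            cfg = SimConfig(seed=seed, fragment_efficiency=0.8,
                            fragment_ppm_sigma=3.0)
            site = candidates[seed % 3]
            peaks, truth = make_spectrum(cfg, seq, site=site, comp=comp)
            res = localize(seq, candidates, comp, peaks, tol_ppm=10.0)
            if res.status == "unambiguous":
                if res.best_site == truth["site"]:
                    correct += 1
                else:
                    wrong += 1
        assert wrong == 0
        assert correct / n_spectra >= 0.95
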