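"""Identification rule (precursor + mandatory NL) and internal-standard quantification."""

import numpy as np
import pandas as pd
import pytest

from clicklipid import (
    FattyAcyl,
    InstrumentModel,
    InternalStandard,
    LipidClass,
    MixtureSpec,
    N3PAL,
    QuantTable,
    Subspecies,
    SumSpecies,
    clicked_precursor,
    enumerate_species,
    identify_species,
    identify_subspecies,
    nl_fragment_mz,
    quantify_species,
    quantify_subspecies,
    simulate_run,
    subspecies_percentages,
)
from clicklipid.chem import Polarity
from clicklipid.lipids import C171
from clicklipid.spectra import Run, Spectrum

from conftest import make_sub


@pytest.fixture
def single_species_run(istd):
    """Zero-noise run containing only clicked pPC 31:1 (the IS)."""
    mix = MixtureSpec(components=(), internal_standards=(istd,))
    return simulate_run(mix, InstrumentModel(), seed=0)


CANDS = enumerate_species(LipidClass.PPC, (28, 40), (0, 4))


class TestIdentifySpecies:
    def test_single_species_found_with_nl_fragment(self, single_species_run):
        hits = identify_species(single_species_run, CANDS, N3PAL)
        assert [h.species.name for h in hits] == ["pPC 31:1"]
        prec = clicked_precursor(SumSpecies(LipidClass.PPC, 31, 1), N3PAL).mz
        assert hits[0].nl_peak.mz == pytest.approx(nl_fragment_mz(prec, N3PAL), abs=1e-4)

    def test_absent_species_not_reported(self, single_species_run):
        hits = identify_species(single_species_run,
                                [SumSpecies(LipidClass.PPC, 34, 1)], N3PAL)
        assert hits == []

    def test_nl_fragment_is_mandatory(self, istd):
        """A precursor peak alone, without the characteristic NL, is no hit."""
        mix = MixtureSpec(components=(), internal_standards=(istd,))
        run = simulate_run(mix, InstrumentModel(p_nl=0.0), seed=0)
        assert identify_species(run, CANDS, N3PAL, require_ms1=False) == []

    def test_ms1_corroboration_required_by_default(self, istd):
        mix = MixtureSpec(components=(), internal_standards=(istd,))
        run = simulate_run(mix, InstrumentModel(), seed=0)
        no_ms1 = Run([s for s in run.spectra if s.ms_level == 2], run.polarity)
        with pytest.raises(ValueError, match="MS1"):
            identify_species(no_ms1, CANDS, N3PAL, require_ms1=True)
        hits = identify_species(no_ms1, CANDS, N3PAL, require_ms1=False)
        assert len(hits) == 1

    def test_polarity_mismatch_rejected(self, single_species_run):
        with pytest.raises(ValueError, match="polarity"):
            identify_species(single_species_run, CANDS, C171)


class TestQuantifySpecies:
    def test_unit_and_double_ratio(self, istd, mixture20, candidates20):
        run = simulate_run(mixture20, InstrumentModel(), seed=0)
        hits = identify_species(run, candidates20, N3PAL)
        table = quantify_species(hits, istd)
        by = table.df.set_index("species")["pmol"]
        assert by["pPC 31:1"] == pytest.approx(240.0)
        # pPC 32:0 was mixed at 80 pmol -> third of IS amount
        assert by["pPC 32:0"] == pytest.approx(80.0)

    def test_missing_internal_standard(self, mixture20, candidates20):
        run = simulate_run(mixture20, InstrumentModel(), seed=0)
        hits = identify_species(run, candidates20, N3PAL)
        ghost = InternalStandard(SumSpecies(LipidClass.PPC, 29, 0), 100.0)
        with pytest.raises(ValueError, match="internal standard not detected"):
            quantify_species(hits, ghost)

    def test_noise_free_recovery_exact(self, istd, mixture20, candidates20):
        run = simulate_run(mixture20, InstrumentModel(), seed=0)
        hits = identify_species(run, candidates20, N3PAL)
        got = quantify_species(hits, istd).df.set_index("species")["pmol"]
        from clicklipid import ground_truth
        want = ground_truth(mixture20).species_rows().set_index("species")["pmol"]
        for name in want.index:
            assert got[name] == pytest.approx(want[name], rel=1e-6)

    def test_scale_invariance(self, istd, mixture20, candidates20):
        run = simulate_run(mixture20, InstrumentModel(), seed=0)
        scaled = Run([Spectrum(s.ms_level, s.polarity, s.scan_range, s.mz,
                               s.intensity * 37.5, s.precursor_window)
                      for s in run.spectra], run.polarity)
        q1 = quantify_species(identify_species(run, candidates20, N3PAL), istd)
        q2 = quantify_species(identify_species(scaled, candidates20, N3PAL), istd)
        np.testing.assert_allclose(q1.df["pmol"], q2.df["pmol"], rtol=1e-12)


class TestSubspecies:
    def test_is_chain_pair_resolved(self, single_species_run, istd):
        hits = identify_species(single_species_run, CANDS, N3PAL)
        sub_hits = identify_subspecies(single_species_run, hits)
        names = {h.subspecies.name for h in sub_hits}
        assert names == {"14:0_17:1"}
        assert all(len(h.fa_peaks) == 2 for h in sub_hits)

    def test_single_fragment_kept_and_flagged(self, istd):
        """A heteroacyl pair with one missing FA peak degrades gracefully."""
        mix = MixtureSpec(components=(), internal_standards=(istd,))
        run = simulate_run(mix, InstrumentModel(), seed=0)
        # drop the 267.233 (FA 17:1) peak from every MS2 scan
        pruned = []
        for s in run.spectra:
            if s.ms_level == 2:
                keep = ~np.isclose(s.mz, 267.233, atol=5e-3)
                s = Spectrum(2, s.polarity, s.scan_range, s.mz[keep],
                             s.intensity[keep], s.precursor_window)
            pruned.append(s)
        run2 = Run(pruned, run.polarity)
        hits = identify_species(run2, CANDS, N3PAL)
        lax = identify_subspecies(run2, hits)
        assert len(lax) == 1 and "single_fragment" in lax[0].flags
        strict = identify_subspecies(run2, hits, require_both_fa=True)
        assert strict == []

    def test_homoacyl_single_peak_counts_both_chains(self, istd):
        homo = make_sub("pPC 32:0", "16:0_16:0")
        mix = MixtureSpec(components=((homo, 50.0),), internal_standards=(istd,))
        run = simulate_run(mix, InstrumentModel(), seed=0)
        hits = identify_species(run, CANDS, N3PAL)
        sub_hits = identify_subspecies(run, hits)
        table = quantify_subspecies(sub_hits, istd)
        by = table.df.set_index("subspecies")["pmol"]
        assert by["16:0_16:0"] == pytest.approx(50.0, rel=1e-6)
        assert by["14:0_17:1"] == pytest.approx(240.0, rel=1e-6)

    def test_noise_free_subspecies_recovery(self, istd, mixture20, candidates20):
        run = simulate_run(mixture20, InstrumentModel(), seed=0)
        hits = identify_species(run, candidates20, N3PAL)
        table = quantify_subspecies(identify_subspecies(run, hits), istd)
        from clicklipid import ground_truth
        want = ground_truth(mixture20).subspecies_rows()
        got = table.df.set_index(["species", "subspecies"])["pmol"]
        for _, row in want.iterrows():
            assert got[(row["species"], row["subspecies"])] == pytest.approx(
                row["pmol"], rel=1e-6)

    def test_missing_is_fragments(self, mixture20, candidates20):
        run = simulate_run(mixture20, InstrumentModel(), seed=0)
        hits = identify_species(run, candidates20, N3PAL)
        sub_hits = identify_subspecies(run, hits)
        ghost = InternalStandard(SumSpecies(LipidClass.PPC, 29, 0), 100.0,
                                 (FattyAcyl(14, 0), FattyAcyl(15, 0)))
        with pytest.raises(ValueError, match="internal standard"):
            quantify_subspecies(sub_hits, ghost)


class TestPercentages:
    def test_reported_species_shares(self):
        rows = [
            {"sample": "s", "lipid_class": "pPC", "species": "pPC 34:1",
             "subspecies": n, "pmol": p, "quant_basis": "FA",
             "internal_standard": "pPC 31:1", "flags": "-"}
            for n, p in [("14:0_20:1", 0.4), ("16:1_18:0", 20.0), ("16:0_18:1", 686.1)]
        ] + [
            {"sample": "s", "lipid_class": "pPC", "species": "pPC 32:1",
             "subspecies": n, "pmol": p, "quant_basis": "FA",
             "internal_standard": "pPC 31:1", "flags": "-"}
            for n, p in [("14:0_18:1", 10.3), ("16:0_16:1", 183.6)]
        ]
        table = QuantTable(pd.DataFrame(rows))
        pct = subspecies_percentages(table).set_index("subspecies")["pct_of_subspecies"]
        assert pct["16:0_18:1"] == pytest.approx(97.1, abs=0.1)
        assert pct["16:1_18:0"] == pytest.approx(2.9, abs=0.1)
        assert pct["16:0_16:1"] == pytest.approx(94.7, abs=0.1)
        assert pct["14:0_18:1"] == pytest.approx(5.3, abs=0.1)

    def test_shares_sum_to_100_per_species(self, istd, mixture20, candidates20):
        run = simulate_run(mixture20, InstrumentModel(lognormal_sd=0.05), seed=3)
        hits = identify_species(run, candidates20, N3PAL)
        table = quantify_subspecies(identify_subspecies(run, hits), istd)
        pct = subspecies_percentages(table)
        sums = pct.groupby("species")["pct_of_subspecies"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-9)

    def test_single_subspecies_is_100(self, single_species_run, istd):
        hits = identify_species(single_species_run, CANDS, N3PAL)
        table = quantify_subspecies(identify_subspecies(single_species_run, hits), istd)
        pct = subspecies_percentages(table)
        assert pct["pct_of_subspecies"].tolist() == [100.0]
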