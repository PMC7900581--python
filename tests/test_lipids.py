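"""Species enumeration, clicked-product ions and diagnostic fragment masses."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from clicklipid.chem import monoisotopic_mass, parse_formula
from clicklipid.lipids import (
    C171,
    FattyAcyl,
    InternalStandard,
    LipidClass,
    N3PAL,
    Subspecies,
    SumSpecies,
    clicked_precursor,
    enumerate_species,
    enumerate_subspecies,
    export_db,
    fa_fragment_mz,
    import_db,
    nl_fragment_mz,
    species_composition,
)

species_strategy = st.builds(
    SumSpecies,
    st.sampled_from([LipidClass.PPC, LipidClass.PPC_O, LipidClass.PSM]),
    st.integers(28, 44),
    st.integers(0, 8),
)


class TestComposition:
    def test_ppc_31_1(self):
        comp = species_composition(SumSpecies(LipidClass.PPC, 31, 1))
        assert comp.formula() == "C41H76NO8P"
        # PC 31:1 = C39H76NO8P (717.5309, standard lipid tables) plus C2
        assert comp.mass == pytest.approx(741.5309, abs=1e-3)

    def test_lyso_ppc_16_0(self):
        comp = species_composition(SumSpecies(LipidClass.LPPC, 16, 0))
        assert comp.formula() == "C26H50NO7P"  # LPC 16:0 + C2

    def test_no_radyl_carbons_rejected(self):
        with pytest.raises(ValueError):
            SumSpecies(LipidClass.PC, 0, 0)

    @given(st.integers(28, 44), st.integers(0, 8))
    @settings(deadline=None)
    def test_propargyl_adds_exactly_c2(self, c, d):
        labeled = species_composition(SumSpecies(LipidClass.PPC, c, d)).mass
        parent = species_composition(SumSpecies(LipidClass.PC, c, d)).mass
        assert labeled - parent == pytest.approx(24.0, abs=1e-9)

    @given(st.integers(28, 44), st.integers(0, 8))
    @settings(deadline=None)
    def test_ether_swaps_o_for_h2(self, c, d):
        diacyl = species_composition(SumSpecies(LipidClass.PPC, c, d))
        ether = species_composition(SumSpecies(LipidClass.PPC_O, c, d))
        expected = monoisotopic_mass(parse_formula("H2")) - monoisotopic_mass(parse_formula("O"))
        assert ether.mass - diacyl.mass == pytest.approx(expected, abs=1e-9)


class TestClickedPrecursor:
    def test_azidopalmitate_product(self):
        ion = clicked_precursor(SumSpecies(LipidClass.PPC, 31, 1), N3PAL)
        assert ion.composition.formula() == "C57H107N4O10P"
        assert ion.mz == pytest.approx(1037.7652, abs=2e-3)

    def test_unlabeled_class_rejected(self):
        with pytest.raises(ValueError):
            clicked_precursor(SumSpecies(LipidClass.PC, 31, 1), N3PAL)

    def test_c171_intrinsic_cation_shift(self):
        # the quaternary-ammonium reporter confers a nominal +171 shift
        sp = SumSpecies(LipidClass.PPC, 31, 1)
        ion = clicked_precursor(sp, C171)
        assert ion.mz - species_composition(sp).mass == pytest.approx(171.16, abs=0.01)

    @given(species_strategy)
    @settings(deadline=None)
    def test_nl_offset_closure(self, sp):
        # precursor minus NL fragment equals the NL mass exactly
        prec = clicked_precursor(sp, N3PAL).mz
        assert prec - nl_fragment_mz(prec, N3PAL) == pytest.approx(N3PAL.nl_mass, abs=1e-9)

    def test_nl_larger_than_precursor_rejected(self):
        with pytest.raises(ValueError):
            nl_fragment_mz(100.0, N3PAL)


class TestFaFragments:
    @pytest.mark.parametrize("c, d, expected", [
        (14, 0, 227.2017), (17, 1, 267.2330), (16, 0, 255.2330),
    ])
    def test_carboxylate_masses(self, c, d, expected):
        assert fa_fragment_mz(FattyAcyl(c, d)) == pytest.approx(expected, abs=1e-3)

    def test_impossible_double_bonds_rejected(self):
        with pytest.raises(ValueError):
            FattyAcyl(4, 2)


class TestEnumeration:
    def test_even_c_only(self):
        got = enumerate_species(LipidClass.PPC, (30, 32), (0, 1), even_c_only=True)
        assert [(s.c, s.d) for s in got] == [(30, 0), (30, 1), (32, 0), (32, 1)]

    def test_singleton(self):
        got = enumerate_species(LipidClass.PPC, (34, 34), (1, 1))
        assert [s.name for s in got] == ["pPC 34:1"]

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError):
            enumerate_species(LipidClass.PPC, (32, 30), (0, 1))

    def test_small_exhaustive_case(self):
        got = enumerate_subspecies(SumSpecies(LipidClass.PPC, 30, 0), (14, 16), (0, 0))
        assert {ss.name for ss in got} == {"14:0_16:0", "15:0_15:0"}

    def test_reported_34_1_pairs_present(self):
        got = enumerate_subspecies(SumSpecies(LipidClass.PPC, 34, 1), (14, 20), (0, 1))
        names = {ss.name for ss in got}
        assert {"16:0_18:1", "14:0_20:1", "16:1_18:0"} <= names

    def test_lyso_has_no_subspecies(self):
        with pytest.raises(ValueError):
            enumerate_subspecies(SumSpecies(LipidClass.LPPC, 16, 0))

    @given(species_strategy, st.tuples(st.integers(12, 16), st.integers(20, 26)),
           st.tuples(st.integers(0, 1), st.integers(3, 6)))
    @settings(deadline=None, max_examples=40)
    def test_matches_brute_force(self, sp, c_range, d_range):
        got = enumerate_subspecies(sp, c_range, d_range)
        # brute-force double loop over all chain pairs
        ordered = sp.lipid_class.is_ether or sp.lipid_class.is_sphingo
        seen = set()
        for c1, d1 in itertools.product(range(c_range[0], c_range[1] + 1),
                                        range(d_range[0], d_range[1] + 1)):
            c2, d2 = sp.c - c1, sp.d - d1
            if not (c_range[0] <= c2 <= c_range[1] and d_range[0] <= d2 <= d_range[1]):
                continue
            if d1 > (c1 - 1) // 2 or d2 > (c2 - 1) // 2 or min(c1, c2) < 2:
                continue
            pair = ((c1, d1), (c2, d2)) if ordered else tuple(sorted(((c1, d1), (c2, d2))))
            seen.add(pair)
        assert len(got) == len(seen)
        # within a species, each observable FA fragment determines its
        # subspecies uniquely (the partner is fixed by the sum constraint)
        if not ordered:
            firsts = [(ss.fa1.c, ss.fa1.d) for ss in got]
            assert len(firsts) == len(set(firsts))


class TestInternalStandard:
    def test_subspecies_needs_acyl_pair(self, istd):
        assert istd.subspecies.name == "14:0_17:1"
        bare = InternalStandard(SumSpecies(LipidClass.PPC, 31, 1), 240.0)
        with pytest.raises(ValueError):
            bare.subspecies

    def test_positive_amount_required(self):
        with pytest.raises(ValueError):
            InternalStandard(SumSpecies(LipidClass.PPC, 31, 1), 0.0)


class TestDbExport:
    def test_roundtrip_and_determinism(self, tmp_path):
        species = enumerate_species(LipidClass.PPC, (30, 32), (0, 1))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        t1 = export_db(species, N3PAL, p1, (14, 18), (0, 1))
        t2 = export_db(species, N3PAL, p2, (14, 18), (0, 1))
        assert t1 == t2  # byte-identical
        assert import_db(p1) == sorted(species, key=lambda s: s.sort_key)
        header, first = t1.splitlines()[:2]
        assert header.startswith("class\tspecies")
        # m/z printed to 4 decimals
        assert len(first.split("\t")[3].split(".")[1]) == 4
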