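"""Diagnostic fragment library of the two click reporters.

Builds the clicked-precursor and fragment masses for a propargyl-PC internal
standard (pPC 31:1, chains FA 14:0 + FA 17:1) under both reporters and prints
the masses an analyst would look for in the spectra.
"""

from clicklipid import (
    C171,
    FattyAcyl,
    LipidClass,
    N3PAL,
    SumSpecies,
    clicked_precursor,
    fa_fragment_mz,
    nl_fragment_mz,
    species_composition,
)

species = SumSpecies(LipidClass.PPC, 31, 1)
print(f"{species.name}: {species_composition(species).formula()}, "
      f"monoisotopic {species_composition(species).mass:.4f} Da")

for reporter in (N3PAL, C171):
    prec = clicked_precursor(species, reporter)
    nl = nl_fragment_mz(prec.mz, reporter)
    print(f"\n{reporter.name} ({reporter.polarity.value} mode)")
    print(f"  clicked precursor {prec.adduct.value}: m/z {prec.mz:.4f}")
    print(f"  diagnostic neutral loss: {reporter.nl_mass:.2f} Da "
          f"-> fragment at m/z {nl:.4f}")

print("\nFA carboxylate fragments (negative mode only):")
for fa in (FattyAcyl(14, 0), FattyAcyl(17, 1)):
    print(f"  FA {fa.name}: m/z {fa_fragment_mz(fa):.4f}")

# The NL fragment identifies the labeled class and sum composition; the FA
# carboxylates reveal which two chains compose the species.
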