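"""Simulate a direct-infusion DIA run and recover the mixture by the full pipeline.

A three-species propargyl-PC mixture (including the 240 pmol pPC 31:1 internal
standard) is sprayed by the simulated instrument; the pipeline identifies each
species by its clicked precursor plus the 335.26 Da neutral loss, quantifies
species from NL intensities and subspecies from FA-fragment intensities, and
the printed amounts are compared with the ground truth.
"""

from clicklipid import (
    FattyAcyl,
    InstrumentModel,
    InternalStandard,
    LipidClass,
    MixtureSpec,
    N3PAL,
    Subspecies,
    SumSpecies,
    ground_truth,
    identify_species,
    identify_subspecies,
    quantify_species,
    quantify_subspecies,
    simulate_run,
)

istd = InternalStandard(SumSpecies(LipidClass.PPC, 31, 1), 240.0,
                        (FattyAcyl(14, 0), FattyAcyl(17, 1)))


def sub(name, chains):
    sp = SumSpecies.from_name(name)
    fa1, fa2 = sorted(FattyAcyl.from_name(x) for x in chains.split("_"))
    return Subspecies(sp, fa1, fa2)


mixture = MixtureSpec(
    components=(
        (sub("pPC 34:1", "18:1_16:0"), 686.1),
        (sub("pPC 32:1", "16:0_16:1"), 183.6),
        (sub("pPC 36:4", "18:2_18:2"), 60.9),
    ),
    internal_standards=(istd,),
)

# 2% intensity noise, 1 ppm mass error, light chemical noise floor
instrument = InstrumentModel(lognormal_sd=0.02, mass_error_ppm_sd=1.0,
                             noise_peaks_per_scan=2.0, noise_intensity_scale=30.0)
run = simulate_run(mixture, instrument, seed=7)
print(f"simulated {len(run.spectra)} scans "
      f"({len(run.ms1_scans())} MS1 windows, {len(run.ms2_scans())} DIA MS2 windows)")

candidates = sorted({e[0].parent for e in mixture.all_entries()}, key=lambda s: s.sort_key)
hits = identify_species(run, candidates, N3PAL)
species_q = quantify_species(hits, istd)
sub_q = quantify_subspecies(identify_subspecies(run, hits), istd)

truth = ground_truth(mixture).species_rows().set_index("species")["pmol"]
print("\nspecies (NL 335.26 basis):")
for _, row in species_q.df.iterrows():
    print(f"  {row['species']:<10} {row['pmol']:8.1f} pmol   (truth {truth[row['species']]:.1f})")

print("\nsubspecies (FA-peak basis):")
for _, row in sub_q.df.iterrows():
    print(f"  {row['species']:<10} {row['subspecies']:<12} {row['pmol']:8.1f} pmol")

# Amounts agree with the spiked truth to within the simulated noise; the
# internal standard itself quantifies at exactly 240 pmol by construction.
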