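"""Generate a small synthetic serum cohort with pre/post spectrum pairs.

Scales the full study design (600 PDAC / 1200 controls, 10 spectra per
subject) down to 60 subjects, forward-models every replicate assay, and
summarizes the resulting dataset manifest.
"""

import dataclasses

from plasmokan import CohortDesign, SensorConfig, simulate

design = dataclasses.replace(CohortDesign().scaled(60), seed=0)
dataset = simulate(design, SensorConfig())
manifest = dataset.manifest()

print(f"subjects: {manifest['subject_id'].nunique()}, records: {len(manifest)}")
print("\nper class (subjects):")
print(manifest.drop_duplicates("subject_id")["class_label"].value_counts().to_string())
print("\nper partition (records):")
print(manifest["partition"].value_counts().to_string())
rec = dataset.records[0]
print(
    f"\nfirst record: {rec.record_id} subject={rec.subject_id} marker={rec.marker} "
    f"grid {rec.pre_spectrum.wavelength_nm[0]:.0f}-{rec.pre_spectrum.wavelength_nm[-1]:.0f} nm, "
    f"{rec.pre_spectrum.wavelength_nm.size} points"
)
print("Each record pairs a bare-chip spectrum with a post-binding spectrum at the")
print("subject's marker concentration; labels are 1 for PDAC, 0 for all controls.")
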