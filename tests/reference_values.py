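"""Published reference values from a replicated vole-molar landmark error audit.

These are the printed per-comparison and per-dataset results of the original
museum-specimen study this package's pipeline re-implements (247 recent
specimens of five Microtus species, 21 landmarks, nine acquisition
replicates, 31 fossil unknowns).  The raw landmark data are not shipped;
these printed numbers serve as fixtures for checking that the reporting
machinery reproduces the published summary rows from their constituent
values.
"""

# comparison, error source, repeatability, ProcANOVA R2 %, |dPGM error| %,
# fossil PGM change %
PAIRWISE_ROWS = [
    ("Dinolite_NoTilt_EO_T1-Dinolite_NoTilt_EO_T2", "intraobserver", 0.80, 6.99, 3.6, 9.7),
    ("Dinolite_NoTilt_NO_T1-Dinolite_NoTilt_NO_T2", "intraobserver", 0.61, 13.74, 3.7, 22.6),
    ("Nikon_NoTilt_EO_T1-Nikon_NoTilt_EO_T2", "intraobserver", 0.64, 12.69, 0.0, 35.5),
    ("Nikon_NoTilt_NO_T1-Nikon_NoTilt_NO_T2", "intraobserver", 0.61, 13.70, 3.3, 22.6),
    ("Dinolite_NoTilt_EO_T1-Dinolite_NoTilt_NO_T1", "interobserver", 0.21, 31.01, 20.6, 32.3),
    ("Dinolite_NoTilt_EO_T2-Dinolite_NoTilt_NO_T2", "interobserver", 0.19, 32.24, 20.7, 16.1),
    ("Dinolite_NoTilt_EO_T1-Dinolite_NoTilt_NO_T2", "interobserver", 0.18, 32.66, 24.3, 25.8),
    ("Dinolite_NoTilt_EO_T2-Dinolite_NoTilt_NO_T1", "interobserver", 0.21, 31.32, 19.8, 32.3),
    ("Nikon_NoTilt_EO_T1-Nikon_NoTilt_NO_T1", "interobserver", 0.58, 14.84, 7.3, 32.3),
    ("Nikon_NoTilt_EO_T2-Nikon_NoTilt_NO_T2", "interobserver", 0.25, 28.87, 10.6, 32.3),
    ("Nikon_NoTilt_EO_T1-Nikon_NoTilt_NO_T2", "interobserver", 0.42, 21.31, 10.6, 29.0),
    ("Nikon_NoTilt_EO_T2-Nikon_NoTilt_NO_T1", "interobserver", 0.39, 22.78, 7.3, 35.5),
    ("Dinolite_NoTilt_EO_T1-Nikon_NoTilt_EO_T1", "device", 0.54, 16.56, 6.4, 35.5),
    ("Dinolite_NoTilt_EO_T2-Nikon_NoTilt_EO_T2", "device", 0.65, 12.36, 2.8, 32.3),
    ("Dinolite_NoTilt_EO_T1-Nikon_NoTilt_EO_T2", "device", 0.63, 12.87, 6.4, 41.9),
    ("Dinolite_NoTilt_EO_T2-Nikon_NoTilt_EO_T1", "device", 0.55, 15.97, 2.8, 25.8),
    ("Dinolite_NoTilt_NO_T1-Nikon_NoTilt_NO_T1", "device", 0.30, 26.65, 6.9, 29.0),
    ("Dinolite_NoTilt_NO_T2-Nikon_NoTilt_NO_T2", "device", 0.35, 24.11, 7.3, 32.3),
    ("Dinolite_NoTilt_NO_T1-Nikon_NoTilt_NO_T2", "device", 0.39, 22.72, 3.6, 29.0),
    ("Dinolite_NoTilt_NO_T2-Nikon_NoTilt_NO_T1", "device", 0.27, 27.84, 10.6, 35.5),
    ("Dinolite_NoTilt_EO_T1-Dinolite_Tilted_EO_T1", "presentation", 0.44, 20.36, 20.6, 45.2),
    ("Dinolite_NoTilt_EO_T2-Dinolite_Tilted_EO_T1", "presentation", 0.45, 20.08, 17.0, 41.9),
]

# nested decomposition across the eight untilted replicate datasets:
# effect -> (df, SS, R2)
NESTED_ROWS = {
    "species": (4, 0.7619, 0.07818),
    "individuals": (247, 5.1919, 0.53276),
    "device": (242, 0.7302, 0.07493),
    "interobservers": (494, 2.0661, 0.21201),
    "intraobservers": (988, 0.9953, 0.10213),
}
NESTED_TOTAL = (1975, 9.7453)

# per-dataset vetted fossil assignment counts and cross-validated training
# error: dataset -> (Mc, Ml, Mm, Mo, Mt, error %)
FOSSIL_ROWS = {
    "Dinolite_NoTilt_EO_T1": (20, 1, 0, 2, 1, 13.8),
    "Dinolite_NoTilt_EO_T2": (14, 1, 0, 2, 0, 17.4),
    "Nikon_NoTilt_EO_T1": (6, 3, 0, 1, 0, 20.2),
    "Nikon_NoTilt_EO_T2": (3, 8, 0, 1, 0, 20.2),
    "Nikon_NoTilt_NO_T1": (10, 1, 0, 1, 0, 27.5),
    "Nikon_NoTilt_NO_T2": (6, 3, 0, 0, 0, 30.8),
    "Dinolite_NoTilt_NO_T1": (12, 1, 0, 0, 0, 34.4),
    "Dinolite_Tilted_EO_T1": (3, 1, 0, 0, 0, 34.4),
    "Dinolite_NoTilt_NO_T2": (13, 0, 0, 0, 0, 38.1),
}
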