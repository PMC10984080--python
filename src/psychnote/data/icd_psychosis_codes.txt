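# Psychosis-related discharge diagnosis codes used by the exact-match ICD baseline.
# One code (or family stem, for prefix matching) per line; '#' starts a comment.
# Edit freely: the baseline reads this file at run time.

# ICD-10
F28        # Other psychotic disorder not due to a substance or known physiological condition
F29        # Unspecified psychosis
F23        # Brief psychotic disorder / other transient psychoses
F20        # Schizophrenia (family stem)
F25        # Schizoaffective disorders (family stem)
F12.15     # Cannabis abuse with psychotic disorder
F12.25     # Cannabis dependence with psychotic disorder
F15.15     # Stimulant abuse with psychotic disorder
F15.25     # Stimulant dependence with psychotic disorder

# ICD-9 equivalents (reconstructed family stems, not an authoritative mapping)
295        # Schizophrenic disorders
297        # Delusional disorders
298        # Other nonorganic psychoses
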