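"""Frozen case/control summary counts for the WES and WGS cohorts.

These are fixed published descriptive-statistics tables used as test
inputs; each entry is ``name -> (counts, expected_p, method)`` where
counts are [case, control] per row and the expected p-value is given at
its printed precision.
"""

# (rows of [case, control] counts, printed p, method)
WES_BLOCKS = {
    "type_of_variant": ([[17, 34], [2, 68]], None, "fisher_exact_2x2"),  # p < 0.0001
    "distribution_of_variants": ([[18, 33], [17, 53]], "0.2250", "fisher_exact_2x2"),
    "cr_sites": ([[6, 5], [9, 7], [1, 1], [2, 4]], "0.8061", "chi_square"),
    "coding_regions": (
        [[2, 2], [3, 7], [4, 3], [2, 2], [4, 3], [0, 2], [0, 4], [1, 5], [0, 1], [4, 7]],
        "0.4854",
        "chi_square",
    ),
    "rrna_trna_genes": ([[9, 8], [1, 7], [3, 1], [0, 1]], "0.1052", "chi_square"),
    "substitution": ([[21, 34], [6, 13], [4, 10], [20, 12]], "0.0527", "chi_square"),
}

WGS_BLOCKS = {
    "type_of_variant": ([[154, 178], [167, 146]], "0.0833", "fisher_exact_2x2"),
    "distribution_of_variants": ([[74, 247], [54, 270]], "0.0482", "fisher_exact_2x2"),
    "cr_sites": ([[18, 17], [32, 23], [8, 6], [16, 8]], "0.7145", "chi_square"),
    "cr_functional_domains": (
        [[16, 10], [1, 1], [5, 10], [7, 5]],
        "0.3574",
        "chi_square",
    ),
    "coding_regions": (
        [
            [15, 14], [19, 27], [12, 21], [9, 6], [2, 1], [16, 19], [8, 11],
            [4, 7], [6, 8], [25, 29], [28, 33], [6, 9], [40, 26],
        ],
        "0.6290",
        "chi_square",
    ),
    "rrna_trna_genes": ([[24, 21], [22, 28], [9, 5], [2, 5]], "0.3456", "chi_square"),
    "substitution": ([[92, 54], [46, 64], [129, 144], [36, 46]], "0.002", "chi_square"),
    "substitution_het": ([[8, 8], [21, 33], [105, 121], [5, 4]], "0.675", "chi_square"),
    # printed p (0.007) appears truncated, not rounded: computed 0.0077
    "substitution_hom": ([[84, 46], [25, 31], [24, 23], [31, 42]], "0.007", "chi_square"),
}

# group summaries: (n, mean, sd) case vs control, printed two-tailed pooled-t p
T_TEST_BLOCKS = {
    "cn_wgs": ((8, 450.3, 71.85), (4, 362.0, 7.20), "0.0377"),
    # printed p (0.413) appears truncated: computed 0.4135
    "cn_wes": ((3, 18.1, 4.5), (3, 26.6, 15.51), "0.413"),
    "burden_wgs": ((8, 40.13, 28.75), (4, 81.0, 70.16), "0.17"),
}
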