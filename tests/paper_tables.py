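"""Published per-region score tables, frozen as test inputs.

Each row: (name, n, raw, min, max, normalized) for the diversity family
and the connectivity family of the two case studies — a beetle
(*Brachyderes rugatus rugatus*, 69 mitochondrial haplotypes, 6 regions,
PD diversity) and a pine (*Pinus pinaster*, 34 chloroplast SSR
haplotypes, 10 locations, AD diversity).  The raw haplotype data behind
these tables is not available in machine-readable form; what the suite
checks is that the normalization arithmetic reproduces every printed
normalized value under exact rational arithmetic and half-up 2-decimal
rounding.
"""

# (region, n, PD, PD_min, PD_max, PD*, HC, HC_min, HC_max, HC*)
BEETLE_TABLE = [
    ("R6", 21, "47", "25", "87", "0.35", "14", "3", "25", "0.50"),
    ("R3", 11, "28", "10", "67", "0.32", "16", "1", "27", "0.58"),
    ("R2", 18, "33", "20", "81", "0.21", "7", "3", "25", "0.18"),
    ("R4", 7, "14", "6", "55", "0.16", "5", "1", "27", "0.15"),
    ("R5", 18, "29", "20", "81", "0.15", "5", "3", "25", "0.09"),
    ("R1", 5, "10", "4", "48", "0.14", "7", "1", "28", "0.22"),
]

# (location, n, AD, AD_min, AD_max, AD*, HC, HC_min, HC_max, HC*)
PINE_TABLE = [
    ("Landes", 6, "2.45", "0.33", "7.14", "0.31", "6", "1", "10", "0.56"),
    ("Pantelleria", 9, "1.67", "0.37", "5.66", "0.25", "3", "1", "10", "0.22"),
    ("Leiria", 8, "0.73", "0.36", "6.06", "0.06", "1", "1", "10", "0.00"),
    ("Sardinia", 9, "0.70", "0.37", "5.66", "0.06", "2", "1", "10", "0.11"),
    ("Morocco", 8, "0.69", "0.36", "6.06", "0.06", "1", "1", "10", "0.00"),
    ("Corsica", 8, "0.68", "0.36", "6.06", "0.06", "1", "1", "10", "0.00"),
    ("Liguria", 5, "0.64", "0.31", "8.06", "0.04", "2", "1", "11", "0.10"),
    ("Moncao", 6, "0.33", "0.33", "7.14", "0.00", "1", "1", "10", "0.00"),
    ("Tuscany", 5, "0.31", "0.31", "8.06", "0.00", "1", "1", "11", "0.00"),
    ("Alcacier", 5, "0.31", "0.31", "8.06", "0.00", "1", "1", "11", "0.00"),
]


def iter_normalization_cells():
    """Yield (table, region, family, raw, lo, hi, printed_normalized)."""
    for table_name, table in (("beetle", BEETLE_TABLE), ("pine", PINE_TABLE)):
        for row in table:
            name = row[0]
            yield (table_name, name, "diversity", *row[2:6])
            yield (table_name, name, "HC", *row[6:10])
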