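"""Regenerate the frozen package data tables in src/epiforest/data/.

Run from the repository root after editing a value; the shipped TSVs are
the source of truth at run time.
"""

AA_IN = "ARNDCQEGHILKMFPSTWYV"  # order values are listed in below
AA_OUT = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical order used in the shipped tables

SCALES = {
    "C1": ("Kyte-Doolittle hydrophobicity", "Kyte & Doolittle, J Mol Biol 157:105 (1982)",
           [1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5, 3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2]),
    "C2": ("Molecular weight", "standard residue molecular weights (Da)",
           [89.0, 174.0, 132.0, 133.0, 121.0, 146.0, 147.0, 75.0, 155.0, 131.0, 131.0, 146.0, 149.0, 165.0, 115.0, 105.0, 119.0, 204.0, 181.0, 117.0]),
    "C3": ("Bulkiness", "Zimmerman, Eliezer & Simha, J Theor Biol 21:170 (1968)",
           [11.50, 14.28, 12.82, 11.68, 13.46, 14.45, 13.57, 3.40, 13.69, 21.40, 21.40, 15.71, 16.25, 19.80, 17.43, 9.47, 15.77, 21.67, 18.03, 21.57]),
    "C4": ("Polarity", "Grantham, Science 185:862 (1974)",
           [8.1, 10.5, 11.6, 13.0, 5.5, 10.5, 12.3, 9.0, 10.4, 5.2, 4.9, 11.3, 5.7, 5.2, 8.0, 9.2, 8.6, 5.4, 6.2, 5.9]),
    "C5": ("Recognition factors", "Fraga, Can J Chem 60:2606 (1982)",
           [78, 95, 94, 81, 89, 87, 78, 84, 84, 88, 85, 87, 80, 81, 91, 107, 93, 104, 84, 89]),
    "C6": ("Hydrophobicity (Fauchere-Pliska)", "Fauchere & Pliska, Eur J Med Chem 18:369 (1983)",
           [0.31, -1.01, -0.60, -0.77, 1.54, -0.22, -0.64, 0.00, 0.13, 1.80, 1.70, -0.99, 1.23, 1.79, 0.72, -0.04, 0.26, 2.25, 0.96, 1.22]),
    "C7": ("HPLC retention coefficient (TFA)", "Browne, Bennett & Solomon, Anal Biochem 124:201 (1982)",
           [7.3, -3.6, -5.7, -2.9, -9.2, -0.3, -7.1, -1.2, -2.1, 6.6, 20.0, -3.7, 5.6, 19.2, 5.1, -4.1, 0.8, 16.3, 5.9, 3.5]),
    "C8": ("Ratio hetero end/side", "Grantham, Science 185:862 (1974)",
           [0.00, 0.65, 1.33, 1.38, 2.75, 0.89, 0.92, 0.74, 0.58, 0.00, 0.00, 0.33, 0.00, 0.00, 0.39, 1.42, 0.71, 0.13, 0.20, 0.00]),
    "C9": ("Average flexibility", "Bhaskaran & Ponnuswamy, Int J Pept Protein Res 32:241 (1988)",
           [0.360, 0.530, 0.460, 0.510, 0.350, 0.490, 0.500, 0.540, 0.320, 0.460, 0.370, 0.470, 0.300, 0.310, 0.510, 0.510, 0.440, 0.310, 0.420, 0.390]),
    "C10": ("Beta-sheet propensity", "Deleage & Roux, Protein Eng 1:289 (1987)",
            [0.709, 0.920, 0.604, 0.541, 1.191, 0.840, 0.567, 0.657, 0.863, 1.799, 1.261, 0.721, 1.210, 1.393, 0.354, 0.928, 1.221, 1.306, 1.266, 1.965]),
    "C11": ("Alpha-helix propensity", "Deleage & Roux, Protein Eng 1:289 (1987)",
            [1.489, 1.224, 0.772, 0.924, 0.966, 1.164, 1.504, 0.510, 1.003, 1.003, 1.236, 1.172, 1.363, 1.195, 0.492, 0.739, 0.785, 1.090, 0.787, 0.990]),
    "C12": ("Beta-turn propensity", "Deleage & Roux, Protein Eng 1:289 (1987)",
            [0.788, 0.912, 1.572, 1.197, 0.965, 0.997, 1.149, 1.860, 0.970, 0.240, 0.670, 1.302, 0.436, 0.624, 1.415, 1.316, 0.739, 0.546, 0.795, 0.387]),
    "C13": ("Relative mutability", "Dayhoff, Schwartz & Orcutt, Atlas Protein Seq Struct 5(3):345 (1978)",
            [100, 65, 134, 106, 20, 93, 102, 49, 66, 96, 40, 56, 94, 41, 56, 120, 97, 18, 41, 74]),
    "C14": ("Number of codons", "standard genetic code",
            [4, 6, 2, 2, 2, 2, 2, 4, 2, 3, 6, 2, 1, 2, 4, 6, 4, 1, 2, 4]),
    "C15": ("Refractivity", "Jones, J Theor Biol 50:167 (1975)",
            [4.34, 26.66, 13.28, 12.00, 35.77, 17.56, 17.26, 0.00, 21.81, 19.06, 18.78, 21.29, 21.64, 29.40, 10.93, 6.35, 11.01, 42.53, 31.53, 13.92]),
    "C16": ("Transmembrane tendency", "Zhao & London, Protein Sci 15:1987 (2006)",
            [0.38, -2.57, -1.62, -3.27, -0.30, -1.84, -2.90, -0.19, -1.44, 1.97, 1.82, -3.46, 1.40, 1.98, -1.44, -0.53, -0.32, 1.53, 0.49, 1.46]),
    "C17": ("Accessible residues (%)", "Janin, Nature 277:491 (1979)",
            [6.6, 4.5, 6.7, 7.7, 0.9, 5.2, 5.7, 6.7, 2.5, 2.8, 4.8, 10.3, 1.0, 2.4, 4.8, 9.4, 7.0, 1.4, 5.1, 4.5]),
    "C18": ("Average area buried", "Rose et al., Science 229:834 (1985)",
            [86.6, 162.2, 103.3, 97.8, 132.3, 119.2, 113.9, 62.9, 155.8, 158.0, 164.1, 115.5, 172.9, 194.1, 92.9, 85.6, 106.5, 224.6, 177.7, 141.0]),
    "C19": ("Coil propensity", "Deleage & Roux, Protein Eng 1:289 (1987)",
            [0.824, 0.893, 1.167, 1.197, 0.953, 0.947, 0.761, 1.251, 1.068, 0.886, 1.085, 0.897, 0.810, 0.915, 1.540, 1.130, 1.148, 0.941, 1.161, 0.772]),
    "C20": ("Total beta-strand propensity", "Lifson & Sander, Nature 282:109 (1979)",
            [0.92, 0.93, 0.89, 0.81, 1.16, 0.95, 0.94, 0.92, 0.93, 1.81, 1.30, 0.70, 1.19, 1.25, 0.40, 0.95, 1.12, 1.54, 1.53, 2.63]),
    "C21": ("Parallel beta-strand propensity", "Lifson & Sander, Nature 282:109 (1979)",
            [1.00, 0.68, 0.54, 0.50, 0.91, 0.28, 0.59, 0.79, 0.38, 2.60, 1.42, 0.59, 1.49, 1.30, 0.35, 0.70, 0.59, 1.02, 1.08, 2.63]),
}

# approximate human proteome residue composition (%), frozen default background
BACKGROUND = [7.01, 5.64, 3.59, 4.74, 2.30, 4.77, 7.10, 6.58, 2.63, 4.34,
              9.97, 5.72, 2.13, 3.65, 6.31, 8.33, 5.36, 1.22, 2.66, 5.96]

SUPERTYPES = [
    ("A01:01", "A1"), ("A26:01", "A1"),
    ("A02:01", "A2"),
    ("A03:01", "A3"), ("A11:01", "A3"),
    ("A23:01", "A24"), ("A24:02", "A24"),
    ("B07:02", "B7"), ("B35:01", "B7"), ("B51:01", "B7"),
    ("B08:01", "B8"),
    ("B27:05", "B27"),
    ("B37:01", "B44"), ("B40:01", "B44"), ("B44:02", "B44"),
    ("B58:01", "B58"),
    ("B15:01", "B62"),
]


def main() -> None:
    perm = [AA_IN.index(a) for a in AA_OUT]

    with open("src/epiforest/data/aa_scales.tsv", "w") as fh:
        fh.write("scale_id\tname\tcitation\t" + "\t".join(AA_OUT) + "\n")
        for sid, (name, cite, vals) in SCALES.items():
            assert len(vals) == 20, sid
            row = [str(vals[i]) for i in perm]
            fh.write(f"{sid}\t{name}\t{cite}\t" + "\t".join(row) + "\n")

    with open("src/epiforest/data/background_frequencies.tsv", "w") as fh:
        fh.write("aa\tfrequency\n")
        total = sum(BACKGROUND)
        for a in AA_OUT:
            fh.write(f"{a}\t{BACKGROUND[AA_IN.index(a)] / total:.6f}\n")

    with open("src/epiforest/data/supertypes.tsv", "w") as fh:
        fh.write("allele\tsupertype\n")
        for allele, st in SUPERTYPES:
            fh.write(f"{allele}\t{st}\n")


if __name__ == "__main__":
    main()
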