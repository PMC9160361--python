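"""Published count columns from a five-year regional newborn-screening
programme (94,648 newborns screened 2016-2020, 23 confirmed cases) used as
the reference fixture for the evaluation arithmetic.

Only raw counts are stored; every rate, frequency string and percentage is
recomputed by :mod:`neoscreen.evaluate`, which is how the arithmetic is
validated against the programme's published tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "SCREENING_BY_YEAR",
    "CONFIRMED_CASES",
    "MUTATION_ALLELES",
    "AI_VS_INITIAL",
    "OVERALL",
    "make_reference_fixture",
]

#: (year, screened, initially flagged, confirmed cases)
SCREENING_BY_YEAR = (
    (2016, 5016, 90, 3),
    (2017, 10717, 201, 4),
    (2018, 18743, 378, 4),
    (2019, 22447, 522, 5),
    (2020, 37725, 797, 7),
)

#: disorder class -> ((disorder, OMIM, confirmed cases), ...)
CONFIRMED_CASES = {
    "amino_acid_disorders": (
        ("Phenylalanine hydroxylase deficiency", "261600", 6),
        ("Citrullinemia type I", "215700", 1),
        ("Neonatal intrahepatic cholestasis citrin deficiency", "605814", 4),
        ("Tyrosinemia type III", "276710", 2),
    ),
    "organic_acid_disorders": (
        ("Isovaleric acidemia", "243500", 1),
        ("Methylmalonic aciduria combined with homocystinuria", "277400", 1),
        ("3-methylcrotonyl-CoA carboxylase deficiency", "210200", 1),
    ),
    "fatty_acid_oxidation_disorders": (
        ("Primary carnitine deficiency", "212140", 5),
        ("Short-chain acyl-CoA dehydrogenase deficiency", "201470", 1),
        ("Very-long-chain acyl-CoA dehydrogenase deficiency", "201475", 1),
    ),
}

#: gene -> variant -> confirmed mutation allele count
MUTATION_ALLELES = {
    "PAH": {
        "c.721C>T": 2, "c.208_210del": 1, "c.826A>G": 1, "c.969+2dup": 1,
        "c.158G>A": 1, "c.1174T>A": 1, "c.728G>A": 1, "c.440C>T": 1,
        "c.498C>G": 1, "5'UTR-exon1del": 1,
    },
    "SLC25A13": {"c.852-855del": 5, "c.762T>A": 1, "c.955C>T": 1, "c.1638_1660dup": 1},
    "ASS1": {"c.1048C>T": 2, "c.649_651del": 1},
    "HPD": {"c.893A>C": 1, "c.109T>G": 1, "c.217T>C": 1, "c.460G>A": 1},
    "ACADS": {"c.1031A>G": 2},
    "IVD": {"c.433C>T": 1, "c.865G>C": 1},
    "MMACHC": {"c.457C>T": 1, "c.481C>T": 1, "c.482G>A": 1},
    "MCCC1": {"c.1331G>A": 1, "c.2035G>A": 1},
    "SLC22A5": {
        "c.51C>G": 2, "c.338G>A": 1, "c.760C>T": 2, "c.884>T": 1,
        "c.893C>T": 1, "c.1340A>T": 1, "c.1400C>G": 1,
    },
    "ACADVL": {"c.1280G>A": 2},
}

#: (group label, model positives, physician positives,
#:  model positives among first-screen negatives)
AI_VS_INITIAL = (
    ("PCD", 238, 474, 66),
    ("MMA/MMA-HCY/PA", 65, 289, 21),
    ("3-MCCD/BKD/HCSD", 148, 73, 113),
    ("PAHD/BH4D", 131, 83, 64),
    ("SCADD/IBDD", 139, 78, 79),
    ("H-MET/HCY", 118, 81, 76),
    ("IVA/2-MBDD", 96, 111, 36),
    ("NICCD/CIT-I/ASA", 125, 64, 61),
    ("H-PRO", 6, 14, 6),
    ("VLCADD", 38, 28, 10),
    ("CPT-ID", 43, 12, 31),
    ("MCADD", 2, 23, 1),
    ("OTCD", 15, 192, 3),
    ("MSUD", 2, 8, 0),
    ("GA-I", 10, 45, 3),
    ("MADD", 28, 17, 13),
)

#: programme-level counts
OVERALL = {
    "n_screened": 94648,
    "initial_positive": 1988,
    "confirmed": 23,
    "ai_positive": 1058,
    "outside_panel_positive": 579,
    "both_positive": 614,
    "ai_only_positive": 444,
}


def make_reference_fixture(outdir) -> dict:
    """Emit the count columns as tab-delimited files so the evaluation
    arithmetic can be exercised without running the pipeline.  Returns a
    mapping of table name to written path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    frame = pd.DataFrame(SCREENING_BY_YEAR,
                         columns=["year", "n_screened", "suspected_positive", "confirmed"])
    paths["screening_by_year"] = out / "screening_by_year.tsv"
    frame.to_csv(paths["screening_by_year"], sep="\t", index=False)

    rows = [
        {"class": cls, "disorder": d, "omim": omim, "confirmed": n}
        for cls, members in CONFIRMED_CASES.items()
        for d, omim, n in members
    ]
    paths["confirmed_cases"] = out / "confirmed_cases.tsv"
    pd.DataFrame(rows).to_csv(paths["confirmed_cases"], sep="\t", index=False)

    rows = [
        {"gene": gene, "variant": variant, "allele_count": count}
        for gene, variants in MUTATION_ALLELES.items()
        for variant, count in variants.items()
    ]
    paths["mutation_alleles"] = out / "mutation_alleles.tsv"
    pd.DataFrame(rows).to_csv(paths["mutation_alleles"], sep="\t", index=False)

    frame = pd.DataFrame(AI_VS_INITIAL,
                         columns=["group", "ai_pos", "phys_pos", "ai_pos_first_neg"])
    paths["ai_vs_initial"] = out / "ai_vs_initial.tsv"
    frame.to_csv(paths["ai_vs_initial"], sep="\t", index=False)

    return paths
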