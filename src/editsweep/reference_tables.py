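"""Published site-count tables packaged as a consistency fixture.

These are the printed polymorphism counts for the three *D. melanogaster*
population panels (DGRP2 inbred lines, and the pooled Florida/Maine
collections) and the human *Alu* editome survey, plus the potential
synonymous/nonsynonymous A→G site counts. The pipeline recomputes every
percentage, rate, and fold ratio from the raw counts and flags any
disagreement with the printed derived values — one printed rate (ME
synonymous edited) is internally inconsistent with its own counts, and the
check reports it rather than papering over it.
"""

from __future__ import annotations

import pandas as pd

from .coding import RateTable
from .popstats import SiteClassCounts

# -- polymorphism-by-class counts (printed Table of SNP sites and types) ----
# columns: population -> dict of raw counts
SITE_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "DGRP2": dict(
        edited_poly=755, edited_mono=2826,
        unedited_poly=3_951_070, unedited_mono=171_048_930,
        edited_AG=740, edited_AC=3, edited_AT=12,
        unedited_AG=817_333, unedited_AC=355_952, unedited_AT=649_599,
    ),
    "FL": dict(
        edited_poly=543, edited_mono=3038,
        unedited_poly=1_367_160, unedited_mono=118_920_513,
        edited_AG=536, edited_AC=1, edited_AT=6,
        unedited_AG=337_098, unedited_AC=142_183, unedited_AT=217_230,
    ),
    "ME": dict(
        edited_poly=507, edited_mono=3074,
        unedited_poly=1_235_454, unedited_mono=119_052_219,
        edited_AG=502, edited_AC=0, edited_AT=5,
        unedited_AG=309_347, unedited_AC=131_624, unedited_AT=195_528,
    ),
    "human_genic": dict(
        edited_poly=231, edited_mono=977,
        unedited_poly=176_080, unedited_mono=2_811_804,
        edited_AG=225, edited_AC=4, edited_AT=2,
        unedited_AG=102_842, unedited_AC=35_491, unedited_AT=37_747,
    ),
    "human_intergenic": dict(
        edited_poly=110, edited_mono=520,
        unedited_poly=196_030, unedited_mono=3_017_246,
        edited_AG=105, edited_AC=3, edited_AT=2,
        unedited_AG=112_936, unedited_AC=38_772, unedited_AT=42_971,
    ),
}

# printed percentages for the same cells (integer-rounded in the source)
PRINTED_PCT: dict[str, dict[str, int]] = {
    "DGRP2": dict(edited_poly=21, unedited_poly=2, edited_AG=98, unedited_AG=45),
    "FL": dict(edited_poly=15, unedited_poly=1, edited_AG=99, unedited_AG=48),
    "ME": dict(edited_poly=14, unedited_poly=1, edited_AG=99, unedited_AG=49),
    "human_genic": dict(edited_poly=19, unedited_poly=6, edited_AG=97, unedited_AG=58),
    "human_intergenic": dict(edited_poly=18, unedited_poly=6, edited_AG=96,
                             unedited_AG=58),
}

# -- potential A,G replacement counts and observed polymorphisms -----------
POTENTIAL_SITES = dict(S_edited=370, S=777_461, N_edited=645, N=4_448_133)

RATE_COUNTS: dict[str, dict[str, int]] = {
    "DGRP2": dict(poly_s_edited=251, poly_s=84_246, poly_n_edited=68, poly_n=29_727),
    "ME": dict(poly_s_edited=181, poly_s=21_198, poly_n_edited=29, poly_n=4_349),
    "FL": dict(poly_s_edited=194, poly_s=22_603, poly_n_edited=33, poly_n=4_647),
}

PRINTED_RATES: dict[str, dict[str, float]] = {
    "DGRP2": dict(f_s_edited=0.678, f_s=0.108, fold_s=6,
                  f_n_edited=0.105, f_n=0.007, fold_n=15),
    "ME": dict(f_s_edited=0.511, f_s=0.027, fold_s=19,
               f_n_edited=0.045, f_n=0.001, fold_n=45),
    "FL": dict(f_s_edited=0.524, f_s=0.029, fold_s=18,
               f_n_edited=0.051, f_n=0.001, fold_n=51),
}

# neutral synonymous rate used for the pooled binomial excess test
F_S_MEAN = 0.055


def site_class_counts(population: str) -> SiteClassCounts:
    c = SITE_CLASS_COUNTS[population]
    return SiteClassCounts(
        edited_polymorphic=c["edited_poly"],
        edited_monomorphic=c["edited_mono"],
        unedited_polymorphic=c["unedited_poly"],
        unedited_monomorphic=c["unedited_mono"],
        edited_types={"AG": c["edited_AG"], "AC": c["edited_AC"], "AT": c["edited_AT"]},
        unedited_types={
            "AG": c["unedited_AG"], "AC": c["unedited_AC"], "AT": c["unedited_AT"]
        },
    )


def rate_table(population: str) -> RateTable:
    c = RATE_COUNTS[population]
    p = POTENTIAL_SITES
    return RateTable(
        S=p["S"], N=p["N"], S_edited=p["S_edited"], N_edited=p["N_edited"],
        poly_s=c["poly_s"], poly_n=c["poly_n"],
        poly_s_edited=c["poly_s_edited"], poly_n_edited=c["poly_n_edited"],
    )


def check_site_class_table() -> pd.DataFrame:
    """Recompute every percentage from the raw counts and compare with the
    printed integer percentages."""
    rows = []
    for pop in SITE_CLASS_COUNTS:
        counts = site_class_counts(pop)
        computed = {
            "edited_poly": counts.edited_polymorphic_pct,
            "unedited_poly": counts.unedited_polymorphic_pct,
            "edited_AG": counts.type_pct("edited", "AG"),
            "unedited_AG": counts.type_pct("unedited", "AG"),
        }
        for cell, value in computed.items():
            printed = PRINTED_PCT[pop][cell]
            rows.append(
                {
                    "population": pop,
                    "cell": cell,
                    "computed_pct": value,
                    "computed_rounded": round(value),
                    "printed_pct": printed,
                    "match": round(value) == printed,
                }
            )
    return pd.DataFrame(rows)


def check_rate_table() -> pd.DataFrame:
    """Recompute rates and folds from counts; mismatching printed values
    (notably the ME synonymous edited rate) are flagged, not suppressed."""
    rows = []
    for pop in RATE_COUNTS:
        rt = rate_table(pop)
        printed = PRINTED_RATES[pop]
        cells = {
            "f_s_edited": (rt.f_s_edited, 3),
            "f_s": (rt.f_s, 3),
            "fold_s": (rt.fold("s"), 0),
            "f_n_edited": (rt.f_n_edited, 3),
            "f_n": (rt.f_n, 3),
            "fold_n": (rt.fold("n"), 0),
        }
        for cell, (value, ndigits) in cells.items():
            rounded = round(value, ndigits) if ndigits else round(value)
            rows.append(
                {
                    "population": pop,
                    "cell": cell,
                    "computed": value,
                    "computed_rounded": rounded,
                    "printed": printed[cell],
                    "match": rounded == printed[cell],
                }
            )
    return pd.DataFrame(rows)


def pooled_nonsynonymous_excess() -> dict[str, float]:
    """Aggregate nonsynonymous edited-site excess over the neutral synonymous
    rate, under two aggregations (the source states neither explicitly):
    pooled counts across populations, and the mean of per-population rates."""
    from .coding import binomial_excess_test

    pops = list(RATE_COUNTS)
    k = sum(RATE_COUNTS[p]["poly_n_edited"] for p in pops)
    n = POTENTIAL_SITES["N_edited"] * len(pops)
    mean_rate = sum(
        RATE_COUNTS[p]["poly_n_edited"] / POTENTIAL_SITES["N_edited"] for p in pops
    ) / len(pops)
    return {
        "pooled_k": k,
        "pooled_n": n,
        "pooled_ratio": (k / n) / F_S_MEAN,
        "mean_of_rates_ratio": mean_rate / F_S_MEAN,
        "binomial_p_pooled": binomial_excess_test(k, n, F_S_MEAN),
    }
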