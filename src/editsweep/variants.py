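"""Pool-seq SNP calling, allele frequencies, and outgroup polarization.

Polarization follows the ascertainment logic of editome annotation: editing
is only annotatable on a homozygous-A background, so every comparable SNP
has the A allele as the focal reference on the editing strand. Both
polarization directions therefore restrict to sense-A reference sites:
A→G keeps sites where the outgroup is monomorphic A (derived = G), and G→A
keeps sites where the outgroup is monomorphic G (ancestral = G, derived = A).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Outgroup

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def call_pool_snps(
    pool: pd.DataFrame, min_coverage: int = 10, min_alt_reads: int = 2
) -> pd.DataFrame:
    """Call a pooled site polymorphic when total reads ≥ min_coverage and
    alternative reads ≥ min_alt_reads."""
    if (pool[["g", "r"]] < 0).to_numpy().any():
        raise ValueError("negative pool counts")
    called = (pool["r"] >= min_coverage) & (pool["g"] >= min_alt_reads)
    return pool[called].reset_index(drop=True)


def genotype_freq(gt_alt: int, gt_ref: int) -> float | None:
    """Derived-allele frequency from homozygote line counts (panel mode)."""
    denom = gt_alt + gt_ref
    if denom == 0:
        return None
    return gt_alt / denom


def pool_freq(g: int, r: int) -> float | None:
    """Derived-allele frequency from pooled reads: g/r."""
    if r == 0:
        return None
    return g / r


def add_frequencies(snps: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Vectorised derived_freq column for a panel- or pool-mode SNP frame."""
    out = snps.copy()
    if mode == "panel":
        denom = out["gt_alt"] + out["gt_ref"]
        out["derived_freq"] = np.where(denom > 0, out["gt_alt"] / denom.replace(0, 1), np.nan)
        out.loc[denom == 0, "derived_freq"] = np.nan
    elif mode == "pool":
        out["derived_freq"] = np.where(out["r"] > 0, out["g"] / out["r"].replace(0, 1), np.nan)
        out.loc[out["r"] == 0, "derived_freq"] = np.nan
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def _sense(base: str, strand: str) -> str:
    return base if strand == "+" else _COMP[base]


def polarize(
    snps: pd.DataFrame,
    outgroup: Outgroup,
    direction: str = "AG",
    min_outgroup_lines: int = 1,
) -> pd.DataFrame:
    """Assign ancestral/derived states under the ascertainment rules.

    ``snps`` needs chrom/pos/ref/alt columns and optionally a ``strand``
    column (defaults to + for ref A, − for ref T). Every input row is
    returned with ``passes`` and a single ``reason``; rows that pass gain
    ancestral/derived columns. ``min_outgroup_lines`` is the minimum number
    of outgroup alleles observed for a site to count as covered; note that a
    plain allele set carries no multiplicity, so values >1 require the
    loader to have preserved multiple lines as distinct alleles or the
    caller to pre-filter.
    """
    if direction not in ("AG", "GA"):
        raise ValueError("direction must be 'AG' or 'GA'")
    want_outgroup = "A" if direction == "AG" else "G"
    derived = "G" if direction == "AG" else "A"

    rows = []
    has_strand = "strand" in snps.columns
    for row in snps.itertuples(index=False):
        # without an explicit strand, purine reference bases read on +, so a
        # genomic T,C SNP maps to the sense A,G pair on −
        strand = row.strand if has_strand else ("-" if row.ref in ("T", "C") else "+")
        sense_ref = _sense(row.ref, strand)
        sense_alt = _sense(row.alt, strand)
        passes, reason = False, ""
        if {sense_ref, sense_alt} != {"A", "G"}:
            reason = "not_AG"
        elif sense_ref != "A":
            reason = "ref_not_A"
        else:
            og = outgroup.get(row.chrom, row.pos)
            if og is None:
                reason = "uncovered"
            elif len(og) < min_outgroup_lines:
                reason = "too_few_outgroup_lines"
            else:
                og_sense = frozenset(_sense(b, strand) for b in og)
                if len(og_sense) > 1:
                    reason = "outgroup_polymorphic"
                elif og_sense != {want_outgroup}:
                    reason = "outgroup_mismatch"
                else:
                    passes, reason = True, "pass"
        anc = ("A" if direction == "AG" else "G") if passes else ""
        rows.append(
            (row.chrom, row.pos, strand, row.ref, row.alt, anc,
             derived if passes else "", direction[0] + "->" + direction[1],
             passes, reason)
        )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "ref", "alt", "ancestral", "derived",
                 "direction", "passes", "reason"],
    )
    # carry frequency columns through untouched
    for col in ("derived_freq", "gt_ref", "gt_alt", "g", "r", "is_edited", "count", "freq"):
        if col in snps.columns:
            out[col] = snps[col].to_numpy()
    if direction == "GA" and "derived_freq" in out.columns:
        # stored frequency tracks the alt (= G) allele; derived here is A
        out.loc[out["passes"], "derived_freq"] = 1.0 - out.loc[out["passes"], "derived_freq"]
    return out


@dataclass
class CoverageDiagnostics:
    ranksum_stat: float | None
    ranksum_p: float | None
    corr: float | None
    corr_p: float | None


def coverage_diagnostics(pool: pd.DataFrame, edited_mask: np.ndarray
                         ) -> CoverageDiagnostics:
    """Pool-seq sanity checks: edited vs unedited coverage (two-sided
    rank-sum) and Spearman correlation of coverage with minor allele freq."""
    cov = pool["r"].to_numpy(float)
    freq = pool["g"].to_numpy(float) / np.maximum(cov, 1)
    maf = np.minimum(freq, 1 - freq)
    edited_mask = np.asarray(edited_mask, bool)

    if edited_mask.sum() < 2 or (~edited_mask).sum() < 2:
        logger.warning("coverage_diagnostics: <2 sites in a class, rank test skipped")
        rs_stat = rs_p = None
    else:
        rs = stats.ranksums(cov[edited_mask], cov[~edited_mask])
        rs_stat, rs_p = float(rs.statistic), float(rs.pvalue)
    if len(cov) < 3 or np.ptp(cov) == 0 or np.ptp(maf) == 0:
        corr = corr_p = None
    else:
        rho = stats.spearmanr(cov, maf)
        corr, corr_p = float(rho.statistic), float(rho.pvalue)
    return CoverageDiagnostics(rs_stat, rs_p, corr, corr_p)


def write_polarized_tsv(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos1": df["pos"] + 1,
            "ancestral": df["ancestral"],
            "derived": df["derived"],
            "direction": df["direction"],
            "derived_freq": df.get("derived_freq", np.nan),
            "status": np.where(df["passes"], "pass", "fail:" + df["reason"]),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
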