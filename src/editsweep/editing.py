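"""De novo A-to-I editing-site calling from multi-sample RNA pileups.

A site is called edited when the strand-aware edited-read fraction (G reads
over A+G on the + strand, C over T+C on the −) exceeds ``min_g_fraction`` in
strictly more than ``min_sample_fraction`` of the covered samples, and the
site is not a known SNP segregating above ``snp_freq_cutoff``. Both
inequalities are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Genome

logger = logging.getLogger(__name__)


@dataclass
class EditCall:
    chrom: str
    pos: int
    strand: str
    called: bool
    editing_level: float | None
    n_supporting_samples: int
    n_covered_samples: int
    reason: str  # "called" | "below_sample_fraction" | "known_snp" | "no_coverage"


def _strand_counts(df: pd.DataFrame, strand: str) -> tuple[np.ndarray, np.ndarray]:
    """(edited reads, unedited reads) per row on the annotated strand."""
    if strand == "+":
        return df["nG"].to_numpy(), df["nA"].to_numpy()
    return df["nC"].to_numpy(), df["nT"].to_numpy()


def _site_strand(genome: Genome, chrom: str, pos: int) -> str | None:
    base = genome.base(chrom, pos)
    if base == "A":
        return "+"
    if base == "T":
        return "-"
    return None


def call_edited_sites(
    pileups: pd.DataFrame,
    genome: Genome,
    known_snp_freqs: dict[tuple[str, int], float] | None = None,
    min_g_fraction: float = 0.01,
    min_sample_fraction: float = 0.5,
    snp_freq_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Apply the editing decision rule at every site present in the pileups.

    Returns one row per A/T reference site with the call, pooled editing
    level, and supporting-sample counts. Zero-depth samples are excluded from
    the sample-fraction denominator.
    """
    if pileups.empty:
        raise ValueError("pileup table is empty")
    for t in (min_g_fraction, min_sample_fraction, snp_freq_cutoff):
        if not 0.0 < t < 1.0:
            raise ValueError(f"threshold {t} outside (0, 1)")
    known_snp_freqs = known_snp_freqs or {}

    rows = []
    n_zero_depth = 0
    for (chrom, pos), grp in pileups.groupby(["chrom", "pos"], sort=True):
        strand = _site_strand(genome, chrom, pos)
        if strand is None:
            continue  # not an A/T reference site
        edited, unedited = _strand_counts(grp, strand)
        depth = edited + unedited
        covered = depth > 0
        n_zero_depth += int((~covered).sum())
        n_cov = int(covered.sum())
        if n_cov == 0:
            rows.append((chrom, pos, strand, False, np.nan, 0, 0, "no_coverage"))
            continue
        frac = edited[covered] / depth[covered]
        n_support = int((frac > min_g_fraction).sum())
        level = float(edited.sum() / depth.sum())
        passes_rna = n_support > min_sample_fraction * n_cov
        if not passes_rna:
            rows.append(
                (chrom, pos, strand, False, level, n_support, n_cov, "below_sample_fraction")
            )
            continue
        if known_snp_freqs.get((chrom, pos), 0.0) > snp_freq_cutoff:
            rows.append((chrom, pos, strand, False, level, n_support, n_cov, "known_snp"))
            continue
        rows.append((chrom, pos, strand, True, level, n_support, n_cov, "called"))
    if n_zero_depth:
        logger.info("call_edited_sites: %d zero-depth site/sample pairs excluded",
                    n_zero_depth)
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "called", "editing_level",
                 "n_supporting_samples", "n_covered_samples", "reason"],
    )


def editing_level(pileups: pd.DataFrame, chrom: str, pos: int, strand: str
                  ) -> float | None:
    """Pooled editing level: edited reads over edited + unedited reads across
    samples, on the annotated strand. ``None`` when the pooled depth is zero."""
    grp = pileups[(pileups["chrom"] == chrom) & (pileups["pos"] == pos)]
    if grp.empty:
        raise ValueError(f"site {chrom}:{pos} not covered by pileups")
    edited, unedited = _strand_counts(grp, strand)
    depth = int(edited.sum() + unedited.sum())
    if depth == 0:
        logger.warning("editing_level: zero pooled depth at %s:%d", chrom, pos)
        return None
    return float(edited.sum() / depth)


def annotate_region_class(
    sites: pd.DataFrame,
    coding_contexts: pd.DataFrame,
    gene_models: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach a region class to each site: CDS_synonymous/CDS_nonsynonymous
    from the coding-effect scan, intron/UTR from annotated features when the
    gene models carry them, intergenic otherwise."""
    effect = {
        (c, p): e
        for c, p, e in zip(coding_contexts["chrom"], coding_contexts["pos"],
                           coding_contexts["effect"])
    }
    feature_of = {}
    if gene_models is not None and "feature" in gene_models.columns:
        for kind, label in (("intron", "intron"),
                            ("five_prime_UTR", "UTR"), ("three_prime_UTR", "UTR")):
            for r in gene_models[gene_models["feature"] == kind].itertuples(index=False):
                for p in range(r.start, r.end):
                    feature_of[(r.chrom, p)] = label
    classes = []
    for row in sites.itertuples(index=False):
        key = (row.chrom, row.pos)
        eff = effect.get(key)
        if eff == "synonymous":
            classes.append("CDS_synonymous")
        elif eff is not None:
            classes.append("CDS_nonsynonymous")
        else:
            classes.append(feature_of.get(key, "intergenic"))
    out = sites.copy()
    out["region_class"] = classes
    return out


def restrict_to_regions(sites: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Subset sites to those contained in the half-open mask intervals."""
    if intervals.empty:
        return sites.iloc[0:0]
    keep = np.zeros(len(sites), dtype=bool)
    for chrom, grp in intervals.groupby("chrom", sort=False):
        starts = np.sort(grp["start"].to_numpy())
        ends = grp.sort_values("start")["end"].to_numpy()
        mask = sites["chrom"] == chrom
        pos = sites.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        keep[np.flatnonzero(mask.to_numpy())[ok]] = True
    return sites[keep].reset_index(drop=True)
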