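"""Window diversity scans, EHH/iHH/iHS from scratch, and related helpers.

The haplotype statistics follow the standard definitions: EHH at distance x
from a core allele is the probability that two random carrier haplotypes are
identical over the stretch from the core to x; iHH integrates EHH over
genetic distance out to where it decays below a floor; the unstandardized
iHS is ln(iHH_ancestral / iHH_derived), standardized within derived-allele
frequency bins so that strongly negative values mark unusually long
haplotypes carrying the derived allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# windows

def window_snp_counts(
    centers: pd.DataFrame,
    snps: pd.DataFrame,
    window_size: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """SNPs in [center − w/2, center + w/2) around each center, center excluded.

    Windows truncated by a chromosome end are flagged when lengths are given.
    """
    if window_size % 2 != 0:
        raise ValueError("window_size must be even")
    half = window_size // 2
    snp_pos = {c: np.sort(g["pos"].to_numpy()) for c, g in snps.groupby("chrom")}
    rows = []
    for row in centers.itertuples(index=False):
        pos_arr = snp_pos.get(row.chrom, np.empty(0, int))
        lo = np.searchsorted(pos_arr, row.pos - half, side="left")
        hi = np.searchsorted(pos_arr, row.pos + half, side="left")
        count = int(hi - lo)
        # exclude the center site itself if present
        ci = np.searchsorted(pos_arr, row.pos)
        if ci < len(pos_arr) and pos_arr[ci] == row.pos:
            count -= 1
        truncated = False
        if chrom_lengths is not None:
            length = chrom_lengths.get(row.chrom, np.inf)
            truncated = row.pos - half < 0 or row.pos + half > length
        rows.append((row.chrom, row.pos, count, truncated))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "snp_count", "truncated"])
    for col in ("is_edited", "derived_freq"):
        if col in centers.columns:
            out[col] = centers[col].to_numpy()
    return out


def poly_div_windows(
    windows: pd.DataFrame,
    divergence: pd.DataFrame,
    window_size: int = 10_000,
) -> pd.DataFrame:
    """Attach per-window divergence counts and the polymorphism/divergence
    ratio (missing where divergence is zero; the window is retained)."""
    half = window_size // 2
    div_pos = {c: np.sort(g["pos"].to_numpy()) for c, g in divergence.groupby("chrom")}
    counts = []
    for row in windows.itertuples(index=False):
        pos_arr = div_pos.get(row.chrom, np.empty(0, int))
        lo = np.searchsorted(pos_arr, row.pos - half, side="left")
        hi = np.searchsorted(pos_arr, row.pos + half, side="left")
        counts.append(int(hi - lo))
    out = windows.copy()
    out["div_count"] = counts
    out["poly_div_ratio"] = np.where(
        out["div_count"] > 0, out["snp_count"] / np.maximum(out["div_count"], 1), np.nan
    )
    return out


# ---------------------------------------------------------------------------
# recombination map

def interpolate_recomb(
    recomb: pd.DataFrame, chrom: str, position: int | np.ndarray
) -> float | np.ndarray:
    """Piecewise-linear cM at ``position``; positions outside the anchor span
    are clamped to the nearest anchor with a warning."""
    grp = recomb[recomb["chrom"] == chrom]
    if grp.empty:
        raise ValueError(f"no recombination anchors for {chrom}")
    xp = grp["pos"].to_numpy(float)
    fp = grp["cM"].to_numpy(float)
    pos = np.asarray(position, float)
    n_out = int(np.sum((pos < xp[0]) | (pos > xp[-1])))
    if n_out:
        logger.warning("interpolate_recomb: %d position(s) outside map span on %s; "
                       "clamped to nearest anchor", n_out, chrom)
    out = np.interp(pos, xp, fp)
    return float(out) if np.isscalar(position) or pos.ndim == 0 else out


def window_recomb_rate(
    recomb: pd.DataFrame, chrom: str, center: int, window_size: int
) -> float:
    """Mean recombination rate over the window, in cM/Mb."""
    half = window_size // 2
    c0 = interpolate_recomb(recomb, chrom, center - half)
    c1 = interpolate_recomb(recomb, chrom, center + half)
    return (c1 - c0) / (window_size / 1e6)


def annotate_windows(
    windows: pd.DataFrame,
    recomb: pd.DataFrame | None,
    genome=None,
    window_size: int = 10_000,
) -> pd.DataFrame:
    """Add recombination-rate and GC covariates to a window table."""
    out = windows.copy()
    half = window_size // 2
    if recomb is not None:
        rate = np.empty(len(out))
        for chrom in out["chrom"].unique():
            m = (out["chrom"] == chrom).to_numpy()
            pos = out.loc[m, "pos"].to_numpy()
            c0 = interpolate_recomb(recomb, chrom, pos - half)
            c1 = interpolate_recomb(recomb, chrom, pos + half)
            rate[m] = (c1 - c0) / (window_size / 1e6)
        out["recomb_rate"] = rate
    if genome is not None:
        gcs = []
        for r in out.itertuples(index=False):
            seq = genome.fetch(r.chrom, max(0, r.pos - half), r.pos + half)
            gcs.append((seq.count("G") + seq.count("C")) / max(1, len(seq)))
        out["gc"] = gcs
    return out


# ---------------------------------------------------------------------------
# ANCOVA

@dataclass
class AncovaReport:
    coef_editing: float
    f_stat: float
    p_value: float
    n_edited: int
    n_unedited: int
    condition_number: float


def ancova_editing_effect(
    windows: pd.DataFrame, min_center_freq: float = 0.0
) -> AncovaReport:
    """OLS of the polymorphism/divergence ratio on the editing factor with
    recombination rate and GC as covariates; type-II F-test for the factor."""
    df = windows.dropna(subset=["poly_div_ratio", "recomb_rate", "gc"]).copy()
    if "derived_freq" in df.columns and min_center_freq > 0:
        df = df[df["derived_freq"] >= min_center_freq]
    n_e = int(df["is_edited"].sum())
    n_u = int(len(df) - n_e)
    if min(n_e, n_u) < 10:
        raise ValueError(
            f"need >= 10 windows per class after filtering (got {n_e} edited, {n_u} unedited)"
        )
    df["edited"] = df["is_edited"].astype(int)
    model = ols("poly_div_ratio ~ edited + recomb_rate + gc", data=df).fit()
    if model.condition_number > 1e6:
        logger.warning("ancova_editing_effect: collinear covariates "
                       "(condition number %.2g)", model.condition_number)
    anova = sm.stats.anova_lm(model, typ=2)
    return AncovaReport(
        coef_editing=float(model.params["edited"]),
        f_stat=float(anova.loc["edited", "F"]),
        p_value=float(anova.loc["edited", "PR(>F)"]),
        n_edited=n_e,
        n_unedited=n_u,
        condition_number=float(model.condition_number),
    )


# ---------------------------------------------------------------------------
# EHH / iHS

@dataclass
class EhhCurve:
    """EHH per flank; index 0 of each array is the marker adjacent to the core."""

    core: int
    n_carriers: int
    left: np.ndarray   # markers core−1, core−2, ...
    right: np.ndarray  # markers core+1, core+2, ...


def ehh(hap: np.ndarray, core: int, allele: int) -> EhhCurve:
    """Extended haplotype homozygosity of the carriers of ``allele`` at the
    core marker, computed outward per flank. EHH at the core itself is 1."""
    hap = np.asarray(hap)
    carriers = np.flatnonzero(hap[:, core] == allele)
    n = len(carriers)
    if n < 2:
        raise ValueError(f"<2 carriers of allele {allele} at core {core}")
    denom = n * (n - 1) / 2

    def flank(indices) -> np.ndarray:
        vals = np.empty(len(indices))
        labels = np.zeros(n, dtype=np.int64)
        for k, m in enumerate(indices):
            pair = labels * 2 + hap[carriers, m]
            _, labels = np.unique(pair, return_inverse=True)
            counts = np.bincount(labels)
            vals[k] = (counts * (counts - 1) / 2).sum() / denom
        return vals

    return EhhCurve(
        core=core,
        n_carriers=n,
        left=flank(range(core - 1, -1, -1)),
        right=flank(range(core + 1, hap.shape[1])),
    )


def _ihh_side(ehh_vals: np.ndarray, dists: np.ndarray, floor: float) -> float:
    """Trapezoidal integral of [1] + ehh_vals over [0] + dists, truncated at
    the first marker where EHH drops below ``floor`` (that segment included)."""
    values = np.concatenate([[1.0], ehh_vals])
    xs = np.concatenate([[0.0], dists])
    below = np.flatnonzero(values < floor)
    stop = below[0] if len(below) else len(values) - 1
    if stop == 0:
        return 0.0
    return float(np.trapezoid(values[: stop + 1], xs[: stop + 1]))


@dataclass
class IhsSite:
    chrom: str
    pos: int
    derived_freq: float
    ihh_ancestral: float
    ihh_derived: float
    uihs: float


def ihs_unstandardized(
    hap: np.ndarray,
    core: int,
    map_pos: np.ndarray,
    ehh_floor: float = 0.05,
) -> tuple[float, float, float] | None:
    """(iHH_A, iHH_D, uiHS) for one core, or None when undefined (fewer than
    two carriers of either allele, or a zero integral)."""
    try:
        curve_a = ehh(hap, core, 0)
        curve_d = ehh(hap, core, 1)
    except ValueError:
        return None
    left_d = np.abs(map_pos[core] - map_pos[core - 1 :: -1]) if core > 0 else np.empty(0)
    right_d = np.abs(map_pos[core + 1 :] - map_pos[core])

    def total(curve: EhhCurve) -> float:
        return _ihh_side(curve.left, left_d, ehh_floor) + _ihh_side(
            curve.right, right_d, ehh_floor
        )

    ihh_a, ihh_d = total(curve_a), total(curve_d)
    if ihh_a <= 0 or ihh_d <= 0:
        return None
    return ihh_a, ihh_d, float(np.log(ihh_a / ihh_d))


def ihs(
    cores: pd.DataFrame,
    haplotypes: dict[tuple[str, int], tuple[np.ndarray, int, np.ndarray]],
    ehh_floor: float = 0.05,
    freq_bin_width: float = 0.05,
    min_bin_n: int = 10,
) -> pd.DataFrame:
    """Standardized iHS over polarized core sites.

    ``haplotypes`` maps (chrom, pos) to (hap matrix, core column index, map
    positions in cM — physical positions scaled to cM are an accepted
    fallback). Standardization is within derived-frequency bins of width
    ``freq_bin_width`` using the sample SD; bins with fewer than
    ``min_bin_n`` sites keep only the unstandardized score.
    """
    sites: list[IhsSite] = []
    n_skipped = 0
    for row in cores.itertuples(index=False):
        key = (row.chrom, row.pos)
        if key not in haplotypes:
            n_skipped += 1
            continue
        hap, core, map_pos = haplotypes[key]
        res = ihs_unstandardized(hap, core, np.asarray(map_pos, float), ehh_floor)
        if res is None:
            n_skipped += 1
            continue
        ihh_a, ihh_d, u = res
        freq = float(np.mean(hap[:, core]))
        sites.append(IhsSite(row.chrom, row.pos, freq, ihh_a, ihh_d, u))
    if n_skipped:
        logger.info("ihs: %d cores skipped (missing haplotypes or undefined iHH)",
                    n_skipped)
    df = pd.DataFrame([s.__dict__ for s in sites])
    if df.empty:
        df["freq_bin"] = []
        df["ihs"] = []
        return df
    df["freq_bin"] = np.minimum(
        (df["derived_freq"] / freq_bin_width).astype(int),
        int(np.ceil(1.0 / freq_bin_width)) - 1,
    )
    df["ihs"] = np.nan
    for _, idx in df.groupby("freq_bin").groups.items():
        vals = df.loc[idx, "uihs"]
        if len(vals) >= min_bin_n and vals.std(ddof=1) > 0:
            df.loc[idx, "ihs"] = (vals - vals.mean()) / vals.std(ddof=1)
    return df


# ---------------------------------------------------------------------------
# balancing-selection scan input

def build_balancing_input(
    focal: pd.DataFrame,
    informative: pd.DataFrame,
    recomb: pd.DataFrame,
    window_sites: int = 200,
) -> dict[tuple[str, int], pd.DataFrame]:
    """Neighborhood tables for an external balancing-selection likelihood scan.

    ``informative`` holds chrom/pos/kind rows (kind ∈ {poly, div}). For each
    focal site the nearest ``window_sites // 2`` informative sites per side
    are emitted with their type flag and interpolated genetic distance to the
    focal site; shorter windows near chromosome ends are flagged.
    """
    per_side = window_sites // 2
    by_chrom = {
        c: g.sort_values("pos").reset_index(drop=True)
        for c, g in informative.groupby("chrom")
    }
    out: dict[tuple[str, int], pd.DataFrame] = {}
    for row in focal.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        pos_arr = grp["pos"].to_numpy()
        i = np.searchsorted(pos_arr, row.pos)
        # exclude the focal site itself from its own window
        left_end = i
        right_start = i
        while right_start < len(pos_arr) and pos_arr[right_start] == row.pos:
            right_start += 1
        lo = max(0, left_end - per_side)
        hi = min(len(pos_arr), right_start + per_side)
        window = grp.iloc[np.r_[lo:left_end, right_start:hi]].copy()
        focal_cm = interpolate_recomb(recomb, row.chrom, row.pos)
        window["cm_dist"] = np.abs(
            interpolate_recomb(recomb, row.chrom, window["pos"].to_numpy()) - focal_cm
        )
        window["short_window"] = len(window) < 2 * per_side
        out[(row.chrom, row.pos)] = window.reset_index(drop=True)
    return out


def write_balancing_input(tables: dict, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_chrom: dict[str, list[pd.DataFrame]] = {}
    for (chrom, pos), df in sorted(tables.items()):
        d = df.copy()
        d.insert(0, "focal_pos1", pos + 1)
        by_chrom.setdefault(chrom, []).append(d)
    for chrom, frames in by_chrom.items():
        cat = pd.concat(frames, ignore_index=True)
        cat["pos1"] = cat["pos"] + 1
        cat[["focal_pos1", "pos1", "kind", "cm_dist", "short_window"]].to_csv(
            outdir / f"{chrom}.tsv", sep="\t", index=False, float_format="%.6f"
        )
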