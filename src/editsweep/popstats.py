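"""Edited-vs-unedited contingency tables, resampled derived-allele frequency
spectra, nearest-control matching, and spectrum comparisons.

The resampling null draws, per replicate, as many unedited sites as there
are edited sites — without replacement — and bins their derived frequencies.
Since only bin counts enter the spectrum, each replicate's binned draw
follows the multivariate hypergeometric law over the binned unedited
frequencies, which is sampled directly (exactly equivalent to resampling
individual sites and far cheaper at 100,000 replicates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SiteClassCounts:
    """Polymorphism counts by site class, in the printed-table layout."""

    edited_polymorphic: int
    edited_monomorphic: int
    unedited_polymorphic: int
    unedited_monomorphic: int
    edited_types: dict[str, int] = field(default_factory=dict)    # "AG"/"AC"/"AT"
    unedited_types: dict[str, int] = field(default_factory=dict)

    @property
    def edited_polymorphic_pct(self) -> float:
        tot = self.edited_polymorphic + self.edited_monomorphic
        return 100.0 * self.edited_polymorphic / tot if tot else float("nan")

    @property
    def unedited_polymorphic_pct(self) -> float:
        tot = self.unedited_polymorphic + self.unedited_monomorphic
        return 100.0 * self.unedited_polymorphic / tot if tot else float("nan")

    def type_pct(self, which: str, key: str) -> float:
        types = self.edited_types if which == "edited" else self.unedited_types
        tot = sum(types.values())
        return 100.0 * types.get(key, 0) / tot if tot else float("nan")

    def fold(self) -> float | None:
        a, b = self.edited_polymorphic_pct, self.unedited_polymorphic_pct
        return a / b if b else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, poly, mono, types in (
            ("edited", self.edited_polymorphic, self.edited_monomorphic, self.edited_types),
            ("unedited", self.unedited_polymorphic, self.unedited_monomorphic,
             self.unedited_types),
        ):
            tot = poly + mono
            rows.append(
                {
                    "class": cls, "polymorphic": poly, "monomorphic": mono,
                    "polymorphic_pct": round(100.0 * poly / tot) if tot else np.nan,
                    "AG": types.get("AG", 0), "AC": types.get("AC", 0),
                    "AT": types.get("AT", 0),
                }
            )
        return pd.DataFrame(rows)


def tabulate(
    snps: pd.DataFrame,
    edited_sites: pd.DataFrame,
    n_edited_total: int,
    n_unedited_total: int,
) -> SiteClassCounts:
    """Cross-tabulate polymorphism and polymorphism type by editing class.

    ``snps`` needs chrom/pos and a sense alternative allele column
    (``sense_alt``); totals are the numbers of scanned A sites per class.
    """
    edited_keys = set(zip(edited_sites["chrom"], edited_sites["pos"]))
    if snps.empty:
        is_edited = np.zeros(0, dtype=bool)
    else:
        is_edited = np.fromiter(
            ((c, p) in edited_keys for c, p in zip(snps["chrom"], snps["pos"])),
            bool, len(snps),
        )
    e_poly = int(is_edited.sum())
    u_poly = int(len(snps) - e_poly)

    def type_counts(sub: pd.DataFrame) -> dict[str, int]:
        out = {"AG": 0, "AC": 0, "AT": 0}
        if sub.empty:
            return out
        vc = sub["sense_alt"].value_counts()
        for alt, key in (("G", "AG"), ("C", "AC"), ("T", "AT")):
            out[key] = int(vc.get(alt, 0))
        return out

    return SiteClassCounts(
        edited_polymorphic=e_poly,
        edited_monomorphic=n_edited_total - e_poly,
        unedited_polymorphic=u_poly,
        unedited_monomorphic=n_unedited_total - u_poly,
        edited_types=type_counts(snps[is_edited]),
        unedited_types=type_counts(snps[~is_edited]),
    )


@dataclass
class SpectrumEstimate:
    bin_edges: np.ndarray
    edited_props: np.ndarray
    null_mean: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    n_resamples: int
    mean_shift: float


def _bin_freqs(freqs: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram on (0, 1]-style bins: right-closed so a frequency equal to
    an upper edge falls in the lower bin."""
    idx = np.ceil(freqs * (len(edges) - 1) / edges[-1]).astype(int) - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1)


def resampled_spectrum(
    edited_freqs: np.ndarray,
    unedited_freqs: np.ndarray,
    n_bins: int = 10,
    n_resamples: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> SpectrumEstimate:
    """Edited-site spectrum against a resampled unedited null with 95% band."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edited_freqs = np.asarray(edited_freqs, float)
    unedited_freqs = np.asarray(unedited_freqs, float)
    m, n = len(edited_freqs), len(unedited_freqs)
    if not 1 <= m <= n:
        raise ValueError("need |unedited| >= |edited| >= 1")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    edited_counts = _bin_freqs(edited_freqs, edges)
    colors = _bin_freqs(unedited_freqs, edges)
    draws = rng.multivariate_hypergeometric(colors, m, size=n_resamples)
    props = draws / m
    return SpectrumEstimate(
        bin_edges=edges,
        edited_props=edited_counts / m,
        null_mean=props.mean(axis=0),
        null_lo=np.percentile(props, 2.5, axis=0),
        null_hi=np.percentile(props, 97.5, axis=0),
        n_resamples=n_resamples,
        mean_shift=mean_shift(edited_freqs, unedited_freqs),
    )


def mean_shift(freqs_edited: np.ndarray, freqs_unedited: np.ndarray) -> float:
    """Difference of mean derived frequencies, edited − unedited."""
    if len(freqs_edited) == 0 or len(freqs_unedited) == 0:
        raise ValueError("empty frequency vector")
    return float(np.mean(freqs_edited) - np.mean(freqs_unedited))


def match_nearest_controls(
    edited: pd.DataFrame, candidates: pd.DataFrame
) -> pd.DataFrame:
    """For each edited site, the nearest same-chromosome candidate site.

    Distance ties are broken toward the downstream (larger-coordinate)
    candidate. Edited sites on chromosomes without candidates are returned
    unmatched (NaN distance) and logged.
    """
    rows = []
    cand_by_chrom = {c: g["pos"].to_numpy() for c, g in candidates.groupby("chrom")}
    n_unmatched = 0
    for row in edited.itertuples(index=False):
        pos_arr = cand_by_chrom.get(row.chrom)
        if pos_arr is None or len(pos_arr) == 0:
            rows.append((row.chrom, row.pos, np.nan, np.nan))
            n_unmatched += 1
            continue
        pos_arr = np.sort(pos_arr)
        i = np.searchsorted(pos_arr, row.pos)
        best, bdist = None, None
        for j in (i, i - 1):  # downstream candidate first: wins ties
            if 0 <= j < len(pos_arr):
                d = abs(int(pos_arr[j]) - row.pos)
                if bdist is None or d < bdist:
                    best, bdist = int(pos_arr[j]), d
        rows.append((row.chrom, row.pos, best, bdist))
    if n_unmatched:
        logger.warning("match_nearest_controls: %d sites unmatched", n_unmatched)
    return pd.DataFrame(rows, columns=["chrom", "pos", "control_pos", "distance"])


def compare_spectra(
    freqs_a: np.ndarray, freqs_b: np.ndarray, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) with normal approximation and tie
    correction. ``alternative``: two_sided or a_greater."""
    a = np.asarray(freqs_a, float)
    b = np.asarray(freqs_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        warnings.warn("all values tied; p = 1", stacklevel=2)
        return float(len(a) * len(b) / 2), 1.0
    alt = {"two_sided": "two-sided", "a_greater": "greater"}[alternative]
    res = stats.mannwhitneyu(a, b, alternative=alt, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def write_spectrum_tsv(spec: SpectrumEstimate, path) -> None:
    df = pd.DataFrame(
        {
            "bin_lo": spec.bin_edges[:-1],
            "bin_hi": spec.bin_edges[1:],
            "edited_prop": spec.edited_props,
            "null_mean": spec.null_mean,
            "null_lo": spec.null_lo,
            "null_hi": spec.null_hi,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
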