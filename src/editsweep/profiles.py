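"""Strand-aware nucleotide composition around edited sites with a resampled
genomic background band.

Minus-strand flanks are reverse-complemented before tallying, so offset −1
always reads "5′ of the edited A" regardless of genomic strand. Offset 0 is
reported as a sanity row (it is A by construction at genuine edit sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Genome, revcomp

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


@dataclass
class NucleotideProfile:
    offsets: np.ndarray                  # −flank..+flank
    fractions: pd.DataFrame              # index offset, columns A/C/G/T
    n_sites: int
    n_excluded: int = 0
    background_mean: pd.DataFrame | None = None
    background_lo: pd.DataFrame | None = None
    background_hi: pd.DataFrame | None = None
    n_resamples: int = 0


_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_TABLE[_a] = _b


def _tally(genome: Genome, sites: pd.DataFrame, flank: int
           ) -> tuple[np.ndarray, int, int]:
    """(counts[offset, base], n_used, n_excluded); − strand flanks flipped."""
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=np.int64)
    lengths = genome.lengths
    used = excluded = 0
    offsets = np.arange(-flank, flank + 1)
    for (chrom, strand), grp in sites.groupby(["chrom", "strand"], sort=True):
        arr = genome.char_array(chrom).view(np.uint8)
        pos = grp["pos"].to_numpy()
        ok = (pos - flank >= 0) & (pos + flank + 1 <= lengths[chrom])
        excluded += int((~ok).sum())
        pos = pos[ok]
        if len(pos) == 0:
            continue
        used += len(pos)
        block = arr[pos[:, None] + offsets[None, :]]  # (n, width)
        if strand == "-":
            block = _COMP_TABLE[block][:, ::-1]
        for i, b in enumerate(b"ACGT"):
            counts[:, i] += (block == b).sum(axis=0)
    return counts, used, excluded


def _to_frame(counts: np.ndarray, flank: int) -> pd.DataFrame:
    totals = counts.sum(axis=1, keepdims=True)
    frac = counts / np.maximum(totals, 1)
    return pd.DataFrame(frac, index=np.arange(-flank, flank + 1), columns=list(_BASES))


def site_profile(genome: Genome, sites: pd.DataFrame, flank: int) -> NucleotideProfile:
    """Foreground composition profile over strand-annotated sites."""
    if sites.empty:
        raise ValueError("empty site list")
    counts, used, excluded = _tally(genome, sites, flank)
    if excluded:
        logger.info("site_profile: %d sites too close to a contig end excluded",
                    excluded)
    if used == 0:
        raise ValueError("no site has a complete flank")
    return NucleotideProfile(
        offsets=np.arange(-flank, flank + 1),
        fractions=_to_frame(counts, flank),
        n_sites=used,
        n_excluded=excluded,
    )


def background_profile(
    genome: Genome,
    n_a_sites: int,
    n_t_sites: int,
    flank: int,
    n_resamples: int = 100,
    seed: int | np.random.Generator = 0,
    region_mask: pd.DataFrame | None = None,
) -> NucleotideProfile:
    """Null composition band from repeatedly sampling unannotated A sites
    (+ strand) and T sites (tallied as − strand), mirroring the strand mix of
    the annotated editome."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    a_pool: list[tuple[str, int]] = []
    t_pool: list[tuple[str, int]] = []
    for chrom in genome.chroms:
        arr = genome.char_array(chrom)
        allowed = None
        if region_mask is not None:
            allowed = np.zeros(len(arr), dtype=bool)
            sub = region_mask[region_mask["chrom"] == chrom]
            for r in sub.itertuples(index=False):
                allowed[r.start : r.end] = True
        for target, pool in ((b"A", a_pool), (b"T", t_pool)):
            pos = np.flatnonzero(arr == target)
            if allowed is not None:
                pos = pos[allowed[pos]]
            pool.extend((chrom, int(p)) for p in pos)
    if len(a_pool) < n_a_sites or len(t_pool) < n_t_sites:
        raise ValueError(
            f"insufficient background sites: {len(a_pool)} A (< {n_a_sites}) or "
            f"{len(t_pool)} T (< {n_t_sites})"
        )

    reps = []
    for _ in range(n_resamples):
        ai = rng.choice(len(a_pool), size=n_a_sites, replace=False)
        ti = rng.choice(len(t_pool), size=n_t_sites, replace=False)
        sites = pd.DataFrame(
            [(a_pool[i][0], a_pool[i][1], "+") for i in ai]
            + [(t_pool[i][0], t_pool[i][1], "-") for i in ti],
            columns=["chrom", "pos", "strand"],
        )
        counts, used, _ = _tally(genome, sites, flank)
        if used:
            reps.append(_to_frame(counts, flank).to_numpy())
    stack = np.stack(reps)
    offsets = np.arange(-flank, flank + 1)

    def frame(arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(arr, index=offsets, columns=list(_BASES))

    return NucleotideProfile(
        offsets=offsets,
        fractions=frame(stack.mean(axis=0)),
        n_sites=n_a_sites + n_t_sites,
        background_mean=frame(stack.mean(axis=0)),
        background_lo=frame(np.percentile(stack, 2.5, axis=0)),
        background_hi=frame(np.percentile(stack, 97.5, axis=0)),
        n_resamples=len(reps),
    )


def write_profile_tsv(
    fg: NucleotideProfile, bg: NucleotideProfile | None, path
) -> None:
    rows = []
    for off in fg.offsets:
        for b in _BASES:
            row = {
                "offset": off,
                "base": b,
                "foreground_frac": fg.fractions.loc[off, b],
            }
            if bg is not None:
                row["bg_mean"] = bg.background_mean.loc[off, b]
                row["bg_lo"] = bg.background_lo.loc[off, b]
                row["bg_hi"] = bg.background_hi.loc[off, b]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
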